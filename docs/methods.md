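# Methods

This note records the models implemented in dynsuite, the defaults and why
they were chosen, the numerical machinery, what the synthetic-data generator
does and does not emulate, and known limitations.

## Spin physics and constants

Relaxation of a backbone amide ¹⁵N is modelled as dipolar (¹⁵N–¹H) plus CSA,
with the Lipari–Szabo spectral density (simple form for M1–M4, extended
two-timescale form for M5) and isotropic overall tumbling — a single τc, no
rotational diffusion tensor. Angular frequencies enter J(ω) as magnitudes;
the negative ¹⁵N gyromagnetic ratio enters only through the γH/γN ratio in
the NOE expression. Rex adds to R2 only and is assumed field-independent in
magnitude at the reference field, scaling as B0² if fields are combined.

Default constants (all overridable via the YAML config or `SpinConstants`):

| quantity | default | unit |
|---|---|---|
| γH | 2.6752219×10⁸ | rad s⁻¹ T⁻¹ |
| γN | −2.7126×10⁷ | rad s⁻¹ T⁻¹ |
| r_NH | 1.02 | Å |
| Δσ (¹⁵N CSA) | −160 | ppm |
| field | 700 (B0 ≈ 16.44 T) | MHz |

These are the community-standard values for backbone amide work; results are
always reported alongside the constants used. The static dipolar splitting
constant implied by them, D_max = −(μ0ħγHγN)/(4π²r³) ≈ −22.95 kHz, is the
scale between Saupe elements and RDCs and is printed by the RDC fitter so
the convention travels with the numbers.

## τc estimation

Per residue, the rigid-limit (S² = 1, Rex = 0) R2/R1 ratio is inverted by a
1-D Brent root search on τc ∈ [0.5, 50] ns; that ratio is strictly
increasing in τc over the search window. Residues are excluded with recorded
reasons when:

* NOE < 0.65 — mobile residues whose R2/R1 is biased by internal motion;
* the ratio has no root in the window;
* the per-residue τc lies more than 1.5 SD from the mean (one trimming
  pass) — residues with unrecognised exchange broadening.

The estimate is the trimmed mean; its uncertainty is the SEM over retained
residues. The NOE cutoff and trimming width are exposed as options; the
defaults are conventional choices for single-field data rather than values
with a unique justification.

## Per-residue model-free fitting

With τc held fixed (two-stage procedure — keeps three-observable fits
identifiable and matches how single-field analyses are usually run), each
residue is fitted against

| model | free parameters | bounds |
|---|---|---|
| M1 | S² | [0, 1] |
| M2 | S², τe | τe ∈ [0, τc) |
| M3 | S², Rex | Rex ∈ [0, 50] s⁻¹ |
| M4 | S², τe, Rex | as above |
| M5 | Sf², S², τs | internally (Sf², Ss², τs) so S² ≤ Sf² is a box bound |

χ² = Σ[(obs−calc)/σ]² is minimised by bounded trust-region least squares
(scipy `least_squares`, xtol = ftol = gtol = 10⁻¹⁴) started from the best
point of a fixed 5-per-parameter grid, so fits are deterministic.
Correlation times are optimised in nanosecond units: with τe in seconds the
parameter scale differs from S² by nine orders of magnitude and the
finite-difference trust region stalls at the starting point.

**Model selection.** Candidates are ranked by the small-sample-corrected
information score AICc = χ² + 2k + 2k(k+1)/(n−k−1) whenever its correction
is defined for every non-saturated candidate (n > k+1). On single-field data
a residue contributes only n = 3 observables, where the correction term is
undefined already at k = 2; all candidates are then ranked by plain AIC
(χ² + 2k) so the ranking stays internally consistent. Saturated models
(k ≥ n: M4 and M5 on one field) are always fitted and reported, flagged
`saturated`, but score +∞ — with one exception: when the score winner still
fails a χ² goodness-of-fit test at the 5% level and a saturated model fits
acceptably, the saturated model is selected. This escape is what makes
residues carrying both internal motion and exchange identifiable at a single
field; without it their exchange is silently absorbed into inflated S²/τe
(measured exchange sensitivity on the packaged scenarios rises from ~0.5 to
1.0, with zero false positives, when it is enabled). Ties break toward fewer
parameters.

**Uncertainties.** Monte-Carlo: observables are resampled from
Normal(obs, σ_obs), the selected model refitted (warm-started at the best
fit), and the per-parameter SD reported; ≥100 draws are required and the
residue errors out if more than 20% of refits fail. Fixed seeds make the
SDs reproducible.

**Exchange classification.** A residue is labelled as undergoing ms-scale
conformational exchange iff fitted Rex strictly exceeds 2 s⁻¹.

## H/D exchange

Observed rates come from I(t) = I₀e^(−kt) fits with a fixed zero baseline
(fully exchanged amides vanish in D₂O); an optional baseline is deliberately
not fitted by default. Two degenerate regimes are handled explicitly:

* **censored** (too slow): if the fitted decay over the window is smaller
  than twice the intensity noise, the residue's rate is reported as the
  upper bound ln(1/0.95)/t_max — the largest rate compatible with <5% decay
  — and its PF as a lower bound. The 5% threshold is a declared detection
  limit, not a fitted quantity.
* **no signal** (too fast): if the peak never rises above twice the noise,
  the amide exchanged within the experimental dead time; the residue is
  flagged and no PF is reported.

Intrinsic rates use the reference-peptide approach: k_int = k_A[D⁺] +
k_B[OD⁻] + k_W, each term corrected by tabulated nearest-neighbour
side-chain factors (the residue's own λ plus its left neighbour's ρ, with
N-/C-terminal corrections) and Arrhenius temperature factors
(Ea = 14/17/19 kcal mol⁻¹ for acid/base/water) from the 293 K reference
(log₁₀ k ref = 1.62/10.05/−1.50 in M⁻¹min⁻¹ or min⁻¹; pK_D = 15.05).
Ionizable side chains are tabulated in their neutral-pH forms. The factor
table ships as plain text (`dynsuite/data/exchange_factors.tsv`) and was
transcribed from the standard literature tables; users needing
literature-exact absolute k_int should verify the bundled values against
their preferred source — all packaged round trips are insensitive to the
table because generator and analyser share it. The pD glass-electrode
correction (+0.4) is available behind a flag, off by default.

## CSP screening

Δδ = √(Δδ_H² + (αΔδ_N)²), α = 0.14 (0.20 for glycine). The null
distribution's μ and σ are estimated iteratively with exceedances removed;
"binding" requires ≥3 residues above μ + kσ with k = 4 by default. k = 4
rather than the Gaussian-habit 3 because the combined CSP is a folded,
Rayleigh-like variable: its upper tail is heavy relative to its SD, and
with ~200 probes a 3σ rule false-alarms on pure referencing noise in about
a third of screens, while 4σ holds the family-wise false-positive rate
below 5% and loses no sensitivity at binding-site perturbations ≥0.1 ppm.
At least 20 matched residues are required for a call.

## RDC tensor fitting

D_i = D_max u_iᵀSu_i is solved for the five independent Saupe elements by
SVD-based least squares (optionally σ-weighted). The design-matrix condition
number is checked and fits with cond > 10⁶ are rejected as orientationally
degenerate (e.g. collinear bond vectors). Eigenvalues are ordered
|Szz| ≥ |Syy| ≥ |Sxx|; Da = D_max·Szz/2 and R = (2/3)|Syy−Sxx|/|Szz| ∈
[0, 2/3]. All-zero couplings return the zero tensor with Q reported as NaN.
Extraction from IPAP splittings is D = aniso − iso with quadrature error
propagation and a sign-flip flag for inverted component assignment.

## Ensemble RMSD

RMSD_ab = √(Σ|x_a−x_b|²/n) over all N(N−1)/2 model pairs; mean ± SD is
reported with the superposition mode. Default is `none` — deposited NMR
families are already superimposed on their well-defined core, and a ligand
fragment's spread *in that frame* is the quantity usually quoted. Modes
`selection` (per-pair Kabsch fit on the measured atoms) and `reference`
(fit on a separate selection) are provided so both conventions can be
compared on deposited families. "Heavy" means non-H/D; the SAH/SAM
methionine fragment is defined as atoms N, CA, CB, CG, SD, C, O (+OXT when
present) and the adenosine fragment as the remaining heavy atoms — a
declared partition, since no unique convention exists. Alternative
locations resolve to the highest-occupancy conformer at read time.

## Synthetic data generator

The generator emulates the data shapes of a two-state dynamics study on a
244-residue single-domain protein at 700 MHz and 308 K:

* segments: tail 1–51, core 52–203 and 229–244, mobile loop 204–228;
* `apo` preset: tail S² ∈ [0.2, 0.5] with long τe (0.2–1.5 ns), τc = 12.5 ns;
* `complex` preset: tail S² ∈ [0.8, 0.95], τc = 10.4 ns;
* both: core S² ∈ [0.85, 0.95] (τe 20–100 ps), loop S² ∈ [0.5, 0.75] —
  the loop stays mobile in both states;
* residue-wise Rex ∈ [2.5, 8] s⁻¹ with segment-dependent probability
  (loop 0.30; tail/core 0.15/0.10 apo, 0.05 complex);
* noise: 2% fractional on R1/R2, 0.02 absolute on NOE — typical of careful
  single-field measurements;
* HDX: log₁₀PF per segment (apo tail 0–0.5, core 4–6, loop 0.5–1.5; complex
  tail 3–5, core 5–7), decays on a 10-point log grid from 5 min to 24 h at
  pH 7.0 with 2% intensity noise;
* CSP: null = referencing noise only (0.005/0.05 ppm ¹H/¹⁵N); site = five
  contiguous residues perturbed by 0.15 ppm combined, split at a random
  angle between the two axes;
* RDC: back-calculation from a fixed mildly rhombic Saupe tensor
  (|S| ~ 10⁻³) on N–H vectors of an idealised three-helix toy fold
  (15° cone around three orthogonal axes, 100°/residue phase advance),
  1 Hz noise.

All randomness flows through generators spawned from a single seed (one
independent stream per data type), so every output is bit-reproducible, and
every simulator accepts `noise_scale=0` for exact forward-model output with
nominal uncertainties retained.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: anisotropic tumbling and its τc/S² biases,
peak overlap and intensity-extraction error, baseline and phasing artefacts,
field-dependent Rex dispersion, EX1 exchange kinetics, proline-rich or
terminally frayed sequences beyond random placement, and correlated (rather
than independent Gaussian) measurement errors.

## Problem sizes

The packaged checks run per-residue fits on the full 244-residue scenarios
(about 6 s per preset on one CPU), 100-seed CSP calibrations, 500-draw
Monte-Carlo error estimates, and 50-vector tensor fits — sizes chosen so
the whole suite and the acceptance script each complete in minutes while
keeping Monte-Carlo assertions statistically comfortable.

## Known limitations

* Single-field R1/R2/NOE triples cannot uniquely identify three-parameter
  models; M4/M5 fits are exact by construction there and are only reachable
  through the goodness-of-fit escape. Multi-field input removes the
  restriction (n = 3 × fields) and switches selection to AICc throughout.
* τc is a trimmed-mean point estimate under isotropic tumbling; a protein
  with a long disordered tail violates the rigid-rotor premise, and the
  estimate should be read as an effective correlation time. Whether the
  reported uncertainty (SEM) matches any particular literature convention
  (SEM vs SD) is a reporting choice, stated in the output.
* Intrinsic-rate absolute accuracy is bounded by the bundled factor table
  (see above); PFs carry that systematic uncertainty on real data.
* The CSP screen detects coherent multi-residue perturbation; a genuine
  single-residue effect below ~3 hits will read "no specific binding" by
  design.
* The RDC module fits one medium at a time; cross-validation between media
  beyond comparing Q factors is out of scope.
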