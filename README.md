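# dynsuite

Protein NMR dynamics analysis in Python: Lipari–Szabo model-free
interpretation of backbone ¹⁵N relaxation, rotational-correlation-time
estimation, amide H/D-exchange protection factors, residual-dipolar-coupling
(RDC) alignment tensors, chemical-shift-perturbation (CSP) ligand screening,
and precision metrics for NMR structure ensembles.

The package is aimed at structural biologists characterising how a protein's
backbone dynamics change upon ligand binding — the canonical example being a
~26 kDa single-domain methyltransferase whose disordered N-terminal tail
becomes ordered when the cofactor product SAH occupies its binding site.
Every analysis stage is paired with a synthetic-data generator that emits the
same table formats with known ground truth, so the whole pipeline is testable
by parameter recovery.

## The models

**Spin relaxation.** The amide ¹⁵N nuclei relax through the ¹⁵N–¹H dipolar
interaction and ¹⁵N CSA, driven by the spectral density of N–H bond
reorientation. dynsuite uses the model-free form

```
J(ω) = (2/5) [ S²τc / (1 + (ωτc)²) + (1 − S²)τ / (1 + (ωτ)²) ],   τ⁻¹ = τc⁻¹ + τe⁻¹
```

with order parameter S² (1 = rigid), overall rotational correlation time τc
(isotropic tumbling), and effective internal correlation time τe; the
extended two-timescale form (Sf², S², τs) is available as model M5. Observed
rates follow the standard expressions

```
R1  = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c²J(ωN)
R2  = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)] + (c²/6)[4J(0) + 3J(ωN)] + Rex
NOE = 1 + (d²/4)(γH/γN)[6J(ωH+ωN) − J(ωH−ωN)] / R1
```

with the chemical-exchange term Rex entering R2 only. τc is estimated from
the R2/R1 ratio of rigid residues; each residue is then fitted against models
M1 {S²} … M5 {Sf², S², τs} with information-score selection and Monte-Carlo
uncertainties, and residues with Rex > 2 s⁻¹ are labelled as undergoing
ms-timescale conformational exchange.

**H/D exchange.** Peak intensities decay as I(t) = I₀e^(−k_obs·t); the
protection factor PF = k_int/k_obs compares the observed rate to the
intrinsic rate of an unstructured peptide (reference rates with
nearest-neighbour, pH/pD and temperature corrections). Residues with no
detectable decay are censored and reported as lower bounds.

**RDC.** Couplings D = D_max·uᵀSu are linear in the five independent
elements of the traceless Saupe matrix S; the tensor is fitted by SVD of the
orientation design matrix and summarised by the quality factor
Q = √(Σ(D_obs−D_calc)²/ΣD_obs²), Da and rhombicity.

**CSP.** Combined shifts Δδ = √(Δδ_H² + (α·Δδ_N)²) with α = 0.14 (0.20 for
glycine); binding is called when ≥3 residues exceed an iteratively estimated
μ + 4σ threshold.

**Ensemble precision.** Mean ± SD pairwise RMSD over all model pairs of an
NMR family for any atom selection, e.g.
`resname SAH and fragment met and heavy`, with optional per-pair or
reference-set superposition.

## Worked example

Generate a synthetic apo-state dataset (disordered tail, τc = 12.5 ns) and
analyse it:

```
$ dynsuite --seed 1 simulate --preset apo --out demo
wrote synthetic 'apo' dataset (seed 1) to demo/

$ dynsuite tauc demo/relaxation.tsv
tau_c = 12.446 +/- 0.043 ns (142 residues)
  excluded residue 1: NOE below cutoff
  ...
```

The estimate recovers the generating value (12.5 ns) within 0.5%; tail
residues are excluded automatically by the NOE cutoff. The full model-free
analysis, from Python:

```python
from dynsuite import ModelFreeAnalysis, read_table

table = read_table("demo/relaxation.tsv", "relaxation")
mfa = ModelFreeAnalysis(models=("M1", "M2", "M3", "M4")).fit(table)
print(f"tau_c = {mfa.tauc_.tau_c_ns:.2f} ns")
print(mfa.results_[["res_num", "model", "s2", "tau_e_ps", "rex", "exchange"]]
      .iloc[[0, 1, 60, 61, 210]].to_string(index=False))
```

```
tau_c = 12.45 ns
 res_num model    s2  tau_e_ps   rex  exchange
       1    M4 0.290   967.646 1.240     False
       2    M2 0.525    60.171 0.000     False
      61    M2 0.857    52.338 0.000     False
      62    M2 0.920    74.762 0.000     False
     211    M2 0.662   486.028 0.000     False
```

Tail residues (1–51) come out with low S² and long τe — high-amplitude
sub-ns motion — while core residues sit near S² ≈ 0.9; residue 211 lies in
the mobile loop. The CSP screen on the same dataset's null shift tables
reads `no specific binding`, and the RDC fit reports the Saupe tensor with
its Q factor and the D_max convention used:

```
$ dynsuite csp demo/shifts_apo.tsv demo/shifts_holo.tsv
verdict: no specific binding (1 residue(s) above 0.0247 ppm)

$ dynsuite rdc fit demo/rdc.tsv --vectors demo/nh_vectors.tsv
Q factor      : 0.1235
Da            : -11.513 Hz
rhombicity    : 0.1273
D_max         : -22954.7 Hz
```

Ensemble precision of a deposited NMR family (multi-model PDB/mmCIF):

```
dynsuite rmsd 7QCB.pdb --select "resname SAH and fragment met and heavy" --both-modes
```

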