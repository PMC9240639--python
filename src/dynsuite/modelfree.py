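"""Per-residue model-free dynamics inference from ¹⁵N R1/R2/NOE.

Two-stage procedure, as is standard for single-field backbone relaxation data:

1. the overall rotational correlation time tau_c is estimated from the
   R2/R1 ratio of rigid residues (NOE above a cutoff, ratio outliers trimmed),
   by inverting the rigid-limit ratio residue by residue and averaging;
2. with tau_c held fixed, each residue is fitted against the candidate
   Lipari-Szabo models M1 {S²}, M2 {S², te}, M3 {S², Rex}, M4 {S², te, Rex}
   and M5 {Sf², S², ts}; the model minimising the small-sample-corrected
   information score AICc = chi² + 2k + 2k(k+1)/(n-k-1) is selected, with
   ties broken toward fewer parameters.

On single-field data a residue contributes n = 3 observables, so M4 and M5
are saturated (k = n) and the AICc correction is undefined (it is already
undefined at k = 2, n = 3); such residues are ranked by plain AIC instead,
with saturated models still fitted and reported (flagged "saturated") but
given an infinite selection score. With two or more fields all models
compete by AICc. Rex is treated as field-independent in magnitude at the
reference field and scaled as B0² when combining fields.

Parameter uncertainties come from Monte-Carlo resampling of the observables
within their measurement errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .spin import (
    MODEL_PARAMS,
    DynamicsParams,
    SpinConstants,
    predict_rates,
    rates_grid,
)

__all__ = [
    "TaucEstimate",
    "FitResult",
    "TumblingTimeEstimator",
    "ModelFreeAnalysis",
    "estimate_tauc",
    "fit_residue",
    "select_model",
    "monte_carlo_errors",
    "classify_exchange",
    "rigid_r2_over_r1",
]

REX_MAX = 50.0  # s^-1, upper fit bound
_LS_OPTS = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)


@dataclass
class TaucEstimate:
    tau_c: float  # seconds
    tau_c_err: float  # SEM over retained residues, seconds
    n_residues_used: int
    excluded_residues: pd.DataFrame  # columns: res_num, reason
    per_residue: pd.DataFrame | None = None  # res_num, tau_c_ns for retained residues

    @property
    def tau_c_ns(self) -> float:
        return self.tau_c * 1e9


@dataclass
class FitResult:
    params: DynamicsParams
    chi2: float
    n_obs: int
    n_par: int
    errors: dict = dc_field(default_factory=dict)
    flags: list = dc_field(default_factory=list)
    success: bool = True

    @property
    def aic(self) -> float:
        """Plain information score chi² + 2k; +inf for failed or saturated fits."""
        k, n = self.n_par, self.n_obs
        if not self.success or not math.isfinite(self.chi2) or k >= n:
            return math.inf
        return self.chi2 + 2 * k

    @property
    def aicc(self) -> float:
        """chi² + 2k + 2k(k+1)/(n-k-1); +inf when the correction is undefined."""
        k, n = self.n_par, self.n_obs
        if not self.success or not math.isfinite(self.chi2):
            return math.inf
        if n - k - 1 <= 0:
            return math.inf
        return self.chi2 + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def rigid_r2_over_r1(tau_c: float, const: SpinConstants) -> float:
    """R2/R1 of a rigid (S²=1, Rex=0) residue tumbling with tau_c."""
    r = predict_rates(DynamicsParams(s2=1.0, tau_c=tau_c, model="M1"), const)
    return r.R2 / r.R1


def _tauc_from_ratio(ratio: float, const: SpinConstants, lo: float, hi: float) -> float | None:
    f = lambda tc: rigid_r2_over_r1(tc, const) - ratio
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return None
    return brentq(f, lo, hi, xtol=1e-15)


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"relaxation table is missing column(s) {missing}")


class TumblingTimeEstimator(BaseEstimator):
    """Overall rotational correlation time from the R2/R1 ratio of rigid residues.

    Residues with NOE below `noe_cutoff` (mobile) are excluded, the rigid-limit
    ratio is inverted per residue by a 1-D root search on
    [tau_min_ns, tau_max_ns], per-residue values more than `trim_sd` standard
    deviations from the mean are trimmed, and the trimmed mean +/- SEM is
    reported.

    Fitted attributes: ``tau_c_`` (s), ``tau_c_err_`` (s), ``n_used_``,
    ``excluded_`` (DataFrame of residue/reason), ``estimate_``.
    """

    def __init__(
        self,
        noe_cutoff: float = 0.65,
        trim_sd: float = 1.5,
        tau_min_ns: float = 0.5,
        tau_max_ns: float = 50.0,
        constants: SpinConstants | None = None,
    ):
        self.noe_cutoff = noe_cutoff
        self.trim_sd = trim_sd
        self.tau_min_ns = tau_min_ns
        self.tau_max_ns = tau_max_ns
        self.constants = constants

    def fit(self, X: pd.DataFrame, y=None) -> "TumblingTimeEstimator":
        df = pd.DataFrame(X)
        _require_columns(df, ["res_num", "R1", "R2", "NOE"])
        excluded: list[tuple[int, str]] = []
        per_res: list[tuple[int, float]] = []
        lo, hi = self.tau_min_ns * 1e-9, self.tau_max_ns * 1e-9
        for res_num, grp in df.groupby("res_num", sort=True):
            row = grp.iloc[0]
            const = self._constants_for(row)
            if not np.isfinite([row.R1, row.R2, row.NOE]).all():
                excluded.append((int(res_num), "missing data"))
                continue
            if row.NOE < self.noe_cutoff:
                excluded.append((int(res_num), "NOE below cutoff"))
                continue
            tc = _tauc_from_ratio(row.R2 / row.R1, const, lo, hi)
            if tc is None:
                excluded.append((int(res_num), "ratio outside search window"))
                continue
            per_res.append((int(res_num), tc))
        if not per_res:
            raise ValueError("no rigid residues available for tumbling estimate")
        nums = np.array([p[0] for p in per_res])
        vals = np.array([p[1] for p in per_res])
        mean, sd = vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0
        keep = np.abs(vals - mean) <= self.trim_sd * sd if sd > 0 else np.ones_like(vals, bool)
        for rn in nums[~keep]:
            excluded.append((int(rn), "ratio outlier"))
        vals, nums = vals[keep], nums[keep]
        self.tau_c_ = float(vals.mean())
        self.tau_c_err_ = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        self.n_used_ = int(len(vals))
        self.excluded_ = pd.DataFrame(excluded, columns=["res_num", "reason"])
        self.estimate_ = TaucEstimate(
            tau_c=self.tau_c_,
            tau_c_err=self.tau_c_err_,
            n_residues_used=self.n_used_,
            excluded_residues=self.excluded_,
            per_residue=pd.DataFrame({"res_num": nums, "tau_c_ns": vals * 1e9}),
        )
        return self

    def _constants_for(self, row) -> SpinConstants:
        const = self.constants or SpinConstants()
        if "field_MHz" in row and np.isfinite(row.field_MHz):
            const = const.with_field(float(row.field_MHz))
        return const


def estimate_tauc(
    records: pd.DataFrame,
    const: SpinConstants | None = None,
    noe_cutoff: float = 0.65,
    trim_sd: float = 1.5,
) -> TaucEstimate:
    """Functional wrapper around :class:`TumblingTimeEstimator`."""
    est = TumblingTimeEstimator(noe_cutoff=noe_cutoff, trim_sd=trim_sd, constants=const)
    return est.fit(records).estimate_


# ---------------------------------------------------------------------------
# per-residue fitting

_S2_STARTS = np.array([0.2, 0.5, 0.7, 0.85, 0.95])
_TAUE_STARTS = np.array([0.0, 10e-12, 50e-12, 200e-12, 1e-9])
_TAUS_STARTS = np.array([50e-12, 200e-12, 500e-12, 1e-9, 2e-9])
_REX_STARTS = np.array([0.0, 1.0, 3.0, 8.0, 20.0])


_NS = 1e-9  # internal correlation times are optimised in ns for conditioning


def _model_setup(model_id: str, tau_c: float):
    """Start grid, bounds, scale and parameter names for one model.

    M5 is parameterised internally as (sf2, ss2, tau_s) so the constraint
    s2 = sf2*ss2 <= sf2 is a box bound. `scale` converts the optimiser's
    parameter vector to physical units (times in seconds).
    """
    te_hi = tau_c * 0.999
    if model_id == "M1":
        names, lo, hi, scale = ("s2",), [0.0], [1.0], [1.0]
        grids = [_S2_STARTS]
    elif model_id == "M2":
        names, lo, hi, scale = ("s2", "tau_e"), [0.0, 0.0], [1.0, te_hi / _NS], [1.0, _NS]
        grids = [_S2_STARTS, np.clip(_TAUE_STARTS, 0, te_hi) / _NS]
    elif model_id == "M3":
        names, lo, hi, scale = ("s2", "rex"), [0.0, 0.0], [1.0, REX_MAX], [1.0, 1.0]
        grids = [_S2_STARTS, _REX_STARTS]
    elif model_id == "M4":
        names = ("s2", "tau_e", "rex")
        lo, hi, scale = [0.0, 0.0, 0.0], [1.0, te_hi / _NS, REX_MAX], [1.0, _NS, 1.0]
        grids = [_S2_STARTS, np.clip(_TAUE_STARTS, 0, te_hi) / _NS, _REX_STARTS]
    elif model_id == "M5":
        names = ("sf2", "ss2", "tau_s")
        lo, hi, scale = [0.0, 0.0, 0.0], [1.0, 1.0, te_hi / _NS], [1.0, 1.0, _NS]
        grids = [_S2_STARTS, _S2_STARTS, np.clip(_TAUS_STARTS, 0, te_hi) / _NS]
    else:
        raise ValueError(f"unknown model '{model_id}', expected one of {list(MODEL_PARAMS)}")
    return names, np.array(lo), np.array(hi), np.array(scale), grids


def _obs_arrays(record: pd.DataFrame | pd.Series, const: SpinConstants):
    """Flatten one residue's rows into observation/sigma arrays per field."""
    if isinstance(record, pd.Series):
        record = record.to_frame().T
    _require_columns(record, ["R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"])
    consts, obs, sig = [], [], []
    for _, row in record.iterrows():
        c = const.with_field(float(row.field_MHz)) if "field_MHz" in row and np.isfinite(row.get("field_MHz", np.nan)) else const
        for col, err in (("R1", "R1_err"), ("R2", "R2_err"), ("NOE", "NOE_err")):
            if row[err] <= 0:
                raise ValueError(f"non-positive uncertainty in column {err}")
        consts.append(c)
        obs.append([row.R1, row.R2, row.NOE])
        sig.append([row.R1_err, row.R2_err, row.NOE_err])
    return consts, np.array(obs), np.array(sig)


def _theta_to_params(theta, names, tau_c, model_id) -> DynamicsParams:
    d = dict(zip(names, theta))
    if model_id == "M5":
        return DynamicsParams(
            s2=d["sf2"] * d["ss2"], tau_c=tau_c, tau_s=d["tau_s"], sf2=d["sf2"], model="M5"
        )
    return DynamicsParams(
        s2=d["s2"], tau_c=tau_c, tau_e=d.get("tau_e", 0.0), rex=d.get("rex", 0.0), model=model_id
    )


def _rates_fast(s2_slow, amp_fast, tau_fast, rex, tau_c, const: SpinConstants):
    """Scalar fast path of the forward model (no dataclass construction)."""
    from .spin import _lorentzian_mix, _rates_from_j, relaxation_frequencies

    w = relaxation_frequencies(const)  # 0, wN, wH-wN, wH, wH+wN
    j = _lorentzian_mix(s2_slow, amp_fast, tau_fast, tau_c, w)
    return _rates_from_j(j[0], j[1], j[3], j[2], j[4], rex, const)


def _residuals(theta, names, scale, tau_c, model_id, consts, obs, sig):
    d = dict(zip(names, theta * scale))
    if model_id == "M5":
        s2 = d["sf2"] * d["ss2"]
        amp, tf, rex = d["sf2"] - s2, d["tau_s"], 0.0
    else:
        s2 = d["s2"]
        amp, tf, rex = 1.0 - s2, d.get("tau_e", 0.0), d.get("rex", 0.0)
    tau_fast = tf * tau_c / (tf + tau_c) if tf > 0 else 0.0
    b0_ref = consts[0].B0
    out = np.empty_like(obs)
    for i, c in enumerate(consts):
        rex_i = rex * (c.B0 / b0_ref) ** 2
        r1, r2, noe = _rates_fast(s2, amp, tau_fast, rex_i, tau_c, c)
        out[i] = [r1, r2, noe]
    return ((out - obs) / sig).ravel()


def _grid_chi2(names, grids, scale, tau_c, model_id, consts, obs, sig):
    """chi² over the full start grid, vectorized per field; returns best theta
    (in optimiser units)."""
    mesh = np.meshgrid(*grids, indexing="ij")
    flat = [m.ravel() for m in mesh]
    d = dict(zip(names, [f * s for f, s in zip(flat, scale)]))
    chi2 = np.zeros_like(flat[0])
    b0_ref = consts[0].B0
    for i, c in enumerate(consts):
        if model_id == "M5":
            r1, r2, noe = rates_grid(
                d["sf2"] * d["ss2"], 0.0, 0.0, tau_c, c, sf2=d["sf2"], tau_s=d["tau_s"]
            )
        else:
            rex = d.get("rex", np.zeros_like(flat[0])) * (c.B0 / b0_ref) ** 2
            r1, r2, noe = rates_grid(d["s2"], d.get("tau_e", 0.0), rex, tau_c, c)
        chi2 += ((r1 - obs[i, 0]) / sig[i, 0]) ** 2
        chi2 += ((r2 - obs[i, 1]) / sig[i, 1]) ** 2
        chi2 += ((noe - obs[i, 2]) / sig[i, 2]) ** 2
    best = int(np.argmin(chi2))
    return np.array([f[best] for f in flat])


def fit_residue(
    record: pd.DataFrame | pd.Series,
    tau_c: float,
    model_id: str,
    const: SpinConstants | None = None,
    start: np.ndarray | None = None,
) -> FitResult:
    """Fit one residue's relaxation data with a fixed Lipari-Szabo model.

    `record` holds the residue's rows (one per field). tau_c (seconds) is held
    fixed. A deterministic multi-start grid precedes bounded least-squares
    refinement unless an explicit `start` vector is given.
    """
    const = const or SpinConstants()
    names, lo, hi, scale, grids = _model_setup(model_id, tau_c)
    consts, obs, sig = _obs_arrays(record, const)
    n_obs, n_par = obs.size, len(names)
    flags = []
    if n_par >= n_obs:
        flags.append("saturated")
    if start is not None:
        theta0 = np.asarray(start, dtype=float) / scale  # physical -> fit units
    else:
        theta0 = _grid_chi2(names, grids, scale, tau_c, model_id, consts, obs, sig)
    theta0 = np.clip(theta0, lo, hi)
    try:
        sol = least_squares(
            _residuals, theta0, bounds=(lo, hi),
            args=(names, scale, tau_c, model_id, consts, obs, sig), **_LS_OPTS,
        )
        success = sol.status > 0
        theta, chi2 = sol.x, float(2 * sol.cost)
    except Exception:
        success = False
        theta, chi2 = np.full(n_par, np.nan), math.nan
    if not success:
        flags.append("non-convergence")
        params = DynamicsParams(s2=math.nan, tau_c=tau_c, model=model_id)
        return FitResult(params, math.nan, n_obs, n_par, flags=flags, success=False)
    params = _theta_to_params(theta * scale, names, tau_c, model_id)
    return FitResult(params, chi2, n_obs, n_par, flags=flags, success=True)


def select_model(fits: dict[str, FitResult]) -> str | None:
    """Pick the lowest-information-score model; ties go to fewer parameters.

    The small-sample-corrected AICc is used whenever its correction term is
    defined for every non-saturated candidate (n > k+1); otherwise — notably
    on single-field data, where a residue contributes only n = 3 observables —
    all candidates are compared by plain AIC so the ranking stays consistent.
    Saturated fits (k >= n) score +inf and are auto-selected only through the
    goodness-of-fit escape: when the information-score winner still fails a
    chi² test at the 5% level (its data genuinely need more parameters, e.g. a
    residue with both internal motion and exchange seen at a single field) and
    a saturated model fits acceptably, the saturated model is taken instead.
    Returns None when every candidate fit failed.
    """
    if len(fits) < 2:
        raise ValueError("need at least two candidate models to select among")
    usable = {m: f for m, f in fits.items() if f.n_par < f.n_obs}
    use_aicc = all(f.n_obs - f.n_par - 1 >= 1 for f in usable.values()) and usable
    score = (lambda f: f.aicc) if use_aicc else (lambda f: f.aic)
    ranked = sorted(
        fits.items(), key=lambda kv: (round(score(kv[1]), 10), kv[1].n_par, kv[0])
    )
    best_id, best = ranked[0]
    if not best.success or not math.isfinite(best.chi2):
        return None
    if math.isinf(score(best)):
        # only saturated/failed candidates: fall back to lowest chi2 among successes
        ok = [(m, f) for m, f in fits.items() if f.success and math.isfinite(f.chi2)]
        if not ok:
            return None
        ok.sort(key=lambda kv: (kv[1].chi2, kv[1].n_par, kv[0]))
        return ok[0][0]
    dof = best.n_obs - best.n_par
    if dof > 0 and best.chi2 > chi2_dist.ppf(0.95, dof):
        saturated = sorted(
            ((m, f) for m, f in fits.items()
             if f.success and f.n_par >= f.n_obs and math.isfinite(f.chi2)),
            key=lambda kv: (kv[1].chi2, kv[1].n_par, kv[0]),
        )
        if saturated and saturated[0][1].chi2 < best.chi2:
            return saturated[0][0]
    return best_id


def monte_carlo_errors(
    record: pd.DataFrame | pd.Series,
    fit: FitResult,
    n_draws: int = 500,
    seed: int | np.random.Generator = 0,
    const: SpinConstants | None = None,
    max_fail_frac: float = 0.2,
) -> dict[str, float]:
    """Monte-Carlo parameter uncertainties for a converged fit.

    Draws `n_draws` synthetic datasets from Normal(obs, sigma_obs), refits the
    selected model (warm-started at the best-fit parameters), and returns the
    per-parameter standard deviation. Reproducible for a fixed seed.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    if not fit.success:
        raise ValueError("cannot propagate errors through a failed fit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    const = const or SpinConstants()
    if isinstance(record, pd.Series):
        record = record.to_frame().T
    model_id = fit.params.model
    names, lo, hi, scale, _ = _model_setup(model_id, fit.params.tau_c)
    if model_id == "M5":
        sf2 = fit.params.sf2 if fit.params.sf2 is not None else 1.0
        ss2 = fit.params.s2 / sf2 if sf2 > 0 else 0.0
        start = np.array([sf2, ss2, fit.params.tau_s or 0.0])
    else:
        start = np.array(
            [getattr(fit.params, n) for n in names]
        )
    draws = {n: [] for n in ("s2", "tau_e", "rex", "sf2", "tau_s")}
    n_fail = 0
    res_label = record.iloc[0].get("res_num", "?")
    for _ in range(n_draws):
        noisy = record.copy()
        for col, err in (("R1", "R1_err"), ("R2", "R2_err"), ("NOE", "NOE_err")):
            noisy[col] = rng.normal(record[col].to_numpy(float), record[err].to_numpy(float))
        f = fit_residue(noisy, fit.params.tau_c, model_id, const,
                        start=np.clip(start / scale, lo, hi) * scale)
        if not f.success:
            n_fail += 1
            continue
        p = f.params
        draws["s2"].append(p.s2)
        draws["tau_e"].append(p.tau_e)
        draws["rex"].append(p.rex)
        draws["sf2"].append(p.sf2 if p.sf2 is not None else np.nan)
        draws["tau_s"].append(p.tau_s if p.tau_s is not None else np.nan)
    if n_fail > max_fail_frac * n_draws:
        raise RuntimeError(
            f"Monte-Carlo error estimation failed for residue {res_label}: "
            f"{n_fail}/{n_draws} refits did not converge"
        )
    free = MODEL_PARAMS[model_id]
    out = {}
    for name in ("s2", "tau_e", "rex", "sf2", "tau_s"):
        vals = np.asarray(draws[name], float)
        if name in free or (model_id == "M5" and name in ("s2", "sf2", "tau_s")):
            out[f"{name}_err"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
        else:
            out[f"{name}_err"] = 0.0
    return out


def classify_exchange(rex, threshold: float = 2.0):
    """Label residues undergoing ms-timescale conformational exchange.

    A residue is in exchange iff its fitted Rex strictly exceeds `threshold`
    (default 2 s^-1). Accepts a scalar, array, or Series; returns bool(s).
    """
    arr = np.asarray(rex, dtype=float)
    lab = arr > threshold
    return bool(lab) if arr.ndim == 0 else lab


DEFAULT_MODELS = ("M1", "M2", "M3", "M4", "M5")


class ModelFreeAnalysis(BaseEstimator):
    """Full per-residue model-free analysis of a relaxation table.

    Estimates tau_c (unless given), fits each residue with every candidate
    model, selects by AICc, optionally attaches Monte-Carlo uncertainties,
    and labels conformational exchange.

    Fitted attributes: ``tauc_`` (:class:`TaucEstimate` or None when tau_c was
    supplied), ``results_`` (per-residue DataFrame), ``constants_``.
    """

    def __init__(
        self,
        tau_c: float | None = None,
        models: tuple = DEFAULT_MODELS,
        mc_draws: int = 0,
        seed: int | None = 0,
        rex_threshold: float = 2.0,
        noe_cutoff: float = 0.65,
        trim_sd: float = 1.5,
        constants: SpinConstants | None = None,
    ):
        self.tau_c = tau_c
        self.models = models
        self.mc_draws = mc_draws
        self.seed = seed
        self.rex_threshold = rex_threshold
        self.noe_cutoff = noe_cutoff
        self.trim_sd = trim_sd
        self.constants = constants

    def fit(self, X: pd.DataFrame, y=None) -> "ModelFreeAnalysis":
        df = pd.DataFrame(X)
        _require_columns(df, ["res_num", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"])
        const = self.constants or SpinConstants()
        if "field_MHz" in df.columns and df["field_MHz"].notna().any():
            const = const.with_field(float(df["field_MHz"].dropna().iloc[0]))
        if self.tau_c is None:
            self.tauc_ = estimate_tauc(df, const, self.noe_cutoff, self.trim_sd)
            tau_c = self.tauc_.tau_c
        else:
            self.tauc_ = None
            tau_c = float(self.tau_c)
        rng = np.random.default_rng(self.seed)
        rows = []
        for res_num, grp in df.groupby("res_num", sort=True):
            complete = grp.dropna(subset=["R1", "R2", "NOE"])
            row_out = {
                "res_num": int(res_num),
                "res_name": grp.iloc[0].get("res_name", ""),
                "tau_c_ns": tau_c * 1e9,
            }
            if complete.empty:
                row_out.update(model=None, flags="missing data")
                rows.append(row_out)
                continue
            fits = {m: fit_residue(complete, tau_c, m, const) for m in self.models}
            best_id = select_model(fits) if len(fits) > 1 else next(iter(fits))
            if best_id is None:
                row_out.update(model=None, flags="unassigned")
                rows.append(row_out)
                continue
            best = fits[best_id]
            errs = {}
            if self.mc_draws:
                try:
                    errs = monte_carlo_errors(
                        complete, best, n_draws=self.mc_draws, seed=rng, const=const
                    )
                except RuntimeError:
                    best.flags.append("mc-failed")
            p = best.params
            row_out.update(
                model=best_id,
                s2=p.s2,
                s2_err=errs.get("s2_err", np.nan),
                tau_e_ps=p.tau_e * 1e12,
                tau_e_err_ps=errs.get("tau_e_err", np.nan) * 1e12 if errs else np.nan,
                rex=p.rex,
                rex_err=errs.get("rex_err", np.nan),
                sf2=p.sf2,
                tau_s_ps=(p.tau_s or 0.0) * 1e12 if p.tau_s is not None else np.nan,
                chi2=best.chi2,
                exchange=classify_exchange(p.rex, self.rex_threshold),
                flags=";".join(best.flags),
            )
            rows.append(row_out)
        self.results_ = pd.DataFrame(rows)
        self.constants_ = const
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).results_
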