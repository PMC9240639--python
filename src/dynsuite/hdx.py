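"""Amide hydrogen/deuterium exchange: observed rates, intrinsic rates, protection factors.

A residue's amide proton exchanges with solvent deuterons at an observed rate
k_obs extracted from the mono-exponential decay of its HSQC peak intensity,

    I(t) = I0 * exp(-k_obs * t),

with a fixed zero baseline (a fully exchanged amide is invisible in D2O).
The intrinsic rate k_int is the rate the same amide would show in an
unstructured peptide, predicted from reference rates with nearest-neighbour
side-chain, pH/pD and temperature corrections:

    k_int = k_A * [D+] * 10^(AL(i) + AR(i-1))
          + k_B * [OD-] * 10^(BL(i) + BR(i-1))
          + k_W * 10^(BL(i) + BR(i-1))

each term Arrhenius-scaled from the 293 K reference. The protection factor

    PF = k_int / k_obs

measures how much structure (hydrogen bonding, burial) slows exchange;
log10 PF is the conventional reporting scale. Residues whose decay over the
observation window is below detection are censored: their PF is a lower
bound computed from the largest rate compatible with <5% decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "HDXSeries",
    "PFResult",
    "intrinsic_rate",
    "intrinsic_rates",
    "fit_exchange_rate",
    "protection_factor",
    "compare_states",
    "ExchangeRateFit",
    "ProtectionFactorAnalysis",
    "CENSOR_DECAY_FRACTION",
]

R_GAS_KCAL = 1.987204e-3  # kcal mol^-1 K^-1
T_REF = 293.0  # K, reference temperature of the rate tables

# reference rates for the unstructured-peptide standard, log10, min^-1 units
# (acid and base terms are second order: per M of D+ / OD-)
LOG_KA_REF = 1.62
LOG_KB_REF = 10.05
LOG_KW_REF = -1.50
PKD = 15.05  # ion product of D2O at the reference temperature
EA_ACID = 14.0  # kcal/mol
EA_BASE = 17.0
EA_WATER = 19.0

#: below this fractional decay over the run a residue is considered
#: non-exchanging within detection and its rate is censored
CENSOR_DECAY_FRACTION = 0.05

_SECONDS = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0}


def _load_factors() -> pd.DataFrame:
    with resources.files("dynsuite.data").joinpath("exchange_factors.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col="res")


_FACTORS = _load_factors()


@dataclass
class HDXSeries:
    """One residue's peak-intensity decay."""

    residue_number: int
    times: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray
    intensity_err: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensity_err is not None:
            self.intensity_err = np.asarray(self.intensity_err, dtype=float)
        if len(self.times) < 3:
            raise ValueError(
                f"residue {self.residue_number}: need >=3 time points, got {len(self.times)}"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"residue {self.residue_number}: times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError(f"residue {self.residue_number}: negative intensities")


@dataclass
class PFResult:
    residue_number: int
    k_obs: float  # s^-1 (upper bound when censored)
    k_obs_err: float
    k_int: float  # s^-1
    pf: float  # lower bound when censored
    log10_pf: float
    censored: bool = False
    flags: str = ""


def _site_factors(sequence: str, position: int) -> tuple[float, float]:
    """Summed acid and base log-factors for the amide of `position` (1-based)."""
    seq = sequence.upper()
    n = len(seq)
    if position < 2 or position > n:
        raise ValueError(
            f"position {position} has no backbone amide in a {n}-residue chain"
        )
    res, left = seq[position - 1], seq[position - 2]
    for code in (res, left):
        if code not in _FACTORS.index or code in ("NT", "CT"):
            raise ValueError(f"unknown residue code '{code}'")
    if res == "P":
        raise ValueError(f"residue {position} is proline: no exchangeable amide proton")
    acid = _FACTORS.at[res, "acid_lambda"] + _FACTORS.at[left, "acid_rho"]
    base = _FACTORS.at[res, "base_lambda"] + _FACTORS.at[left, "base_rho"]
    if position == 2:  # left neighbour carries the free N-terminal amine
        acid += _FACTORS.at["NT", "acid_rho"]
        base += _FACTORS.at["NT", "base_rho"]
    if position == n:  # C-terminal carboxylate on the residue itself
        acid += _FACTORS.at["CT", "acid_lambda"]
        base += _FACTORS.at["CT", "base_lambda"]
    return acid, base


def intrinsic_rate(
    sequence: str,
    position: int,
    pH: float,
    temperature_K: float,
    pd_correction: bool = False,
) -> float:
    """Intrinsic (unstructured-peptide) exchange rate of one amide, in s^-1.

    `position` is 1-based along `sequence` (one-letter codes). `pH` is the
    measured pH; with ``pd_correction=True`` the glass-electrode offset for
    D2O solutions is applied (pD = pH_read + 0.4).
    """
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    pD = pH + 0.4 if pd_correction else pH
    acid, base = _site_factors(sequence, position)
    arr = lambda ea: math.exp(ea / R_GAS_KCAL * (1.0 / T_REF - 1.0 / temperature_K))
    k_acid = 10.0 ** (LOG_KA_REF + acid) * 10.0 ** (-pD) * arr(EA_ACID)
    k_base = 10.0 ** (LOG_KB_REF + base) * 10.0 ** (pD - PKD) * arr(EA_BASE)
    k_water = 10.0 ** (LOG_KW_REF + base) * arr(EA_WATER)
    return (k_acid + k_base + k_water) / 60.0  # table rates are per minute


def intrinsic_rates(
    sequence: str, pH: float, temperature_K: float, pd_correction: bool = False
) -> pd.Series:
    """Intrinsic rates (s^-1) for every amide-bearing position of `sequence`."""
    out = {}
    for pos in range(2, len(sequence) + 1):
        if sequence[pos - 1].upper() == "P":
            continue
        out[pos] = intrinsic_rate(sequence, pos, pH, temperature_K, pd_correction)
    return pd.Series(out, name="k_int")


class ExchangeRateFit(BaseEstimator):
    """Mono-exponential decay fit I(t) = I0 exp(-k t) with zero baseline.

    Fitted attributes: ``k_``, ``k_err_`` (s^-1), ``i0_``, ``censored_``,
    ``k_bound_`` (largest rate compatible with <5% decay; only meaningful
    when censored).
    """

    def __init__(self, censor_decay: float = CENSOR_DECAY_FRACTION):
        self.censor_decay = censor_decay

    def fit(self, t, intensity, intensity_err=None) -> "ExchangeRateFit":
        t = np.asarray(t, dtype=float)
        y = np.asarray(intensity, dtype=float)
        if len(t) < 3:
            raise ValueError("need at least 3 time points")
        if not np.any(y > 0):
            raise ValueError("no positive intensities: nothing to fit")
        sigma = None if intensity_err is None else np.asarray(intensity_err, dtype=float)
        if sigma is not None and float(np.max(y)) < 2.0 * float(np.mean(sigma)):
            # peak never rises above the noise: exchange completed before the
            # first time point (dead time), not a protected residue
            raise ValueError("no signal above noise: exchanged within dead time")
        i0_guess = float(np.max(y))
        pos = y > 0
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0] if pos.sum() >= 2 else 0.0
        k_guess = max(-slope, 1e-12)
        popt, pcov = curve_fit(
            lambda tt, i0, k: i0 * np.exp(-k * tt),
            t,
            y,
            p0=[i0_guess, k_guess],
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        self.i0_, self.k_ = float(popt[0]), float(popt[1])
        self.k_err_ = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
        resid = y - popt[0] * np.exp(-popt[1] * t)
        noise = float(np.mean(sigma)) if sigma is not None else float(np.std(resid, ddof=2))
        t_max = float(t[-1])
        decay = self.i0_ * (1.0 - math.exp(-self.k_ * t_max))
        self.k_bound_ = math.log(1.0 / (1.0 - self.censor_decay)) / t_max
        self.censored_ = bool(decay < 2.0 * noise)
        return self

    @property
    def k_reported_(self) -> float:
        """k_obs to report: the fit, or the censoring upper bound."""
        return self.k_bound_ if self.censored_ else self.k_


def fit_exchange_rate(series: HDXSeries) -> tuple[float, float, bool]:
    """Fit one decay; returns (k_obs, k_err, censored).

    When censored, k_obs is the upper bound ln(1/0.95)/t_max.
    """
    est = ExchangeRateFit().fit(series.times, series.intensities, series.intensity_err)
    return est.k_reported_, est.k_err_, est.censored_


def protection_factor(
    k_int: float,
    k_obs: float,
    residue_number: int = 0,
    k_obs_err: float = 0.0,
    censored: bool = False,
) -> PFResult:
    """PF = k_int / k_obs. Censored observed rates yield a lower-bound PF."""
    if k_int <= 0:
        raise ValueError(f"k_int must be positive, got {k_int}")
    if k_obs <= 0:
        raise ValueError(f"k_obs must be positive, got {k_obs}")
    flags = ""
    if k_obs > 10.0 * k_int:
        flags = "k_obs >10x k_int: unphysical (EX1 or misassignment?)"
    pf = k_int / k_obs
    return PFResult(
        residue_number=residue_number,
        k_obs=k_obs,
        k_obs_err=k_obs_err,
        k_int=k_int,
        pf=pf,
        log10_pf=math.log10(pf),
        censored=censored,
        flags=flags,
    )


def _pf_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    return pd.DataFrame(
        [
            {
                "res_num": r.residue_number,
                "k_obs": r.k_obs,
                "k_obs_err": r.k_obs_err,
                "k_int": r.k_int,
                "PF": r.pf,
                "log10_PF": r.log10_pf,
                "censored": r.censored,
                "flags": r.flags,
            }
            for r in results
        ]
    )


def compare_states(state_a, state_b) -> tuple[pd.DataFrame, dict]:
    """Per-residue protection change between two states (e.g. apo vs complex).

    Returns a table with delta_log10_PF = log10(PF_B / PF_A) per shared
    residue, and a summary dict. Pairs involving a censored PF carry bound
    semantics: the delta is itself a bound, flagged in the `bounded` column.
    """
    a, b = _pf_frame(state_a).set_index("res_num"), _pf_frame(state_b).set_index("res_num")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("states share no residues: cannot compare")
    out = pd.DataFrame(index=shared)
    out["log10_PF_a"] = a.loc[shared, "log10_PF"]
    out["log10_PF_b"] = b.loc[shared, "log10_PF"]
    out["delta_log10_PF"] = out["log10_PF_b"] - out["log10_PF_a"]
    out["bounded"] = a.loc[shared, "censored"] | b.loc[shared, "censored"]
    summary = {
        "n_compared": int(len(shared)),
        "n_increased": int((out["delta_log10_PF"] > 0).sum()),
        "n_decreased": int((out["delta_log10_PF"] < 0).sum()),
        "n_bounded": int(out["bounded"].sum()),
        "median_delta_log10_PF": float(out["delta_log10_PF"].median()),
    }
    return out.reset_index().rename(columns={"index": "res_num"}), summary


class ProtectionFactorAnalysis(BaseEstimator):
    """End-to-end protection factors from a long-format intensity table.

    Expects columns res_num, time_s, intensity[, intensity_err]. Intrinsic
    rates come from `sequence` (one-letter codes) at the stated pH and
    temperature. Fitted attribute ``results_`` is the per-residue PF table.
    """

    def __init__(
        self,
        sequence: str = "",
        pH: float = 7.0,
        temperature_K: float = 308.0,
        pd_correction: bool = False,
        time_unit: str = "s",
    ):
        self.sequence = sequence
        self.pH = pH
        self.temperature_K = temperature_K
        self.pd_correction = pd_correction
        self.time_unit = time_unit

    def fit(self, X: pd.DataFrame, y=None) -> "ProtectionFactorAnalysis":
        df = pd.DataFrame(X)
        for col in ("res_num", "time_s", "intensity"):
            if col not in df.columns:
                raise ValueError(f"intensity table is missing column '{col}'")
        if not self.sequence:
            raise ValueError("a protein sequence is required for intrinsic rates")
        scale = _SECONDS[self.time_unit]
        kints = intrinsic_rates(
            self.sequence, self.pH, self.temperature_K, self.pd_correction
        )
        rows = []
        for res_num, grp in df.groupby("res_num", sort=True):
            if res_num not in kints.index:
                continue
            grp = grp.sort_values("time_s")
            series = HDXSeries(
                residue_number=int(res_num),
                times=grp["time_s"].to_numpy(float) * scale,
                intensities=grp["intensity"].to_numpy(float),
                intensity_err=grp["intensity_err"].to_numpy(float)
                if "intensity_err" in grp.columns
                else None,
            )
            try:
                k_obs, k_err, censored = fit_exchange_rate(series)
            except ValueError:
                # peak already absent at the first time point: exchange faster
                # than the experimental dead time, PF unmeasurable from below
                rows.append(
                    PFResult(int(res_num), math.nan, math.nan, float(kints[res_num]),
                             math.nan, math.nan, censored=False,
                             flags="no signal: exchanged within dead time")
                )
                continue
            rows.append(
                protection_factor(
                    float(kints[res_num]), k_obs, int(res_num), k_err, censored
                )
            )
        self.results_ = _pf_frame(rows)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).results_
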