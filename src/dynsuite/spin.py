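"""Spin constants and the Lipari-Szabo forward model for backbone amide ¹⁵N relaxation.

The spectral density of N-H bond reorientation is the model-free form

    J(w) = (2/5) [ S² tc / (1 + (w tc)²) + (1 - S²) t / (1 + (w t)²) ],
    1/t = 1/tc + 1/te,

with the extended (two-timescale) variant used by model M5

    J(w) = (2/5) [ S² tc / (1 + (w tc)²) + (Sf² - S²) t' / (1 + (w t')²) ],
    1/t' = 1/tc + 1/ts,   S² = Sf² Ss².

Relaxation rates follow the standard dipolar + CSA expressions for an amide
¹⁵N spin relaxed by its attached proton:

    R1  = (d²/4) [J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c² J(wN)
    R2  = (d²/8) [4 J(0) + J(wH-wN) + 3 J(wN) + 6 J(wH) + 6 J(wH+wN)]
          + (c²/6) [4 J(0) + 3 J(wN)] + Rex
    NOE = 1 + (d²/4) (gH/gN) [6 J(wH+wN) - J(wH-wN)] / R1

with d = (mu0/4pi) hbar gH |gN| / r³ and c = |wN| |Dsigma| / sqrt(3).

Sign convention: angular frequencies enter J as magnitudes; the negative sign
of the ¹⁵N gyromagnetic ratio is honoured only through the gH/gN ratio in the
NOE expression (so NOE < 1 always, and negative for sub-ns tumbling).
Chemical exchange Rex adds to R2 only. Overall tumbling is isotropic: a single
tc, no diffusion-tensor anisotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

MU0 = 4.0e-7 * math.pi  # vacuum permeability, T m / A
HBAR = 1.0545718e-34  # reduced Planck constant, J s

#: community-standard values for the amide ¹⁵N-¹H spin pair
GAMMA_H = 2.6752219e8  # rad s^-1 T^-1
GAMMA_N = -2.7126e7  # rad s^-1 T^-1
R_NH_ANGSTROM = 1.02
CSA_PPM = -160.0
DEFAULT_FIELD_MHZ = 700.0


class Rates(NamedTuple):
    R1: float
    R2: float
    NOE: float


@dataclass(frozen=True)
class SpinConstants:
    """Field-dependent constants of the ¹⁵N-¹H relaxation experiment.

    Parameters
    ----------
    gamma_H, gamma_N : float
        Gyromagnetic ratios in rad s^-1 T^-1 (gamma_N is negative).
    r_NH : float
        N-H bond length in metres.
    delta_sigma : float
        ¹⁵N chemical-shift anisotropy in ppm.
    B0 : float
        Static field in tesla.
    """

    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N
    r_NH: float = R_NH_ANGSTROM * 1e-10
    delta_sigma: float = CSA_PPM
    B0: float = 2.0 * math.pi * DEFAULT_FIELD_MHZ * 1e6 / GAMMA_H

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError(f"B0 must be positive, got {self.B0}")
        if self.r_NH <= 0:
            raise ValueError(f"r_NH must be positive, got {self.r_NH}")

    @classmethod
    def at_field(cls, field_MHz: float, **overrides) -> "SpinConstants":
        """Constants at a proton resonance frequency given in MHz."""
        gamma_H = overrides.pop("gamma_H", GAMMA_H)
        B0 = 2.0 * math.pi * field_MHz * 1e6 / gamma_H
        return cls(gamma_H=gamma_H, B0=B0, **overrides)

    @property
    def field_MHz(self) -> float:
        return self.gamma_H * self.B0 / (2.0 * math.pi * 1e6)

    @property
    def omega_H(self) -> float:
        """¹H Larmor angular frequency, magnitude (rad/s)."""
        return abs(self.gamma_H) * self.B0

    @property
    def omega_N(self) -> float:
        """¹⁵N Larmor angular frequency, magnitude (rad/s)."""
        return abs(self.gamma_N) * self.B0

    @property
    def d(self) -> float:
        """Dipolar coupling constant (rad/s), magnitude."""
        return MU0 / (4.0 * math.pi) * HBAR * abs(self.gamma_H * self.gamma_N) / self.r_NH**3

    @property
    def c(self) -> float:
        """CSA coupling constant (rad/s), magnitude."""
        return self.omega_N * abs(self.delta_sigma) * 1e-6 / math.sqrt(3.0)

    @property
    def d_max_Hz(self) -> float:
        """Static N-H dipolar splitting constant in Hz (negative by convention).

        This is the scale factor between Saupe-tensor order elements and the
        residual dipolar coupling observed on the ¹⁵N-¹H splitting.
        """
        return -self.d / math.pi  # 2 * d / (2 pi), sign from gamma_N < 0

    def with_field(self, field_MHz: float) -> "SpinConstants":
        return replace(self, B0=2.0 * math.pi * field_MHz * 1e6 / self.gamma_H)


#: free parameters of each Lipari-Szabo model
MODEL_PARAMS = {
    "M1": ("s2",),
    "M2": ("s2", "tau_e"),
    "M3": ("s2", "rex"),
    "M4": ("s2", "tau_e", "rex"),
    "M5": ("sf2", "s2", "tau_s"),
}


@dataclass
class DynamicsParams:
    """Per-residue Lipari-Szabo dynamics parameters.

    s2 is the generalized order parameter (1 = rigid), tau_e the effective
    internal correlation time in seconds, rex the exchange contribution to R2
    in s^-1, tau_c the overall rotational correlation time in seconds.
    sf2/tau_s populate the extended model (M5), where s2 = sf2 * ss2.
    """

    s2: float
    tau_c: float
    tau_e: float = 0.0
    rex: float = 0.0
    model: str = "M2"
    sf2: float | None = None
    tau_s: float | None = None

    def validate(self) -> None:
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError(f"s2 must lie in [0, 1], got {self.s2}")
        if self.tau_c <= 0:
            raise ValueError(f"tau_c must be positive, got {self.tau_c}")
        if self.tau_e < 0:
            raise ValueError(f"tau_e must be non-negative, got {self.tau_e}")
        if self.tau_e >= self.tau_c:
            raise ValueError(
                f"tau_e ({self.tau_e}) must be smaller than tau_c ({self.tau_c})"
            )
        if self.rex < 0:
            raise ValueError(f"rex must be non-negative, got {self.rex}")
        if self.sf2 is not None:
            if not 0.0 <= self.sf2 <= 1.0:
                raise ValueError(f"sf2 must lie in [0, 1], got {self.sf2}")
            if self.s2 > self.sf2 + 1e-12:
                raise ValueError(
                    f"extended model requires s2 <= sf2, got s2={self.s2}, sf2={self.sf2}"
                )
        if self.tau_s is not None and self.tau_s < 0:
            raise ValueError(f"tau_s must be non-negative, got {self.tau_s}")


def _lorentzian_mix(s2_slow, amp_fast, tau_fast, tau_c, omega):
    """(2/5)[s2_slow * tc/(1+(w tc)^2) + amp_fast * t/(1+(w t)^2)], vectorized."""
    slow = s2_slow * tau_c / (1.0 + (omega * tau_c) ** 2)
    fast = amp_fast * tau_fast / (1.0 + (omega * tau_fast) ** 2)
    return 0.4 * (slow + fast)


def spectral_density(params: DynamicsParams, omega) -> float | np.ndarray:
    """Lipari-Szabo spectral density J(omega) in s/rad.

    omega may be a scalar or array of angular frequencies (rad/s, magnitudes).
    """
    params.validate()
    omega = np.abs(np.asarray(omega, dtype=float))
    if params.model == "M5" or (params.sf2 is not None and params.tau_s is not None):
        sf2 = 1.0 if params.sf2 is None else params.sf2
        tau_s = 0.0 if params.tau_s is None else params.tau_s
        tau_p = tau_s * params.tau_c / (tau_s + params.tau_c) if tau_s > 0 else 0.0
        j = _lorentzian_mix(params.s2, sf2 - params.s2, tau_p, params.tau_c, omega)
    else:
        te = params.tau_e
        tau = te * params.tau_c / (te + params.tau_c) if te > 0 else 0.0
        j = _lorentzian_mix(params.s2, 1.0 - params.s2, tau, params.tau_c, omega)
    return float(j) if j.ndim == 0 else j


def _rates_from_j(j0, jn, jh, jhmn, jhpn, rex, const: SpinConstants):
    """Assemble (R1, R2, NOE) from spectral-density values. Vectorized."""
    d2 = const.d**2
    c2 = const.c**2
    r1 = d2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (
        d2 / 8.0 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
        + c2 / 6.0 * (4.0 * j0 + 3.0 * jn)
        + rex
    )
    noe = 1.0 + d2 / 4.0 * (const.gamma_H / const.gamma_N) * (6.0 * jhpn - jhmn) / r1
    return r1, r2, noe


def relaxation_frequencies(const: SpinConstants) -> np.ndarray:
    """The five angular frequencies sampled by R1/R2/NOE: 0, wN, wH-wN, wH, wH+wN."""
    wh, wn = const.omega_H, const.omega_N
    return np.array([0.0, wn, wh - wn, wh, wh + wn])


def predict_rates(params: DynamicsParams, const: SpinConstants) -> Rates:
    """Forward-model (R1, R2, NOE) for one residue from its dynamics parameters."""
    w0, wn, whmn, wh, whpn = relaxation_frequencies(const)
    j = spectral_density(params, np.array([w0, wn, wh, whmn, whpn]))
    r1, r2, noe = _rates_from_j(j[0], j[1], j[2], j[3], j[4], params.rex, const)
    return Rates(float(r1), float(r2), float(noe))


def rates_grid(s2, tau_e, rex, tau_c, const: SpinConstants, sf2=None, tau_s=None):
    """Vectorized forward model over parameter arrays (broadcasting).

    Used by the model-free grid search and the synthetic generator; equivalent
    to calling :func:`predict_rates` element-wise.
    """
    s2 = np.asarray(s2, dtype=float)
    tau_e = np.broadcast_to(np.asarray(tau_e, dtype=float), s2.shape)
    rex = np.broadcast_to(np.asarray(rex, dtype=float), s2.shape)
    freqs = relaxation_frequencies(const)
    w = freqs.reshape((-1,) + (1,) * s2.ndim)  # (5, ...) against params
    if sf2 is not None:
        sf2 = np.broadcast_to(np.asarray(sf2, dtype=float), s2.shape)
        tau_s = np.broadcast_to(np.asarray(tau_s, dtype=float), s2.shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where(tau_s > 0, tau_s * tau_c / (tau_s + tau_c), 0.0)
        amp = sf2 - s2
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where(tau_e > 0, tau_e * tau_c / (tau_e + tau_c), 0.0)
        amp = 1.0 - s2
    j = _lorentzian_mix(s2, amp, tau, tau_c, w)
    r1, r2, noe = _rates_from_j(j[0], j[1], j[3], j[2], j[4], rex, const)
    # j rows follow relaxation_frequencies order: 0, wN, wH-wN, wH, wH+wN
    return r1, r2, noe
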