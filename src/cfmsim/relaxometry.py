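"""Transverse relaxation rates per volume-fraction unit and regime formulas.

Rates are estimated by ordinary least squares of ln(S) on the vessel volume
fraction f across geometries with increasing segment counts, and normalized
as ``rate_per_f = -slope / TE`` -- the reading of "relaxation rate per volume
fraction unit" in s^-1 at the single simulated echo time.  The intercept is
estimated rather than pinned at ln S(0) = 0 so small non-exponential
transients do not bias the slope.  Natural logarithms throughout.

The closed-form regime expressions for cylindrical perturbers are provided
as analytic references:

* motional averaging (MAR, dOmega*tau_D < 1):
  R2* = R2 = (16/45) * dOmega^2 * f * tau_D
* static dephasing (SDR, dOmega*tau_D > 1):
  R2* = (2*pi/sqrt(27)) * dOmega * f
* echo-limited (ELR, tau_D > 2*tau_CP), with x = dOmega*tau_CP:
  R2 = 7.2 * f * x^(1/3) * (1.52 + f*x)^(5/3) / (4 * R^2)

The last expression is dimensionally resolved by substituting
R^2 = tau_D * D, i.e. the denominator is 4*tau_D, which keeps the rate in
s^-1 for any consistent unit choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .walk import SignalRecord

__all__ = [
    "RateEstimate",
    "RegimeInputs",
    "RegimeLabels",
    "fit_rate_per_f",
    "correlation_time",
    "mar_rate",
    "sdr_rate",
    "elr_rate",
    "classify_regime",
]

RateKind = Literal["R2*", "R2"]


@dataclass(frozen=True)
class RateEstimate:
    """A fitted relaxation rate per unit volume fraction."""

    rate_per_f: float
    r_squared: float
    points: tuple
    te: float
    kind: RateKind


@dataclass(frozen=True)
class RegimeInputs:
    """Quantities that locate a configuration among the relaxation regimes.

    radius_um in micrometers, diffusion in m^2/s, tau_cp in seconds,
    delta_omega in rad/s, f dimensionless.  tau_D = R^2/D and
    x = delta_omega * tau_CP are derived, keeping their defining invariants
    true by construction.
    """

    radius_um: float
    diffusion: float
    tau_cp: float
    delta_omega: float
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.diffusion <= 0 or self.tau_cp <= 0:
            raise ValueError("radius, diffusion and tau_cp must be positive")
        if self.delta_omega < 0:
            raise ValueError("delta_omega must be >= 0")

    @property
    def tau_d(self) -> float:
        return correlation_time(self.radius_um, self.diffusion)

    @property
    def x(self) -> float:
        return self.delta_omega * self.tau_cp


class RegimeLabels(NamedTuple):
    """Regime of the gradient-echo rate and of the spin-echo rate."""

    r2star: str  # "MAR" or "SDR"
    r2: str      # "MAR", "ELR" or "SDR"


def fit_rate_per_f(
    records: Sequence[SignalRecord],
    kind: RateKind,
    te: float,
) -> RateEstimate:
    """OLS fit of ln(signal) against volume fraction; rate = -slope/TE."""
    if kind not in ("R2*", "R2"):
        raise ValueError(f"kind must be 'R2*' or 'R2', got {kind!r}")
    fs = np.array([rec.f for rec in records], dtype=float)
    sig = np.array(
        [rec.s_ge if kind == "R2*" else rec.s_se for rec in records], dtype=float
    )
    if len(np.unique(fs)) < 3:
        raise ValueError("need at least 3 records with distinct volume fractions")
    bad = np.nonzero(sig <= 0.0)[0]
    if bad.size:
        j = bad[0]
        raise ValueError(
            f"non-positive {kind} signal (total dephasing) in record {j} "
            f"(f = {fs[j]:.5f}, hash = {records[j].params_hash})"
        )
    if te <= 0:
        raise ValueError("te must be positive")
    res = stats.linregress(fs, np.log(sig))
    return RateEstimate(
        rate_per_f=float(-res.slope / te),
        r_squared=float(res.rvalue**2),
        points=tuple(zip(fs.tolist(), np.log(sig).tolist())),
        te=te,
        kind=kind,
    )


def correlation_time(radius_um: float, diffusion: float) -> float:
    """Correlation time tau_D = R^2 / D in seconds (R in um, D in m^2/s)."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if diffusion <= 0:
        raise ValueError("diffusion must be positive (tau_D undefined at D = 0)")
    return (radius_um * 1e-6) ** 2 / diffusion


def mar_rate(delta_omega: float, f: float, tau_d: float) -> float:
    """Motional-averaging rate (16/45) * dOmega^2 * f * tau_D, s^-1."""
    return (16.0 / 45.0) * delta_omega**2 * f * tau_d


def sdr_rate(delta_omega: float, f: float) -> float:
    """Static-dephasing R2* ceiling (2*pi/sqrt(27)) * dOmega * f, s^-1."""
    return (2.0 * np.pi / np.sqrt(27.0)) * delta_omega * f


def elr_rate(f: float, x: float, radius_um: float, diffusion: float) -> float:
    """Echo-limited spin-echo rate, s^-1.

    7.2 * f * x^(1/3) * (1.52 + f*x)^(5/3) / (4 * R^2), with the 1/R^2
    expressed as 1/(tau_D * D) so the result carries s^-1.
    """
    if f < 0 or x < 0:
        raise ValueError("f and x must be >= 0")
    tau_d = correlation_time(radius_um, diffusion)
    return 7.2 * f * x ** (1.0 / 3.0) * (1.52 + f * x) ** (5.0 / 3.0) / (4.0 * tau_d)


def classify_regime(inputs: RegimeInputs) -> RegimeLabels:
    """Label the gradient-echo and spin-echo regimes of a configuration.

    MAR iff dOmega*tau_D < 1 (strict; the boundary is classified SDR).
    The spin echo additionally enters the echo-limited regime when
    tau_D > 2*tau_CP.  Labels are classification only -- they never alter
    any computation.
    """
    fast = inputs.delta_omega * inputs.tau_d < 1.0
    r2star = "MAR" if fast else "SDR"
    if fast:
        r2 = "MAR"
    elif inputs.tau_d > 2.0 * inputs.tau_cp:
        r2 = "ELR"
    else:
        r2 = "SDR"
    return RegimeLabels(r2star=r2star, r2=r2)
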