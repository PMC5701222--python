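"""Random-walk Monte Carlo of extravascular protons.

Protons start uniformly distributed in the extravascular space, take
isotropic Gaussian steps (per-axis sigma = sqrt(2*D*dt)), wrap periodically
at the cube faces, and are rejected (wait in place for one step) whenever a
step would land them inside a vessel -- the impermeability rule.  Each step
accrues phase gamma * dB * dt from the field at the walker's voxel
(nearest-voxel lookup, matching the binary susceptibility discretization).

One echo is simulated: 90 deg excitation, ``steps_per_interval`` steps to the
180 deg pulse at tau_CP, the same number again to the echo at TE = 2*tau_CP.
The gradient-echo signal is read at the same TE without refocusing, so both
rates are directly comparable.  Both signals come from the same trajectories:
s_ge uses the total phase, s_se the total phase minus twice the phase at
tau_CP (the 180 deg pulse negates accumulated phase).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np

from .field import GAMMA, FieldMap
from .geometry import SusceptibilityMap

__all__ = [
    "SequenceParams",
    "WalkerEnsemble",
    "SignalRecord",
    "init_walkers",
    "step",
    "accrue_phase",
    "simulate_signal",
]


@dataclass(frozen=True)
class SequenceParams:
    """Timing of the simulated 90-180 echo.

    dt: time step in seconds (default 0.1 ms).
    steps_per_interval: steps between the 90 and 180 pulses (default 50).
    tau_cp = steps_per_interval * dt;  TE = 2 * tau_cp.
    """

    dt: float = 1e-4
    steps_per_interval: int = 50
    gamma: float = GAMMA

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.steps_per_interval < 1:
            raise ValueError("steps_per_interval must be >= 1")

    @property
    def tau_cp(self) -> float:
        return self.steps_per_interval * self.dt

    @property
    def te(self) -> float:
        return 2.0 * self.tau_cp


@dataclass
class WalkerEnsemble:
    """Positions (um) and accumulated phases (rad) of N protons."""

    positions: np.ndarray
    phases: np.ndarray

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SignalRecord:
    """Magnitude signals of one simulation at the echo time.

    s_ge: gradient echo (no refocusing); s_se: spin echo (one 180 at tau_CP);
    f: vessel volume fraction of the simulated geometry.
    """

    s_ge: float
    s_se: float
    f: float
    n_walkers: int
    seed: int
    params_hash: str

    def __post_init__(self) -> None:
        for s in (self.s_ge, self.s_se):
            if not 0.0 <= s <= 1.0 + 1e-12:
                raise ValueError(f"signal magnitude out of [0, 1]: {s}")


def _voxel_indices(positions: np.ndarray, smap: SusceptibilityMap) -> tuple:
    idx = (positions / smap.voxel_size_um).astype(np.intp)
    np.clip(idx, 0, smap.grid_n - 1, out=idx)
    return idx[:, 0], idx[:, 1], idx[:, 2]


def init_walkers(
    smap: SusceptibilityMap,
    n: int,
    seed: int | np.random.Generator = 0,
    max_rounds: int = 200,
) -> WalkerEnsemble:
    """Uniform extravascular initial positions by rejection sampling."""
    if smap.volume_fraction >= 1.0:
        raise ValueError("no extravascular volume to place walkers in")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = smap.cube_side_um
    out = np.empty((n, 3))
    filled = 0
    for _ in range(max_rounds):
        if filled >= n:
            break
        draw = rng.uniform(0.0, L, size=(n - filled, 3))
        ix, iy, iz = _voxel_indices(draw, smap)
        keep = draw[~smap.inside_mask[ix, iy, iz]]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    else:
        raise RuntimeError(
            f"could not place {n} extravascular walkers in {max_rounds} rounds "
            f"(f = {smap.volume_fraction:.3f})"
        )
    return WalkerEnsemble(positions=out, phases=np.zeros(n))


def step(
    ensemble: WalkerEnsemble,
    smap: SusceptibilityMap,
    D: float,
    dt: float,
    rng: np.random.Generator,
) -> WalkerEnsemble:
    """One diffusion step: Gaussian displacement, periodic wrap, rejection.

    D is the diffusion coefficient in m^2/s; positions are in micrometers.
    A step whose endpoint lands intravascular is rejected and the walker
    keeps its position for this step (impermeable vessel walls).
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if D == 0:
        return ensemble
    sigma_um = np.sqrt(2.0 * D * dt) * 1e6
    L = smap.cube_side_um
    proposed = ensemble.positions + rng.normal(0.0, sigma_um, ensemble.positions.shape)
    proposed %= L
    ix, iy, iz = _voxel_indices(proposed, smap)
    allowed = ~smap.inside_mask[ix, iy, iz]
    ensemble.positions[allowed] = proposed[allowed]
    return ensemble


def accrue_phase(
    ensemble: WalkerEnsemble,
    field: FieldMap,
    dt: float,
    gamma: float = GAMMA,
) -> WalkerEnsemble:
    """Add gamma * dB * dt from the walker's current voxel to each phase."""
    idx = (ensemble.positions / field.voxel_size_um).astype(np.intp)
    np.clip(idx, 0, field.grid_n - 1, out=idx)
    ensemble.phases += gamma * dt * field.delta_b[idx[:, 0], idx[:, 1], idx[:, 2]]
    return ensemble


def _magnitude(phases: np.ndarray) -> float:
    return float(np.abs(np.exp(1j * phases).mean()))


def simulate_signal(
    smap: SusceptibilityMap,
    field: FieldMap,
    seq: SequenceParams,
    D: float,
    n_walkers: int = 40000,
    seed: int = 0,
) -> SignalRecord:
    """Simulate one cell: gradient-echo and spin-echo magnitudes at TE.

    Runs ``2 * steps_per_interval`` steps; both signals are formed from the
    same trajectories (the spin echo negates the phase accumulated up to
    tau_CP).  Deterministic for a given (seed, parameters).
    """
    if smap.values.shape != field.delta_b.shape:
        raise ValueError("susceptibility map and field map grids differ")
    rng = np.random.default_rng(seed)
    ens = init_walkers(smap, n_walkers, rng)
    half = np.zeros(n_walkers)
    for k in range(2 * seq.steps_per_interval):
        step(ens, smap, D, seq.dt, rng)
        accrue_phase(ens, field, seq.dt, seq.gamma)
        if k + 1 == seq.steps_per_interval:
            half = ens.phases.copy()
    payload = json.dumps(
        {
            "D": D,
            "n_walkers": n_walkers,
            "seed": seed,
            "dt": seq.dt,
            "spi": seq.steps_per_interval,
            "f": smap.volume_fraction,
            "b0": field.b0_magnitude,
            "b0_dir": field.b0_direction.tolist(),
        },
        sort_keys=True,
    )
    return SignalRecord(
        s_ge=_magnitude(ens.phases),
        s_se=_magnitude(ens.phases - 2.0 * half),
        f=smap.volume_fraction,
        n_walkers=n_walkers,
        seed=seed,
        params_hash=format(zlib.crc32(payload.encode()), "08x"),
    )
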