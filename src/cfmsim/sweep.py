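"""Parameter sweeps, two-way ANOVA and correlation-time summaries.

A sweep cell is one combination of (orientation, bifurcation angle, rotation
angle, diameter, diffusion rate, susceptibility).  For every cell the driver
builds the fork arrangement at each segment count, solves the dipole field,
simulates the random walk, and fits the gradient-echo and spin-echo rates per
volume-fraction unit, emitting one row per (cell, kind).  Geometry masks and
unit-susceptibility fields are reused across the inner diffusion and
susceptibility loops (the field is linear in chi).  Per-cell seeds derive
deterministically from the master seed and the cell parameters, so any subset
of a sweep reproduces in isolation and interrupted runs resume bit-identical.

Angle effects are tested with a two-way ANOVA *without replication* (one rate
per factor-level pair; the interaction is the error term), the design the
one-rate-per-cell sweep tables support.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .field import DEFAULT_B0, b0_direction_for_orientation, dipole_field, \
    equatorial_delta_omega
from .geometry import FOUR_PI, CFMParams, OverlapError, SusceptibilityMap, \
    build_susceptibility_map
from .relaxometry import RegimeInputs, classify_regime, correlation_time, \
    fit_rate_per_f
from .walk import SequenceParams, simulate_signal

logger = logging.getLogger(__name__)

__all__ = [
    "SweepGrid",
    "AnovaResult",
    "run_sweep",
    "anova_two_way",
    "summarize_vs_tau_d",
    "peak_tau_d",
    "tau_d_ladder_grid",
]

#: Full production factor levels.
PAPER_ANGLES = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)
PAPER_DIAMETERS_UM = (2.8, 5.6, 8.6)
PAPER_DIFFUSIONS = (1e-11, 1e-10, 1e-9)
PAPER_CHIS_CGS = (3e-8, 1e-7, 4e-7)
PAPER_SEGMENT_COUNTS = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class SweepGrid:
    """Factor levels and run parameters of one sweep.

    Defaults mirror the production grids; desk-scale runs shrink the angle
    lists and walker count rather than the physics.  With
    ``pair_diameter_diffusion`` the diameter and diffusion lists are zipped
    (one (d, D) pair per entry) instead of crossed -- used by the
    correlation-time ladder.
    """

    betas: Sequence[float] = PAPER_ANGLES
    phis: Sequence[float] = PAPER_ANGLES
    orientations: Sequence[int] = (1, 2, 3)
    diameters_um: Sequence[float] = PAPER_DIAMETERS_UM
    diffusions: Sequence[float] = PAPER_DIFFUSIONS
    chis_cgs: Sequence[float] = PAPER_CHIS_CGS
    segment_counts: Sequence[int] = PAPER_SEGMENT_COUNTS
    n_walkers: int = 10000
    b0: float = DEFAULT_B0
    master_seed: int = 0
    grid_n: int = 128
    cube_side_um: float = 64.0
    pair_diameter_diffusion: bool = False
    sequence: SequenceParams = dc_field(default_factory=SequenceParams)

    def __post_init__(self) -> None:
        for name in ("betas", "phis", "orientations", "diameters_um",
                     "diffusions", "chis_cgs", "segment_counts"):
            if not len(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty")
        if self.pair_diameter_diffusion and len(self.diameters_um) != len(self.diffusions):
            raise ValueError(
                "paired diameters and diffusions must have equal lengths"
            )


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA (no replication) for two crossed factors."""

    factor_a: str
    factor_b: str
    f_a: float
    f_b: float
    p_a: float
    p_b: float
    df: tuple  # (df_a, df_b, df_resid)
    ss: tuple  # (ss_a, ss_b, ss_resid)
    ss_total: float


def _cell_hash(cell: dict) -> str:
    return format(zlib.crc32(json.dumps(cell, sort_keys=True).encode()), "08x")


def _cell_seed(master_seed: int, cell_hash: str) -> int:
    return (master_seed * 2654435761 + int(cell_hash, 16)) % (2**31)


def _diameter_diffusion_pairs(grid: SweepGrid):
    if grid.pair_diameter_diffusion:
        return [(d, (D,)) for d, D in zip(grid.diameters_um, grid.diffusions)]
    return [(d, tuple(grid.diffusions)) for d in grid.diameters_um]


def run_sweep(grid: SweepGrid, store_path: str | Path | None = None) -> pd.DataFrame:
    """Run every sweep cell and return the rate table.

    One row per (cell, kind in {R2*, R2}) with full parameter provenance.
    Cells already present in ``store_path`` (matched by parameter hash) are
    skipped; per-cell failures (geometry overlap, total dephasing) are logged
    and recorded as missing, never fatal.
    """
    store = Path(store_path) if store_path is not None else None
    rows: list[dict] = []
    done: set[str] = set()
    if store is not None and store.exists():
        prior = pd.read_csv(store)
        rows = prior.to_dict("records")
        done = set(prior["cell_hash"].astype(str))

    seq = grid.sequence
    for beta, phi, (diam, d_list) in itertools.product(
        grid.betas, grid.phis, _diameter_diffusion_pairs(grid)
    ):
        pending = [
            (orientation, D, chi)
            for orientation, D, chi in itertools.product(
                grid.orientations, d_list, grid.chis_cgs
            )
            if _cell_hash(_cell_dict(grid, orientation, beta, phi, diam, D, chi))
            not in done
        ]
        if not pending:
            continue
        try:
            maps = _geometry_set(grid, beta, phi, diam)
        except (OverlapError, ValueError) as exc:
            logger.warning(
                "geometry failed for beta=%s phi=%s d=%s um: %s", beta, phi, diam, exc
            )
            continue
        for orientation in grid.orientations:
            if not any(o == orientation for o, _, _ in pending):
                continue
            t0 = time.perf_counter()
            unit_fields = [
                dipole_field(
                    SusceptibilityMap(
                        values=np.where(m.inside_mask, FOUR_PI, 0.0),
                        inside_mask=m.inside_mask,
                        voxel_size_um=m.voxel_size_um,
                        volume_fraction=m.volume_fraction,
                    ),
                    grid.b0,
                    b0_direction_for_orientation(orientation),
                )
                for m in maps
            ]
            for D, chi in itertools.product(d_list, grid.chis_cgs):
                if (orientation, D, chi) not in pending:
                    continue
                cell = _cell_dict(grid, orientation, beta, phi, diam, D, chi)
                h = _cell_hash(cell)
                seed = _cell_seed(grid.master_seed, h)
                try:
                    new_rows = _simulate_cell(
                        grid, seq, maps, unit_fields, cell, h, seed, chi, D
                    )
                except ValueError as exc:
                    logger.warning("cell %s failed: %s", cell, exc)
                    continue
                rows.extend(new_rows)
                done.add(h)
                if store is not None:
                    pd.DataFrame(new_rows).to_csv(
                        store, mode="a", header=not store.exists(), index=False
                    )
            logger.info(
                "beta=%s phi=%s d=%s orientation=%s done in %.1f s",
                beta, phi, diam, orientation, time.perf_counter() - t0,
            )
    return pd.DataFrame(rows)


def _cell_dict(grid, orientation, beta, phi, diam, D, chi) -> dict:
    return {
        "orientation": int(orientation),
        "beta": float(beta),
        "phi": float(phi),
        "diameter_um": float(diam),
        "diffusion": float(D),
        "chi_cgs": float(chi),
        "segment_counts": list(map(int, grid.segment_counts)),
        "n_walkers": int(grid.n_walkers),
        "grid_n": int(grid.grid_n),
        "cube_side_um": float(grid.cube_side_um),
        "b0": float(grid.b0),
        "dt": grid.sequence.dt,
        "spi": grid.sequence.steps_per_interval,
        "master_seed": int(grid.master_seed),
    }


def _geometry_set(grid: SweepGrid, beta, phi, diam) -> list[SusceptibilityMap]:
    """Susceptibility masks for every segment count (chi = 1 cgs placeholder)."""
    return [
        build_susceptibility_map(
            CFMParams(
                beta=beta,
                phi=phi,
                diameter_um=diam,
                n_segments=n_seg,
                cube_side_um=grid.cube_side_um,
                grid_n=grid.grid_n,
                chi_cgs=1.0,
            )
        )
        for n_seg in grid.segment_counts
    ]


def _simulate_cell(grid, seq, maps, unit_fields, cell, h, seed, chi, D) -> list[dict]:
    records = []
    for i, (smap, ufield) in enumerate(zip(maps, unit_fields)):
        field_i = type(ufield)(
            delta_b=ufield.delta_b * chi,
            b0_magnitude=ufield.b0_magnitude,
            b0_direction=ufield.b0_direction,
            voxel_size_um=ufield.voxel_size_um,
        )
        records.append(
            simulate_signal(
                smap, field_i, seq, D,
                n_walkers=grid.n_walkers, seed=(seed + i) % (2**31),
            )
        )
    dw = equatorial_delta_omega(chi, grid.b0)
    regime = classify_regime(
        RegimeInputs(
            radius_um=cell["diameter_um"] / 2.0,
            diffusion=D,
            tau_cp=seq.tau_cp,
            delta_omega=dw,
            f=records[-1].f,
        )
    )
    out = []
    for kind, label in (("R2*", regime.r2star), ("R2", regime.r2)):
        est = fit_rate_per_f(records, kind, seq.te)
        out.append(
            {
                "cell_hash": h,
                "orientation": cell["orientation"],
                "beta": cell["beta"],
                "phi": cell["phi"],
                "diameter_um": cell["diameter_um"],
                "diffusion": D,
                "chi_cgs": chi,
                "kind": kind,
                "rate_per_f": est.rate_per_f,
                "r_squared": est.r_squared,
                "regime": label,
                "tau_d": correlation_time(cell["diameter_um"] / 2.0, D),
                "delta_omega": dw,
                "seed": seed,
                "n_walkers": grid.n_walkers,
                "b0": grid.b0,
                "grid_n": grid.grid_n,
            }
        )
    return out


def anova_two_way(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    response: str,
) -> AnovaResult:
    """Additive two-way ANOVA without replication.

    Requires exactly one response value per factor-level pair; missing cells
    are rejected (no imputation).  The residual (interaction) mean square is
    the error term; a zero residual with a nonzero factor effect yields the
    maximal-significance convention (F = inf, p = 0), and a constant response
    yields F = 0, p = 1.
    """
    counts = table.pivot_table(
        index=factor_a, columns=factor_b, values=response, aggfunc="count"
    )
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError(
            "two-way ANOVA without replication needs exactly one response per "
            f"({factor_a}, {factor_b}) pair"
        )
    piv = table.pivot_table(index=factor_a, columns=factor_b, values=response)
    y = piv.to_numpy(dtype=float)
    a, b = y.shape
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least two levels")
    grand = y.mean()
    ss_a = b * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_b = a * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_res = max(ss_total - ss_a - ss_b, 0.0)
    df_a, df_b, df_res = a - 1, b - 1, (a - 1) * (b - 1)
    ms_res = ss_res / df_res

    def _test(ss_factor: float, df_factor: int) -> tuple[float, float]:
        ms_factor = ss_factor / df_factor
        if ms_factor == 0.0:
            return 0.0, 1.0
        if ms_res <= 1e-300 or ms_res < 1e-14 * ms_factor:
            return float("inf"), 0.0
        f_stat = ms_factor / ms_res
        return f_stat, float(stats.f.sf(f_stat, df_factor, df_res))

    f_a, p_a = _test(ss_a, df_a)
    f_b, p_b = _test(ss_b, df_b)
    return AnovaResult(
        factor_a=factor_a,
        factor_b=factor_b,
        f_a=f_a,
        f_b=f_b,
        p_a=p_a,
        p_b=p_b,
        df=(df_a, df_b, df_res),
        ss=(ss_a, ss_b, ss_res),
        ss_total=ss_total,
    )


def summarize_vs_tau_d(
    table: pd.DataFrame,
    chi_cgs: float | None = None,
    orientation: int | None = None,
) -> pd.DataFrame:
    """Mean rate per f (and SEM) across angle cells, grouped by tau_D.

    Returns one row per (kind, tau_d): mean over all (beta, phi) cells,
    standard error of that mean, and the cell count n (SEM is 0 by
    convention when n = 1).
    """
    sub = table
    if chi_cgs is not None:
        sub = sub[np.isclose(sub["chi_cgs"], chi_cgs)]
    if orientation is not None:
        sub = sub[sub["orientation"] == orientation]
    if sub.empty:
        raise ValueError("no rows match the requested chi/orientation")
    grouped = (
        sub.groupby(["kind", "tau_d"])["rate_per_f"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_rate", "count": "n"})
    )
    grouped["sem"] = np.where(
        grouped["n"] > 1, grouped["std"] / np.sqrt(grouped["n"]), 0.0
    )
    return grouped.drop(columns="std").sort_values(["kind", "tau_d"]).reset_index(drop=True)


def peak_tau_d(summary: pd.DataFrame, kind: str = "R2") -> float:
    """tau_D grid point at which the mean rate of ``kind`` is maximal."""
    sub = summary[summary["kind"] == kind]
    if sub.empty:
        raise ValueError(f"summary has no rows of kind {kind!r}")
    return float(sub.loc[sub["mean_rate"].idxmax(), "tau_d"])


def tau_d_ladder_grid(
    tau_ds: Sequence[float],
    betas: Sequence[float],
    phis: Sequence[float],
    orientation: int = 1,
    chi_cgs: float = 1e-7,
    radius_bounds_um: tuple[float, float] = (1.4, 4.3),
    candidate_diffusions: Sequence[float] = PAPER_DIFFUSIONS,
    **grid_kwargs,
) -> SweepGrid:
    """Sweep grid sampling a log-spaced correlation-time ladder.

    Each tau_D is realized as a (radius, diffusion) pair with
    R = sqrt(tau_D * D): the fastest candidate diffusion rate whose implied
    radius stays inside ``radius_bounds_um`` (the capillary range) is chosen,
    so large correlation times come from slow diffusion rather than vessels
    too large to pack without overlap.
    """
    lo, hi = radius_bounds_um
    diameters, diffusions = [], []
    for tau in tau_ds:
        for D in sorted(candidate_diffusions, reverse=True):
            r_um = np.sqrt(tau * D) * 1e6
            if lo <= r_um <= hi:
                diameters.append(2.0 * r_um)
                diffusions.append(D)
                break
        else:
            raise ValueError(
                f"tau_D = {tau} s not realizable with radii in {radius_bounds_um} um"
            )
    return SweepGrid(
        betas=tuple(betas),
        phis=tuple(phis),
        orientations=(orientation,),
        diameters_um=tuple(diameters),
        diffusions=tuple(diffusions),
        chis_cgs=(chi_cgs,),
        pair_diameter_diffusion=True,
        **grid_kwargs,
    )
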