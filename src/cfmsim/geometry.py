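"""Cylinder fork model (CFM) geometry and voxelized susceptibility maps.

A fork is a straight vessel trunk that splits, at the cube center, into two
straight branches.  The trunk runs from the x = 0 cube face to the center
(length ``a`` = half the cube side); each branch leaves the center at an angle
``beta`` from the trunk axis (inter-branch angle ``2*beta``) inside the fork
plane (the grid xy-plane) and is long enough to terminate on a cube face,
i.e. its length is ``a / max(cos(beta), sin(beta))``.  The whole centerline is
then rotated in-plane by ``phi`` about the fork-plane normal (the +z axis)
through the cube center.  These conventions give the closed-form total
centerline lengths ``2a``, ``a*(1 + 2*sqrt(2))`` and ``3a`` at
``beta = 0, 45, 90`` degrees (the T-shape).

Multiple forks are placed with parallel trunks and parallel fork planes.
Straight segments (``beta = 0``) use the classical 3x3 cross-sectional lattice
in the (y, z) plane; bifurcated forks are stacked center-out along the fork
plane normal, the only parallel-plane arrangement whose pairwise clearance is
independent of the bifurcation angle.  Overlap is always verified on the
rasterized masks and raised as :class:`OverlapError`.

Rasterization is binary (a voxel belongs to the vessel iff its center lies
within one radius of a centerline segment) and clipped to the cube; the FFT
field solver then periodizes the cube contents, so face-to-face segments act
as infinite cylinders under the periodic boundary.  Susceptibility
differences are accepted in cgs units at the interface and stored in SI
(multiplied by 4*pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FOUR_PI = 4.0 * np.pi

__all__ = [
    "CFMParams",
    "ForkCenterline",
    "SusceptibilityMap",
    "OverlapError",
    "build_fork",
    "place_forks",
    "rasterize",
    "build_susceptibility_map",
    "volume_fraction",
]


class OverlapError(RuntimeError):
    """Two distinct forks share at least one voxel after rasterization."""


@dataclass(frozen=True)
class CFMParams:
    """Full parametric description of one fork arrangement.

    Parameters
    ----------
    beta:
        Bifurcation angle of each branch from the trunk axis, degrees,
        in [0, 90].
    phi:
        In-plane rotation of the whole fork (about the fork-plane normal
        through the cube center), degrees, in [0, 90].
    orientation:
        1, 2 or 3 -- selects the main-field direction relative to the fork
        plane (see :func:`cfmsim.field.b0_direction_for_orientation`).
    diameter_um:
        Vessel diameter in micrometers; must be positive and smaller than
        half the cube side.
    n_segments:
        Number of forks in the cube; odd, 1 to 9.
    cube_side_um:
        Side of the simulation cube in micrometers.
    grid_n:
        Voxels per cube side (even).
    chi_cgs:
        Susceptibility difference between intra- and extravascular space,
        dimensionless, cgs convention (multiplied by 4*pi for SI).
    """

    beta: float
    phi: float = 0.0
    orientation: int = 1
    diameter_um: float = 5.6
    n_segments: int = 1
    cube_side_um: float = 64.0
    grid_n: int = 128
    chi_cgs: float = 3e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 90.0:
            raise ValueError(f"beta must be in [0, 90] degrees, got {self.beta}")
        if not 0.0 <= self.phi <= 90.0:
            raise ValueError(f"phi must be in [0, 90] degrees, got {self.phi}")
        if self.orientation not in (1, 2, 3):
            raise ValueError(f"orientation must be 1, 2 or 3, got {self.orientation}")
        if not 0.0 < self.diameter_um < self.cube_side_um / 2.0:
            raise ValueError(
                "diameter must be positive and below half the cube side, "
                f"got {self.diameter_um} um"
            )
        if self.n_segments not in (1, 3, 5, 7, 9):
            raise ValueError(f"n_segments must be odd in 1..9, got {self.n_segments}")
        if self.grid_n < 2 or self.grid_n % 2:
            raise ValueError(f"grid_n must be even and >= 2, got {self.grid_n}")
        if self.cube_side_um <= 0:
            raise ValueError("cube_side_um must be positive")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def half_side_um(self) -> float:
        """a, half the cube side (the trunk length)."""
        return self.cube_side_um / 2.0

    @property
    def voxel_size_um(self) -> float:
        return self.cube_side_um / self.grid_n


@dataclass(frozen=True)
class ForkCenterline:
    """Continuous centerline of one fork: trunk plus two branches.

    Each segment is a (2, 3) array of endpoints in micrometers.
    """

    trunk: np.ndarray
    branch_a: np.ndarray
    branch_b: np.ndarray
    radius_um: float

    def segments(self) -> list[np.ndarray]:
        """Distinct centerline segments (coincident branches collapse)."""
        segs = [self.trunk, self.branch_a]
        if not np.array_equal(self.branch_a, self.branch_b):
            segs.append(self.branch_b)
        return segs

    def total_length(self) -> float:
        """Length of the centerline union (coincident branches counted once)."""
        return float(
            sum(np.linalg.norm(seg[1] - seg[0]) for seg in self.segments())
        )


@dataclass(frozen=True)
class SusceptibilityMap:
    """3D voxel grid of susceptibility differences (SI units).

    ``values`` is nonzero exactly on ``inside_mask`` (intravascular voxels),
    where it equals ``4*pi*chi_cgs``.
    """

    values: np.ndarray
    inside_mask: np.ndarray
    voxel_size_um: float
    volume_fraction: float = field(default=0.0)

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    @property
    def cube_side_um(self) -> float:
        return self.grid_n * self.voxel_size_um


def _rotation_z(phi_deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(phi_deg)), np.sin(np.deg2rad(phi_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_fork(params: CFMParams, center_offset=(0.0, 0.0, 0.0)) -> ForkCenterline:
    """Construct one fork centerline.

    The fork is built at ``phi = 0`` (trunk along +x from the x = 0 face to
    the cube center, shifted by ``center_offset``), validated to lie inside
    the cube, then rotated by ``phi`` about +z through the cube center.
    Offsets that push any unrotated segment endpoint outside the cube are
    rejected; in-plane rotation may carry branch tips past a face, which the
    periodic rasterization wraps.
    """
    a = params.half_side_um
    off = np.asarray(center_offset, dtype=float)
    if off.shape != (3,):
        raise ValueError("center_offset must be a 3-vector")
    cube_center = np.array([a, a, a])
    fork_center = cube_center + off

    beta = np.deg2rad(params.beta)
    branch_len = a / max(np.cos(beta), np.sin(beta))
    dir_a = np.array([np.cos(beta), np.sin(beta), 0.0])
    dir_b = np.array([np.cos(beta), -np.sin(beta), 0.0])

    trunk = np.array([fork_center - [a, 0.0, 0.0], fork_center])
    branch_a = np.array([fork_center, fork_center + branch_len * dir_a])
    branch_b = np.array([fork_center, fork_center + branch_len * dir_b])

    tol = 1e-9 * params.cube_side_um
    for seg in (trunk, branch_a, branch_b):
        if (seg < -tol).any() or (seg > params.cube_side_um + tol).any():
            raise ValueError(
                f"center_offset {tuple(off)} pushes a segment outside the cube"
            )

    rot = _rotation_z(params.phi)

    def _rot(seg: np.ndarray) -> np.ndarray:
        return (seg - cube_center) @ rot.T + cube_center

    return ForkCenterline(
        trunk=_rot(trunk),
        branch_a=_rot(branch_a),
        branch_b=_rot(branch_b),
        radius_um=params.radius_um,
    )


def _lattice_offsets(params: CFMParams, spacing_um: float | None = None) -> list[np.ndarray]:
    """Deterministic fork-center offsets, center first, symmetric outward."""
    n = params.n_segments
    if params.beta == 0.0:
        # 3x3 cross-sectional lattice in the plane perpendicular to the trunk:
        # center, then corners, then edge midpoints.
        s = params.cube_side_um / 3.0 if spacing_um is None else spacing_um
        pattern = [
            (0.0, 0.0),
            (s, s), (-s, -s), (-s, s), (s, -s),
            (0.0, s), (0.0, -s), (s, 0.0), (-s, 0.0),
        ]
        return [np.array([0.0, dy, dz]) for dy, dz in pattern[:n]]
    # Bifurcated forks: stack along the fork-plane normal (z), center out.
    s = params.cube_side_um / n if spacing_um is None else spacing_um
    ks = [0, 1, -1, 2, -2, 3, -3, 4, -4][:n]
    return [np.array([0.0, 0.0, k * s]) for k in ks]


def place_forks(
    params: CFMParams,
    spacing_um: float | None = None,
    check_overlap: bool = True,
) -> list[ForkCenterline]:
    """Place ``params.n_segments`` forks with parallel trunks and fork planes.

    Offsets live in the plane perpendicular to the (unrotated) trunk axis and
    the whole assembly rotates rigidly by ``phi``, so pairwise clearances are
    independent of the rotation angle.  With ``check_overlap`` the rasterized
    masks are verified pairwise disjoint; any shared voxel raises
    :class:`OverlapError`.
    """
    forks = [build_fork(params, off) for off in _lattice_offsets(params, spacing_um)]
    if check_overlap and len(forks) > 1:
        union = np.zeros((params.grid_n,) * 3, dtype=bool)
        for i, fork in enumerate(forks):
            mask = _fork_mask(fork, params)
            if (union & mask).any():
                raise OverlapError(
                    f"fork {i} overlaps an earlier fork (beta={params.beta}, "
                    f"phi={params.phi}, d={params.diameter_um} um, "
                    f"n_segments={params.n_segments})"
                )
            union |= mask
    return forks


def _segment_mask(mask: np.ndarray, a: np.ndarray, b: np.ndarray,
                  radius: float, params: CFMParams) -> None:
    """Mark voxels whose centers lie within ``radius`` of segment ab.

    Only voxels inside the cube are marked (the matrix holds what the cube
    contains; geometry carried past a face by the in-plane rotation is
    clipped, not wrapped).  The FFT field solver then periodizes the cube
    contents as a whole.
    """
    ab = b - a
    length2 = float(ab @ ab)
    if length2 == 0.0:
        raise ValueError("zero-length centerline segment")
    n = params.grid_n
    centers = (np.arange(n) + 0.5) * params.voxel_size_um
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    i0 = np.searchsorted(centers, lo)
    i1 = np.searchsorted(centers, hi, side="right")
    if (i1 <= i0).any():
        return
    x = centers[i0[0]:i1[0]][:, None, None]
    y = centers[i0[1]:i1[1]][None, :, None]
    z = centers[i0[2]:i1[2]][None, None, :]
    px, py, pz = x - a[0], y - a[1], z - a[2]
    t = (px * ab[0] + py * ab[1] + pz * ab[2]) / length2
    np.clip(t, 0.0, 1.0, out=t)
    d2 = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
    sub = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    sub |= d2 <= radius * radius


def _fork_mask(fork: ForkCenterline, params: CFMParams) -> np.ndarray:
    mask = np.zeros((params.grid_n,) * 3, dtype=bool)
    for seg in fork.segments():
        _segment_mask(mask, seg[0], seg[1], fork.radius_um, params)
    return mask


def rasterize(forks: list[ForkCenterline], params: CFMParams) -> SusceptibilityMap:
    """Rasterize fork centerlines into a binary susceptibility map.

    A voxel is intravascular iff its center lies within one radius of any
    centerline segment (union of capped cylinders; voxels covered by several
    segments count once).  Interior voxels carry ``4*pi*chi_cgs`` (SI), the
    exterior zero.
    """
    mask = np.zeros((params.grid_n,) * 3, dtype=bool)
    for fork in forks:
        mask |= _fork_mask(fork, params)
    values = np.where(mask, FOUR_PI * params.chi_cgs, 0.0)
    return SusceptibilityMap(
        values=values,
        inside_mask=mask,
        voxel_size_um=params.voxel_size_um,
        volume_fraction=float(mask.mean()),
    )


def build_susceptibility_map(
    params: CFMParams, spacing_um: float | None = None
) -> SusceptibilityMap:
    """Place the fork arrangement, verify non-overlap, and rasterize it."""
    masks = [
        _fork_mask(fork, params)
        for fork in place_forks(params, spacing_um, check_overlap=False)
    ]
    union = np.zeros((params.grid_n,) * 3, dtype=bool)
    for i, mask in enumerate(masks):
        if (union & mask).any():
            raise OverlapError(
                f"fork {i} overlaps an earlier fork (beta={params.beta}, "
                f"phi={params.phi}, d={params.diameter_um} um, "
                f"n_segments={params.n_segments})"
            )
        union |= mask
    values = np.where(union, FOUR_PI * params.chi_cgs, 0.0)
    return SusceptibilityMap(
        values=values,
        inside_mask=union,
        voxel_size_um=params.voxel_size_um,
        volume_fraction=float(union.mean()),
    )


def volume_fraction(smap: SusceptibilityMap) -> float:
    """Vessel volume fraction f = intravascular voxels / total voxels."""
    return float(smap.inside_mask.mean())
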