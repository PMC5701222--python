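"""Susceptibility-induced field perturbations.

The forward model convolves the voxelized susceptibility distribution with
the k-space dipole kernel ``1/3 - (k.b)^2/|k|^2`` (b the unit main-field
direction) via FFTs, yielding the field component along B0.  The k = 0
component is zeroed, i.e. the field is defined relative to its volume mean;
a global offset only adds a common phase and cannot change signal magnitude.
The FFT makes the cube periodic -- the geometry tiles space, matching the
periodic random walk.

The classical closed-form exterior field of an infinite cylinder,

    dB = B0 * 2*pi*dchi_cgs * (R/r)^2 * cos(2*phi) * sin(theta)^2,

is provided as an independent oracle, together with the equatorial frequency
offset  dOmega = gamma * dB(r=R, phi=0, theta=90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SusceptibilityMap

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA = 2.675e8

#: Default main-field magnitude, tesla.
DEFAULT_B0 = 1.0

_B0_DIRECTIONS = {
    1: np.array([0.0, 0.0, 1.0]),
    2: np.array([1.0, 0.0, 0.0]),
    3: np.array([0.0, 1.0, 0.0]),
}

__all__ = [
    "GAMMA",
    "DEFAULT_B0",
    "FieldMap",
    "b0_direction_for_orientation",
    "dipole_field",
    "analytic_cylinder_field",
    "equatorial_delta_omega",
]


@dataclass(frozen=True)
class FieldMap:
    """Field perturbation along B0 on the susceptibility map's grid, tesla."""

    delta_b: np.ndarray
    b0_magnitude: float
    b0_direction: np.ndarray
    voxel_size_um: float

    @property
    def grid_n(self) -> int:
        return self.delta_b.shape[0]


def b0_direction_for_orientation(orientation: int) -> np.ndarray:
    """Unit B0 direction for the three canonical orientations.

    Orientation 1: B0 along +z (normal to the fork plane; trunk at 90 deg).
    Orientation 2: B0 along +x (along the unrotated trunk; 0 deg).
    Orientation 3: B0 along +y (in-plane, perpendicular to the trunk; 90 deg).
    """
    try:
        return _B0_DIRECTIONS[orientation].copy()
    except KeyError:
        raise ValueError(f"orientation must be 1, 2 or 3, got {orientation}") from None


def dipole_field(
    smap: SusceptibilityMap,
    b0_magnitude: float = DEFAULT_B0,
    b0_direction=(0.0, 0.0, 1.0),
) -> FieldMap:
    """Field perturbation along B0 from the k-space dipole kernel.

    ``delta_b = B0 * IFFT[(1/3 - (k.b)^2/|k|^2) * FFT[chi_SI]]`` with the
    k = 0 term set to zero.  Result is real and periodic on the cubic grid.
    """
    values = smap.values
    if values.ndim != 3 or len(set(values.shape)) != 1:
        raise ValueError("susceptibility grid must be cubic")
    b = np.asarray(b0_direction, dtype=float)
    norm = np.linalg.norm(b)
    if norm == 0.0:
        raise ValueError("b0_direction must be a nonzero vector")
    b = b / norm

    n = values.shape[0]
    k = np.fft.fftfreq(n)
    kx = k[:, None, None]
    ky = k[None, :, None]
    kz = k[None, None, :]
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - kb**2 / k2
    kernel[0, 0, 0] = 0.0

    delta_b = b0_magnitude * np.fft.ifftn(kernel * np.fft.fftn(values)).real
    return FieldMap(
        delta_b=delta_b,
        b0_magnitude=float(b0_magnitude),
        b0_direction=b,
        voxel_size_um=smap.voxel_size_um,
    )


def analytic_cylinder_field(
    radius_um: float,
    r_um,
    phi_deg,
    theta_deg: float,
    chi_cgs: float,
    b0: float = DEFAULT_B0,
):
    """Exterior field of an infinite cylinder (closed form, cgs susceptibility).

    ``phi`` is the azimuth in the cross-sectional plane measured from the
    projection of B0, ``theta`` the angle between cylinder axis and B0.
    Only valid outside the vessel (r >= R).
    """
    r = np.asarray(r_um, dtype=float)
    if np.any(r < radius_um):
        raise ValueError("analytic exterior field requires r >= R")
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    theta = np.deg2rad(theta_deg)
    out = (
        b0
        * 2.0
        * np.pi
        * chi_cgs
        * (radius_um / r) ** 2
        * np.cos(2.0 * phi)
        * np.sin(theta) ** 2
    )
    return out if out.ndim else float(out)


def equatorial_delta_omega(chi_cgs: float, b0: float = DEFAULT_B0,
                           gamma: float = GAMMA) -> float:
    """Larmor frequency offset at the equatorial vessel surface, rad/s.

    gamma * B_eq(R) with B_eq evaluated from the analytic exterior field at
    r = R, phi = 0, theta = 90 deg, i.e. gamma * 2*pi*chi_cgs * B0.
    """
    if chi_cgs < 0:
        raise ValueError("chi_cgs must be >= 0")
    return gamma * analytic_cylinder_field(1.0, 1.0, 0.0, 90.0, chi_cgs, b0)
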