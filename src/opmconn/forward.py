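"""Dipole forward model in a homogeneous conducting sphere.

The magnetic field of a current dipole inside a spherically symmetric
conductor has the closed-form Sarvas solution. Two classical properties are
exploited throughout the package and its tests: (i) the field outside the
sphere does not depend on the sphere radius or conductivity profile, and
(ii) a dipole with radial moment produces no field outside the conductor.

Units: positions in metres, dipole moments in nAm, fields in fT.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ParcelSet, SensorArray

__all__ = ["dipole_leadfield", "parcel_leadfields"]

# mu0 / 4pi in SI, times the nAm -> A·m (1e-9) and T -> fT (1e15) conversions.
_SCALE = 1e-7 * 1e-9 * 1e15  # fT per nAm, metre geometry


def _sarvas_field(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vector field (fT) of a dipole q (nAm) at r0, sampled at points r.

    ``r`` is (n, 3); the sphere centre is the coordinate origin.
    """
    r = np.atleast_2d(np.asarray(r, dtype=float))
    r0 = np.asarray(r0, dtype=float)
    q = np.asarray(q, dtype=float)

    a_vec = r - r0  # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("dipole coincides with a field point (singular)")

    r0_dot_r = r @ r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)

    F = a * (rn * a + rn**2 - r0_dot_r)
    grad_coeff_r = a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn
    grad_coeff_r0 = a + 2.0 * rn + a_dot_r / a
    gradF = grad_coeff_r[:, None] * r - grad_coeff_r0[:, None] * r0

    q_x_r0 = np.cross(q, r0)
    q_x_r0_dot_r = r @ q_x_r0

    B = (F[:, None] * q_x_r0 - q_x_r0_dot_r[:, None] * gradF) / F[:, None] ** 2
    return _SCALE * B


def dipole_leadfield(
    r0: np.ndarray,
    q_axis: np.ndarray,
    array: SensorArray,
    sphere_radius: float | None = None,
) -> np.ndarray:
    """Channel response (fT per nAm) to a unit dipole at ``r0`` along ``q_axis``.

    Each channel measures the projection of the field at its position onto
    its sensitive axis. ``sphere_radius``, when given, is used only to
    validate the geometry (dipole strictly inside, sensors strictly
    outside); the exterior field itself is radius-independent.
    """
    r0 = np.asarray(r0, dtype=float)
    q_axis = np.asarray(q_axis, dtype=float)
    if sphere_radius is not None:
        if np.linalg.norm(r0) >= sphere_radius:
            raise ValueError("dipole must lie strictly inside the conductor sphere")
        array.validate_outside_sphere(sphere_radius)
    B = _sarvas_field(r0, q_axis, array.positions)
    return np.einsum("ij,ij->i", B, array.orientations)


def parcel_leadfields(
    parcels: ParcelSet,
    array: SensorArray,
    sphere_radius: float | None = None,
) -> np.ndarray:
    """Leadfield set: (n_parcels, n_channels, 3) for unit x/y/z dipole moments."""
    if sphere_radius is not None:
        parcels.validate_inside_sphere(sphere_radius)
        array.validate_outside_sphere(sphere_radius)
    axes = np.eye(3)
    L = np.empty((parcels.n_parcels, array.n_channels, 3))
    for p, r0 in enumerate(parcels.centroids):
        for k in range(3):
            L[p, :, k] = dipole_leadfield(r0, axes[k], array)
    return L
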