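"""Magnetic forward models for sources in and around a conducting sphere.

The phantom is a homogeneous conducting sphere, for which the external
magnetic field of a current dipole has the closed form derived by Sarvas.
The same code path is used both to synthesise recordings and to compute the
beamformer leadfield, so simulator and source analysis are consistent by
construction.

A useful property of the sphere: the radial component of the external field
equals the radial component of the primary (Biot-Savart) dipole field alone
- volume currents contribute nothing radially - and a purely radial dipole
moment is magnetically silent.
"""

from __future__ import annotations

import numpy as np

from .core import SensorArray

MU0 = 4.0e-7 * np.pi


def sarvas_field(dipole_pos, dipole_moment, points, center=None):
    """External field of current dipoles in a homogeneous conducting sphere.

    Parameters
    ----------
    dipole_pos : array, shape (3,) or (m, 3)
        Dipole location(s) in metres.
    dipole_moment : array, shape (3,) or (m, 3)
        Dipole moment(s) in A*m.
    points : array, shape (n, 3)
        Field points in metres (must be outside the sphere for the formula
        to describe a measurable field, this is not enforced here).
    center : array, shape (3,), optional
        Sphere centre; defaults to the origin.

    Returns
    -------
    B : ndarray, shape (n, 3) or (m, n, 3)
        Magnetic field in Tesla.
    """
    r0 = np.atleast_2d(np.asarray(dipole_pos, dtype=float))
    q = np.atleast_2d(np.asarray(dipole_moment, dtype=float))
    pts = np.asarray(points, dtype=float)
    if center is not None:
        r0 = r0 - np.asarray(center, dtype=float)
        pts = pts - np.asarray(center, dtype=float)
    single = np.asarray(dipole_pos).ndim == 1

    # shapes: dipoles (m, 1, 3), points (1, n, 3)
    r0b = r0[:, None, :]
    qb = q[:, None, :]
    r = pts[None, :, :]

    a_vec = r - r0b
    a = np.linalg.norm(a_vec, axis=-1)
    rn = np.linalg.norm(r, axis=-1)
    adotr = np.sum(a_vec * r, axis=-1)
    r0dotr = np.sum(r0b * r, axis=-1)

    F = a * (rn * a + rn**2 - r0dotr)
    # gradient of F with respect to the field point
    c1 = a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + adotr / a
    gradF = c1[..., None] * r - c2[..., None] * r0b

    qxr0 = np.cross(qb, r0b)  # (m, 1, 3)
    term = F[..., None] * qxr0 - np.sum(qxr0 * r, axis=-1)[..., None] * gradF
    B = MU0 / (4.0 * np.pi) * term / (F**2)[..., None]
    return B[0] if single else B


def dipole_field(dipole_pos, dipole_moment, sensors: SensorArray) -> np.ndarray:
    """Per-channel field (Tesla) of a current dipole inside the phantom sphere.

    The dipole must lie strictly inside the conducting sphere.  The field is
    projected onto each sensor's orientation.
    """
    r0 = np.asarray(dipole_pos, dtype=float)
    depth = np.linalg.norm(r0 - sensors.sphere_center)
    if depth >= sensors.sphere_radius:
        raise ValueError(
            f"dipole at radius {depth:.4f} m is not inside the sphere "
            f"(radius {sensors.sphere_radius:.4f} m)"
        )
    B = sarvas_field(r0, dipole_moment, sensors.positions, center=sensors.sphere_center)
    return np.sum(B * sensors.orientations, axis=-1)


def magnetic_dipole_field(positions, moments, points):
    """Field of point magnetic dipoles (used for wire magnetisation sources).

    B(r) = mu0/(4 pi) * (3 (m.n)n - m) / d^3  with n the unit vector from the
    dipole to the field point.  ``positions``/``moments`` are (m, 3); result
    is summed over dipoles, shape (n, 3).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    mom = np.atleast_2d(np.asarray(moments, dtype=float))
    pts = np.asarray(points, dtype=float)
    d_vec = pts[None, :, :] - pos[:, None, :]
    d = np.linalg.norm(d_vec, axis=-1)
    n = d_vec / d[..., None]
    mdotn = np.sum(mom[:, None, :] * n, axis=-1)
    B = (3.0 * mdotn[..., None] * n - mom[:, None, :]) / (d**3)[..., None]
    return MU0 / (4.0 * np.pi) * B.sum(axis=0)
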