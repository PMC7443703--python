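"""Signal space separation (SSS) and its temporal extension (tSSS).

Outside all sources the magnetic field is the gradient of a harmonic scalar
potential, which separates into an interior expansion (multipoles inside the
sensor array, potential ~ r^-(l+1)) and an exterior expansion (distant
sources, potential ~ r^l).  Evaluating these multipole fields at the sensors
gives a basis matrix S = [S_in S_out]; least-squares fitting a data segment
onto S splits it into an inner reconstruction B_in, an outer part, and a
residual B_res that no quasi-static source at the modelled distances can
explain.

tSSS additionally assumes genuine interior activity is uncorrelated with
artefacts: any temporal subspace shared between B_in and B_res must be
leaked artefact, is found by canonical correlation of the two temporal
subspaces, and every direction correlating above the correlation limit CL is
projected out of B_in.  The cleaned output is the concatenation of the
cleaned inner reconstructions of consecutive 10 s segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from ..core import Recording, SensorArray


@dataclass
class TSSSParams:
    """tSSS settings: correlation limit CL, segment length, expansion orders
    L_in/L_out and the pseudoinverse truncation tolerance."""

    CL: float = 0.95
    segment_length: float = 10.0
    L_in: int = 8
    L_out: int = 3
    basis_rtol: float = 1e-8
    intersect_floor: float = 1e-3

    def __post_init__(self):
        if not 0.0 < self.CL <= 1.0:
            raise ValueError("correlation limit must be in (0, 1]")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")


@dataclass
class SSSBasis:
    """Multipole field basis evaluated on a sensor array."""

    S: np.ndarray       # channels x (n_in + n_out), column-normalised
    n_in: int
    n_out: int
    L_in: int
    L_out: int
    origin: np.ndarray

    @property
    def S_in(self) -> np.ndarray:
        return self.S[:, :self.n_in]

    @property
    def S_out(self) -> np.ndarray:
        return self.S[:, self.n_in:]


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic of degree l, order m (theta = polar angle)."""
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(sph_harm_y(l, m, theta, phi))
    if m < 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.imag(sph_harm_y(l, -m, theta, phi))
    return np.real(sph_harm_y(l, 0, theta, phi))


def _potential(points: np.ndarray, l: int, m: int, kind: str, r_scale: float) -> np.ndarray:
    r = np.linalg.norm(points, axis=1)
    theta = np.arccos(np.clip(points[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(points[:, 1], points[:, 0])
    rho = r / r_scale
    radial = rho ** (-(l + 1)) if kind == "in" else rho**l
    return radial * _real_sph_harm(l, m, theta, phi)


def sss_basis(sensors: SensorArray, L_in: int = 8, L_out: int = 3,
              origin=None, basis_rtol: float = 1e-8) -> SSSBasis:
    """Interior and exterior multipole field basis at the sensors.

    Each column is the field of one multipole, B = -grad(V), evaluated by
    central differences of the scalar potential at the sensor positions and
    projected onto the sensor orientations; columns are normalised to unit
    Euclidean norm.  n_in = L_in(L_in+2), n_out = L_out(L_out+2).
    """
    if origin is None:
        origin = sensors.sphere_center
    origin = np.asarray(origin, dtype=float)
    pts = sensors.positions - origin
    radii = np.linalg.norm(pts, axis=1)
    if np.any(radii <= 0.5 * sensors.sphere_radius):
        raise ValueError("sensors must lie well outside the inner expansion region")
    r_scale = float(np.mean(radii))
    h = 1e-6 * r_scale
    shifts = np.zeros((6, 3))
    for ax in range(3):
        shifts[2 * ax, ax] = h
        shifts[2 * ax + 1, ax] = -h

    cols = []
    for kind, L in (("in", L_in), ("out", L_out)):
        for l in range(1, L + 1):
            for m in range(-l, l + 1):
                vals = np.stack([
                    _potential(pts + s, l, m, kind, r_scale) for s in shifts
                ])
                grad = np.column_stack([
                    (vals[0] - vals[1]) / (2 * h),
                    (vals[2] - vals[3]) / (2 * h),
                    (vals[4] - vals[5]) / (2 * h),
                ])
                b = -np.sum(grad * sensors.orientations, axis=1)
                cols.append(b)
    S = np.column_stack(cols)
    S = S / np.linalg.norm(S, axis=0)
    n_in = L_in * (L_in + 2)
    n_out = L_out * (L_out + 2)
    cond = np.linalg.cond(S)
    if cond > 1.0 / basis_rtol:
        warnings.warn(f"SSS basis is ill-conditioned (cond={cond:.2e}); "
                      "truncated pseudoinverse will regularise the fit")
    return SSSBasis(S=S, n_in=n_in, n_out=n_out, L_in=L_in, L_out=L_out,
                    origin=origin)


@dataclass
class _TsssSegment:
    """Per-segment cache: inner reconstruction and the candidate temporal
    directions with their inner-residual canonical correlations."""

    B_in: np.ndarray        # channels x T
    mean: np.ndarray        # channels (removed before the fit)
    E: np.ndarray           # T x m orthonormal temporal directions (residual side)
    corr: np.ndarray        # canonical correlations, descending


def _segment_bounds(n: int, seg: int):
    bounds = list(range(0, n, seg))
    return [(b, min(b + seg, n)) for b in bounds]


def tsss_decompose(rec: Recording, params: TSSSParams,
                   sensors: SensorArray | None = None,
                   basis: SSSBasis | None = None):
    """SSS fit plus inner/residual canonical correlation for every segment.

    The result is independent of the correlation limit, so one decomposition
    serves a whole CL sweep.
    """
    if sensors is None:
        sensors = rec.sensors
    if basis is None:
        basis = sss_basis(sensors, params.L_in, params.L_out,
                          basis_rtol=params.basis_rtol)
    if rec.n_channels < basis.n_in + basis.n_out:
        raise ValueError("fewer channels than multipole coefficients")
    pinvS = np.linalg.pinv(basis.S, rcond=params.basis_rtol)
    seg = int(round(params.segment_length * rec.fs))
    segments = []
    for b0, b1 in _segment_bounds(rec.n_samples, seg):
        X = rec.data[:, b0:b1]
        mean = X.mean(axis=1)
        X0 = X - mean[:, None]
        a = pinvS @ X0
        B_in = basis.S_in @ a[:basis.n_in]
        B_out = basis.S_out @ a[basis.n_in:]
        B_res = X0 - B_in - B_out

        _, sv_in, vt_in = np.linalg.svd(B_in, full_matrices=False)
        _, sv_res, vt_res = np.linalg.svd(B_res, full_matrices=False)
        sin_max = sv_in[0] if sv_in.size else 0.0
        Vin = vt_in[sv_in > 1e-10 * sin_max] if sv_in.size else vt_in[:0]
        # Residual directions with negligible energy relative to the segment
        # are not intersection candidates: the multipole truncation error of a
        # perfectly representable interior source is rank-deficient with the
        # source's own time course and would otherwise cancel the signal.
        if sv_res.size:
            floor = max(1e-10 * sv_res[0], params.intersect_floor * sin_max)
            Vres = vt_res[sv_res > floor]
        else:
            Vres = vt_res[:0]
        if Vin.size == 0 or Vres.size == 0:
            segments.append(_TsssSegment(B_in=B_in, mean=mean,
                                         E=np.zeros((X.shape[1], 0)),
                                         corr=np.zeros(0)))
            continue
        M = Vin @ Vres.T
        _, corr, wt = np.linalg.svd(M)
        E = Vres.T @ wt.T            # T x m, orthonormal, ordered by corr desc
        segments.append(_TsssSegment(B_in=B_in, mean=mean, E=E, corr=corr))
    return segments


def tsss_assemble(segments, CL: float) -> np.ndarray:
    """Project temporal directions correlating above CL out of each segment's
    inner reconstruction and concatenate."""
    outs = []
    for s in segments:
        m = int(np.sum(s.corr > CL))
        if m:
            E = s.E[:, :m]
            outs.append(s.B_in - (s.B_in @ E) @ E.T)
        else:
            outs.append(s.B_in)
    return np.concatenate(outs, axis=1)


def tsss_clean(rec: Recording, params: TSSSParams,
               sensors: SensorArray | None = None) -> Recording:
    """Temporal signal space separation of a recording.

    Per non-overlapping segment: least-squares multipole fit, canonical
    correlation between the temporal subspaces of the inner reconstruction
    and the residual, projection of directions with correlation > CL out of
    the inner part.  The output is the cleaned inner reconstruction
    (segment means, which the multipole basis cannot represent, are not
    restored).
    """
    segments = tsss_decompose(rec, params, sensors)
    return rec.copy_with(tsss_assemble(segments, params.CL))
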