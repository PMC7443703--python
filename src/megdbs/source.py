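"""Source-level analysis: LCMV beamforming and activation overlap.

A 5 mm cubic grid is clipped to the interior of the phantom sphere and a
three-column (free-orientation) leadfield is computed per voxel with the
same closed-form sphere model used by the simulator.  Vector unit-gain LCMV
weights are formed after whitening with the (regularised) noise covariance;
per-window source power at a target frequency is obtained by beamforming the
4 s Hamming-window Fourier coefficients, and activation is thresholded at a
bootstrap percentile of resampled window means.  Spatial correspondence
between two activation maps is summarised by the intersection-over-union
measure D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Recording, SensorArray
from .forward import sarvas_field


@dataclass
class SourceGrid:
    """Regular cubic lattice of candidate source locations inside the sphere."""

    points: np.ndarray          # voxels x 3, metres
    spacing: float              # metres
    inside_mask: np.ndarray     # per candidate point of the bounding lattice

    @property
    def n_voxels(self) -> int:
        return self.points.shape[0]


@dataclass
class LeadField:
    """Free-orientation leadfield: three unit-dipole columns per voxel."""

    matrix: np.ndarray          # channels x (3 * voxels), T per (A*m)
    grid: SourceGrid

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels


@dataclass
class SourceMap:
    """Per-voxel power at one frequency, with optional activation mask."""

    power: np.ndarray                    # voxels
    frequency: float
    grid: SourceGrid
    per_window_power: np.ndarray | None = None   # voxels x windows
    active: np.ndarray | None = None
    threshold: float | None = None
    valid: np.ndarray | None = None      # voxels where weights were computable


@dataclass
class DResult:
    """Intersection-over-union of two activation maps."""

    d: float
    n_intersection: int
    n_union: int


def build_grid(sensors: SensorArray, spacing: float = 5e-3,
               interior_fraction: float = 0.95) -> SourceGrid:
    """Cubic lattice clipped to ``interior_fraction`` of the sphere radius
    (the leadfield is singular at the surface)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    r_max = interior_fraction * sensors.sphere_radius
    c = sensors.sphere_center
    ax = np.arange(-r_max, r_max + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(pts, axis=1) < r_max
    return SourceGrid(points=pts[inside] + c, spacing=spacing, inside_mask=inside)


def compute_leadfield(grid: SourceGrid, sensors: SensorArray,
                      chunk: int = 2048) -> LeadField:
    """Three orthogonal unit-dipole columns per voxel (Tesla per A*m)."""
    r = np.linalg.norm(grid.points - sensors.sphere_center, axis=1)
    if np.any(r >= sensors.sphere_radius):
        raise ValueError("grid extends outside the sphere")
    n_vox = grid.n_voxels
    n_ch = sensors.n_channels
    out = np.empty((n_ch, 3 * n_vox))
    eye = np.eye(3)
    for s in range(0, n_vox, chunk):
        pts = grid.points[s:s + chunk]
        m = pts.shape[0]
        for ax in range(3):
            B = sarvas_field(pts, np.tile(eye[ax], (m, 1)), sensors.positions,
                             center=sensors.sphere_center)
            proj = np.sum(B * sensors.orientations[None], axis=-1)  # m x ch
            out[:, 3 * s + ax:3 * (s + m):3] = proj.T
    return LeadField(matrix=out, grid=grid)


def regularize_cov(C: np.ndarray) -> np.ndarray:
    """Replace every eigenvalue below the median eigenvalue with the median."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.allclose(C, C.T, rtol=1e-8, atol=0):
        raise ValueError("covariance must be a symmetric matrix")
    w, v = np.linalg.eigh(C)
    med = np.median(w)
    w = np.maximum(w, med)
    return (v * w) @ v.T


@dataclass
class LCMVWeights:
    """Unit-gain vector beamformer weights applied to raw sensor data."""

    weights: np.ndarray         # voxels x 3 x channels
    grid: SourceGrid
    valid: np.ndarray           # voxels with an invertible 3x3 gain matrix


def lcmv_weights(data_cov: np.ndarray, noise_cov: np.ndarray,
                 lf: LeadField, rcond: float = 1e-8) -> LCMVWeights:
    """Vector unit-gain LCMV with noise-covariance whitening.

    Sensors are whitened by the inverse square root of the noise covariance;
    per voxel W = (L^T C^-1 L)^+ L^T C^-1 (in whitened coordinates, mapped
    back to raw data).  The 3x3 gain matrix L^T C^-1 L is rank deficient in
    a spherical volume conductor - a radially oriented dipole is magnetically
    silent - so it is inverted on its numerically significant eigenspace
    (eigenvalues above ``rcond`` x the leading one).  W @ L then acts as the
    identity on the non-silent orientation subspace; voxels with fewer than
    two usable orientations are flagged invalid.
    """
    wn_e, wn_v = np.linalg.eigh(noise_cov)
    if np.any(wn_e <= 0):
        raise ValueError("noise covariance is not positive definite; regularise it first")
    Wn = (wn_v / np.sqrt(wn_e)) @ wn_v.T
    n_ch = lf.matrix.shape[0]
    n_vox = lf.n_voxels
    Lw = Wn @ lf.matrix                                   # ch x 3V
    Cw = Wn @ data_cov @ Wn
    Cw = 0.5 * (Cw + Cw.T)
    ce, cv = np.linalg.eigh(Cw)
    if np.any(ce <= 0):
        raise ValueError("data covariance is not positive definite; regularise it first")
    Ci = (cv / ce) @ cv.T
    A = Ci @ Lw                                           # ch x 3V
    Lv = np.moveaxis(Lw.reshape(n_ch, n_vox, 3), 0, 1)    # V x ch x 3
    Av = np.moveaxis(A.reshape(n_ch, n_vox, 3), 0, 1)     # V x ch x 3
    K = np.einsum("vci,vcj->vij", Lv, Av)                 # V x 3 x 3
    K = 0.5 * (K + np.swapaxes(K, 1, 2))
    ke, kv = np.linalg.eigh(K)                            # ascending
    keep = ke > rcond * ke[:, -1:]
    inv_e = np.where(keep, 1.0 / np.where(keep, ke, 1.0), 0.0)
    Kinv = np.einsum("vik,vk,vjk->vij", kv, inv_e, kv)
    valid = keep.sum(axis=1) >= 2
    Kinv[~valid] = 0.0
    W = np.einsum("vij,vcj->vic", Kinv, Av)               # V x 3 x ch (whitened)
    W = W @ Wn                                            # apply to raw data
    return LCMVWeights(weights=W, grid=lf.grid, valid=valid)


def data_covariance(rec: Recording) -> np.ndarray:
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    return (x @ x.T) / rec.n_samples


def source_power_at(rec: Recording, weights: LCMVWeights, frequency: float,
                    window_length: float = 4.0, overlap: float = 0.5) -> SourceMap:
    """Per-window beamformed power at the bin nearest ``frequency``.

    Uses the same 4 s Hamming windows with 50% overlap as the sensor-level
    Welch spectra, so the bootstrap can resample exactly the terms that
    average into the map.
    """
    if frequency >= rec.fs / 2:
        raise ValueError("frequency must be below Nyquist")
    nper = int(round(window_length * rec.fs))
    hop = int(round(nper * (1.0 - overlap)))
    win = sps.get_window("hamming", nper, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(
        rec.data, nper, axis=1)[:, ::hop, :]
    spec = np.fft.rfft(frames * win, axis=-1)             # ch x n_win x nf
    freqs = np.fft.rfftfreq(nper, 1.0 / rec.fs)
    j = int(np.argmin(np.abs(freqs - frequency)))
    c = spec[:, :, j]                                     # ch x n_win
    scale = 2.0 / (rec.fs * np.sum(win**2))
    proj = np.einsum("vic,cw->viw", weights.weights, c)   # V x 3 x n_win
    per_win = scale * np.sum(proj.real**2 + proj.imag**2, axis=1)
    per_win[~weights.valid] = 0.0
    return SourceMap(power=per_win.mean(axis=1), frequency=float(freqs[j]),
                     grid=weights.grid, per_window_power=per_win,
                     valid=weights.valid)


def bootstrap_threshold(smap: SourceMap, n_iter: int = 1000,
                        percentile: float = 95.0,
                        exclude: np.ndarray | None = None,
                        seed: int | None = None) -> float:
    """Significance threshold from resampled window means.

    Each iteration draws ``n_windows`` windows with replacement and averages
    them per voxel; the threshold is the ``percentile`` of the pooled means
    over all non-excluded voxels and iterations.
    """
    if smap.per_window_power is None:
        raise ValueError("source map lacks per-window power estimates")
    P = smap.per_window_power
    n_vox, n_win = P.shape
    if n_win < 8:
        raise ValueError("need at least 8 windows to bootstrap")
    keep = np.ones(n_vox, dtype=bool)
    if smap.valid is not None:
        keep &= smap.valid
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if not keep.any():
        raise ValueError("all voxels excluded from the bootstrap pool")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_win, np.full(n_win, 1.0 / n_win), size=n_iter)
    means = (P[keep] @ counts.T) / n_win                  # kept voxels x n_iter
    return float(np.percentile(means, percentile))


def active_map(smap: SourceMap, threshold: float) -> SourceMap:
    """Return a copy of the map with the activation mask set."""
    act = smap.power > threshold
    if smap.valid is not None:
        act &= smap.valid
    return SourceMap(power=smap.power, frequency=smap.frequency, grid=smap.grid,
                     per_window_power=smap.per_window_power, active=act,
                     threshold=float(threshold), valid=smap.valid)


def overlap_D(a: SourceMap, b: SourceMap) -> DResult:
    """Intersection-over-union of two activation maps on the same grid."""
    if a.active is None or b.active is None:
        raise ValueError("both maps must be thresholded first")
    if a.grid.n_voxels != b.grid.n_voxels:
        raise ValueError("maps live on different grids")
    inter = int(np.sum(a.active & b.active))
    union = int(np.sum(a.active | b.active))
    if union == 0:
        raise ValueError("both maps are empty; D is undefined (0/0)")
    return DResult(d=inter / union, n_intersection=inter, n_union=union)
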