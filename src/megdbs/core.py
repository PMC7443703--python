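"""Core data containers shared by the simulator and the analysis pipeline.

A :class:`Recording` is the universal currency of the package: a dense
channels x samples array of magnetometer signals in Tesla, together with its
sampling rate, the sensor geometry it was measured (or simulated) on, and a
condition label.  All cleaning operations map ``Recording -> Recording`` and
preserve channel count, length, sampling rate and realness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CONDITIONS = ("reference", "dmw", "dsmw", "empty_room")


@dataclass(frozen=True)
class SensorArray:
    """Geometry of an array of radial point magnetometers on a helmet.

    Parameters
    ----------
    positions : ndarray, shape (n, 3)
        Sensor positions in metres.
    orientations : ndarray, shape (n, 3)
        Unit vectors along which each sensor measures the magnetic field.
    names : tuple of str
        Channel labels.
    sphere_center : ndarray, shape (3,)
        Centre of the conducting sphere (the phantom) in metres.
    sphere_radius : float
        Radius of the conducting sphere in metres.  All sensors must lie
        strictly outside this sphere.
    """

    positions: np.ndarray
    orientations: np.ndarray
    names: tuple
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sphere_radius: float = 0.075

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        ctr = np.asarray(self.sphere_center, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "sphere_center", ctr)
        object.__setattr__(self, "names", tuple(self.names))
        if pos.ndim != 2 or pos.shape[1] != 3 or ori.shape != pos.shape:
            raise ValueError("positions and orientations must both be (n, 3)")
        if pos.shape[0] < 32:
            raise ValueError("sensor arrays need at least 32 channels")
        if len(self.names) != pos.shape[0]:
            raise ValueError("number of names does not match channel count")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientation vectors must have unit norm")
        radii = np.linalg.norm(pos - ctr, axis=1)
        if np.any(radii <= self.sphere_radius):
            raise ValueError("all sensors must lie strictly outside the sphere")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.positions - self.sphere_center, axis=1)


@dataclass
class Recording:
    """A multichannel magnetometer recording.

    ``data`` has shape (channels, samples) in Tesla; ``fs`` is the sampling
    rate in Hz.  ``condition`` is one of ``reference``, ``dmw``, ``dsmw``,
    ``empty_room`` (or a free-form label for derived data).
    """

    data: np.ndarray
    fs: float
    sensors: SensorArray
    condition: str = "reference"
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.sensors.n_channels:
            raise ValueError("channel count does not match sensor array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray, condition: str | None = None) -> "Recording":
        """Return a new recording sharing geometry/metadata with new data."""
        return Recording(
            data=np.asarray(data, dtype=float),
            fs=self.fs,
            sensors=self.sensors,
            condition=self.condition if condition is None else condition,
            t0=self.t0,
        )


def check_same_geometry(*recs: Recording) -> None:
    first = recs[0]
    for r in recs[1:]:
        if r.fs != first.fs or r.n_samples != first.n_samples:
            raise ValueError("recordings differ in sampling rate or length")
        if r.sensors is not first.sensors and not np.array_equal(
            r.sensors.positions, first.sensors.positions
        ):
            raise ValueError("recordings use different sensor arrays")
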