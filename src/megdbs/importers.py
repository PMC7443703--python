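"""Best-effort import of real MEG recordings in standard formats.

The core pipeline runs entirely on synthetic data; this bridge maps
magnetometer-type channels of FIF or CTF acquisitions into a
:class:`~megdbs.core.Recording` when the optional ``mne`` dependency is
available.
"""

from __future__ import annotations

import numpy as np

from .core import Recording, SensorArray


def import_standard(path, format: str, condition: str = "reference",
                    sphere_radius: float = 0.075) -> Recording:
    """Read a FIF or CTF recording; magnetometer-type channels only."""
    if format not in ("fif", "ctf"):
        raise ValueError(f"unsupported format {format!r} (expected 'fif' or 'ctf')")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is normally present
        raise ImportError(
            "importing real recordings requires the optional dependency "
            "'mne' (pip install mne)") from exc

    if format == "fif":
        raw = mne.io.read_raw_fif(path, preload=True, verbose=False)
    else:
        raw = mne.io.read_raw_ctf(path, preload=True, verbose=False)
    picks = mne.pick_types(raw.info, meg="mag", ref_meg=False)
    if picks.size < 32:
        raise ValueError("recording has fewer than 32 magnetometer channels")
    data = raw.get_data(picks=picks)
    chs = [raw.info["chs"][i] for i in picks]
    positions = np.array([c["loc"][:3] for c in chs])
    orientations = np.array([c["loc"][9:12] for c in chs])
    norms = np.linalg.norm(orientations, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    orientations = orientations / norms
    names = tuple(c["ch_name"] for c in chs)
    center = positions.mean(axis=0)
    center[2] -= 0.04  # rough head-centre guess below the helmet centroid
    sensors = SensorArray(positions=positions, orientations=orientations,
                          names=names, sphere_center=center,
                          sphere_radius=sphere_radius)
    return Recording(data=data, fs=float(raw.info["sfreq"]), sensors=sensors,
                     condition=condition)
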