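"""Hierarchical array container (HDF5) for simulation and analysis objects.

One file holds one object; the object kind is recorded in a ``kind``
attribute together with a format name and version, and :func:`read_container`
dispatches on it.  Round trips are lossless.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .core import Recording, SensorArray
from .phantom import ConditionSet, SimConfig
from .spectral import SpectrumEstimate
from .source import SourceGrid, SourceMap

FORMAT_NAME = "megdbs-container"
FORMAT_VERSION = "1"


class ContainerError(RuntimeError):
    """Raised for unknown formats, versions or object kinds."""


def _write_header(h: h5py.File, kind: str, provenance: dict | None):
    h.attrs["format"] = FORMAT_NAME
    h.attrs["version"] = FORMAT_VERSION
    h.attrs["kind"] = kind
    if provenance:
        h.attrs["provenance"] = json.dumps(provenance)


def _check_header(h: h5py.File) -> str:
    if h.attrs.get("format") != FORMAT_NAME:
        raise ContainerError("not a megdbs container")
    if h.attrs.get("version") != FORMAT_VERSION:
        raise ContainerError(
            f"unsupported container version {h.attrs.get('version')!r} "
            f"(expected {FORMAT_VERSION})")
    kind = h.attrs.get("kind")
    if kind not in ("recording", "condition_set", "spectrum", "source_map"):
        raise ContainerError(f"unknown object kind {kind!r}")
    return kind


def _save_sensors(g: h5py.Group, sensors: SensorArray):
    g.create_dataset("positions", data=sensors.positions)
    g.create_dataset("orientations", data=sensors.orientations)
    g.create_dataset("names", data=np.array(sensors.names, dtype="S"))
    g.attrs["sphere_center"] = sensors.sphere_center
    g.attrs["sphere_radius"] = sensors.sphere_radius


def _load_sensors(g: h5py.Group) -> SensorArray:
    return SensorArray(
        positions=g["positions"][()],
        orientations=g["orientations"][()],
        names=tuple(n.decode() for n in g["names"][()]),
        sphere_center=g.attrs["sphere_center"],
        sphere_radius=float(g.attrs["sphere_radius"]))


def _save_recording(g: h5py.Group, rec: Recording):
    g.create_dataset("data", data=rec.data)
    g.attrs["fs"] = rec.fs
    g.attrs["condition"] = rec.condition
    g.attrs["t0"] = rec.t0


def _load_recording(g: h5py.Group, sensors: SensorArray) -> Recording:
    return Recording(data=g["data"][()], fs=float(g.attrs["fs"]),
                     sensors=sensors, condition=g.attrs["condition"],
                     t0=float(g.attrs["t0"]))


def save_container(path, obj, provenance: dict | None = None):
    """Write a Recording, ConditionSet, SpectrumEstimate or SourceMap."""
    with h5py.File(path, "w") as h:
        if isinstance(obj, ConditionSet):
            _write_header(h, "condition_set", provenance)
            _save_sensors(h.create_group("sensors"), obj.sensors)
            for name in ("reference", "dmw", "dsmw", "empty_room"):
                _save_recording(h.create_group(name), getattr(obj, name))
            h.create_dataset("dbs_reference_channel",
                             data=obj.dbs_reference_channel)
            h.attrs["config"] = json.dumps(obj.config.to_dict())
        elif isinstance(obj, Recording):
            _write_header(h, "recording", provenance)
            _save_sensors(h.create_group("sensors"), obj.sensors)
            _save_recording(h.create_group("recording"), obj)
        elif isinstance(obj, SpectrumEstimate):
            _write_header(h, "spectrum", provenance)
            h.create_dataset("freqs", data=obj.freqs)
            h.create_dataset("power", data=obj.power)
            if obj.per_window_power is not None:
                h.create_dataset("per_window_power", data=obj.per_window_power)
            h.attrs["window_length"] = obj.window_length
            h.attrs["overlap"] = obj.overlap
            h.attrs["window_kind"] = obj.window_kind
            h.attrs["n_windows"] = obj.n_windows
        elif isinstance(obj, SourceMap):
            _write_header(h, "source_map", provenance)
            h.create_dataset("power", data=obj.power)
            h.create_dataset("points", data=obj.grid.points)
            h.create_dataset("inside_mask", data=obj.grid.inside_mask)
            h.attrs["spacing"] = obj.grid.spacing
            h.attrs["frequency"] = obj.frequency
            if obj.per_window_power is not None:
                h.create_dataset("per_window_power", data=obj.per_window_power)
            if obj.active is not None:
                h.create_dataset("active", data=obj.active)
                h.attrs["threshold"] = obj.threshold
            if obj.valid is not None:
                h.create_dataset("valid", data=obj.valid)
        else:
            raise TypeError(f"cannot serialise {type(obj).__name__}")


def read_container(path):
    """Read back whatever :func:`save_container` wrote."""
    with h5py.File(path, "r") as h:
        kind = _check_header(h)
        if kind == "condition_set":
            sensors = _load_sensors(h["sensors"])
            recs = {name: _load_recording(h[name], sensors)
                    for name in ("reference", "dmw", "dsmw", "empty_room")}
            cfg = SimConfig.from_dict(json.loads(h.attrs["config"]))
            return ConditionSet(dbs_reference_channel=h["dbs_reference_channel"][()],
                                config=cfg, **recs)
        if kind == "recording":
            sensors = _load_sensors(h["sensors"])
            return _load_recording(h["recording"], sensors)
        if kind == "spectrum":
            return SpectrumEstimate(
                freqs=h["freqs"][()], power=h["power"][()],
                window_length=float(h.attrs["window_length"]),
                overlap=float(h.attrs["overlap"]),
                window_kind=h.attrs["window_kind"],
                n_windows=int(h.attrs["n_windows"]),
                per_window_power=(h["per_window_power"][()]
                                  if "per_window_power" in h else None))
        grid = SourceGrid(points=h["points"][()], spacing=float(h.attrs["spacing"]),
                          inside_mask=h["inside_mask"][()])
        return SourceMap(
            power=h["power"][()], frequency=float(h.attrs["frequency"]),
            grid=grid,
            per_window_power=(h["per_window_power"][()]
                              if "per_window_power" in h else None),
            active=h["active"][()] if "active" in h else None,
            threshold=(float(h.attrs["threshold"])
                       if "threshold" in h.attrs else None),
            valid=h["valid"][()] if "valid" in h else None)


def read_provenance(path) -> dict | None:
    with h5py.File(path, "r") as h:
        _check_header(h)
        if "provenance" in h.attrs:
            return json.loads(h.attrs["provenance"])
    return None
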