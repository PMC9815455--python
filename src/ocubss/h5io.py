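"""HDF5 container for recordings, ground truth and decompositions.

Layout: ``/meg`` (data, channel table, sfreq, page spans/labels), ``/truth``
(artifact sources and mixing, brain sources, noise seed), ``/sensors``,
``/config`` (JSON-serialized simulation parameters as an attribute).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import h5py
import numpy as np

from .core import Decomposition, Recording, SensorArray
from .synth import GazeTrace, SimConfig, SimulationTruth

__all__ = ["save_dataset", "load_recording", "load_truth", "load_config",
           "save_decomposition", "load_decomposition"]


def _write_sensors(g: h5py.Group, sensors: SensorArray) -> None:
    for name in ("positions", "normals", "tangent1", "tangent2"):
        g.create_dataset(name, data=getattr(sensors, name))
    g.attrs["baseline"] = sensors.baseline


def _read_sensors(g: h5py.Group) -> SensorArray:
    return SensorArray(positions=g["positions"][()], normals=g["normals"][()],
                       tangent1=g["tangent1"][()], tangent2=g["tangent2"][()],
                       baseline=float(g.attrs["baseline"]))


def save_dataset(path, rec: Recording, truth: Optional[SimulationTruth] = None,
                 config: Optional[SimConfig] = None) -> None:
    with h5py.File(path, "w") as f:
        meg = f.create_group("meg")
        meg.create_dataset("data", data=rec.data)
        meg.attrs["sfreq"] = rec.sfreq
        meg.attrs["scale"] = rec.scale
        str_dt = h5py.string_dtype()
        meg.create_dataset("ch_names", data=np.array(rec.ch_names, dtype=object),
                           dtype=str_dt)
        meg.create_dataset("ch_types", data=np.array(rec.ch_types, dtype=object),
                           dtype=str_dt)
        meg.create_dataset("site_ids", data=rec.site_ids)
        meg.create_dataset("pair_ids", data=rec.pair_ids)
        meg.create_dataset("page_spans", data=np.asarray(rec.page_spans))
        meg.create_dataset("page_labels",
                           data=np.array(rec.page_labels, dtype=object), dtype=str_dt)
        if rec.sensors is not None:
            _write_sensors(f.create_group("sensors"), rec.sensors)
        if truth is not None:
            t = f.create_group("truth")
            src = t.create_group("artifact_sources")
            mix = t.create_group("artifact_mixing")
            for name in truth.artifact_sources:
                src.create_dataset(name, data=truth.artifact_sources[name])
                mix.create_dataset(name, data=truth.artifact_mixing[name])
            t.create_dataset("brain_sources", data=truth.brain_sources)
            t.create_dataset("brain_mixing", data=truth.brain_mixing)
            t.create_dataset("brain_points", data=truth.brain_points)
            t.attrs["noise_seed"] = truth.noise_seed if truth.noise_seed is not None else -1
            t.attrs["noise_sigma"] = truth.noise_sigma
            t.attrs["n_meg"] = truth.n_meg
            gz = t.create_group("gaze")
            gz.create_dataset("horizontal_angle", data=truth.gaze.horizontal_angle)
            gz.create_dataset("vertical_angle", data=truth.gaze.vertical_angle)
            gz.create_dataset("labels", data=truth.gaze.labels)
            gz.create_dataset("blink", data=truth.gaze.blink)
            gz.attrs["sfreq"] = truth.gaze.sfreq
        if config is not None:
            f.create_group("config").attrs["json"] = json.dumps(
                dataclasses.asdict(config))


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        meg = f["meg"]
        sensors = _read_sensors(f["sensors"]) if "sensors" in f else None
        return Recording(
            data=meg["data"][()],
            ch_names=[s.decode() if isinstance(s, bytes) else s
                      for s in meg["ch_names"][()]],
            ch_types=[s.decode() if isinstance(s, bytes) else s
                      for s in meg["ch_types"][()]],
            sfreq=float(meg.attrs["sfreq"]),
            page_spans=[tuple(x) for x in meg["page_spans"][()]],
            site_ids=meg["site_ids"][()],
            pair_ids=meg["pair_ids"][()],
            page_labels=[s.decode() if isinstance(s, bytes) else s
                         for s in meg["page_labels"][()]],
            scale=float(meg.attrs.get("scale", 1.0)),
            sensors=sensors,
        )


def load_truth(path) -> SimulationTruth:
    with h5py.File(path, "r") as f:
        t = f["truth"]
        gz = t["gaze"]
        n = gz["horizontal_angle"].shape[0]
        gaze = GazeTrace(time=np.arange(n) / float(gz.attrs["sfreq"]),
                         horizontal_angle=gz["horizontal_angle"][()],
                         vertical_angle=gz["vertical_angle"][()],
                         labels=gz["labels"][()], blink=gz["blink"][()],
                         sfreq=float(gz.attrs["sfreq"]))
        seed = int(t.attrs["noise_seed"])
        return SimulationTruth(
            artifact_sources={k: v[()] for k, v in t["artifact_sources"].items()},
            artifact_mixing={k: v[()] for k, v in t["artifact_mixing"].items()},
            gaze=gaze,
            brain_sources=t["brain_sources"][()],
            brain_mixing=t["brain_mixing"][()],
            brain_points=t["brain_points"][()],
            noise_seed=None if seed < 0 else seed,
            noise_sigma=float(t.attrs["noise_sigma"]),
            n_meg=int(t.attrs["n_meg"]),
        )


def load_config(path) -> SimConfig:
    with h5py.File(path, "r") as f:
        return SimConfig(**json.loads(f["config"].attrs["json"]))


def save_decomposition(path, dec: Decomposition) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mixing", data=dec.mixing)
        f.create_dataset("demixing", data=dec.demixing)
        if dec.sources is not None:
            f.create_dataset("sources", data=dec.sources)
        f.attrs["method"] = dec.method
        f.attrs["scale"] = dec.scale
        f.create_dataset("ch_names", data=np.array(dec.ch_names, dtype=object),
                         dtype=h5py.string_dtype())


def load_decomposition(path) -> Decomposition:
    with h5py.File(path, "r") as f:
        return Decomposition(
            mixing=f["mixing"][()], demixing=f["demixing"][()],
            sources=f["sources"][()] if "sources" in f else None,
            method=str(f.attrs["method"]), scale=float(f.attrs["scale"]),
            ch_names=[s.decode() if isinstance(s, bytes) else s
                      for s in f["ch_names"][()]],
        )
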