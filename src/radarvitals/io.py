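"""Scene configuration files and data-cube containers.

Scenes are stored as YAML key/value documents; raw IF cubes round-trip
through HDF5 with a fixed ``samples`` dataset of axis order
(fast, slow, channel) and the radar configuration in the root attributes.
"""

from __future__ import annotations

import h5py
import numpy as np
import yaml

from .config import RadarConfig
from .synth import DataCube, SceneDescription, TargetTruth, VitalProfile

__all__ = ["load_scene", "save_scene", "load_cube", "save_cube"]


def _vital_to_dict(v: VitalProfile) -> dict:
    return {
        "respiration_frequency": v.respiration_frequency,
        "respiration_amplitude": v.respiration_amplitude,
        "respiration_harmonics": [list(h) for h in v.respiration_harmonics],
        "heartbeat_frequency": v.heartbeat_frequency,
        "heartbeat_amplitude": v.heartbeat_amplitude,
        "respiration_phase": v.respiration_phase,
        "heartbeat_phase": v.heartbeat_phase,
    }


def _vital_from_dict(d: dict) -> VitalProfile:
    d = dict(d)
    if "respiration_harmonics" in d:
        d["respiration_harmonics"] = tuple(
            (int(m), float(w)) for m, w in d["respiration_harmonics"])
    return VitalProfile(**d)


def save_scene(scene: SceneDescription, path) -> None:
    """Write a scene description to a YAML file (documented schema:
    ``targets`` list with range_m/azimuth_deg/reflectivity/vital,
    ``static_clutter`` list of [range_m, amplitude], ``snr_db``,
    ``duration``, ``seed``)."""
    doc = {
        "targets": [{
            "range_m": t.range_m,
            "azimuth_deg": t.azimuth_deg,
            "reflectivity": t.reflectivity,
            "vital": _vital_to_dict(t.vital),
        } for t in scene.targets],
        "static_clutter": [list(c) for c in scene.static_clutter],
        "snr_db": scene.snr_db,
        "duration": scene.duration,
        "seed": scene.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scene(path) -> SceneDescription:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    targets = tuple(
        TargetTruth(range_m=float(t["range_m"]),
                    azimuth_deg=float(t.get("azimuth_deg", 0.0)),
                    vital=_vital_from_dict(t.get("vital", {})),
                    reflectivity=float(t.get("reflectivity", 1.0)))
        for t in doc.get("targets", []))
    clutter = tuple((float(r), float(a))
                    for r, a in doc.get("static_clutter", []))
    return SceneDescription(targets=targets, static_clutter=clutter,
                            snr_db=doc.get("snr_db"),
                            duration=float(doc.get("duration", 32.0)),
                            seed=int(doc.get("seed", 0)))


def save_cube(cube: DataCube, path) -> None:
    """Store a cube in HDF5: dataset ``samples`` (complex, fast x slow x
    channel) with the radar configuration as root attributes."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("samples", data=cube.samples)
        fh.attrs["axis_order"] = "fast,slow,channel"
        for key, val in cube.config.to_dict().items():
            fh.attrs[key] = "none" if val is None else val


def load_cube(path) -> DataCube:
    with h5py.File(path, "r") as fh:
        samples = fh["samples"][()]
        attrs = dict(fh.attrs)
    attrs.pop("axis_order", None)
    cfg = {k: (None if isinstance(v, (str, bytes)) and str(v) == "none" else v)
           for k, v in attrs.items()}
    for key in ("samples_per_chirp", "n_tx", "n_rx"):
        if key in cfg:
            cfg[key] = int(cfg[key])
    return DataCube(samples=np.asarray(samples),
                    config=RadarConfig.from_dict(cfg))
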