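"""HDF5 container for cohorts of recordings and preprocessed segments.

Layout (one file per cohort):

    /                 attrs: format fields + acquisition metadata (see
                      REQUIRED_ROOT_ATTRS) and provenance (seed,
                      config_hash, software_version)
    /geometry         (64, 3) sensor positions in metres
    /patients/<pid>   attrs: patient_id, labels_json, class_label
        signal          (64, N) float32         [recording containers]
        valid_channels  (64,) bool
        r_peaks         (n,) int                [optional ground truth]
        segments/<i>    (64, 5000) float32      [segment containers]
                        attrs: segment_index, snr, r_peaks

Writing then reading returns bit-identical signal arrays and metadata;
missing required attributes raise :class:`SchemaError` naming the field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .fieldsim import Recording, SensorArray
from .preprocess import Segment

REQUIRED_ROOT_ATTRS = (
    "fs", "units", "component", "sensor_type", "n_channels", "standoff_m",
    "positioning", "shielding", "noise_conditions", "recording_protocol",
    "synchronization", "preprocessing", "label_reference", "validation_design",
)

DEFAULT_METADATA = {
    "units": "arbitrary field units",
    "component": "Bz",
    "sensor_type": "simulated 64-channel SQUID array (current-dipole forward model)",
    "n_channels": 64,
    "positioning": "simulated supine, array centred over the anterior thorax",
    "shielding": "simulated shielded environment (noise injected explicitly)",
    "noise_conditions": "white + baseline drift + 50 Hz line, amplitudes in config",
    "recording_protocol": "continuous resting sinus-rhythm simulation",
    "synchronization": "none (R-peak ground truth stored by the simulator)",
    "preprocessing": "none (raw simulator output)",
    "label_reference": "synthetic class-conditional generative labels",
    "validation_design": "patient-level stratified k-fold cross-validation",
}


class SchemaError(ValueError):
    """A required container attribute or dataset is missing."""


def _write_common(f: h5py.File, array: SensorArray, fs: int,
                  metadata: dict | None, seed: int | None,
                  config_hash: str | None) -> None:
    meta = dict(DEFAULT_METADATA)
    if metadata:
        meta.update(metadata)
    f.attrs["fs"] = fs
    f.attrs["standoff_m"] = array.standoff
    for key, value in meta.items():
        f.attrs[key] = value
    f.attrs["software_version"] = __version__
    if seed is not None:
        f.attrs["seed"] = int(seed)
    if config_hash is not None:
        f.attrs["config_hash"] = config_hash
    f.create_dataset("geometry", data=array.positions)


def write_recordings(path: str | Path, recordings: list[Recording],
                     metadata: dict | None = None, seed: int | None = None,
                     config_hash: str | None = None) -> None:
    if not recordings:
        raise ValueError("no recordings to write")
    with h5py.File(path, "w") as f:
        _write_common(f, recordings[0].sensor_array, recordings[0].fs,
                      metadata, seed, config_hash)
        pats = f.create_group("patients")
        for rec in recordings:
            g = pats.create_group(rec.patient_id)
            g.attrs["patient_id"] = rec.patient_id
            g.attrs["labels_json"] = json.dumps(rec.labels)
            g.attrs["class_label"] = rec.class_label
            g.create_dataset("signal", data=rec.signal)
            g.create_dataset("valid_channels", data=rec.valid_channels)
            if rec.ground_truth_r_peaks is not None:
                g.create_dataset("r_peaks", data=rec.ground_truth_r_peaks)


def _require_attr(obj, name: str):
    if name not in obj.attrs:
        raise SchemaError(name)
    return obj.attrs[name]


def read_recordings(path: str | Path) -> list[Recording]:
    with h5py.File(path, "r") as f:
        fs = int(_require_attr(f, "fs"))
        if "geometry" not in f:
            raise SchemaError("geometry")
        array = SensorArray(np.array(f["geometry"]),
                            component=str(f.attrs.get("component", "Bz")))
        recs = []
        for pid in sorted(f["patients"]):
            g = f["patients"][pid]
            recs.append(Recording(
                signal=np.array(g["signal"]),
                fs=fs,
                sensor_array=array,
                patient_id=str(_require_attr(g, "patient_id")),
                labels=json.loads(_require_attr(g, "labels_json")),
                valid_channels=np.array(g["valid_channels"], dtype=bool),
                ground_truth_r_peaks=(np.array(g["r_peaks"])
                                      if "r_peaks" in g else None),
                class_label=str(g.attrs.get("class_label", "control")),
            ))
        return recs


def write_segments(path: str | Path, segments: list[Segment],
                   array: SensorArray, metadata: dict | None = None,
                   seed: int | None = None, config_hash: str | None = None) -> None:
    if not segments:
        raise ValueError("no segments to write")
    with h5py.File(path, "w") as f:
        _write_common(f, array, segments[0].fs, metadata, seed, config_hash)
        pats = f.create_group("patients")
        for seg in segments:
            if seg.patient_id not in pats:
                g = pats.create_group(seg.patient_id)
                g.attrs["patient_id"] = seg.patient_id
                g.attrs["labels_json"] = json.dumps(seg.labels)
                g.attrs["class_label"] = seg.class_label
                g.create_dataset("valid_channels", data=seg.valid_channels)
                g.create_group("segments")
            sg = pats[seg.patient_id]["segments"].create_dataset(
                str(seg.segment_index), data=seg.signal)
            sg.attrs["segment_index"] = seg.segment_index
            if seg.snr is not None:
                sg.attrs["snr_db"] = seg.snr
            if seg.r_peaks is not None:
                sg.attrs["r_peaks"] = seg.r_peaks


def read_segments(path: str | Path) -> tuple[list[Segment], SensorArray]:
    with h5py.File(path, "r") as f:
        fs = int(_require_attr(f, "fs"))
        if "geometry" not in f:
            raise SchemaError("geometry")
        array = SensorArray(np.array(f["geometry"]),
                            component=str(f.attrs.get("component", "Bz")))
        segments = []
        for pid in sorted(f["patients"]):
            g = f["patients"][pid]
            labels = json.loads(_require_attr(g, "labels_json"))
            valid = np.array(g["valid_channels"], dtype=bool)
            for key in sorted(g["segments"], key=int):
                ds = g["segments"][key]
                segments.append(Segment(
                    signal=np.array(ds), fs=fs, patient_id=pid,
                    segment_index=int(ds.attrs["segment_index"]),
                    valid_channels=valid.copy(), labels=dict(labels),
                    snr=float(ds.attrs["snr_db"]) if "snr_db" in ds.attrs else None,
                    r_peaks=(np.array(ds.attrs["r_peaks"])
                             if "r_peaks" in ds.attrs else None),
                    class_label=str(g.attrs.get("class_label", "control")),
                ))
        return segments, array
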