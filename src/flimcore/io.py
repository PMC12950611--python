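"""File formats: YAML instrument config, CSV tables, HDF5 waveform container.

Waveforms are stored hierarchically (one group per core, one dataset per
band per pass); everything tabular (layouts, annotations, truth, features,
labeled datasets) is plain CSV so it stays diffable and portable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .instrument import DEFAULT_BANDS, InstrumentConfig, SpectralBand
from .labeling import AnnotationTrack
from .simulate import CoreLayout, WaveformScan

__all__ = [
    "save_waveforms",
    "load_waveforms",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_layouts_csv",
    "read_layouts_csv",
    "instrument_to_yaml",
    "instrument_from_yaml",
]


# -- waveform container -----------------------------------------------------

def save_waveforms(scans: List[WaveformScan], path) -> None:
    with h5py.File(path, "w") as f:
        for scan in scans:
            grp = f.require_group(scan.core_id)
            grp.attrs["patient_id"] = scan.patient_id
            sub = grp.create_group(f"pass{scan.pass_index}")
            sub.create_dataset("positions_mm", data=scan.positions_mm)
            for band, wf in scan.waveforms.items():
                sub.create_dataset(band, data=wf, compression="gzip", compression_opts=1)


def load_waveforms(path) -> List[WaveformScan]:
    scans = []
    with h5py.File(path, "r") as f:
        for core_id in f:
            grp = f[core_id]
            pid = grp.attrs["patient_id"]
            for key in grp:
                pass_index = int(key.removeprefix("pass"))
                sub = grp[key]
                positions = sub["positions_mm"][...]
                wf = {b: sub[b][...] for b in sub if b != "positions_mm"}
                scans.append(WaveformScan(core_id, pid, pass_index, positions, wf))
    scans.sort(key=lambda s: (s.core_id, s.pass_index))
    return scans


# -- annotation / layout tables ---------------------------------------------

def write_annotations_csv(tracks: List[AnnotationTrack], path) -> None:
    rows = []
    for t in tracks:
        for lbl, s, e in t.intervals:
            rows.append((t.core_id, t.histology_length_mm, lbl, s, e))
    pd.DataFrame(
        rows, columns=["core_id", "histology_length_mm", "label", "start_mm", "end_mm"]
    ).to_csv(path, index=False)


def read_annotations_csv(path) -> Dict[str, AnnotationTrack]:
    df = pd.read_csv(path)
    tracks = {}
    for core_id, grp in df.groupby("core_id"):
        tracks[core_id] = AnnotationTrack(
            core_id=core_id,
            histology_length_mm=float(grp["histology_length_mm"].iloc[0]),
            intervals=[
                (r.label, float(r.start_mm), float(r.end_mm))
                for r in grp.itertuples()
            ],
        )
    return tracks


def write_layouts_csv(layouts: List[CoreLayout], path) -> None:
    rows = []
    for l in layouts:
        for lbl, s, e in l.segments:
            rows.append((l.core_id, l.patient_id, l.fresh_length_mm, lbl, s, e))
    pd.DataFrame(
        rows,
        columns=["core_id", "patient_id", "fresh_length_mm", "label", "start_mm", "end_mm"],
    ).to_csv(path, index=False)


def read_layouts_csv(path) -> List[CoreLayout]:
    df = pd.read_csv(path)
    layouts = []
    for (core_id, pid, length), grp in df.groupby(
        ["core_id", "patient_id", "fresh_length_mm"]
    ):
        segments = [
            (r.label, float(r.start_mm), float(r.end_mm))
            for r in grp.sort_values("start_mm").itertuples()
        ]
        layouts.append(CoreLayout(core_id, pid, float(length), segments))
    layouts.sort(key=lambda l: l.core_id)
    return layouts


# -- instrument config ------------------------------------------------------

def instrument_to_yaml(config: InstrumentConfig, path) -> None:
    doc = {
        "rep_rate_hz": config.rep_rate_hz,
        "sample_rate_gsps": config.sample_rate_gsps,
        "scan_speed_mm_s": config.scan_speed_mm_s,
        "avg_factor": config.avg_factor,
        "excitation_nm": config.excitation_nm,
        "lateral_resolution_um": config.lateral_resolution_um,
        "n_samples": config.n_samples,
        "irf_fwhm_ns": config.irf_fwhm_ns,
        "irf_peak_ns": config.irf_peak_ns,
        "bands": [
            {
                "name": b.name,
                "center_nm": b.center_nm,
                "halfwidth_nm": b.halfwidth_nm,
                "fluorophore_tag": b.fluorophore_tag,
            }
            for b in config.bands
        ],
    }
    if config.irf is not None:
        doc["irf"] = {k: np.asarray(v).tolist() for k, v in config.irf.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def instrument_from_yaml(path) -> InstrumentConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("instrument config must be a mapping")
    kwargs = dict(doc)
    if "bands" in kwargs:
        kwargs["bands"] = [SpectralBand(**b) for b in kwargs["bands"]]
    if "irf" in kwargs and kwargs["irf"] is not None:
        irf = {}
        for k, v in kwargs["irf"].items():
            if isinstance(v, str):
                # path to a single-column CSV
                v = pd.read_csv(v, header=None).iloc[:, 0].to_numpy(float)
            irf[k] = np.asarray(v, float)
        kwargs["irf"] = irf
    return InstrumentConfig(**kwargs)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
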