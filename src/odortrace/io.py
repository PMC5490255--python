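"""Trial file formats: delimited-text traces with a JSON metadata sidecar.

One trial is stored as ``<stem>.csv`` (columns ``time_s``,
``fluorescence`` and, for GC-coupled trials, ``fid_signal``) plus
``<stem>.json`` holding the sample spec, acquisition spec, free-form
metadata and — for simulated trials — the ground truth.  Movies are
multi-page grayscale TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import TraceValidationError
from .simulate import AcquisitionSpec, GroundTruth, Trial
from .substances import (
    ExcitatoryModel,
    InertModel,
    InhibitoryModel,
    Kinetics,
    SampleSpec,
    SubstanceSpec,
)
from .trace import Trace


# --- dataclass (de)serialization -----------------------------------------

def _model_to_dict(model) -> dict:
    if isinstance(model, ExcitatoryModel):
        return {"kind": "excitatory", "rmax": model.rmax, "ec50": model.ec50,
                "h": model.h, "kinetics": dataclasses.asdict(model.kinetics)}
    if isinstance(model, InhibitoryModel):
        return {"kind": "inhibitory", "amplitude": model.amplitude_value,
                "kinetics": dataclasses.asdict(model.kinetics)}
    return {"kind": "inert"}


def _model_from_dict(d: dict):
    kind = d["kind"]
    if kind == "inert":
        return InertModel()
    kin = Kinetics(**d["kinetics"])
    if kind == "excitatory":
        return ExcitatoryModel(rmax=d["rmax"], ec50=d["ec50"], h=d["h"],
                               kinetics=kin)
    if kind == "inhibitory":
        return InhibitoryModel(amplitude_value=d["amplitude"], kinetics=kin)
    raise TraceValidationError(f"unknown receptor model kind {kind!r}")


def substance_to_dict(sub: SubstanceSpec) -> dict:
    return {"name": sub.name, "retention_time": sub.retention_time,
            "elution_width": sub.elution_width,
            "fid_response_factor": sub.fid_response_factor,
            "receptor_model": _model_to_dict(sub.receptor_model)}


def substance_from_dict(d: dict) -> SubstanceSpec:
    return SubstanceSpec(
        name=d["name"], retention_time=d["retention_time"],
        elution_width=d["elution_width"],
        fid_response_factor=d["fid_response_factor"],
        receptor_model=_model_from_dict(d["receptor_model"]))


def sample_to_dict(sample: SampleSpec) -> dict:
    return {"main_substance": substance_to_dict(sample.main_substance),
            "dilution": sample.dilution,
            "contaminants": [[substance_to_dict(s), f]
                             for s, f in sample.contaminants]}


def sample_from_dict(d: dict) -> SampleSpec:
    return SampleSpec(
        main_substance=substance_from_dict(d["main_substance"]),
        dilution=d["dilution"],
        contaminants=tuple((substance_from_dict(s), f)
                           for s, f in d["contaminants"]))


def write_trial(trial: Trial, stem: Path | str) -> tuple[Path, Path]:
    """Write a trial as ``<stem>.csv`` + ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    cols = {"time_s": trial.fluorescence.times,
            "fluorescence": trial.fluorescence.values}
    if trial.fid is not None:
        if not trial.fid.same_grid(trial.fluorescence):
            raise TraceValidationError("FID and fluorescence grids differ")
        cols["fid_signal"] = trial.fid.values
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = {
        "sample": sample_to_dict(trial.sample),
        "acquisition": dataclasses.asdict(trial.acquisition),
        "meta": trial.meta,
        "ground_truth": _truth_to_dict(trial.truth) if trial.truth else None,
    }
    json_path.write_text(json.dumps(sidecar, indent=1, default=_json_default))
    return csv_path, json_path


def _json_default(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _truth_to_dict(truth: GroundTruth) -> dict:
    d = dataclasses.asdict(truth)
    return d


def _truth_from_dict(d: dict) -> GroundTruth:
    d = dict(d)
    if d.get("bleach") is not None:
        d["bleach"] = tuple(d["bleach"])
    if d.get("stimulus_onsets") is not None:
        d["stimulus_onsets"] = tuple(d["stimulus_onsets"])
    return GroundTruth(**d)


def read_trial(stem: Path | str) -> Trial:
    """Read a trial written by :func:`write_trial`."""
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"))
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    acq_d = dict(sidecar["acquisition"])
    acq_d["bleach"] = tuple(acq_d["bleach"])
    acq = AcquisitionSpec(**acq_d)
    times = df["time_s"].to_numpy()
    fluo = Trace(times, df["fluorescence"].to_numpy(), acq.rate,
                 channel="fluorescence", meta=dict(sidecar["meta"]))
    fid = None
    if "fid_signal" in df.columns:
        fid = Trace(times, df["fid_signal"].to_numpy(), acq.rate, channel="fid")
    truth = (_truth_from_dict(sidecar["ground_truth"])
             if sidecar.get("ground_truth") else None)
    return Trial(fluorescence=fluo, fid=fid,
                 sample=sample_from_dict(sidecar["sample"]),
                 acquisition=acq, truth=truth, meta=dict(sidecar["meta"]))


def read_trial_dir(directory: Path | str) -> list[Trial]:
    """Read every trial (``*.csv`` with matching ``*.json``) in a directory."""
    directory = Path(directory)
    trials = []
    for csv_path in sorted(directory.glob("*.csv")):
        if csv_path.with_suffix(".json").exists():
            trials.append(read_trial(csv_path.with_suffix("")))
    return trials


def write_movie(stack: np.ndarray, path: Path | str) -> Path:
    """Write an image stack as multi-page grayscale TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    return path


def write_peak_table(peaks, path: Path | str,
                     assigned: dict | None = None) -> Path:
    """Write a detected-peak table as delimited text."""
    inv = {}
    if assigned:
        for name, pk in assigned.items():
            if name == "unassigned":
                continue
            if pk is not None:
                inv[id(pk)] = name
    rows = [{"apex_s": p.apex_time, "amplitude": p.amplitude,
             "width_s": p.width, "baseline": p.baseline, "channel": p.channel,
             "assigned_substance": inv.get(id(p), "")} for p in peaks]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
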