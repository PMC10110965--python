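"""HDF5 container and tabular I/O.

Container layout (schema-versioned, attribute ``vseeg_container``):

* recordings: ``/data`` (channels x samples, float32), ``/fs``,
  ``/channel_table`` (ids, modality)
* epochs: ``/epochs/{data, fs, first_sample, labels, correct, rt,
  channel_ids, space, subject}``
* beamformer: ``/beamformer/{weights, orientations, grid_indices, grid_points,
  channel_ids, output_names}``
* SOBI: ``/sobi/{whitener, rotation, mixing, unmixing, lags}``
* decoding: ``/decoding/{scores, times, space, n_folds, seed}``

Events, geometry, scores and ROI tables travel as TSV; cluster test results
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .beamformer import SpatialFilter
from .containers import ContinuousRecording, EpochArray
from .decoding import DecodingScores, ROILabeling
from .geometry import Sensor, SensorGeometry
from .inference import Cluster, ClusterTestResult
from .schedule import TrialEvent, TrialSchedule
from .sobi import UnmixingModel

__all__ = ["ContainerSchemaError", "CONTAINER_VERSION",
           "write_recording", "read_recording", "write_epochs", "read_epochs",
           "write_events_tsv", "read_events_tsv", "write_geometry_tsv",
           "read_geometry_tsv", "write_scores_tsv", "write_roi_tsv",
           "read_roi_tsv", "write_beamformer", "read_beamformer",
           "write_sobi", "read_sobi", "write_clusters_json",
           "read_clusters_json", "read_edf"]

CONTAINER_VERSION = 1
_MAGIC = "vseeg_container"


class ContainerSchemaError(RuntimeError):
    pass


def _open(path, mode):
    try:
        return h5py.File(path, mode)
    except OSError as err:
        raise ContainerSchemaError(f"not a readable container: {path}") from err


def _check_magic(f: h5py.File) -> None:
    version = f.attrs.get(_MAGIC)
    if version is None:
        raise ContainerSchemaError("missing container magic attribute")
    if int(version) != CONTAINER_VERSION:
        raise ContainerSchemaError(
            f"container schema version {version} != {CONTAINER_VERSION}")


def _stamp(f: h5py.File) -> None:
    f.attrs[_MAGIC] = CONTAINER_VERSION


# ------------------------------------------------------------- recordings

def write_recording(path, rec: ContinuousRecording, dtype=np.float32) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f)
        f.create_dataset("data", data=rec.data.astype(dtype))
        f["fs"] = rec.fs
        table = np.array(
            [(ch, rec.modality) for ch in rec.channel_ids],
            dtype=[("id", "S32"), ("modality", "S16")])
        f.create_dataset("channel_table", data=table)


def read_recording(path) -> ContinuousRecording:
    with _open(path, "r") as f:
        _check_magic(f)
        table = f["channel_table"][...]
        ids = [x.decode() for x in table["id"]]
        modality = table["modality"][0].decode()
        return ContinuousRecording(f["data"][...].astype(np.float64),
                                   float(f["fs"][()]), ids, modality)


# ------------------------------------------------------------- epochs

def write_epochs(path, ep: EpochArray, group: str = "epochs",
                 mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        _stamp(f)
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("data", data=ep.data)
        g["fs"] = ep.fs
        g["first_sample"] = ep.first_sample
        g.create_dataset("labels", data=np.array([s.encode() for s in ep.labels]))
        g.create_dataset("correct", data=ep.correct)
        g.create_dataset("rt", data=ep.response_time_s)
        g.create_dataset("channel_ids",
                         data=np.array([c.encode() for c in ep.channel_ids]))
        g.attrs["space"] = ep.space
        g.attrs["subject"] = ep.subject


def read_epochs(path, group: str = "epochs") -> EpochArray:
    with _open(path, "r") as f:
        _check_magic(f)
        g = f[group]
        return EpochArray(
            data=g["data"][...],
            fs=float(g["fs"][()]),
            first_sample=int(g["first_sample"][()]),
            labels=np.array([x.decode() for x in g["labels"][...]], dtype=object),
            correct=g["correct"][...],
            response_time_s=g["rt"][...],
            subject=str(g.attrs["subject"]),
            channel_ids=[x.decode() for x in g["channel_ids"][...]],
            space=str(g.attrs["space"]),
        )


# ------------------------------------------------------------- events

def write_events_tsv(path, schedule: TrialSchedule, duration_s: float = 0.5) -> None:
    rows = []
    for e in schedule.events:
        rows.append({
            "onset": e.onset_s,
            "duration": duration_s,
            "trial_type": e.phase,
            "novelty": e.novelty if e.novelty is not None else "n/a",
            "response_time": e.response_time_s if e.response_time_s is not None else "n/a",
            "correct": int(e.correct) if e.correct is not None else "n/a",
            "block": e.block_index,
            "image_id": e.image_id,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> TrialSchedule:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    events = []
    for _, r in df.iterrows():
        nov = r.get("novelty")
        nov = None if pd.isna(nov) else str(nov)
        rt = r.get("response_time", np.nan)
        corr = r.get("correct", np.nan)
        events.append(TrialEvent(
            block_index=int(r.get("block", 0)),
            phase=str(r["trial_type"]),
            image_id=int(r.get("image_id", -1)),
            novelty=nov,
            onset_s=float(r["onset"]),
            response_time_s=None if pd.isna(rt) else float(rt),
            correct=None if pd.isna(corr) else bool(corr),
        ))
    return TrialSchedule(events)


# ------------------------------------------------------------- geometry

def write_geometry_tsv(path, geom: SensorGeometry) -> None:
    rows = []
    for s in geom.sensors:
        x, y, z = s.position_mm
        rows.append({"id": s.id, "modality": s.modality, "x": x, "y": y, "z": z,
                     "shaft": s.shaft_id or "n/a",
                     "index": s.contact_index if s.contact_index is not None else "n/a"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_geometry_tsv(path, sphere_radius_mm: float = 90.0) -> SensorGeometry:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    sensors = []
    for _, r in df.iterrows():
        sensors.append(Sensor(
            id=str(r["id"]), modality=str(r["modality"]),
            position_mm=(float(r["x"]), float(r["y"]), float(r["z"])),
            shaft_id=None if pd.isna(r["shaft"]) else str(r["shaft"]),
            contact_index=None if pd.isna(r["index"]) else int(r["index"]),
        ))
    return SensorGeometry(sensors, sphere_radius_mm)


# ------------------------------------------------------------- scores / ROI

def write_scores_tsv(path, scores: DecodingScores) -> None:
    folds, times = np.meshgrid(np.arange(scores.n_folds), scores.times,
                               indexing="ij")
    df = pd.DataFrame({
        "fold": folds.ravel(), "time_s": times.ravel(),
        "auc": scores.scores.ravel(), "space": scores.space,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_roi_tsv(path, roi: ROILabeling) -> None:
    df = pd.DataFrame(sorted(roi.labels.items()), columns=["channel", "label"])
    df.to_csv(path, sep="\t", index=False)


def read_roi_tsv(path, vocabulary=None) -> ROILabeling:
    df = pd.read_csv(path, sep="\t")
    labels = dict(zip(df["channel"].astype(str), df["label"].astype(str)))
    if vocabulary is not None:
        return ROILabeling(labels, tuple(vocabulary))
    return ROILabeling(labels)


# ------------------------------------------------------------- models

def write_beamformer(path, filt: SpatialFilter, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        _stamp(f)
        if "beamformer" in f:
            del f["beamformer"]
        g = f.create_group("beamformer")
        g.create_dataset("weights", data=filt.weights)
        g.create_dataset("orientations", data=filt.orientations)
        g.create_dataset("grid_indices", data=filt.grid_indices)
        g.create_dataset("channel_ids",
                         data=np.array([c.encode() for c in filt.channel_ids]))
        g.create_dataset("output_names",
                         data=np.array([c.encode() for c in filt.output_names]))


def read_beamformer(path) -> SpatialFilter:
    with _open(path, "r") as f:
        _check_magic(f)
        g = f["beamformer"]
        return SpatialFilter(
            g["weights"][...], g["orientations"][...], g["grid_indices"][...],
            [x.decode() for x in g["channel_ids"][...]],
            [x.decode() for x in g["output_names"][...]])


def write_sobi(path, model: UnmixingModel, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        _stamp(f)
        if "sobi" in f:
            del f["sobi"]
        g = f.create_group("sobi")
        for name in ("whitener", "rotation", "mixing", "unmixing"):
            g.create_dataset(name, data=getattr(model, name))
        g.create_dataset("lags", data=np.array(model.lags))


def read_sobi(path) -> UnmixingModel:
    with _open(path, "r") as f:
        _check_magic(f)
        g = f["sobi"]
        return UnmixingModel(
            g["whitener"][...], g["rotation"][...], g["mixing"][...],
            g["unmixing"][...], [int(x) for x in g["lags"][...]])


# ------------------------------------------------------------- clusters

def write_clusters_json(path, res: ClusterTestResult,
                        extra: dict | None = None) -> None:
    payload = {
        "clusters": [
            {"start": c.start, "end": c.end, "mass": c.mass, "p_value": c.p_value}
            for c in res.clusters],
        "threshold": res.threshold,
        "n_permutations": res.n_permutations,
        "seed": res.seed,
        "alternative": res.alternative,
        "exact": res.exact,
        "note": res.note,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_clusters_json(path) -> ClusterTestResult:
    payload = json.loads(Path(path).read_text())
    clusters = [Cluster(c["start"], c["end"], c["mass"], c["p_value"])
                for c in payload["clusters"]]
    return ClusterTestResult(clusters, payload["threshold"],
                             payload["n_permutations"], payload["seed"],
                             payload["alternative"], payload["exact"],
                             payload.get("note", ""))


# ------------------------------------------------------------- EDF import

def read_edf(path, modality: str = "scalp") -> ContinuousRecording:
    """Import a continuous recording from EDF (requires the optional mne
    dependency)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF import requires the optional 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6          # volts -> microvolts
    return ContinuousRecording(data, float(raw.info["sfreq"]),
                               list(raw.ch_names), modality)
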