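"""Continuous-to-epochs preprocessing for scalp and depth recordings.

Standard order: resample to 256 Hz, zero-phase 0.5–45 Hz band-pass, reference
(common average for scalp, bipolar montage for SEEG), epoch around recognition
onsets with pre-stimulus baseline correction keeping correct trials only, and
automatic artifact rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import ContinuousRecording, EpochArray
from .geometry import SensorGeometry
from .schedule import TrialSchedule

__all__ = ["resample", "bandpass", "common_average", "BipolarMap",
           "make_bipolar_map", "bipolar", "epoch", "reject_artifacts",
           "RejectionReport", "preprocess"]


def resample(rec: ContinuousRecording, fs_out: float) -> ContinuousRecording:
    """Anti-aliased polyphase resampling (downsampling only)."""
    if fs_out > rec.fs:
        raise ValueError(f"no upsampling: fs_out {fs_out} > fs_in {rec.fs}")
    if fs_out == rec.fs:
        return rec.copy_with()
    frac = Fraction(fs_out / rec.fs).limit_denominator(10_000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=out, fs=fs_out)


def bandpass(rec: ContinuousRecording, lo: float = 0.5, hi: float = 45.0,
             order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (forward-backward application)."""
    nyq = rec.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"invalid band [{lo}, {hi}] Hz at fs {rec.fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out)


def common_average(rec: ContinuousRecording) -> ContinuousRecording:
    """Re-reference every channel to the instantaneous cross-channel mean."""
    if rec.n_channels < 2:
        raise ValueError("common average needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=out)


@dataclass
class BipolarMap:
    """Adjacent-contact pairs on each shaft, deeper minus shallower.

    ``pairs`` holds (contact_a, contact_b) channel ids with a the deeper
    (lower-index) contact; ``midpoints_mm`` the per-pair contact midpoint.
    """

    pairs: list[tuple[str, str]]
    midpoints_mm: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.midpoints_mm = np.asarray(self.midpoints_mm, dtype=float)
        if self.midpoints_mm.shape != (len(self.pairs), 3):
            raise ValueError("one 3-D midpoint per pair required")


def make_bipolar_map(geometry: SensorGeometry) -> BipolarMap:
    """Exhaustive bipolar montage: contacts (k, k+1) on every shaft."""
    pairs, mids, names = [], [], []
    for shaft, contacts in geometry.shafts().items():
        for a, b in zip(contacts[:-1], contacts[1:]):
            pairs.append((a.id, b.id))
            mids.append((np.asarray(a.position_mm) + np.asarray(b.position_mm)) / 2.0)
            names.append(f"{a.id}-{b.id}")
    return BipolarMap(pairs, np.array(mids), names)


def bipolar(rec: ContinuousRecording, bmap: BipolarMap) -> ContinuousRecording:
    """Apply the bipolar montage: output k = deeper contact − shallower."""
    index = {ch: i for i, ch in enumerate(rec.channel_ids)}
    rows = []
    for a, b in bmap.pairs:
        if a not in index or b not in index:
            raise KeyError(f"bipolar pair ({a}, {b}) not in recording channels")
        rows.append(rec.data[index[a]] - rec.data[index[b]])
    return ContinuousRecording(np.array(rows), rec.fs, list(bmap.names), rec.modality)


def epoch(
    rec: ContinuousRecording,
    schedule: TrialSchedule,
    tmin_s: float = -0.2,
    tmax_s: float = 1.0,
    baseline: tuple[float, float] | None = (-0.2, 0.0),
    correct_only: bool = True,
    subject: str = "sim01",
    space: str | None = None,
) -> EpochArray:
    """Cut recognition-locked epochs with per-trial baseline correction.

    t = 0 falls exactly on the sample nearest each stimulus onset; trials with
    ``correct=False`` (or unknown correctness) are dropped when
    ``correct_only``.
    """
    n0 = int(round(tmin_s * rec.fs))
    n1 = int(round(tmax_s * rec.fs))
    events = schedule.recognition_events
    if correct_only:
        events = [e for e in events if e.correct]
    if not events:
        raise ValueError("no epochs to extract")
    trials, labels, correct, rts = [], [], [], []
    for ev in events:
        onset = int(round(ev.onset_s * rec.fs))
        if onset + n0 < 0 or onset + n1 >= rec.n_samples:
            raise IndexError(
                f"epoch window for onset {ev.onset_s:.2f}s outside recording")
        trials.append(rec.data[:, onset + n0: onset + n1 + 1])
        labels.append(ev.novelty)
        correct.append(bool(ev.correct) if ev.correct is not None else True)
        rts.append(ev.response_time_s if ev.response_time_s is not None else np.nan)
    data = np.array(trials)
    times = (n0 + np.arange(data.shape[2])) / rec.fs
    if baseline is not None:
        mask = (times >= baseline[0]) & (times <= baseline[1])
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        data = data - data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochArray(
        data=data, fs=rec.fs, first_sample=n0,
        labels=np.array(labels, dtype=object),
        correct=np.array(correct), response_time_s=np.array(rts),
        subject=subject, channel_ids=list(rec.channel_ids),
        space=space or ("scalp" if rec.modality == "scalp" else "seeg-bipolar"),
    )


@dataclass
class RejectionReport:
    dropped_trials: list[tuple[int, float]]    # (trial index, peak |z|)
    bad_channels: list[tuple[str, float]]      # (channel id, variance)
    n_retained: int


def reject_artifacts(
    ep: EpochArray, z_max: float = 6.0, flat_tol: float = 1e-12,
) -> tuple[EpochArray, RejectionReport]:
    """Automatic trial/channel rejection.

    Channels with variance below ``flat_tol`` are flagged bad and excluded;
    trials whose peak absolute z-score (z computed across trials, per channel
    and sample) exceeds ``z_max`` are dropped.
    """
    if ep.n_trials < 2:
        raise ValueError("need at least 2 trials")
    var = ep.data.var(axis=(0, 2))
    bad = [(ep.channel_ids[i], float(var[i])) for i in np.flatnonzero(var < flat_tol)]
    keep_ch = np.flatnonzero(var >= flat_tol)
    data = ep.data[:, keep_ch, :]
    mu = data.mean(axis=0, keepdims=True)
    sd = data.std(axis=0, keepdims=True)
    sd[sd == 0] = np.inf
    peak = np.abs((data - mu) / sd).max(axis=(1, 2)) if keep_ch.size else \
        np.zeros(ep.n_trials)
    dropped = [(int(i), float(peak[i])) for i in np.flatnonzero(peak > z_max)]
    keep_tr = np.flatnonzero(peak <= z_max)
    if keep_tr.size == 0:
        raise ValueError("all trials rejected")
    out = ep.select_channels(keep_ch).select_trials(keep_tr)
    return out, RejectionReport(dropped, bad, int(keep_tr.size))


def preprocess(
    rec: ContinuousRecording,
    schedule: TrialSchedule,
    fs_out: float = 256.0,
    band: tuple[float, float] = (0.5, 45.0),
    bipolar_map: BipolarMap | None = None,
    tmin_s: float = -0.2,
    tmax_s: float = 1.0,
    z_max: float = 6.0,
    subject: str = "sim01",
) -> tuple[EpochArray, RejectionReport]:
    """Full preprocessing chain for one modality.

    Scalp recordings get common-average referencing; depth recordings the
    bipolar montage (``bipolar_map`` required).
    """
    rec = resample(rec, fs_out)
    rec = bandpass(rec, *band)
    if rec.modality == "scalp":
        rec = common_average(rec)
    else:
        if bipolar_map is None:
            raise ValueError("depth preprocessing requires a bipolar map")
        rec = bipolar(rec, bipolar_map)
    ep = epoch(rec, schedule, tmin_s=tmin_s, tmax_s=tmax_s, subject=subject)
    return reject_artifacts(ep, z_max=z_max)
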