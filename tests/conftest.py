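"""Shared fixtures: scaled simulated sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from vseeg import (default_sources, make_geometry, make_task_schedule,
                   simulate_subject)
from vseeg.containers import EpochArray
from vseeg.preprocessing import make_bipolar_map, preprocess


@pytest.fixture(scope="session")
def small_session():
    """One scaled simulated session: 3 block pairs, 16 scalp + 4x8 depth."""
    schedule = make_task_schedule(3, 12, isi_s=2.5, seed=11,
                                  inter_block_gap_s=5.0)
    geometry = make_geometry(16, 4, 8, seed=12)
    sources = default_sources(2, seed=13)
    rec_scalp, rec_depth, gt = simulate_subject(
        schedule, geometry, sources, snr={"scalp": 0.25, "depth": 2.5},
        fs=512.0, seed=14)
    return {"schedule": schedule, "geometry": geometry, "sources": sources,
            "rec_scalp": rec_scalp, "rec_depth": rec_depth, "gt": gt,
            "bmap": make_bipolar_map(geometry)}


@pytest.fixture(scope="session")
def small_epochs(small_session):
    """Preprocessed epochs for both modalities of the scaled session."""
    s = small_session
    ep_scalp, _ = preprocess(s["rec_scalp"], s["gt"].schedule)
    ep_depth, _ = preprocess(s["rec_depth"], s["gt"].schedule,
                             bipolar_map=s["bmap"])
    return ep_scalp, ep_depth


def make_synthetic_epochs(
    n_trials=200, n_channels=8, n_samples=30, fs=100.0, first_sample=None,
    effect_channels=None, effect_window=None, effect_size=0.0, seed=0,
    ar_coeff=0.0,
):
    """Directly constructed epochs: Gaussian (optionally AR(1)) noise plus a
    class-dependent mean shift on selected channels inside a sample window."""
    if first_sample is None:
        first_sample = -(n_samples // 4)
    rng = np.random.default_rng(seed)
    labels = np.array(["OLD", "NEW"] * (n_trials // 2), dtype=object)
    rng.shuffle(labels)
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    if ar_coeff:
        for t in range(1, n_samples):
            data[:, :, t] = ar_coeff * data[:, :, t - 1] + \
                np.sqrt(1 - ar_coeff ** 2) * data[:, :, t]
    if effect_size and effect_window is not None:
        lo, hi = effect_window
        chans = effect_channels if effect_channels is not None \
            else np.arange(n_channels)
        sign = np.where(labels == "OLD", 1.0, -1.0)
        for c in chans:
            data[:, c, lo:hi] += 0.5 * effect_size * sign[:, None]
    return EpochArray(
        data=data, fs=fs, first_sample=first_sample, labels=labels,
        correct=np.ones(n_trials, dtype=bool),
        response_time_s=np.full(n_trials, 0.7),
        subject="synth", channel_ids=[f"ch{i:02d}" for i in range(n_channels)],
        space="scalp")
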