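"""Forward simulation of simultaneous scalp and depth recordings.

Each recognition trial evokes, in every dipole source, a condition-independent
response plus a condition-differential response (OLD minus NEW) confined to the
source's effect window.  Incorrect trials flip the sign of the differential —
the neural correlate of a wrong novelty judgment — which gives the
correct-trial filter downstream operational meaning.  Sensor noise has a 1/f
amplitude spectrum and is spatially correlated through a random mixing matrix.

SNR is defined per modality as RMS of the trial-averaged evoked response over
RMS of noise, within the effect window, averaged over channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ContinuousRecording
from .forward import (DipoleSourceSet, DipoleSource, HeadModel, LeadField,
                      Waveform, lead_field)
from .geometry import SensorGeometry
from .schedule import RESPONSE_DEADLINE_S, TrialSchedule

__all__ = ["GroundTruth", "default_sources", "simulate_subject",
           "annotate_behavior", "DEFAULT_RT_PARAMS", "DEFAULT_ACCURACY"]

# session-level behavioral statistics used as defaults: observed accuracy and
# per-condition response-time mean/SD in seconds
DEFAULT_ACCURACY = 0.8953
DEFAULT_RT_PARAMS = {"OLD": (0.7191, 0.1624), "NEW": (0.7650, 0.1912)}


@dataclass
class GroundTruth:
    """Everything the simulator knows that the analysis must rediscover."""

    effect_window_s: tuple[float, float]
    snr_realized: dict[str, np.ndarray]      # per-channel, per modality
    mixing_scalp: np.ndarray                  # channels x sources
    mixing_depth: np.ndarray
    schedule: TrialSchedule                   # behavior-annotated copy
    source_set: DipoleSourceSet
    seed: int
    noise_gain: dict[str, float]


def default_sources(
    n_sources: int = 2,
    sphere_radius_mm: float = 90.0,
    seed: int = 0,
    baseline_amplitude_nAm: float = 30.0,
    differential_amplitude_nAm: float = 20.0,
    effect_window_s: tuple[float, float] = (0.3, 0.5),
) -> DipoleSourceSet:
    """Deep dipole sources with a mid-latency old/new differential.

    Sources sit at 30–50% of the head radius (deep structures, nearer the
    depth contacts than the scalp), with a condition-independent response at
    100–450 ms and the differential confined to ``effect_window_s``.
    """
    rng = np.random.default_rng(seed)
    sources = []
    for _ in range(n_sources):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos = u * rng.uniform(0.3, 0.5) * sphere_radius_mm
        ori = rng.normal(size=3)
        ori /= np.linalg.norm(ori)
        sources.append(DipoleSource(
            position_mm=tuple(pos),
            orientation=tuple(ori),
            baseline=Waveform(baseline_amplitude_nAm, 0.1, 0.45),
            differential=Waveform(differential_amplitude_nAm, *effect_window_s),
        ))
    return DipoleSourceSet(sources)


def annotate_behavior(
    schedule: TrialSchedule,
    accuracy: float,
    rt_params: dict[str, tuple[float, float]],
    rng: np.random.Generator,
) -> TrialSchedule:
    """Draw correctness and response times for every recognition trial.

    Correctness is Bernoulli(accuracy); response times are lognormal with the
    given per-condition mean/SD, rejection-sampled below the 1.5 s deadline so
    the configured accuracy is the net observed rate.
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must be in (0, 1]")
    rec = schedule.recognition_events
    correct = rng.random(len(rec)) < accuracy
    rts = np.empty(len(rec))
    for i, ev in enumerate(rec):
        m, s = rt_params[ev.novelty]
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        while True:
            rt = rng.lognormal(mu, np.sqrt(sigma2))
            if rt <= RESPONSE_DEADLINE_S:
                break
        rts[i] = rt
    return schedule.with_behavior(rts, correct)


def _one_over_f_noise(n_rows: int, n_samples: int, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Rows of unit-RMS noise with 1/f amplitude spectrum (power ~ 1/f^2 per
    amplitude scaling 1/f; we use amplitude ~ f^-0.5, i.e. power ~ 1/f)."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** -0.5
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale[None, :], n=n_samples, axis=1)
    rms = np.sqrt(np.mean(out ** 2, axis=1, keepdims=True))
    return out / rms


def _resolve_snr(snr) -> dict[str, float]:
    if isinstance(snr, dict):
        missing = {"scalp", "depth"} - set(snr)
        if missing:
            raise ValueError(f"snr dict missing {missing}")
        return {k: float(snr[k]) for k in ("scalp", "depth")}
    return {"scalp": float(snr), "depth": 10.0 * float(snr)}


def simulate_subject(
    schedule: TrialSchedule,
    geometry: SensorGeometry,
    sources: DipoleSourceSet,
    snr=0.25,
    accuracy: float = DEFAULT_ACCURACY,
    rt_params: dict[str, tuple[float, float]] | None = None,
    fs: float = 512.0,
    seed: int = 0,
    model: HeadModel | None = None,
    subject: str = "sim01",
) -> tuple[ContinuousRecording, ContinuousRecording, GroundTruth]:
    """Simulate one session of synchronized scalp and depth recordings.

    Parameters
    ----------
    snr : float or dict
        Evoked-to-noise RMS ratio in the effect window, channel-averaged per
        modality.  A scalar sets the scalp SNR; depth then defaults to ten
        times that (near-field contacts a few mm from the generators vs
        far-field scalp sensors).  Use ``{"scalp": x, "depth": y}`` for
        explicit control; ``inf`` disables noise.
    """
    if fs < 256.0:
        raise ValueError("fs must be >= 256 Hz")
    model = model or HeadModel(sphere_radius_mm=geometry.sphere_radius_mm)
    if abs(model.sphere_radius_mm - geometry.sphere_radius_mm) > 1e-9:
        raise ValueError("head model and geometry sphere radii disagree")
    rt_params = rt_params or DEFAULT_RT_PARAMS
    snr_target = _resolve_snr(snr)
    rng = np.random.default_rng(seed)

    sched = annotate_behavior(schedule, accuracy, rt_params, rng)
    rec_events = sched.recognition_events
    if not rec_events:
        raise ValueError("schedule contains no recognition events")

    t_end = max(e.onset_s for e in sched.events) + 2.0
    n_samples = int(np.ceil(t_end * fs))

    # per-source waveform rows for the whole session
    n_src = len(sources.sources)
    S = np.zeros((n_src, n_samples))
    epoch_t = np.arange(0, int(1.2 * fs)) / fs      # 1.2 s of response support
    for ev in rec_events:
        onset = int(round(ev.onset_s * fs))
        sl = slice(onset, min(onset + epoch_t.size, n_samples))
        tt = epoch_t[: sl.stop - sl.start]
        nov_sign = 1.0 if ev.novelty == "OLD" else -1.0
        corr_sign = 1.0 if ev.correct else -1.0
        for k, src in enumerate(sources.sources):
            S[k, sl] += src.baseline.sample(tt) + \
                0.5 * nov_sign * corr_sign * src.differential.sample(tt)

    lf_scalp = lead_field(geometry, sources.positions, model, "scalp")
    lf_depth = lead_field(geometry, sources.positions, model, "depth")
    mix_scalp = lf_scalp.fixed(sources.orientations)   # channels x sources
    mix_depth = lf_depth.fixed(sources.orientations)

    # trial-averaged clean evoked response, for SNR calibration
    win = sources.effect_window_s
    win_idx = (epoch_t >= win[0]) & (epoch_t <= win[1])
    n_ep = min(epoch_t.size, n_samples)
    avg_src = np.zeros((n_src, n_ep))
    for ev in rec_events:
        onset = int(round(ev.onset_s * fs))
        seg = S[:, onset:onset + n_ep]
        avg_src[:, :seg.shape[1]] += seg
    avg_src /= len(rec_events)

    out = {}
    snr_realized = {}
    noise_gain = {}
    for modality, mix in [("scalp", mix_scalp), ("depth", mix_depth)]:
        clean = mix @ S
        evoked = mix @ avg_src
        evoked_rms = np.sqrt(np.mean(evoked[:, win_idx[:n_ep]] ** 2, axis=1))
        n_ch = mix.shape[0]
        target = snr_target[modality]
        if np.isinf(target):
            gain = 0.0
            noise = np.zeros_like(clean)
            realized = np.full(n_ch, np.inf)
        else:
            base = _one_over_f_noise(n_ch, n_samples, fs, rng)
            spatial = rng.standard_normal((n_ch, n_ch)) / np.sqrt(n_ch)
            noise = spatial @ base
            ch_rms = np.sqrt(np.mean(noise ** 2, axis=1))
            gain = float(np.mean(evoked_rms) / target / np.mean(ch_rms))
            noise *= gain
            realized = evoked_rms / (gain * ch_rms)
        out[modality] = ContinuousRecording(
            clean + noise, fs, geometry.ids(modality), modality)
        snr_realized[modality] = realized
        noise_gain[modality] = gain

    gt = GroundTruth(
        effect_window_s=win,
        snr_realized=snr_realized,
        mixing_scalp=mix_scalp,
        mixing_depth=mix_depth,
        schedule=sched,
        source_set=sources,
        seed=seed,
        noise_gain=noise_gain,
    )
    return out["scalp"], out["depth"], gt
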