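"""Old/new recognition-memory task schedules.

The task alternates encoding blocks (a set of images shown once) with
recognition blocks in which the just-encoded images ("OLD") are pseudo-randomly
interleaved with as many unseen images ("NEW"), under the constraint that the
same novelty label never occurs more than three times in a row.  Subjects
respond OLD/NEW within 1.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TrialEvent", "TrialSchedule", "make_task_schedule",
           "MAX_NOVELTY_RUN", "RESPONSE_DEADLINE_S"]

MAX_NOVELTY_RUN = 3
RESPONSE_DEADLINE_S = 1.5


@dataclass(frozen=True)
class TrialEvent:
    block_index: int
    phase: str                       # "encoding" | "recognition"
    image_id: int
    novelty: str | None              # "OLD" | "NEW"; None for encoding
    onset_s: float
    response_time_s: float | None = None
    correct: bool | None = None


@dataclass
class TrialSchedule:
    """Ordered sequence of task events for one session."""

    events: list[TrialEvent]

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b >= a for a, b in zip(onsets[1:], onsets[:-1])):
            raise ValueError("event onsets must be strictly increasing")
        for e in self.events:
            if e.phase not in ("encoding", "recognition"):
                raise ValueError(f"bad phase {e.phase!r}")
            if e.phase == "recognition" and e.novelty not in ("OLD", "NEW"):
                raise ValueError("recognition events need OLD/NEW novelty")
            if e.phase == "encoding" and e.novelty is not None:
                raise ValueError("encoding events carry no novelty label")
            if e.response_time_s is not None and e.response_time_s > RESPONSE_DEADLINE_S:
                raise ValueError("response time exceeds the 1.5 s deadline")

    @property
    def recognition_events(self) -> list[TrialEvent]:
        return [e for e in self.events if e.phase == "recognition"]

    @property
    def n_blocks(self) -> int:
        return max(e.block_index for e in self.events) + 1

    def image_ids(self) -> set[int]:
        return {e.image_id for e in self.events}

    def max_novelty_run(self) -> int:
        """Longest run of identical novelty labels within any recognition block."""
        longest = 0
        for b in range(self.n_blocks):
            labels = [e.novelty for e in self.recognition_events if e.block_index == b]
            run = 0
            prev = None
            for lab in labels:
                run = run + 1 if lab == prev else 1
                prev = lab
                longest = max(longest, run)
        return longest

    def with_behavior(self, response_times: np.ndarray, correct: np.ndarray) -> "TrialSchedule":
        """Return a copy with behavior filled in for recognition events (in order)."""
        out = []
        k = 0
        for e in self.events:
            if e.phase == "recognition":
                out.append(replace(e, response_time_s=float(response_times[k]),
                                   correct=bool(correct[k])))
                k += 1
            else:
                out.append(e)
        if k != len(response_times):
            raise ValueError("behavior arrays do not match recognition trial count")
        return TrialSchedule(out)


def _novelty_sequence(n_each: int, rng: np.random.Generator,
                      max_run: int = MAX_NOVELTY_RUN) -> list[str]:
    """Pseudo-random interleave of n_each OLD and n_each NEW, runs <= max_run."""
    labels = np.array(["OLD"] * n_each + ["NEW"] * n_each, dtype=object)
    for _ in range(10_000):
        rng.shuffle(labels)
        run, prev, ok = 0, None, True
        for lab in labels:
            run = run + 1 if lab == prev else 1
            prev = lab
            if run > max_run:
                ok = False
                break
        if ok:
            return list(labels)
    raise RuntimeError("could not satisfy the run-length constraint")  # pragma: no cover


def make_task_schedule(
    n_block_pairs: int = 7,
    images_per_block: int = 12,
    isi_s: float = 2.5,
    seed: int = 0,
    inter_block_gap_s: float = 60.0,
    start_offset_s: float = 5.0,
) -> TrialSchedule:
    """Generate an old/new session schedule.

    Each block pair is an encoding block of ``images_per_block`` fresh images
    followed (after the distractor-video gap of ``inter_block_gap_s``) by a
    recognition block of those images plus ``images_per_block`` unseen ones.
    With the defaults (7 pairs of 12) a session consumes 168 distinct images.

    Parameters
    ----------
    isi_s : float
        Inter-stimulus onset asynchrony within a block, seconds.
    inter_block_gap_s : float
        Gap between consecutive blocks (the 1-min distractor video by default).
    """
    if n_block_pairs < 1 or images_per_block < 1:
        raise ValueError("n_block_pairs and images_per_block must be >= 1")
    if isi_s <= 0:
        raise ValueError("isi_s must be positive")
    rng = np.random.default_rng(seed)
    events: list[TrialEvent] = []
    t = float(start_offset_s)
    next_image = 0
    block = 0
    for _ in range(n_block_pairs):
        old_ids = list(range(next_image, next_image + images_per_block))
        new_ids = list(range(next_image + images_per_block,
                             next_image + 2 * images_per_block))
        next_image += 2 * images_per_block

        for img in old_ids:
            events.append(TrialEvent(block, "encoding", img, None, t))
            t += isi_s
        t += inter_block_gap_s

        labels = _novelty_sequence(images_per_block, rng)
        olds = list(rng.permutation(old_ids))
        news = list(rng.permutation(new_ids))
        for lab in labels:
            img = olds.pop() if lab == "OLD" else news.pop()
            events.append(TrialEvent(block, "recognition", img, lab, t))
            t += isi_s
        t += inter_block_gap_s
        block += 1
    return TrialSchedule(events)
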