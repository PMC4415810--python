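"""Selection and concatenation of burst-only / suppression-only EEG.

Burst-suppression analysis needs long same-phase data: the labeled phases
are cut out of the recording and concatenated into a fixed-duration segment
per phase (60 s by default).  Concatenation joins are recorded so that
spectral epochs can later be aligned to avoid straddling the artificial
discontinuities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import Recording

__all__ = ["PhaseSegments", "label_phases_by_amplitude", "concatenate_phase_segments"]

log = logging.getLogger(__name__)

BURST_THRESHOLD_UV = 30.0
SUPPRESSION_THRESHOLD_UV = 25.0
LABEL_WINDOW_S = 0.25


@dataclass
class PhaseSegments:
    """Concatenated same-phase EEG with its provenance intervals."""

    phase: str
    intervals: list[tuple[int, int]]  # half-open [start, end) sample intervals
    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    joins: list[int]  # sample offsets where a new interval begins (first = 0)

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.intervals]
        if starts != sorted(starts):
            raise ValueError("intervals must be sorted")
        for (s0, e0), (s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError("intervals must not overlap")
        total = sum(e - s for s, e in self.intervals)
        if total != self.data.shape[1]:
            raise ValueError("concatenated length must equal the interval total")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


def label_phases_by_amplitude(
    recording: Recording,
    burst_threshold: float = BURST_THRESHOLD_UV,
    suppression_threshold: float = SUPPRESSION_THRESHOLD_UV,
    window: float = LABEL_WINDOW_S,
) -> list[tuple[float, float, str]]:
    """Classify every sample by sliding-window peak-to-peak amplitude.

    A sample is ``burst`` when the windowed peak-to-peak reaches
    ``burst_threshold`` on any channel, ``suppression`` when it stays below
    ``suppression_threshold`` on all channels, and unlabeled otherwise.
    The centered window makes each labeled run overreach true phase
    boundaries by up to half a window, so every run is trimmed by that
    guard band before the merged (onset, duration, label) annotations are
    returned.  The burst threshold sits well below the 150 uV clinical
    floor because a sub-second window sees only part of a slow delta swing.
    """
    if burst_threshold <= 0 or suppression_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if burst_threshold <= suppression_threshold:
        raise ValueError("burst threshold must exceed the suppression threshold")
    n = recording.data.shape[1]
    w = int(round(window * recording.fs))
    if w > n:
        raise ValueError(f"window ({window}s) longer than the recording")
    w = max(w, 2)
    hi = ndimage.maximum_filter1d(recording.data, size=w, axis=1, mode="nearest")
    lo = ndimage.minimum_filter1d(recording.data, size=w, axis=1, mode="nearest")
    p2p = hi - lo
    is_burst = np.any(p2p >= burst_threshold, axis=0)
    is_supp = np.all(p2p < suppression_threshold, axis=0)

    labels = np.full(n, "", dtype=object)
    labels[is_supp] = "suppression"
    labels[is_burst] = "burst"  # burst dominates if both somehow hold

    guard = w // 2
    annotations = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            if labels[start]:
                s, e = start + guard, i - guard
                if e > s:
                    annotations.append(
                        (s / recording.fs, (e - s) / recording.fs, labels[start]))
            start = i
    return annotations


def concatenate_phase_segments(
    recording: Recording,
    annotations: list[tuple[float, float, str]],
    phase: str,
    target_duration: float = 60.0,
    min_segment: float = 1.0,
) -> PhaseSegments:
    """Earliest-first concatenation of one phase into an exact duration.

    Segments shorter than ``min_segment`` (one spectral epoch) are skipped;
    the last used segment is truncated so the output has exactly
    ``target_duration * fs`` samples.
    """
    fs = recording.fs
    n_target = int(round(target_duration * fs))
    intervals: list[tuple[int, int]] = []
    got = 0
    skipped = 0
    for onset, dur, lab in sorted(annotations):
        if lab != phase:
            continue
        s = int(round(onset * fs))
        e = int(round((onset + dur) * fs))
        if e - s < int(round(min_segment * fs)):
            skipped += 1
            continue
        take = min(e - s, n_target - got)
        intervals.append((s, s + take))
        got += take
        if got >= n_target:
            break
    if skipped:
        log.info("concatenate_phase_segments: skipped %d %s segments shorter than %.3g s",
                 skipped, phase, min_segment)
    if got < n_target:
        raise ValueError(
            f"insufficient {phase} data: {got / fs:.2f} s available (after skipping "
            f"segments < {min_segment} s), {target_duration:.2f} s requested")
    data = np.concatenate([recording.data[:, s:e] for s, e in intervals], axis=1)
    joins = list(np.cumsum([0] + [e - s for s, e in intervals[:-1]]).astype(int))
    return PhaseSegments(phase=phase, intervals=intervals, data=data, fs=fs, joins=joins)
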