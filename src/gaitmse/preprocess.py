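"""Signal preprocessing: trimming, differential channels, windowing, artifact
screening and per-window normalization.

The raw three channels D = (LF, RF, AF) — left foot, right foot and their
elementwise average — are extended with first differences D1 and second
differences D2, giving nine channels in the fixed order
LF, RF, AF, LF1, RF1, AF1, LF2, RF2, AF2 on which the downstream feature
layout depends. Differentiation happens before windowing on the full series;
the 1–2 sample shortfall of D1/D2 is absorbed by limiting window placement
to the shortest (D2) length so all nine segments stay index-aligned.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from gaitmse.io import GaitRecord

logger = logging.getLogger(__name__)

#: Fixed channel order; the F1..F72 feature layout indexes channels this way.
CHANNEL_NAMES = ("LF", "RF", "AF", "LF1", "RF1", "AF1", "LF2", "RF2", "AF2")

#: The three undifferentiated channels.
D_CHANNELS = ("LF", "RF", "AF")


@dataclass
class ChannelSet:
    """The nine derived series of one record."""

    subject_id: str
    class_label: str
    fs: float
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if tuple(self.channels) != CHANNEL_NAMES:
            raise ValueError(f"channels must be exactly {CHANNEL_NAMES} in order")

    @property
    def min_length(self) -> int:
        """Length of the shortest channel (the second differences)."""
        return len(self.channels["LF2"])


@dataclass
class SignalWindow:
    """One fixed-length segment of all nine channels."""

    window_id: int
    subject_id: str
    class_label: str
    start_s: float
    tw_s: float
    fs: float
    segments: dict[str, np.ndarray]
    artifact_flag: bool = False


@dataclass
class WindowSet:
    """All windows of a record or cohort at one window length."""

    windows: list[SignalWindow]
    tw_s: float
    d_s: float

    @property
    def n_total(self) -> int:
        return len(self.windows)

    @property
    def n_verified(self) -> int:
        """Windows that survived artifact screening."""
        return sum(not w.artifact_flag for w in self.windows)


@dataclass
class ArtifactRules:
    """Thresholds for automated artifact screening.

    ``flat_eps`` is in normalized units; ``flat_run_s`` is the minimum
    flatline duration; ``clip_fraction`` the fraction of samples pinned at
    the segment extremes that counts as sensor clipping.
    """

    flat_eps: float = 1e-6
    flat_run_s: float = 2.0
    clip_fraction: float = 0.01
    exclude: set[tuple[str, int]] = field(default_factory=set)


def trim_initial(record: GaitRecord, trim_s: float = 20.0, max_s: float = 300.0) -> GaitRecord:
    """Drop the initial acclimatization interval and cap the record length.

    The first ``trim_s`` seconds are removed (the start of a walk is not a
    steady gait) and anything beyond ``max_s`` from the original origin is
    discarded, so a 5-min recording becomes 280 s.
    """
    if record.duration_s <= trim_s:
        raise ValueError(
            f"record {record.subject_id}: duration {record.duration_s:g} s "
            f"not longer than trim {trim_s:g} s"
        )
    start = int(round(trim_s * record.fs))
    stop = min(record.n_samples, int(round(max_s * record.fs)))
    return GaitRecord(
        subject_id=record.subject_id,
        class_label=record.class_label,
        fs=record.fs,
        lf=record.lf[start:stop].copy(),
        rf=record.rf[start:stop].copy(),
    )


def average_foot(lf: Sequence[float], rf: Sequence[float]) -> np.ndarray:
    """Average-foot channel AF = (LF + RF) / 2, elementwise."""
    lf = np.asarray(lf, dtype=float)
    rf = np.asarray(rf, dtype=float)
    if lf.shape != rf.shape:
        raise ValueError(f"length mismatch: {lf.shape} vs {rf.shape}")
    return (lf + rf) / 2.0


def differentiate(x: Sequence[float]) -> np.ndarray:
    """First difference x[i+1] − x[i]; output is one sample shorter."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.diff(x)


def build_channels(record: GaitRecord) -> ChannelSet:
    """Build the nine-channel representation D, D1, D2 of a (trimmed) record."""
    lf, rf = record.lf, record.rf
    af = average_foot(lf, rf)
    d = {"LF": lf, "RF": rf, "AF": af}
    channels: dict[str, np.ndarray] = dict(d)
    for name, series in d.items():
        channels[name + "1"] = differentiate(series)
    for name, series in d.items():
        channels[name + "2"] = differentiate(channels[name + "1"])
    ordered = {name: channels[name] for name in CHANNEL_NAMES}
    return ChannelSet(
        subject_id=record.subject_id,
        class_label=record.class_label,
        fs=record.fs,
        channels=ordered,
    )


def expected_window_count(l_s: float, tw_s: float, d_s: float, T: int) -> int:
    """Closed-form count of overlapping windows over a cohort.

    For a group of ``T`` subjects each recorded for ``l_s`` seconds, windowed
    at length ``tw_s`` with step ``d_s``, the count is
    ``floor(((l_s − tw_s)/d_s + 1) × T)``; a fractional per-subject count is
    truncated toward zero at the cohort total. Evaluated in exact rational
    arithmetic so an integral total (e.g. 125.0) is never floored away by a
    one-ulp float error.
    """
    if tw_s <= 0 or d_s <= 0:
        raise ValueError("window length and step must be positive")
    if l_s < tw_s:
        raise ValueError(f"record length {l_s} shorter than window {tw_s}")
    if T < 1:
        raise ValueError("subject count must be >= 1")
    l_f, tw_f, d_f = (Fraction(str(v)) for v in (l_s, tw_s, d_s))
    return math.floor(((l_f - tw_f) / d_f + 1) * T)


def segment_windows(
    channels: ChannelSet, tw_s: float, overlap_fraction: float = 0.5
) -> WindowSet:
    """Cut all nine channels into fixed-length windows with fractional overlap.

    Windows start at 0, d, 2d, … samples with ``d = tw_s × (1 −
    overlap_fraction)`` and are placed over the raw (D) channel length;
    every channel is sliced over the same sample-index range. The 1–2
    sample shortfall of the differentiated channels only touches the final
    window, whose D1/D2 segments are edge-padded so all nine segments keep
    the full window length and the emitted count matches the closed-form
    window-count arithmetic.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    fs = channels.fs
    n_win = int(round(tw_s * fs))
    n_raw = len(channels.channels["LF"])
    if n_win > n_raw:
        raise ValueError(
            f"window of {tw_s:g} s ({n_win} samples) exceeds record length ({n_raw} samples)"
        )
    d_s = tw_s * (1.0 - overlap_fraction)
    step = int(round(d_s * fs))
    if step < 1:
        raise ValueError("window step must be at least one sample")
    windows = []
    window_id = 0
    start = 0
    while start + n_win <= n_raw:
        segments = {}
        for name, series in channels.channels.items():
            seg = series[start : start + n_win]
            if len(seg) < n_win:  # differentiation shortfall at the record tail
                seg = np.concatenate([seg, np.full(n_win - len(seg), seg[-1])])
            segments[name] = seg
        windows.append(
            SignalWindow(
                window_id=window_id,
                subject_id=channels.subject_id,
                class_label=channels.class_label,
                start_s=start / fs,
                tw_s=tw_s,
                fs=fs,
                segments=segments,
            )
        )
        window_id += 1
        start += step
    return WindowSet(windows=windows, tw_s=tw_s, d_s=d_s)


def detect_artifacts(window: SignalWindow, rules: ArtifactRules | None = None) -> bool:
    """Screen one window for recording artifacts.

    Flags the window when any rule fires on a raw (D) channel segment:
    flatline (a run of at least ``flat_run_s`` seconds with standard
    deviation below ``flat_eps``), clipping (at least ``clip_fraction`` of
    samples exactly at the segment minimum or maximum), or dropout (any
    non-finite sample, checked on all nine channels). An explicit
    ``(subject_id, window_id)`` exclusion list stands in for manual review.
    """
    if rules is None:
        rules = ArtifactRules()
    if (window.subject_id, window.window_id) in rules.exclude:
        return True
    for seg in window.segments.values():
        if not np.isfinite(seg).all():
            return True
    run = int(round(rules.flat_run_s * window.fs))
    for name in D_CHANNELS:
        seg = window.segments[name]
        n = len(seg)
        if run >= 2 and n >= run:
            # exact rolling population variance over every run-length stretch
            c1 = np.concatenate([[0.0], np.cumsum(seg)])
            c2 = np.concatenate([[0.0], np.cumsum(seg * seg)])
            mean = (c1[run:] - c1[:-run]) / run
            var = (c2[run:] - c2[:-run]) / run - mean * mean
            if np.any(np.maximum(var, 0.0) < rules.flat_eps**2):
                return True
        at_min = np.count_nonzero(seg == seg.min())
        at_max = np.count_nonzero(seg == seg.max())
        if (at_min + at_max) / n >= rules.clip_fraction:
            return True
    return False


def normalize(x: Sequence[float], method: str = "zscore") -> np.ndarray:
    """Normalize one segment.

    ``minmax`` maps onto [0, 1]; ``zscore`` centers to mean 0 and population
    standard deviation 1. A constant segment is degenerate under both and is
    returned as all zeros with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to normalize")
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            logger.warning("degenerate window: constant segment under minmax normalization")
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    if method == "zscore":
        mu = x.mean()
        sigma = x.std()  # population SD
        if sigma == 0:
            logger.warning("degenerate window: constant segment under zscore normalization")
            return np.zeros_like(x)
        return (x - mu) / sigma
    raise ValueError(f"unknown normalization method: {method!r}")


def normalize_window(window: SignalWindow, method: str = "zscore") -> SignalWindow:
    """Return a copy of a window with every channel segment normalized."""
    segments = {name: normalize(seg, method) for name, seg in window.segments.items()}
    return SignalWindow(
        window_id=window.window_id,
        subject_id=window.subject_id,
        class_label=window.class_label,
        start_s=window.start_s,
        tw_s=window.tw_s,
        fs=window.fs,
        segments=segments,
        artifact_flag=window.artifact_flag,
    )


def prepare_windows(
    record: GaitRecord,
    tw_s: float,
    overlap_fraction: float = 0.5,
    trim_s: float = 20.0,
    max_s: float = 300.0,
    normalization: str = "zscore",
    rules: ArtifactRules | None = None,
) -> WindowSet:
    """Full preprocessing of one record: trim → channels → windows →
    artifact flags → per-window, per-channel normalization.

    Flagged windows keep their raw segments (they are excluded downstream).
    """
    trimmed = trim_initial(record, trim_s=trim_s, max_s=max_s)
    channels = build_channels(trimmed)
    wset = segment_windows(channels, tw_s, overlap_fraction)
    out = []
    for w in wset.windows:
        w.artifact_flag = detect_artifacts(w, rules)
        out.append(normalize_window(w, normalization) if not w.artifact_flag else w)
    return WindowSet(windows=out, tw_s=wset.tw_s, d_s=wset.d_s)
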