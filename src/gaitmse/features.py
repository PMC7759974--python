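"""Per-window feature extraction: mean, population SD, and multiscale sample
entropy (MSE), assembling the 72-entry feature vector.

Each of the nine channels contributes eight features — mean, standard
deviation, and sample entropy of the coarse-grained series at scales
s = 1..6 — laid out as F(8·(i−1)+1) = mean, F(8·(i−1)+2) = SD,
F(8·(i−1)+2+s) = MSE at scale s, for channel index i = 1..9 over
(LF, RF, AF, LF1, RF1, AF1, LF2, RF2, AF2).

Sample entropy follows the Richman–Moorman convention: Chebyshev template
distance, self-matches excluded, SampEn = −ln(A/B) with B the number of
m-template pairs within tolerance and A the same count for (m+1)-templates.
The tolerance is r × the population SD of the uncoarsened window, held
fixed across scales; with per-window z-score normalization this is simply r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numba
import numpy as np
import pandas as pd

from gaitmse.preprocess import CHANNEL_NAMES, SignalWindow, WindowSet

logger = logging.getLogger(__name__)

#: Per-channel feature kinds in layout order.
_KINDS = ("mean", "std", "mse1", "mse2", "mse3", "mse4", "mse5", "mse6")


@dataclass
class MSEParams:
    """Multiscale sample entropy parameters.

    ``m`` is the embedding dimension, ``r`` the tolerance as a fraction of
    the window's scale-1 standard deviation, ``scales`` the coarse-graining
    factors. Defaults m=3, r=0.2, s=1..6.
    """

    m: int = 3
    r: float = 0.2
    scales: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance fraction r must be positive")
        scales = tuple(int(s) for s in self.scales)
        if not scales or any(s < 1 for s in scales):
            raise ValueError("scales must be positive integers")
        if list(scales) != sorted(set(scales)):
            raise ValueError("scales must be sorted and unique")
        self.scales = scales


def feature_names(params: MSEParams | None = None) -> list[str]:
    """Ordered feature names F1..F72 (for the default six scales)."""
    n_scales = len(params.scales) if params is not None else 6
    per_channel = 2 + n_scales
    return [f"F{k}" for k in range(1, per_channel * len(CHANNEL_NAMES) + 1)]


def feature_description(params: MSEParams | None = None) -> pd.DataFrame:
    """Table mapping each feature name to its channel and kind."""
    if params is None:
        params = MSEParams()
    kinds = ["mean", "std"] + [f"mse{s}" for s in params.scales]
    rows = []
    k = 1
    for channel in CHANNEL_NAMES:
        for kind in kinds:
            rows.append({"feature": f"F{k}", "channel": channel, "kind": kind})
            k += 1
    return pd.DataFrame(rows)


def mean_of(x: Sequence[float]) -> float:
    """Arithmetic mean."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mean of empty sequence")
    return float(x.mean())


def std_of(x: Sequence[float]) -> float:
    """Population standard deviation (divisor N, not N−1)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("SD of empty sequence")
    return float(x.std())


def coarse_grain(x: Sequence[float], s: int) -> np.ndarray:
    """Coarse-grain a series at scale ``s``: replace each consecutive
    non-overlapping block of ``s`` samples by its mean; a trailing remainder
    shorter than ``s`` is dropped. Scale 1 is the identity."""
    x = np.asarray(x, dtype=float)
    if s < 1:
        raise ValueError("scale must be >= 1")
    if s > len(x):
        raise ValueError(f"scale {s} exceeds series length {len(x)}")
    if s == 1:
        return x.copy()
    n_blocks = len(x) // s
    return x[: n_blocks * s].reshape(n_blocks, s).mean(axis=1)


@numba.njit(cache=True)
def _count_template_matches(x: np.ndarray, m: int, r_abs: float):
    """Ordered pair counts (i ≠ j) of templates within Chebyshev distance
    ``r_abs``: B over m-length templates, A over (m+1)-length templates,
    both over the first N−m template start points. One pass with early
    exit on the running maximum."""
    n_t = len(x) - m
    b = 0
    a = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            match_m = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r_abs:
                    match_m = False
                    break
            if match_m:
                b += 2
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    a += 2
    return b, a


def sample_entropy(x: Sequence[float], m: int = 3, r_abs: float = 0.2) -> float:
    """Sample entropy SampEn(m, r_abs) of a series.

    Counts pairs of m-length templates whose Chebyshev distance is ≤
    ``r_abs`` (B) and the same for (m+1)-length templates (A), both over the
    first N−m templates with self-matches excluded, and returns −ln(A/B).
    Returns NaN when no m-template pair matches (B = 0, entropy undefined)
    or no (m+1)-template pair matches (A = 0, entropy unbounded); callers
    impute NaN downstream.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series length {n} too short for m={m} (need >= m+2)")
    if r_abs <= 0:
        raise ValueError("tolerance must be positive")
    # use N-m templates for both lengths so A and B are comparable counts
    b, a = _count_template_matches(x, m, r_abs)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_profile(x: Sequence[float], params: MSEParams | None = None) -> np.ndarray:
    """Multiscale sample entropy profile: SampEn of the coarse-grained
    series at each scale, with tolerance fixed at ``r × SD`` of the scale-1
    series. A constant series is returned as an all-zero profile (a constant
    matches itself perfectly at every scale)."""
    if params is None:
        params = MSEParams()
    x = np.asarray(x, dtype=float)
    sigma = std_of(x)
    if sigma == 0:
        return np.zeros(len(params.scales))
    r_abs = params.r * sigma
    out = np.empty(len(params.scales))
    for idx, s in enumerate(params.scales):
        coarse = coarse_grain(x, s)
        if len(coarse) < params.m + 2:
            raise ValueError(
                f"scale {s}: coarse-grained length {len(coarse)} too short for m={params.m}"
            )
        out[idx] = sample_entropy(coarse, params.m, r_abs)
    return out


def window_features(window: SignalWindow, params: MSEParams | None = None) -> pd.Series:
    """The full feature vector of one window.

    Returns a Series indexed F1..F72 (for default scales) plus ``label``,
    ``subject_id`` and ``window_id`` metadata attached via ``attrs``.
    Entropy values that are undefined on a segment are left as NaN here and
    imputed with training-set column medians at classification time.
    """
    if params is None:
        params = MSEParams()
    if window.artifact_flag:
        raise ValueError(
            f"window {window.subject_id}/{window.window_id} is artifact-flagged"
        )
    values: list[float] = []
    for name in CHANNEL_NAMES:
        seg = window.segments[name]
        values.append(mean_of(seg))
        values.append(std_of(seg))
        values.extend(mse_profile(seg, params))
    vec = pd.Series(values, index=feature_names(params))
    n_bad = int(vec.isna().sum())
    if n_bad:
        logger.warning(
            "window %s/%d: %d undefined entropy feature(s) left for imputation",
            window.subject_id,
            window.window_id,
            n_bad,
        )
    vec.attrs.update(
        label=window.class_label, subject_id=window.subject_id, window_id=window.window_id
    )
    return vec


def extract_features(
    windows: WindowSet | Iterable[SignalWindow], params: MSEParams | None = None
) -> pd.DataFrame:
    """Feature matrix over all verified windows.

    Artifact-flagged windows are skipped (logged). Columns are F1..F72
    followed by ``label``, ``subject_id``, ``window_id``.
    """
    if params is None:
        params = MSEParams()
    if isinstance(windows, WindowSet):
        windows = windows.windows
    rows = []
    meta = []
    n_skipped = 0
    for w in windows:
        if w.artifact_flag:
            n_skipped += 1
            continue
        vec = window_features(w, params)
        rows.append(vec.to_numpy())
        meta.append((w.class_label, w.subject_id, w.window_id))
    if n_skipped:
        logger.info("skipped %d artifact-flagged window(s)", n_skipped)
    names = feature_names(params)
    df = pd.DataFrame(rows, columns=names)
    meta_df = pd.DataFrame(meta, columns=["label", "subject_id", "window_id"])
    return pd.concat([df, meta_df], axis=1)
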