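"""Greedy sequential feature-subset search (SFS / SBS).

SFS grows a subset from the empty set, at each step adding the single
feature that maximizes a wrapper criterion; SBS shrinks from the full set,
removing the feature whose removal maximizes the criterion. The criterion
is any callable mapping ``(X_subset, y) -> score`` with higher better —
typically cross-validated classifier accuracy on the training data only.
Ties break toward the lowest feature index, making both searches
deterministic. Stopping is either at a requested subset size ``p`` or when
no step improves the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

Criterion = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class SelectionResult:
    """Outcome of one greedy search."""

    method: str
    selected: list[str]
    trajectory: list[tuple[int, float]] = field(default_factory=list)
    criterion: str = ""

    @property
    def final_score(self) -> float:
        return self.trajectory[-1][1] if self.trajectory else float("nan")


def _as_matrix(features: pd.DataFrame | np.ndarray, y=None):
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c.startswith("F")]
        X = features[cols].to_numpy(dtype=float)
        if y is None:
            y = features["label"].to_numpy()
        return X, np.asarray(y), cols
    X = np.asarray(features, dtype=float)
    names = [f"F{k}" for k in range(1, X.shape[1] + 1)]
    return X, np.asarray(y), names


def sfs(
    features: pd.DataFrame | np.ndarray,
    criterion: Criterion,
    p: int | None = None,
    y: np.ndarray | None = None,
) -> SelectionResult:
    """Sequential forward selection.

    With ``p`` given, runs exactly ``p`` steps; otherwise stops at the
    first step whose best addition does not improve the criterion.
    """
    X, y, names = _as_matrix(features, y)
    d = X.shape[1]
    if d < 1:
        raise ValueError("need at least one feature")
    if p is not None and (p < 1 or p > d):
        raise ValueError(f"target size p={p} out of range 1..{d}")
    chosen: list[int] = []
    remaining = list(range(d))
    trajectory: list[tuple[int, float]] = []
    best_so_far = -np.inf
    while remaining:
        scores = [criterion(X[:, chosen + [j]], y) for j in remaining]
        best_pos = int(np.argmax(scores))  # argmax takes the first (lowest index) on ties
        best_score = scores[best_pos]
        if p is None and best_score <= best_so_far:
            break
        chosen.append(remaining.pop(best_pos))
        trajectory.append((len(chosen), float(best_score)))
        best_so_far = max(best_so_far, best_score)
        if p is not None and len(chosen) == p:
            break
    return SelectionResult(
        method="SFS",
        selected=[names[j] for j in chosen],
        trajectory=trajectory,
        criterion=getattr(criterion, "description", repr(criterion)),
    )


def sbs(
    features: pd.DataFrame | np.ndarray,
    criterion: Criterion,
    p: int | None = None,
    y: np.ndarray | None = None,
) -> SelectionResult:
    """Sequential backward selection: mirror of :func:`sfs`, starting from
    the full set and removing the least-contributing feature each step."""
    X, y, names = _as_matrix(features, y)
    d = X.shape[1]
    if d < 1:
        raise ValueError("need at least one feature")
    if p is not None and (p < 1 or p > d):
        raise ValueError(f"target size p={p} out of range 1..{d}")
    kept = list(range(d))
    full_score = float(criterion(X, y))
    trajectory: list[tuple[int, float]] = [(d, full_score)]
    best_so_far = full_score
    while len(kept) > 1 and (p is None or len(kept) > p):
        scores = []
        for pos in range(len(kept)):
            subset = kept[:pos] + kept[pos + 1 :]
            scores.append(criterion(X[:, subset], y))
        best_pos = int(np.argmax(scores))  # ties -> removes the lowest-indexed feature
        best_score = float(scores[best_pos])
        if p is None and best_score <= best_so_far:
            break
        kept.pop(best_pos)
        trajectory.append((len(kept), best_score))
        best_so_far = max(best_so_far, best_score)
    return SelectionResult(
        method="SBS",
        selected=[names[j] for j in kept],
        trajectory=trajectory,
        criterion=getattr(criterion, "description", repr(criterion)),
    )


def selection_report(result: SelectionResult) -> pd.DataFrame:
    """Trajectory as a tidy table (one row per step)."""
    return pd.DataFrame(result.trajectory, columns=["subset_size", "score"]).assign(
        method=result.method
    )
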