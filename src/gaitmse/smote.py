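"""Synthetic minority oversampling (SMOTE) in feature space.

A synthetic sample is drawn on the line segment between a minority-class
row x and one of its k nearest minority neighbors x_k (Euclidean distance):
x' = x + u · (x_k − x) with u ~ Uniform(0, 1). Every synthetic row is a
convex combination of two real minority rows, so it stays inside the
minority class's componentwise envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from gaitmse.features import feature_names

logger = logging.getLogger(__name__)


@dataclass
class SmoteConfig:
    """SMOTE settings: neighborhood size, balancing target and seed."""

    k_neighbors: int = 5
    target: str = "match_majority"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target != "match_majority" and not isinstance(self.target, dict):
            raise ValueError("target must be 'match_majority' or a dict of class counts")


def smote_synthesize(
    minority: np.ndarray,
    n_new: int,
    config: SmoteConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate ``n_new`` synthetic rows from a minority-class matrix.

    Rows with NaN entries are not accepted (impute first). Reproducible
    given ``config.seed`` (or an explicit ``rng``).
    """
    if config is None:
        config = SmoteConfig()
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2:
        raise ValueError("minority must be a 2-D matrix")
    if np.isnan(minority).any():
        raise ValueError("minority rows contain NaN; impute before oversampling")
    n_min = len(minority)
    if n_min < config.k_neighbors + 1:
        raise ValueError(
            f"need at least k+1 = {config.k_neighbors + 1} minority rows, got {n_min}"
        )
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_new == 0:
        return np.empty((0, minority.shape[1]))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(minority)
    # column 0 is the point itself; keep the k true neighbors
    neighbor_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, config.k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = minority[base]
    xk = minority[neighbor_idx[base, pick]]
    return x + u[:, None] * (xk - x)


def balance_classes(
    features: pd.DataFrame, config: SmoteConfig | None = None
) -> pd.DataFrame:
    """Oversample every minority class of a feature matrix up to the
    majority count (or explicit per-class targets).

    Original rows pass through unmodified. Synthetic rows carry
    ``synthetic=True``, an empty ``subject_id`` and ``window_id`` −1. Raises
    when fewer than two classes are present or a class is smaller than
    ``k_neighbors + 1`` (use a smaller k).
    """
    if config is None:
        config = SmoteConfig()
    counts = features["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes to balance")
    cols = [c for c in features.columns if c.startswith("F")]
    if config.target == "match_majority":
        targets = {label: int(counts.max()) for label in counts.index}
    else:
        targets = dict(config.target)
    out = features.copy()
    if "synthetic" not in out.columns:
        out["synthetic"] = False
    new_frames = [out]
    rng = np.random.default_rng(config.seed)
    for label in counts.index:
        n_new = targets.get(label, int(counts[label])) - int(counts[label])
        if n_new <= 0:
            continue
        minority = features.loc[features["label"] == label, cols].to_numpy()
        if len(minority) < config.k_neighbors + 1:
            raise ValueError(
                f"class {label!r} has {len(minority)} rows; SMOTE needs k+1 = "
                f"{config.k_neighbors + 1} — use a smaller k_neighbors"
            )
        synth = smote_synthesize(minority, n_new, config, rng=rng)
        frame = pd.DataFrame(synth, columns=cols)
        frame["label"] = label
        frame["subject_id"] = ""
        frame["window_id"] = -1
        frame["synthetic"] = True
        new_frames.append(frame)
        logger.info("SMOTE: class %s %d -> %d rows", label, counts[label], targets[label])
    if len(new_frames) == 1:
        return out
    return pd.concat(new_frames, ignore_index=True)
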