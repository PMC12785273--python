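"""Per-module labels, stratified 4:1 splitting, and SMOTE class balancing.

Labels are binary per regulator module: 1 = upregulated/agonistic,
0 = downregulated/antagonistic.  The favorable ("mitigating") direction is
down for miR-34a, DNMT3a and HDAC and up for miR-125b and miR-135a.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.neighbors import NearestNeighbors


class Direction(str, Enum):
    DOWN = "DOWN"
    UP = "UP"


class RegulatorModule(str, Enum):
    """The five epigenetic regulator modules and their favorable direction."""

    MIR34A = "MIR34A"
    DNMT3A = "DNMT3A"
    HDAC = "HDAC"
    MIR125B = "MIR125B"
    MIR135A = "MIR135A"

    @property
    def favorable_direction(self) -> Direction:
        if self in (RegulatorModule.MIR34A, RegulatorModule.DNMT3A, RegulatorModule.HDAC):
            return Direction.DOWN
        return Direction.UP

    @property
    def favorable_label(self) -> int:
        """Label value (0/1) corresponding to the favorable direction."""
        return 0 if self.favorable_direction is Direction.DOWN else 1


class StratificationError(ValueError):
    """Raised when a class is too small to stratify."""


class BalancingError(ValueError):
    """Raised when SMOTE preconditions fail."""


@dataclass(frozen=True)
class SplitDataset:
    """A reproducible train/test partition (indices into the dataset rows)."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "train_indices": self.train_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
            "ratio": self.ratio,
            "seed": self.seed,
        }


def split_train_test(
    labels: np.ndarray,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> SplitDataset:
    """Randomly split rows into train/test at ``ratio`` (default 4:1).

    Stratified mode draws round(ratio * class count) training rows from each
    class, so a 250-compound module yields exactly 200 train / 50 test and a
    50-item test set always contains both classes.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 5:
        raise ValueError(f"need at least 5 rows to split, got {n}")
    rng = np.random.default_rng(seed)
    if not stratified:
        order = rng.permutation(n)
        n_train = int(round(ratio * n))
        train = np.sort(order[:n_train])
        test = np.sort(order[n_train:])
        return SplitDataset(train, test, ratio, seed)
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise StratificationError(
                f"class {cls} has {len(idx)} member(s); need >= 2 to stratify"
            )
        idx = rng.permutation(idx)
        n_train = int(round(ratio * len(idx)))
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return SplitDataset(train, test, ratio, seed)


def smote_balance(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    binary: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic sample is ``x + u * (x' - x)`` for a minority row ``x``,
    one of its k nearest minority neighbors ``x'`` (Euclidean distance,
    ``k`` capped at minority size − 1), and ``u`` uniform on [0, 1] from the
    seeded generator.  Original rows are preserved as a prefix in their
    original order; synthetic rows are appended with the minority label.
    For binary fingerprint inputs (``binary=True``, auto-detected when every
    value is 0/1) each synthetic coordinate is rounded to the nearest of
    {0, 1}.  Already-balanced input is returned unchanged.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise BalancingError(f"expected 2 classes, got {len(classes)}")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_minority = counts.min()
    n_needed = int(counts.max() - n_minority)
    if n_minority < 2:
        raise BalancingError("minority class needs >= 2 members for SMOTE")
    if binary is None:
        binary = bool(np.isin(X, (0.0, 1.0)).all())
    k_eff = min(k, n_minority - 1)
    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    # column 0 is the point itself (or an exact duplicate; either is a valid parent)
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    base = rng.integers(0, n_minority, size=n_needed)
    pick = rng.integers(0, k_eff, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    x = X_min[base]
    x_prime = X_min[neighbor_idx[base, pick]]
    synthetic = x + u[:, None] * (x_prime - x)
    if binary:
        synthetic = np.rint(synthetic)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out
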