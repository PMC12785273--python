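"""Euclidean-distance applicability domain.

A query compound is trusted only if it sits in the region of descriptor
space populated by the training set.  The domain statistic is the mean
Euclidean distance to the k nearest training compounds, normalized to [0, 1]
by the minimum and maximum of the same statistic computed leave-one-out over
the training set itself; queries with normalized distance above 1 fall
outside the domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class ADModel:
    reference: np.ndarray
    k: int
    d_min: float
    d_max: float
    _nn: NearestNeighbors

    def __post_init__(self) -> None:
        assert self.d_min <= self.d_max and self.k >= 1


@dataclass(frozen=True)
class ADResult:
    raw_distance: float
    normalized_distance: float
    in_domain: bool


def fit_ad(train_features: np.ndarray, k: int = 5) -> ADModel:
    """Fit the domain model from training features.

    For each training row the mean distance to its k nearest *other*
    training rows is computed (leave-one-out); the min and max of those
    values anchor the 0–1 normalization.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2:
        raise ValueError("train_features must be 2-D")
    n = len(X)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} training rows, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    loo_mean = dist[:, 1:].mean(axis=1)  # column 0 is the row itself
    return ADModel(
        reference=X,
        k=k,
        d_min=float(loo_mean.min()),
        d_max=float(loo_mean.max()),
        _nn=nn,
    )


def score_ad(ad_model: ADModel, query_features: np.ndarray) -> list[ADResult]:
    """Score queries against a fitted domain model.

    ``normalized = (raw − d_min) / (d_max − d_min)``, clipped below at 0;
    a query is in-domain iff its raw distance does not exceed d_max
    (equivalently, normalized ≤ 1).  When the training distances are all
    equal (d_min = d_max), any raw distance ≤ d_max normalizes to 0.
    """
    Q = np.atleast_2d(np.asarray(query_features, dtype=float))
    if Q.shape[1] != ad_model.reference.shape[1]:
        raise ValueError(
            f"query has {Q.shape[1]} columns, reference has {ad_model.reference.shape[1]}"
        )
    dist, _ = ad_model._nn.kneighbors(Q, n_neighbors=ad_model.k)
    raw = dist.mean(axis=1)
    span = ad_model.d_max - ad_model.d_min
    results = []
    for r in raw:
        in_domain = bool(r <= ad_model.d_max)
        if span > 0:
            normalized = max(0.0, (r - ad_model.d_min) / span)
        else:
            normalized = 0.0 if in_domain else float("inf")
        results.append(
            ADResult(
                raw_distance=float(r),
                normalized_distance=float(normalized),
                in_domain=in_domain,
            )
        )
    return results
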