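"""Deterministic Kennard–Stone calibration sampling and nested splits.

The Kennard–Stone algorithm picks design-space-covering points: it seeds
with the pair at maximum Euclidean distance, then repeatedly adds the
candidate whose minimum distance to the already-selected set is largest
(max–min criterion). Ties break to the lowest original row index, so the
selection is fully deterministic.

``nested_split`` applies it twice to produce the calibration /
validation / external-validation partition used for spectral modeling:
¾ of the samples form the modeling pool (the rest is the external set),
and ¾ of that pool forms the calibration set (the rest is validation) —
fractions of the total ≈ 9/16, 3/16, 4/16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitAssignment", "kennard_stone", "nested_split"]


@dataclass
class SplitAssignment:
    """Disjoint calibration / validation / external id lists.

    ``feature_space`` records which matrix distances were computed on
    (e.g. ``"snv"`` for SNV-preprocessed spectra) for provenance.
    """

    calibration_ids: list
    validation_ids: list
    external_ids: list
    feature_space: str = "snv"

    def __post_init__(self) -> None:
        all_ids = self.calibration_ids + self.validation_ids + self.external_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split subsets must be disjoint")

    @property
    def n_total(self) -> int:
        return (
            len(self.calibration_ids)
            + len(self.validation_ids)
            + len(self.external_ids)
        )

    def subset_of(self, sample_id) -> str:
        if sample_id in set(self.calibration_ids):
            return "cal"
        if sample_id in set(self.validation_ids):
            return "val"
        if sample_id in set(self.external_ids):
            return "ext"
        raise KeyError(sample_id)


def kennard_stone(features: np.ndarray, k: int) -> np.ndarray:
    """Select ``k`` row indices by the Kennard–Stone max–min criterion.

    Returns indices in selection order. The first two are the pair at
    maximum Euclidean distance (lowest-index pair on ties); each further
    pick maximizes the minimum distance to the selected set.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not (2 <= k <= n):
        raise ValueError(f"k must satisfy 2 <= k <= n (got k={k}, n={n})")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")

    D = squareform(pdist(X))
    # np.argmax returns the first flat index, i.e. lowest (i, j) in row-major
    # order, which implements the lowest-original-index tie-break.
    i, j = np.unravel_index(np.argmax(D), D.shape)
    if i > j:  # pragma: no cover - argmax scans upper triangle first
        i, j = j, i
    selected = [int(i), int(j)]
    min_d = np.minimum(D[i], D[j])
    min_d[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, D[nxt])
        min_d[nxt] = -np.inf
    return np.asarray(selected)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def nested_split(
    features: np.ndarray,
    sample_ids=None,
    outer_frac: float = 0.25,
    inner_frac: float = 0.25,
    feature_space: str = "snv",
) -> SplitAssignment:
    """Two-stage Kennard–Stone partition into cal / val / ext sets.

    Kennard–Stone first selects the ``1 − outer_frac`` modeling pool
    (most covering points); the remainder is the external set. A second
    run inside the pool selects the ``1 − inner_frac`` calibration
    subset; the rest is validation. Subset sizes use round-half-up,
    clamped so every subset is non-empty for n ≥ 4.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 4:
        raise ValueError("nested split needs n >= 4")
    if sample_ids is None:
        sample_ids = np.arange(n)
    sample_ids = np.asarray(sample_ids)
    if len(sample_ids) != n:
        raise ValueError("sample_ids length must match feature rows")
    if np.allclose(pdist(X), 0):
        raise ValueError("degenerate feature matrix: all points identical")

    k_pool = min(max(_round_half_up((1 - outer_frac) * n), 2), n - 1)
    pool = np.sort(kennard_stone(X, k_pool))
    external = np.setdiff1d(np.arange(n), pool)

    k_cal = min(max(_round_half_up((1 - inner_frac) * k_pool), 1), k_pool - 1)
    if k_cal < 2:
        k_cal = 2  # Kennard-Stone minimum; only reachable at k_pool = 3
    cal_local = kennard_stone(X[pool], k_cal)
    cal = np.sort(pool[cal_local])
    val = np.setdiff1d(pool, cal)

    return SplitAssignment(
        calibration_ids=list(sample_ids[cal]),
        validation_ids=list(sample_ids[val]),
        external_ids=list(sample_ids[external]),
        feature_space=feature_space,
    )
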