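"""Two-stage training-set balancing for heavily imbalanced seizure features.

Stage 1 — cluster-centroid under-sampling: the majority (interictal)
class is replaced by the centroids of a k-means clustering with
k = round(n_minority / under_strategy), so under_strategy = 0.5 leaves a
2:1 majority:minority ratio.

Stage 2 — Borderline-SMOTE (variant 1): minority points are classified
by their m nearest neighbours in the whole set as *safe* (< m/2 majority
neighbours), *danger* (>= m/2 but < m) or *noise* (all m majority);
synthetic points are interpolated between danger points and their
k nearest minority neighbours, s = p + gamma * (q - p), gamma ~ U[0, 1],
until round(over_strategy * n_majority) minority rows exist.

Both stages operate in normalized feature space and must only ever see
training rows; the test set keeps its natural class distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .features import FeatureTable

__all__ = [
    "BalanceConfig",
    "cluster_centroid_undersample",
    "classify_minority_samples",
    "borderline_smote_oversample",
    "two_stage_balance",
]


@dataclass(frozen=True)
class BalanceConfig:
    """Targets, seed and neighbour counts for the two balancing stages."""

    under_strategy: float = 0.5   # minority/majority ratio after stage 1
    over_strategy: float = 1.0    # minority/majority ratio after stage 2
    seed: int = 42
    m_neighbors: int = 10         # danger-set detection
    k_neighbors: int = 5          # interpolation
    strict_danger: bool = False   # error (instead of warn) on empty danger set

    def __post_init__(self):
        if not (0 < self.under_strategy <= 1):
            raise ValueError("under_strategy must be in (0, 1]")
        if not (0 < self.over_strategy <= 1):
            raise ValueError("over_strategy must be in (0, 1]")
        if not (self.m_neighbors > self.k_neighbors >= 1):
            raise ValueError("need m_neighbors > k_neighbors >= 1")


def cluster_centroid_undersample(X_major: np.ndarray, n_min: int,
                                 cfg: BalanceConfig = BalanceConfig()) -> np.ndarray:
    """Replace the majority class by k-means centroids, k = round(n_min/strategy)."""
    X_major = np.asarray(X_major, dtype=float)
    n_maj = X_major.shape[0]
    n_keep = int(np.rint(n_min / cfg.under_strategy))
    if n_keep > n_maj:
        raise ValueError(
            f"cannot under-sample: target {n_keep} exceeds majority count {n_maj}"
        )
    km = KMeans(n_clusters=n_keep, init="k-means++", n_init=1, max_iter=300,
                random_state=cfg.seed)
    km.fit(X_major)
    return km.cluster_centers_.astype(float)


def _neighbor_order(X: np.ndarray) -> np.ndarray:
    """All-pairs neighbour ordering by (Euclidean distance, row index), self excluded."""
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    idx = np.arange(X.shape[0])
    # lexsort: primary key distance, tie-break lower index
    return np.array([np.lexsort((idx, d[i]))[:-1] for i in range(X.shape[0])])


def _minority_label(y: np.ndarray):
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels.tolist()}")
    return labels[np.argmin(counts)]


def classify_minority_samples(X: np.ndarray, y: np.ndarray, m_neighbors: int = 10,
                              minority_label=None) -> np.ndarray:
    """Label each minority row 'safe', 'danger' or 'noise' by its m-NN makeup.

    With m' majority rows among the m nearest neighbours (whole set,
    self excluded, Euclidean, distance ties broken by lower row index):
    noise if m' = m, danger if m/2 <= m' < m, safe otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < m_neighbors + 1:
        raise ValueError(f"need at least m_neighbors + 1 = {m_neighbors + 1} rows")
    if minority_label is None:
        minority_label = _minority_label(y)
    order = _neighbor_order(X)
    is_maj = y != minority_label
    out = []
    for i in np.flatnonzero(y == minority_label):
        m_prime = int(is_maj[order[i, :m_neighbors]].sum())
        if m_prime == m_neighbors:
            out.append("noise")
        elif 2 * m_prime >= m_neighbors:
            out.append("danger")
        else:
            out.append("safe")
    return np.asarray(out)


def borderline_smote_oversample(X: np.ndarray, y: np.ndarray,
                                cfg: BalanceConfig = BalanceConfig()):
    """Borderline-SMOTE-1: interpolate from danger points toward minority neighbours.

    Returns ``(X_aug, y_aug, provenance)`` where provenance is 'original'
    or 'synthetic' per row. The synthetic count is
    ``round(over_strategy * n_majority) - n_minority``, spread as evenly
    as possible over the danger rows (remainder to the lowest-index ones).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority_label = _minority_label(y)
    min_idx = np.flatnonzero(y == minority_label)
    n_min = len(min_idx)
    n_maj = len(y) - n_min
    if n_min < cfg.k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors + 1 = {cfg.k_neighbors + 1} minority rows"
        )
    n_syn = int(np.rint(cfg.over_strategy * n_maj)) - n_min
    prov = np.asarray(["original"] * len(y), dtype=object)
    if n_syn <= 0:
        return X.copy(), y.copy(), prov.astype(str)

    cats = classify_minority_samples(X, y, cfg.m_neighbors, minority_label)
    seeds = min_idx[cats == "danger"]
    if len(seeds) == 0:
        msg = "empty Borderline-SMOTE danger set"
        if cfg.strict_danger:
            raise ValueError(msg)
        warnings.warn(msg + "; falling back to plain SMOTE over all minority rows")
        seeds = min_idx

    # per-seed quota: even split, remainder to lowest-index seeds
    base, rem = divmod(n_syn, len(seeds))
    quotas = np.full(len(seeds), base)
    quotas[:rem] += 1

    # k nearest minority neighbours of each seed (within minority set, self excluded)
    Xm = X[min_idx]
    d = cdist(Xm, Xm)
    np.fill_diagonal(d, np.inf)
    local = np.arange(len(min_idx))
    rng = np.random.default_rng(cfg.seed)
    new_rows = []
    for s, q in zip(seeds, quotas):
        li = int(np.flatnonzero(min_idx == s)[0])
        nn = np.lexsort((local, d[li]))[: cfg.k_neighbors]
        for _ in range(q):
            j = nn[rng.integers(len(nn))]
            gamma = rng.uniform()
            new_rows.append(Xm[li] + gamma * (Xm[j] - Xm[li]))
    X_aug = np.vstack([X, np.asarray(new_rows)])
    y_aug = np.concatenate([y, np.full(n_syn, minority_label, dtype=y.dtype)])
    prov = np.concatenate([prov, np.full(n_syn, "synthetic", dtype=object)])
    return X_aug, y_aug, prov.astype(str)


def two_stage_balance(train: FeatureTable, cfg: BalanceConfig = BalanceConfig()):
    """Stage-1 under-sampling then stage-2 oversampling of a *training* table.

    Returns ``(balanced_table, report)``; the report dict records class
    counts per stage, the danger-set size and the seed, and is what the
    CLI serializes as the balance report JSON.
    """
    if train.role == "test":
        raise ValueError("two_stage_balance must never see test rows")
    y = train.labels
    minority_label = _minority_label(y)
    min_rows = np.flatnonzero(y == minority_label)
    maj_rows = np.flatnonzero(y != minority_label)
    majority_label = y[maj_rows[0]]
    report = {
        "seed": cfg.seed,
        "counts_input": train.class_counts(),
    }

    n_keep = int(np.rint(len(min_rows) / cfg.under_strategy))
    if n_keep >= len(maj_rows):
        # already at (or below) the target ratio: keep the majority as-is
        maj_X = train.values[maj_rows]
        maj_prov = train.provenance[maj_rows].astype(object)
    else:
        maj_X = cluster_centroid_undersample(train.values[maj_rows], len(min_rows), cfg)
        maj_prov = np.full(len(maj_X), "centroid", dtype=object)
    X1 = np.vstack([train.values[min_rows], maj_X])
    y1 = np.concatenate([y[min_rows],
                         np.full(len(maj_X), majority_label, dtype=y.dtype)])
    prov1 = np.concatenate([train.provenance[min_rows], maj_prov])
    report["counts_after_undersample"] = {
        str(minority_label): int(len(min_rows)),
        str(majority_label): int(len(maj_X)),
    }

    cats = classify_minority_samples(X1, y1, cfg.m_neighbors, minority_label)
    report["danger_set_size"] = int(np.sum(cats == "danger"))
    X2, y2, prov2 = borderline_smote_oversample(X1, y1, cfg)
    prov = np.concatenate([prov1, prov2[len(prov1):]]).astype(str)
    report["counts_after_oversample"] = {
        str(lab): int(np.sum(y2 == lab)) for lab in np.unique(y2)
    }

    table = FeatureTable(values=X2, columns=list(train.columns), labels=y2,
                         provenance=prov, norm_state=train.norm_state, role=train.role)
    return table, report
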