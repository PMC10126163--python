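"""Cohort statistics for morphological profiling.

Large imaging-cytometry cohorts make p-values uninformative (any shift is
"significant" at n > 10⁴), so class differences are quantified with
sample-size-independent statistics: Cliff's delta effect size, one-vs-all
AUROC — per raw feature for ranking, and for unregularized least-squares
("linear regression") classifiers built on the full z-scored feature table
— plus Spearman correlation structure among features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import roc_curve

from .exceptions import InsufficientDataError, ParameterError, StructuralError

__all__ = [
    "FeatureTable",
    "RocResult",
    "OvaClassifier",
    "zscore",
    "cliffs_delta",
    "auroc",
    "linear_ova_classifier",
    "spearman_matrix",
    "rank_features",
]

log = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Cells × named features, with optional class labels.

    Rows containing non-finite values are dropped on construction (and
    counted in ``n_dropped``); feature names must be unique.
    """

    values: np.ndarray
    feature_names: list[str]
    cell_ids: list | None = None
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        names = list(self.feature_names)
        if len(set(names)) != len(names):
            raise StructuralError("feature names must be unique")
        if v.shape[1] != len(names):
            raise StructuralError(
                f"{v.shape[1]} columns but {len(names)} feature names"
            )
        ids = list(self.cell_ids) if self.cell_ids is not None else list(range(v.shape[0]))
        if len(ids) != v.shape[0]:
            raise StructuralError("cell_ids length mismatch")
        labels = None
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape[0] != v.shape[0]:
                raise StructuralError("labels length mismatch")
        finite = np.all(np.isfinite(v), axis=1)
        dropped = int((~finite).sum())
        if dropped:
            log.info("FeatureTable: dropping %d rows with non-finite values", dropped)
            v = v[finite]
            ids = [i for i, ok in zip(ids, finite) if ok]
            if labels is not None:
                labels = labels[finite]
        self.values = v
        self.feature_names = names
        self.cell_ids = ids
        self.labels = labels
        self.n_dropped = dropped

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "cell_id", self.cell_ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        meta_cols = [c for c in ("cell_id", "label", "source") if c in df.columns]
        features = [c for c in df.columns if c not in meta_cols]
        return cls(
            values=df[features].to_numpy(dtype=float),
            feature_names=features,
            cell_ids=df["cell_id"].tolist() if "cell_id" in df else None,
            labels=df["label"].to_numpy() if "label" in df else None,
        )

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path))


def zscore(t: FeatureTable) -> FeatureTable:
    """Per-feature standardization (x − mean)/SD over all cells.

    Zero-variance features cannot be standardized and are dropped (logged);
    the operation is idempotent.
    """
    mu = t.values.mean(axis=0)
    sd = t.values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(t.feature_names, keep) if not k]
        log.info("zscore: dropping constant features %s", dropped)
    z = (t.values[:, keep] - mu[keep]) / sd[keep]
    return FeatureTable(
        values=z,
        feature_names=[n for n, k in zip(t.feature_names, keep) if k],
        cell_ids=list(t.cell_ids),
        labels=None if t.labels is None else t.labels.copy(),
        meta={**t.meta, "zscored": True},
    )


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size, d = P(x > y) − P(x < y) ∈ [−1, 1].

    Computed with a rank method (O((n+m) log(n+m))): from average ranks of
    the pooled sample, the Mann–Whitney U of x gives
    P(x > y) + P(x = y)/2, and d = 2·that − 1, so ties contribute zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be nonempty")
    nx, ny = x.size, y.size
    ranks = sp_stats.rankdata(np.concatenate([x, y]))
    u = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    return float(2.0 * u / (nx * ny) - 1.0)


@dataclass(frozen=True)
class RocResult:
    """ROC curve and its trapezoidal area."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


def auroc(scores, binary_labels) -> RocResult:
    """ROC by threshold sweep; AUROC as trapezoidal area.

    Equals the rank-based Mann–Whitney statistic with ties counted ½
    (the diagonal segments of tied thresholds integrate to the same area).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(binary_labels).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError("binary_labels must contain exactly two classes")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auroc=area)


@dataclass(frozen=True)
class OvaClassifier:
    """One-vs-all least-squares classifier: weights, scores, training ROC."""

    target_class: object
    intercept: float
    weights: np.ndarray
    scores: np.ndarray
    roc: RocResult

    @property
    def auroc(self) -> float:
        return self.roc.auroc


def linear_ova_classifier(train: FeatureTable, target_class) -> OvaClassifier:
    """Least-squares fit of a ±1 one-vs-all indicator on the feature table.

    No regularization; the minimum-norm solution handles rank-deficient
    designs (duplicated features leave the fitted scores unchanged).
    Features are expected to be z-scored.  The training ROC treats the
    fitted values as scores.
    """
    if train.labels is None:
        raise ParameterError("training table needs labels")
    labels = np.asarray(train.labels)
    if np.unique(labels).size < 2:
        raise ParameterError("need at least two classes")
    pos = labels == target_class
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise InsufficientDataError("need >= 2 cells in class and rest")
    y = np.where(pos, 1.0, -1.0)
    X = np.column_stack([np.ones(train.n_cells), train.values])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    scores = X @ beta
    roc = auroc(scores, pos.astype(int))
    return OvaClassifier(
        target_class=target_class,
        intercept=float(beta[0]),
        weights=beta[1:],
        scores=scores,
        roc=roc,
    )


def spearman_matrix(
    t: FeatureTable, edge_threshold: float = 0.6
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Feature–feature Spearman rank correlation matrix.

    Average ranks for ties; diagonal 1.  Also returns the edge list of
    feature pairs with |ρ| above ``edge_threshold`` (the graph drawn in
    circular correlation plots).
    """
    if t.n_cells < 3:
        raise InsufficientDataError("need >= 3 cells")
    rho = sp_stats.spearmanr(t.values).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-feature case
        r2 = sp_stats.spearmanr(t.values[:, 0], t.values[:, 1]).statistic
        rho = np.array([[1.0, r2], [r2, 1.0]])
    np.fill_diagonal(rho, 1.0)
    mat = pd.DataFrame(rho, index=t.feature_names, columns=t.feature_names)
    edges = []
    for i in range(len(t.feature_names)):
        for j in range(i + 1, len(t.feature_names)):
            if abs(rho[i, j]) > edge_threshold:
                edges.append((t.feature_names[i], t.feature_names[j], float(rho[i, j])))
    return mat, edges


def rank_features(t: FeatureTable) -> list[tuple[str, float]]:
    """Rank features by mean one-vs-all AUROC across classes.

    Each raw feature is used directly as a score for every class-vs-rest
    problem; orientation is resolved per feature/class as max(a, 1−a).
    Descending by mean AUROC, ties kept in input feature order.
    """
    if t.labels is None:
        raise ParameterError("table needs labels")
    classes = np.unique(t.labels)
    if classes.size < 2:
        raise ParameterError("need >= 2 classes")
    results = []
    for j, name in enumerate(t.feature_names):
        col = t.values[:, j]
        aucs = []
        for c in classes:
            y = (t.labels == c).astype(int)
            a = auroc(col, y).auroc
            aucs.append(max(a, 1.0 - a))
        results.append((name, float(np.mean(aucs))))
    order = sorted(range(len(results)), key=lambda i: (-results[i][1], i))
    return [results[i] for i in order]
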