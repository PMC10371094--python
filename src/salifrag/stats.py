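"""Cohort-level statistics: Welch t tests, adaptive two-stage FDR, ROC/AUC
and PCA feature integration.

Single features are compared between two groups with Welch's unequal-
variance t test. Multi-feature scans (per-bin coverage, per-bin fragment
scores, end-motif frequencies, taxa abundances) are corrected with the
two-stage step-up false-discovery-rate procedure of Benjamini, Krieger and
Yekutieli (BKY): a first linear step-up pass at q' = q/(1+q) estimates the
number of true nulls m0 = m - r1, and a second pass runs at level
q'·m/m0. Discriminative ability of single features is summarised by the
area under the ROC curve, computed as the Mann-Whitney U statistic divided
by n1·n0 (ties counted half). Feature integration mirrors standard
multivariate practice: features are centred, scaled to unit variance and
decomposed by SVD (PCA); group separation is then tested on PC1 scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Samples x features with a two-group label per sample."""

    values: pd.DataFrame          # index: sample ids, columns: feature names
    groups: pd.Series             # index: sample ids, values: group labels

    def __post_init__(self) -> None:
        self.groups = self.groups.loc[self.values.index]
        labels = self.group_labels
        if len(labels) != 2:
            raise ValueError(f"expected exactly two groups, found {labels}")

    @property
    def group_labels(self) -> list[str]:
        return sorted(map(str, pd.unique(self.groups.astype(str))))

    def split(self, feature: str | None = None):
        """Return the two per-group sub-frames (or column vectors)."""
        g1, g2 = self.group_labels
        m1 = self.groups.astype(str) == g1
        v = self.values if feature is None else self.values[feature]
        return v[m1.values], v[~m1.values]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        groups = df.pop("group")
        return cls(values=df, groups=groups)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test with Satterthwaite df; two-sided p.

    Degenerate inputs where both groups are constant return t = 0, p = 1
    when the means agree and |t| = inf, p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch t test needs >= 2 finite values per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if diff == 0:
            return 0.0, float(n1 + n2 - 2), 1.0
        return math.copysign(math.inf, diff), float(n1 + n2 - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _bh_adjusted(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped to 1)."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class BkyResult:
    """Outcome of the two-stage BKY procedure at level q."""

    mask: np.ndarray       # boolean rejections
    qvalues: np.ndarray    # per-feature q on the same scale as q (reject iff <= q)
    m0: int                # estimated number of true null hypotheses
    stage1_rejections: int


def bky_fdr(pvalues, q: float = 0.05) -> BkyResult:
    """Two-stage step-up FDR control (Benjamini-Krieger-Yekutieli).

    Stage 1 runs a linear (BH) step-up at q' = q/(1+q). With r1 rejections:
    zero r1 rejects nothing; r1 == m rejects everything; otherwise m0 is
    estimated as m - r1 and stage 2 reruns the step-up at level q'·m/m0.
    Reported q-values are scaled so that ``qvalues <= q`` reproduces the
    stage-2 mask.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return BkyResult(np.zeros(0, bool), np.zeros(0), 0, 0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q_prime = q / (1.0 + q)
    bh = _bh_adjusted(p)
    r1 = int((bh <= q_prime).sum())
    if r1 == 0:
        return BkyResult(np.zeros(m, bool), np.minimum(bh * (1.0 + q), 1.0), m, 0)
    if r1 == m:
        return BkyResult(np.ones(m, bool), np.minimum(bh * (1.0 + q), 1.0), 0, m)
    m0 = m - r1
    qvalues = np.minimum(bh * (m0 / m) * (1.0 + q), 1.0)
    mask = qvalues <= q
    return BkyResult(mask, qvalues, m0, r1)


@dataclass
class ScanResult:
    """Per-feature two-group scan with FDR flags (volcano-plot ready)."""

    table: pd.DataFrame    # feature, mean_diff, t, p, qvalue, rejected
    q: float
    n_masked: int = 0      # features dropped for insufficient data

    @property
    def n_significant(self) -> int:
        return int(self.table["rejected"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def feature_scan(matrix: FeatureMatrix, q: float = 0.05) -> ScanResult:
    """Per-feature Welch t tests with two-stage BKY FDR at level ``q``.

    Mean differences are group1 - group2 (groups in sorted label order).
    Features with fewer than two finite values in either group are masked
    out and logged.
    """
    a, b = matrix.split()
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    ok = (np.isfinite(av).sum(axis=0) >= 2) & (np.isfinite(bv).sum(axis=0) >= 2)
    n_masked = int((~ok).sum())
    if n_masked:
        logger.warning("masked %d features with <2 values per group", n_masked)
    features = matrix.values.columns[ok]
    if len(features) == 0:
        empty = pd.DataFrame(columns=["feature", "mean_diff", "t", "p", "qvalue", "rejected"])
        return ScanResult(empty, q=q, n_masked=n_masked)
    av, bv = av[:, ok], bv[:, ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(av, bv, axis=0, equal_var=False, nan_policy="omit")
    diff = np.nanmean(av, axis=0) - np.nanmean(bv, axis=0)
    # zero-variance features: equal means -> no evidence, unequal -> certain
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    p = np.where(degenerate & (diff == 0), 1.0, np.where(degenerate, 0.0, p))
    res = bky_fdr(p, q=q)
    table = pd.DataFrame({"feature": features, "mean_diff": diff, "t": t, "p": p,
                          "qvalue": res.qvalues, "rejected": res.mask})
    return ScanResult(table, q=q, n_masked=n_masked)


def roc_auc(scores, labels, positive=None, orient: bool = False) -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    AUC = U / (n1 * n0) where U counts score pairs (positive, negative) with
    the positive ranked higher, ties counted half. Higher scores predict the
    positive label; with ``orient`` the larger of AUC and 1-AUC is returned
    (direction-agnostic discriminability).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("roc_auc needs exactly two classes in labels")
    if positive is None:
        positive = classes[1]
    pos = lab == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = sps.rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return float(max(auc, 1.0 - auc)) if orient else float(auc)


@dataclass
class PcaResult:
    """Scores, loadings and % variance explained from scaled PCA."""

    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    variance_explained: np.ndarray  # percent per component
    dropped_features: list[str] = field(default_factory=list)


def pca_integrate(matrix: FeatureMatrix, n_components: int = 20) -> PcaResult:
    """Integrate features by PCA on the centred, unit-variance matrix.

    Zero-variance features are dropped (logged). The number of components is
    capped at min(n_samples, n_features). Use :func:`welch_t` on
    ``scores['PC1']`` split by group for the downstream separation test.
    """
    from sklearn.decomposition import PCA

    vals = matrix.values.astype(float)
    variances = vals.var(axis=0, ddof=1)
    dropped = list(vals.columns[(variances == 0) | ~np.isfinite(variances)])
    if dropped:
        logger.warning("dropping %d zero-variance features from PCA", len(dropped))
        vals = vals.drop(columns=dropped)
    if vals.shape[1] < 2 or vals.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 usable features")
    scaled = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    k = min(n_components, scaled.shape[0], scaled.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(scaled.to_numpy())
    names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=vals.index, columns=names),
        loadings=pd.DataFrame(pca.components_.T, index=vals.columns, columns=names),
        variance_explained=100.0 * pca.explained_variance_ratio_,
        dropped_features=dropped,
    )


def hierarchical_order(matrix: FeatureMatrix, features: list[str] | None = None) -> list[str]:
    """Sample ordering from average-linkage clustering on correlation distance.

    Mirrors the default heatmap clustering of multivariate web tools; the
    dendrogram leaf order is returned rather than an image.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    vals = matrix.values if features is None else matrix.values[features]
    vals = vals.loc[:, vals.var(axis=0) > 0]
    dist = pdist(vals.to_numpy(dtype=float), metric="correlation")
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    return [matrix.values.index[i] for i in order]
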