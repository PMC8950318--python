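"""Dose-responding feature selection, temporal clustering and group tests.

A metabolic feature is called a dose-responder when, at the early (4 h) or
late (24 h) time point, it jointly shows (i) a strong treatment effect
(max |log2 FC| over treated doses above a threshold, default 1), (ii) a
strong monotone association with the encoded dose (|Pearson r| above a
threshold, default 0.8, with p below alpha) and (iii) a significant linear
regression slope against the encoded dose (Wald test, p below alpha).

Selected features' temporal fold-change profiles are grouped by
agglomerative hierarchical clustering (cosine distance, complete linkage),
and the number of clusters is chosen by minimising the Davies-Bouldin
index over a scan range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .errors import NumericalError, UndefinedCorrelationError, ValidationError
from .preprocess import FoldChangeTable, SampleTable, default_pseudo

DOSE_ENCODINGS = ("ordinal", "raw", "log10")


@dataclass(frozen=True)
class SelectionThresholds:
    """Gate parameters for dose-responder selection.

    lfc: minimum max-|log2FC| over treated doses at the active time point.
    r: minimum |Pearson r| between response and encoded dose.
    alpha: significance level for both the correlation and the Wald slope p.
    dose_encoding: 'ordinal' (default), 'raw' or 'log10'.
    """

    lfc: float = 1.0
    r: float = 0.8
    alpha: float = 0.05
    dose_encoding: str = "ordinal"

    def __post_init__(self) -> None:
        if self.lfc < 0:
            raise ValidationError("lfc threshold must be >= 0")
        if not 0 <= self.r <= 1:
            raise ValidationError("r threshold must lie in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must lie in (0, 1]")
        if self.dose_encoding not in DOSE_ENCODINGS:
            raise ValidationError(f"unknown dose encoding {self.dose_encoding!r}")


@dataclass
class ResponderResult:
    """Per-feature selection statistics and the final boolean call.

    ``stats`` holds, for each tested time point t, columns
    ``max_abs_lfc_t{t}``, ``r_t{t}``, ``r_p_t{t}``, ``slope_t{t}``,
    ``wald_p_t{t}`` and ``selected_t{t}``, plus the overall ``selected``.
    """

    stats: pd.DataFrame
    thresholds: SelectionThresholds
    times: tuple[float, ...]

    @property
    def selected(self) -> pd.Index:
        return self.stats.index[self.stats["selected"]]


@dataclass
class ClusterPartition:
    """A chosen flat partition of clustered features."""

    k: int
    labels: pd.Series
    db_index: float
    linkage: np.ndarray
    db_by_k: dict[int, float] = field(default_factory=dict)


def encode_dose(
    doses, encoding: str = "ordinal", delta: float | None = None
) -> np.ndarray:
    """Map administered doses onto the scale used for correlation/regression.

    'ordinal' assigns 0, 1, 2, ... to the sorted unique doses (the default:
    the study's doses are decade-spaced with a zero, so a raw scale would be
    dominated by the top dose); 'raw' returns the doses unchanged; 'log10'
    returns log10(dose + delta) with delta defaulting to one tenth of the
    smallest nonzero dose.
    """
    doses = np.asarray(doses, dtype=float)
    if (doses < 0).any():
        raise ValidationError("doses must be non-negative")
    if encoding == "ordinal":
        levels = np.unique(doses)
        if levels[0] != 0:
            raise ValidationError("doses must include 0 for ordinal encoding")
        return np.searchsorted(levels, doses).astype(float)
    if encoding == "raw":
        return doses
    if encoding == "log10":
        if delta is None:
            positive = doses[doses > 0]
            if positive.size == 0:
                raise ValidationError("log10 encoding needs a positive dose")
            delta = float(positive.min()) / 10.0
        return np.log10(doses + delta)
    raise ValidationError(f"unknown dose encoding {encoding!r}")


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def wald_slope_test(x, y) -> tuple[float, float]:
    """OLS slope of y on x with the two-sided Wald p-value for slope = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("regression undefined for constant x")
    with warnings.catch_warnings():
        # constant y gives slope 0 with an r=0 warning we handle ourselves
        warnings.simplefilter("ignore")
        fit = scipy.stats.linregress(x, y)
    p = fit.pvalue
    if np.isnan(p):  # zero-variance y: slope exactly 0
        p = 1.0
    return float(fit.slope), float(p)


def mann_whitney_u(
    group_a, group_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U for group_a vs group_b.

    Uses the exact null distribution when both groups have at most 8
    observations and no ties straddle the groups; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def select_responders(
    fc: FoldChangeTable,
    table: SampleTable,
    thresholds: SelectionThresholds | None = None,
    times: tuple[float, ...] = (4.0, 24.0),
    pseudo: float | None = None,
) -> ResponderResult:
    """Apply the joint FC / correlation / Wald-regression gate per feature.

    For each time point in ``times`` the per-sample log2 intensities (all
    doses, all donors at that time) are correlated and regressed against the
    encoded dose.  A feature is selected when the full conjunction of gates
    holds at the early or at the late time point.
    """
    thresholds = thresholds or SelectionThresholds()
    features = list(fc.lfc.columns)
    if features != list(table.intensities.columns):
        raise ValidationError("fold-change table and sample table features differ")
    if pseudo is None:
        pseudo = default_pseudo(table)
    stats = pd.DataFrame(index=pd.Index(features, name="feature"))
    any_selected = np.zeros(len(features), dtype=bool)
    for t in times:
        at_t = table.meta["time_h"] == t
        if not at_t.any():
            raise ValidationError(f"no samples at time {t} h")
        sub = table.subset_samples(at_t)
        x = encode_dose(sub.meta["dose_uM"].to_numpy(), thresholds.dose_encoding)
        y = np.log2(sub.intensities.to_numpy(dtype=float) + pseudo)
        max_abs = fc.at_time(t).abs().max(axis=0).reindex(features).to_numpy()
        r = np.empty(len(features))
        rp = np.empty(len(features))
        slope = np.empty(len(features))
        wp = np.empty(len(features))
        for i in range(len(features)):
            col = y[:, i]
            if np.ptp(col) == 0:
                r[i], rp[i], slope[i], wp[i] = 0.0, 1.0, 0.0, 1.0
                continue
            r[i], rp[i] = pearson_r(x, col)
            slope[i], wp[i] = wald_slope_test(x, col)
        gate = (
            (max_abs > thresholds.lfc)
            & (np.abs(r) > thresholds.r)
            & (rp < thresholds.alpha)
            & (wp < thresholds.alpha)
        )
        tag = f"t{t:g}"
        stats[f"max_abs_lfc_{tag}"] = max_abs
        stats[f"r_{tag}"] = r
        stats[f"r_p_{tag}"] = rp
        stats[f"slope_{tag}"] = slope
        stats[f"wald_p_{tag}"] = wp
        stats[f"selected_{tag}"] = gate
        any_selected |= gate
    stats["selected"] = any_selected
    return ResponderResult(stats=stats, thresholds=thresholds, times=tuple(times))


def responder_profiles(fc: FoldChangeTable, features) -> pd.DataFrame:
    """Features x treated-(dose, time) log2FC matrix for clustering."""
    treated = fc.lfc[
        (fc.lfc.index.get_level_values("dose_uM") > 0)
        & (fc.lfc.index.get_level_values("time_h") > 0)
    ]
    return treated[list(features)].T


def cluster_profiles(profiles) -> np.ndarray:
    """Agglomerative clustering of fold-change profiles.

    Cosine distance (1 - cosine similarity) with complete linkage; returns
    the scipy linkage record.  Deterministic for a given row order.
    """
    mat = np.asarray(profiles, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValidationError("need at least 2 profiles to cluster")
    norms = np.linalg.norm(mat, axis=1)
    if (norms == 0).any():
        bad = int(np.nonzero(norms == 0)[0][0])
        raise ValidationError(f"profile row {bad} is all-zero; cosine undefined")
    return sch.linkage(mat, method="complete", metric="cosine")


def davies_bouldin(points, labels) -> float:
    """Davies-Bouldin cluster-validity index (lower is better).

    DB = mean over clusters i of max_{j != i} (S_i + S_j) / M_ij, with S the
    mean Euclidean distance of a cluster's points to its centroid and M the
    Euclidean distance between centroids.  Coincident centroids make the
    index diverge; +inf is returned with a warning.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if pts.ndim != 2 or pts.shape[0] != labels.shape[0]:
        raise ValidationError("points and labels must align")
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValidationError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.stack([pts[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [
            np.linalg.norm(pts[labels == u] - centroids[i], axis=1).mean()
            for i, u in enumerate(uniq)
        ]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    ratios = np.full((k, k), -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                if sep[i, j] == 0:
                    ratios[i, j] = np.inf
                else:
                    ratios[i, j] = (scatter[i] + scatter[j]) / sep[i, j]
    worst = ratios.max(axis=1)
    if np.isinf(worst).any():
        warnings.warn("coincident cluster centroids: Davies-Bouldin diverges")
        return float("inf")
    return float(worst.mean())


def optimal_partition(profiles, k_range=None) -> ClusterPartition:
    """Cut the cosine/complete dendrogram at each k and pick the DB minimum.

    Ties in the Davies-Bouldin index are broken toward the smallest k.
    """
    if isinstance(profiles, pd.DataFrame):
        index = profiles.index
        mat = profiles.to_numpy(dtype=float)
    else:
        mat = np.asarray(profiles, dtype=float)
        index = pd.RangeIndex(mat.shape[0])
    n = mat.shape[0]
    if k_range is None:
        k_range = range(2, min(12, n - 1) + 1)
    k_range = [int(k) for k in k_range]
    if len(k_range) == 0:
        raise ValidationError("empty k range")
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValidationError(f"k range must lie within [2, {n - 1}]")
    Z = cluster_profiles(mat)
    db_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in sorted(set(k_range)):
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        if np.unique(labels).size != k:  # tie in merge heights: cut unattainable
            continue
        db_by_k[k] = davies_bouldin(mat, labels)
        labels_by_k[k] = labels
    if not db_by_k:
        raise NumericalError("no k in range produced a valid partition")
    best_k = min(db_by_k, key=lambda k: (db_by_k[k], k))
    return ClusterPartition(
        k=best_k,
        labels=pd.Series(labels_by_k[best_k], index=index, name="cluster"),
        db_index=db_by_k[best_k],
        linkage=Z,
        db_by_k=db_by_k,
    )
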