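"""Activity-based sample stratification and cluster characterisation.

Samples are compared by the Spearman correlation of their combined
kinase + TF activity profiles; the Euclidean distances between the rows of
that cross-correlation matrix feed a complete-linkage dendrogram, cut into
k groups.  Each cluster is characterised by a per-regulator score
(median activity in the cluster divided by its standard deviation;
|score| >= 2 marks deregulation) and by hypergeometric over-representation
of clinical annotation levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .associations import bh_adjust

logger = logging.getLogger("protact")


@dataclass
class ClusterResult:
    labels: pd.Series  # sample -> cluster id (1..k), ids by decreasing size
    linkage: np.ndarray
    k: int


@dataclass
class ClusterActivityScore:
    scores: pd.DataFrame  # protein x cluster, NaN where degenerate
    degenerate: pd.DataFrame  # boolean flags, same shape
    dereg_threshold: float

    def deregulated(self) -> pd.DataFrame:
        return self.scores.abs() >= self.dereg_threshold


def sample_cross_correlation(activity: pd.DataFrame,
                             min_shared: int = 3) -> pd.DataFrame:
    """Symmetric sample x sample Spearman correlation matrix.

    Pairwise-complete observations; pairs sharing fewer than `min_shared`
    features yield a missing cell.  The diagonal is exactly 1.
    """
    corr = activity.corr(method="spearman", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    missing = int(corr.isna().sum().sum())
    if missing:
        logger.info("sample_cross_correlation: %d cells missing "
                    "(fewer than %d shared features)", missing, min_shared)
    return corr


def cluster_samples(corr_matrix: pd.DataFrame, k: int = 8) -> ClusterResult:
    """Cut a complete-linkage tree over correlation-profile distances into k
    groups.

    Missing correlation cells are imputed with the column median before the
    Euclidean distances are computed.  Cluster ids are reassigned by
    decreasing cluster size so that id 1 is always the largest group.
    """
    n = corr_matrix.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    med = corr_matrix.median(axis=0, skipna=True).fillna(0.0)
    filled = corr_matrix.fillna(med)  # column-median imputation
    tree = linkage(pdist(filled.to_numpy(), metric="euclidean"),
                   method="complete")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # stable ids: decreasing size, ties by smallest member sample id
    order = sorted(
        set(raw),
        key=lambda c: (-np.sum(raw == c),
                       min(corr_matrix.index[raw == c])))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=corr_matrix.index,
                       name="cluster")
    logger.info("cluster_samples: %d samples into %d groups, sizes %s",
                n, k, labels.value_counts().sort_index().tolist())
    return ClusterResult(labels=labels, linkage=tree, k=k)


def cluster_activity_scores(
    activity: pd.DataFrame,
    clusters: pd.Series,
    dereg_threshold: float = 2.0,
) -> ClusterActivityScore:
    """Median / SD activity score per protein x cluster.

    Clusters contributing fewer than 2 measured samples for a protein, or
    with zero spread, are flagged degenerate and carry no score.
    """
    cluster_ids = sorted(clusters.unique())
    scores = pd.DataFrame(np.nan, index=activity.index, columns=cluster_ids)
    degenerate = pd.DataFrame(False, index=activity.index, columns=cluster_ids)
    for cid in cluster_ids:
        members = clusters.index[clusters == cid]
        sub = activity[activity.columns.intersection(members)]
        for protein in activity.index:
            vals = sub.loc[protein].dropna()
            if len(vals) < 2:
                degenerate.loc[protein, cid] = True
                continue
            sd = vals.std(ddof=1)
            if sd == 0:
                degenerate.loc[protein, cid] = True
                continue
            scores.loc[protein, cid] = vals.median() / sd
    return ClusterActivityScore(scores=scores, degenerate=degenerate,
                                dereg_threshold=dereg_threshold)


def binarise_clinical(clinical: pd.DataFrame,
                      bmi_cutoff: float = 37.0,
                      age_cutoff: float = 50.0) -> pd.DataFrame:
    """Categorical view of the clinical table for over-representation tests.

    Continuous BMI and age are binarised at the configured cutoffs; other
    columns with few levels pass through as categories.
    """
    out = pd.DataFrame(index=clinical.index)
    for col in clinical.columns:
        series = clinical[col]
        if col == "bmi":
            out[col] = np.where(series.isna(), None,
                                np.where(series > bmi_cutoff, "big", "smol"))
        elif col == "age":
            out[col] = np.where(series.isna(), None,
                                np.where(series > age_cutoff,
                                         "venerable", "young"))
        elif col in ("os_time_days", "os_event"):
            continue
        elif series.dtype == object or series.nunique() <= 20:
            out[col] = series.astype(object).where(series.notna(), None)
    return out


def clinical_overrepresentation(
    clusters: pd.Series,
    clinical: pd.DataFrame,
    min_level_count: int = 5,
    bmi_cutoff: float = 37.0,
    age_cutoff: float = 50.0,
) -> pd.DataFrame:
    """Hypergeometric over-representation of clinical levels per cluster.

    For a cohort of N samples, a level populating K of them and a cluster
    of size n with x members of that level, the p-value is the upper tail
    P(X >= x) of Hypergeom(N, K, n).  Levels with fewer than
    `min_level_count` patients are excluded; BH runs across all tests.
    """
    categorical = binarise_clinical(clinical.loc[clusters.index],
                                    bmi_cutoff, age_cutoff)
    n_total = len(clusters)
    rows = []
    for col in categorical.columns:
        series = categorical[col].dropna()
        for level, level_total in series.value_counts().items():
            if level_total < min_level_count:
                continue
            level_samples = set(series.index[series == level])
            for cid in sorted(clusters.unique()):
                members = set(clusters.index[clusters == cid])
                overlap = len(level_samples & members)
                p = float(stats.hypergeom.sf(overlap - 1, n_total,
                                             int(level_total), len(members)))
                rows.append((col, str(level), int(cid), overlap,
                             int(level_total), len(members), p))
    frame = pd.DataFrame(rows, columns=["feature", "level", "cluster",
                                        "overlap", "level_total",
                                        "cluster_size", "p"])
    frame["fdr"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else []
    return frame
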