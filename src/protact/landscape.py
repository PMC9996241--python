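"""Co-regulation analyses over the activity landscape.

Covers: correlating inferred activities with the regulator's own molecular
layers (CNV, mRNA, protein, phosphorylation), correlating activities of
known kinase-kinase regulatory pairs against an unrelated-pair background,
collapsing kinases with near-identical substrate sets, selecting highly
variable kinases, and classifying kinases as preferentially regulated in
tumours versus acute perturbations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .activity import ActivityMatrix, regulation_percentage
from .associations import bh_adjust
from .core_io import FeatureMatrix, PhosphositeKey

logger = logging.getLogger("protact")


@dataclass
class SpecificityCall:
    kinase: str
    pct_tumour: float
    pct_perturbation: float
    residual_z: float
    call: str  # tumour_specific | perturbation_specific | shared


def correlate_activity_layers(
    activity: ActivityMatrix,
    layer_matrices: Mapping[str, FeatureMatrix],
    n_min: int = 10,
    site_map: Mapping[str, Sequence[str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each regulator's activity with its own levels.

    For the ``phospho`` layer the per-protein summary is the mean of the
    protein's measured site rows (`site_map`: protein -> site row ids).
    Pairs with fewer than `n_min` overlapping samples are labelled
    ``unknown``; the rest are BH-adjusted within each layer and called
    significant below `alpha`.
    """
    rows = []
    act = activity.values
    for layer_name, matrix in layer_matrices.items():
        values = matrix.values
        for protein in act.index:
            if layer_name == "phospho":
                site_ids = [s for s in (site_map or {}).get(protein, [])
                            if s in values.index]
                if not site_ids:
                    rows.append((protein, layer_name, np.nan, np.nan, 0))
                    continue
                layer_row = values.loc[site_ids].mean(axis=0, skipna=True)
            else:
                if protein not in values.index:
                    rows.append((protein, layer_name, np.nan, np.nan, 0))
                    continue
                layer_row = values.loc[protein]
            a, b = act.loc[protein].align(layer_row)
            mask = a.notna() & b.notna()
            n = int(mask.sum())
            if n < n_min or a[mask].std() == 0 or b[mask].std() == 0:
                rows.append((protein, layer_name, np.nan, np.nan, n))
                continue
            r, p = stats.pearsonr(a[mask], b[mask])
            rows.append((protein, layer_name, float(r), float(p), n))
    frame = pd.DataFrame(rows, columns=["protein", "layer", "r", "p", "n"])
    frame["fdr"] = np.nan
    frame["status"] = "unknown"
    for layer_name in frame["layer"].unique():
        tested = frame["layer"].eq(layer_name) & frame["p"].notna()
        if tested.any():
            frame.loc[tested, "fdr"] = bh_adjust(frame.loc[tested, "p"])
    known = frame["fdr"].notna()
    frame.loc[known, "status"] = np.where(frame.loc[known, "fdr"] < alpha,
                                          "significant", "not_significant")
    return frame


def kinase_pair_correlation(
    activity: pd.DataFrame,
    directed_pairs: pd.DataFrame,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of annotated kinase pairs, stratified by support.

    `directed_pairs` carries columns ``source``, ``target`` and
    ``n_sources`` (number of databases reporting the interaction).  The
    background stratum is every unordered kinase pair with measured
    activities that is not annotated.  Pairs sharing fewer than
    `min_shared` samples are skipped.
    """
    def spearman(a: pd.Series, b: pd.Series) -> tuple[float, int]:
        mask = a.notna() & b.notna()
        n = int(mask.sum())
        if n < min_shared or a[mask].nunique() < 2 or b[mask].nunique() < 2:
            return np.nan, n
        rho, _ = stats.spearmanr(a[mask], b[mask])
        return float(rho), n

    rows = []
    annotated = set()
    for row in directed_pairs.itertuples(index=False):
        a, b = row.source, row.target
        annotated.add((a, b) if a <= b else (b, a))
        if a not in activity.index or b not in activity.index:
            continue
        rho, n = spearman(activity.loc[a], activity.loc[b])
        if np.isnan(rho):
            continue
        stratum = "multi_source" if int(row.n_sources) >= 2 else "single_source"
        rows.append((a, b, rho, n, stratum))
    kinases = list(activity.index)
    for i, a in enumerate(kinases):
        for b in kinases[i + 1:]:
            if ((a, b) if a <= b else (b, a)) in annotated:
                continue
            rho, n = spearman(activity.loc[a], activity.loc[b])
            if np.isnan(rho):
                continue
            rows.append((a, b, rho, n, "background"))
    frame = pd.DataFrame(rows, columns=["kinase_a", "kinase_b", "rho", "n",
                                        "stratum"])
    return frame


def compare_strata_to_background(pair_corr: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum comparison of each annotated stratum against the background."""
    background = pair_corr.loc[pair_corr["stratum"] == "background", "rho"]
    rows = []
    for stratum in sorted(set(pair_corr["stratum"]) - {"background"}):
        values = pair_corr.loc[pair_corr["stratum"] == stratum, "rho"]
        if values.empty or background.empty:
            continue
        _, p = stats.mannwhitneyu(values, background, alternative="greater")
        rows.append((stratum, float(values.median()),
                     float(background.median()), float(p), len(values)))
    return pd.DataFrame(rows, columns=["stratum", "median_rho",
                                       "background_median_rho", "p", "n_pairs"])


def jaccard_index(a: frozenset, b: frozenset) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def reduce_redundant_kinases(
    substrate_sets: Mapping[str, frozenset[PhosphositeKey]],
    height: float = 0.85,
) -> tuple[list[str], dict[str, int]]:
    """Collapse kinases with overlapping substrate sets.

    Complete-linkage agglomerative clustering on the distance 1 - Jaccard
    index of shared substrates; the dendrogram is cut at `height` and one
    kinase per cluster is kept — the one with the most substrates, ties
    broken lexicographically.  Returns (kept kinases, kinase -> cluster id).
    """
    if not 0.0 < height <= 1.0:
        raise ValueError("height must lie in (0, 1]")
    kinases = sorted(substrate_sets)
    if len(kinases) == 1:
        return kinases, {kinases[0]: 1}
    n = len(kinases)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - jaccard_index(substrate_sets[kinases[i]],
                                    substrate_sets[kinases[j]])
            dist[i, j] = dist[j, i] = d
    tree = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(tree, t=height, criterion="distance")
    cluster_map = dict(zip(kinases, (int(c) for c in labels)))
    kept = []
    for cluster in sorted(set(labels)):
        members = [k for k in kinases if cluster_map[k] == cluster]
        members.sort(key=lambda k: (-len(substrate_sets[k]), k))
        kept.append(members[0])
    logger.info("redundancy reduction at height %.2f: %d -> %d kinases",
                height, n, len(kept))
    return sorted(kept), cluster_map


def select_variable_kinases(activity: pd.DataFrame) -> list[str]:
    """Kinases whose activity SD across measured samples strictly exceeds
    the median SD."""
    sds = activity.std(axis=1, skipna=True, ddof=1).dropna()
    if sds.empty:
        return []
    median_sd = sds.median()
    return sorted(sds.index[sds > median_sd])


def tumour_vs_perturbation(
    activity_tumour: pd.DataFrame,
    activity_perturb: pd.DataFrame,
    cutoff: float = 1.75,
    z_thresh: float = 2.0,
    response: str = "tumour",
) -> list[SpecificityCall]:
    """Classify kinases as tumour- or perturbation-preferentially regulated.

    Both matrices are reduced to per-kinase regulation percentages
    (fraction of samples with |activity| > cutoff); kinases regulated in
    neither set are excluded.  A simple linear regression relates the two
    percentages; standardised residuals beyond `z_thresh` flag the kinase
    as specific to the axis it deviates towards.  With tumour percentage as
    the response (default) a residual z > z_thresh means tumour-specific;
    `response="perturbation"` swaps orientation and flips the calls.
    """
    if response not in ("tumour", "perturbation"):
        raise ValueError("response must be 'tumour' or 'perturbation'")
    pct_t = regulation_percentage(activity_tumour, cutoff)
    pct_p = regulation_percentage(activity_perturb, cutoff)
    common = pct_t.index.intersection(pct_p.index)
    n_t = activity_tumour.shape[1]
    n_p = activity_perturb.shape[1]
    kept = [k for k in common
            if pct_t[k] * n_t >= 1 or pct_p[k] * n_p >= 1]
    if len(kept) < 3:
        raise ValueError("need at least 3 kinases regulated somewhere")
    x = pct_p[kept] if response == "tumour" else pct_t[kept]
    y = pct_t[kept] if response == "tumour" else pct_p[kept]
    X = np.column_stack([np.ones(len(kept)), x.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
    resid = y.to_numpy(dtype=float) - X @ beta
    sd = resid.std(ddof=1)
    z = resid / sd if sd > 0 else np.zeros_like(resid)
    calls = []
    for kinase, zi in zip(kept, z):
        toward_tumour = zi > z_thresh if response == "tumour" else zi < -z_thresh
        toward_perturb = zi < -z_thresh if response == "tumour" else zi > z_thresh
        call = ("tumour_specific" if toward_tumour
                else "perturbation_specific" if toward_perturb
                else "shared")
        calls.append(SpecificityCall(
            kinase=kinase, pct_tumour=float(pct_t[kinase]),
            pct_perturbation=float(pct_p[kinase]),
            residual_z=float(zi), call=call))
    return calls
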