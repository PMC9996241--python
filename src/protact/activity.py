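"""Kinase and transcription-factor activity inference.

Kinase activity in a sample is scored with a one-sample z-test on the
substrate phosphosites: with x the mean log2 fold-change of the kinase's N
measured substrates and mu, sigma the mean and standard deviation of all
phosphosites measured in that sample (the background, substrates included),

    z = (x - mu) / (sigma / sqrt(N))

The two-tailed normal p-value is then signed by the side of the
distribution the z-score falls on, giving the activity score
AS = sign(z) * (-log10 p): positive when the substrates are more
phosphorylated than the background, negative when less.

TF activity is a signed regulon enrichment score: per sample, the gene
log2 fold-changes are rank-transformed to quantiles q = rank / (n + 1),
mapped through the standard-normal inverse, and summed over the m measured
regulon targets with their mode of regulation (+1 activating / -1
repressing):

    NES = sum(mode_i * t_i) / sqrt(m)

Under random ranks the NES is approximately standard normal, so scores are
comparable between TFs and samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FeatureMatrix, PhosphositeKey, PriorNetwork

logger = logging.getLogger("protact")

P_FLOOR = 1e-300  # keeps -log10 p finite


@dataclass
class ActivityMatrix:
    """Regulator x sample signed activity scores with per-cell target counts."""

    values: pd.DataFrame
    n_targets: pd.DataFrame
    score_kind: str  # "signed_log10p" (kinases) or "nes" (TFs)

    def as_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(self.values, "activity")


@dataclass
class ZTestDetail:
    """Per-cell internals of the kinase z-test."""

    kinase: str
    sample: str
    z: float
    x: float
    mu: float
    sigma: float
    n: int
    p: float
    activity: float


def _signed_log10p(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.maximum(p, P_FLOOR)
    return p, np.sign(z) * (-np.log10(p))


def kinase_activity_ztest(
    phospho: FeatureMatrix,
    prior: PriorNetwork,
    min_targets: int = 3,
    mode: str = "substrates",
    exclude_targets_from_background: bool = False,
    self_site_annotations: pd.DataFrame | None = None,
    functional_score_gate: float = 0.4,
    return_details: bool = False,
) -> ActivityMatrix | tuple[ActivityMatrix, list[ZTestDetail]]:
    """Score every kinase in every sample with the one-sample z-test.

    Parameters
    ----------
    phospho
        Residualised phosphosite matrix; row ids are ``PROTEIN_R<pos>``
        strings as produced by :class:`~protact.core_io.PhosphositeKey`.
    prior
        Kinase -> substrate phosphosite mapping.
    min_targets
        A cell is reported only when at least this many substrate sites are
        measured in the sample (default 3).
    mode
        ``substrates`` scores each kinase on its substrate sites;
        ``self_sites`` restricts the target set to sites on the kinase
        itself that are annotated as regulatory or carry a functional score
        above `functional_score_gate` (see `self_site_annotations`, a frame
        indexed by site id with optional boolean ``regulatory`` and numeric
        ``functional_score`` columns; sites without a score do not pass).
    exclude_targets_from_background
        If True, mu and sigma are computed on all phosphosites except the
        kinase's own targets; by default the background is every phosphosite
        measured in the sample, targets included.
    """
    if mode not in ("substrates", "self_sites"):
        raise ValueError(f"unknown mode {mode!r}")
    values = phospho.values
    arr = values.to_numpy(dtype=float)
    measured = ~np.isnan(arr)
    # Per-sample background over all measured phosphosites.
    bg_n = measured.sum(axis=0)
    with np.errstate(invalid="ignore"):
        bg_sum = np.nansum(arr, axis=0)
        bg_sumsq = np.nansum(arr ** 2, axis=0)
    mu = np.where(bg_n > 0, bg_sum / np.maximum(bg_n, 1), np.nan)
    var = np.where(bg_n > 1,
                   (bg_sumsq - bg_n * mu ** 2) / np.maximum(bg_n - 1, 1),
                   np.nan)
    sigma = np.sqrt(np.maximum(var, 0.0))
    degenerate = sigma == 0
    if np.any(degenerate):
        logger.warning("skipping %d degenerate samples with zero background SD",
                       int(np.sum(degenerate)))

    row_index = {rid: i for i, rid in enumerate(values.index)}
    kinases = sorted(prior.kinase_targets)
    act = np.full((len(kinases), arr.shape[1]), np.nan)
    counts = np.zeros((len(kinases), arr.shape[1]), dtype=int)
    details: list[ZTestDetail] = []

    for ki, kin in enumerate(kinases):
        target_sites = _target_sites(kin, prior, mode, self_site_annotations,
                                     functional_score_gate)
        rows = [row_index[str(s)] for s in target_sites if str(s) in row_index]
        if not rows:
            continue
        sub = arr[rows, :]
        sub_measured = ~np.isnan(sub)
        n = sub_measured.sum(axis=0)
        counts[ki, :] = n
        with np.errstate(invalid="ignore"):
            x = np.nansum(sub, axis=0) / np.maximum(n, 1)
        if exclude_targets_from_background:
            n_bg = bg_n - n
            s_bg = bg_sum - np.nansum(sub, axis=0)
            ss_bg = bg_sumsq - np.nansum(sub ** 2, axis=0)
            mu_k = np.where(n_bg > 0, s_bg / np.maximum(n_bg, 1), np.nan)
            var_k = np.where(n_bg > 1,
                             (ss_bg - n_bg * mu_k ** 2) / np.maximum(n_bg - 1, 1),
                             np.nan)
            sigma_k = np.sqrt(np.maximum(var_k, 0.0))
        else:
            mu_k, sigma_k = mu, sigma
        ok = (n >= min_targets) & ~degenerate & (sigma_k > 0) & np.isfinite(mu_k)
        z = np.full(arr.shape[1], np.nan)
        z[ok] = (x[ok] - mu_k[ok]) / (sigma_k[ok] / np.sqrt(n[ok]))
        p, signed = _signed_log10p(z)
        act[ki, ok] = signed[ok]
        if return_details:
            for j in np.flatnonzero(ok):
                details.append(ZTestDetail(
                    kinase=kin, sample=values.columns[j], z=float(z[j]),
                    x=float(x[j]), mu=float(mu_k[j]), sigma=float(sigma_k[j]),
                    n=int(n[j]), p=float(p[j]), activity=float(signed[j])))

    result = ActivityMatrix(
        values=pd.DataFrame(act, index=kinases, columns=values.columns),
        n_targets=pd.DataFrame(counts, index=kinases, columns=values.columns),
        score_kind="signed_log10p",
    )
    logger.info("kinase activities: %d kinases x %d samples, %d cells scored",
                len(kinases), arr.shape[1], int(np.isfinite(act).sum()))
    return (result, details) if return_details else result


def _target_sites(kinase: str, prior: PriorNetwork, mode: str,
                  annotations: pd.DataFrame | None,
                  gate: float) -> list[PhosphositeKey]:
    sites = sorted(prior.kinase_targets[kinase])
    if mode == "substrates":
        return sites
    own = [s for s in sites if s.protein == kinase]
    if annotations is None:
        return []
    kept = []
    for s in own:
        sid = str(s)
        if sid not in annotations.index:
            continue
        row = annotations.loc[sid]
        regulatory = bool(row.get("regulatory", False))
        score = row.get("functional_score", np.nan)
        if regulatory or (pd.notna(score) and float(score) > gate):
            kept.append(s)
    return kept


def tf_activity_nes(
    mrna: FeatureMatrix,
    prior: PriorNetwork,
    min_regulon: int = 5,
) -> ActivityMatrix:
    """Signed regulon enrichment scores for every TF in every sample."""
    values = mrna.values
    arr = values.to_numpy(dtype=float)
    n_samples = arr.shape[1]
    # Per-sample inverse-normal rank transform of the measured genes.
    t = np.full_like(arr, np.nan)
    for j in range(n_samples):
        col = arr[:, j]
        mask = ~np.isnan(col)
        m = int(mask.sum())
        if m == 0:
            continue
        ranks = stats.rankdata(col[mask], method="average")
        t[mask, j] = stats.norm.ppf(ranks / (m + 1))

    row_index = {rid: i for i, rid in enumerate(values.index)}
    tf_names = sorted(prior.regulons)
    nes = np.full((len(tf_names), n_samples), np.nan)
    counts = np.zeros((len(tf_names), n_samples), dtype=int)
    for ti, tf in enumerate(tf_names):
        entries = [(row_index[gene], mode) for gene, mode, _ in prior.regulons[tf]
                   if gene in row_index]
        if not entries:
            continue
        rows = np.array([r for r, _ in entries])
        modes = np.array([m for _, m in entries], dtype=float)
        signed = t[rows, :] * modes[:, None]
        measured = ~np.isnan(signed)
        m_counts = measured.sum(axis=0)
        counts[ti, :] = m_counts
        with np.errstate(invalid="ignore"):
            total = np.nansum(signed, axis=0)
        ok = m_counts >= min_regulon
        nes[ti, ok] = total[ok] / np.sqrt(m_counts[ok])

    result = ActivityMatrix(
        values=pd.DataFrame(nes, index=tf_names, columns=values.columns),
        n_targets=pd.DataFrame(counts, index=tf_names, columns=values.columns),
        score_kind="nes",
    )
    logger.info("TF activities: %d TFs x %d samples, %d cells scored",
                len(tf_names), n_samples, int(np.isfinite(nes).sum()))
    return result


def select_regulated_proteins(
    activity: ActivityMatrix,
    percentile: float = 96.7,
    min_fraction: float = 0.05,
    per_protein: bool = False,
) -> list[str]:
    """Proteins strongly regulated in at least `min_fraction` of samples.

    The regulation threshold is the given percentile of the pooled absolute
    activity distribution (or per-protein distributions when
    `per_protein=True`); a protein is kept when the fraction of its measured
    samples exceeding that threshold is at least `min_fraction`.
    """
    if not 50.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (50, 100)")
    values = activity.values
    if values.empty:
        return []
    abs_vals = values.abs()
    pooled = abs_vals.to_numpy().ravel()
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        return []
    kept = []
    global_thr = np.percentile(pooled, percentile)
    for protein in values.index:
        row = abs_vals.loc[protein].dropna()
        if row.empty:
            continue
        thr = np.percentile(row, percentile) if per_protein else global_thr
        if (row > thr).mean() >= min_fraction:
            kept.append(protein)
    return kept


def regulation_percentage(activity: ActivityMatrix | pd.DataFrame,
                          cutoff: float = 1.75) -> pd.Series:
    """Per-protein fraction of measured samples with |activity| > cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    values = activity.values if isinstance(activity, ActivityMatrix) else activity
    abs_vals = values.abs()
    exceeding = (abs_vals > cutoff).sum(axis=1)
    measured = abs_vals.notna().sum(axis=1)
    frac = exceeding / measured.replace(0, np.nan)
    return frac.fillna(0.0)
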