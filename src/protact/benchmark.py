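"""Benchmarking substrate-prior lists as classifiers of kinase regulation.

Absolute activity scores are used to separate gold-standard
(kinase, condition) pairs with known regulation from pairs with unknown
regulation.  Because the unknown class vastly outnumbers the gold standard,
the AUROC is averaged over repeated balanced draws of negative sets matched
in size to the positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GoldStandardPair

logger = logging.getLogger("protact")


@dataclass
class BenchmarkResult:
    prior_source: str
    aurocs: list[float]
    mean_auroc: float
    n_positives: int
    n_negatives_per_set: int


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative.

    Rank (Mann-Whitney) formulation; ties count one half.  Requires at
    least one positive and one negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc needs at least one positive and one negative")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_prior(
    activity_by_condition: pd.DataFrame,
    gold: list[GoldStandardPair],
    n_resamples: int = 100,
    seed: int = 0,
    prior_source: str = "prior",
    equal_subsample: int | None = None,
) -> BenchmarkResult:
    """Mean balanced-resampling AUROC of |activity| against the gold standard.

    `activity_by_condition` is a kinase x condition score frame.  Positives
    are the gold pairs with a measured score; negatives are drawn without
    replacement, per resample, from the measured pairs of unknown
    regulation, matched in size to the positives.  `equal_subsample`
    additionally subsamples the positives to that size in every resample
    (the control mode that makes sources with different coverage
    comparable).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    abs_scores = activity_by_condition.abs()
    gold_keys = {(p.kinase, p.condition_id) for p in gold}
    pos_scores = []
    for kin, cond in sorted(gold_keys):
        if kin in abs_scores.index and cond in abs_scores.columns:
            v = abs_scores.loc[kin, cond]
            if pd.notna(v):
                pos_scores.append(v)
    if not pos_scores:
        raise ValueError("no gold-standard pair carries a measured score")
    pos_scores = np.array(pos_scores, dtype=float)

    stacked = abs_scores.stack()
    unknown = np.array([v for (kin, cond), v in stacked.items()
                        if (kin, cond) not in gold_keys], dtype=float)
    n_pos_full = len(pos_scores)
    n_draw = equal_subsample or n_pos_full
    if len(unknown) < n_draw:
        raise ValueError(
            f"only {len(unknown)} unknown pairs available, need {n_draw}")

    rng = np.random.default_rng(seed)
    aurocs = []
    for _ in range(n_resamples):
        pos = (pos_scores if equal_subsample is None
               else rng.choice(pos_scores, size=n_draw, replace=False))
        neg = rng.choice(unknown, size=n_draw, replace=False)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(len(pos), dtype=bool),
                                 np.zeros(n_draw, dtype=bool)])
        aurocs.append(auroc(scores, labels))
    result = BenchmarkResult(
        prior_source=prior_source,
        aurocs=aurocs,
        mean_auroc=float(np.mean(aurocs)),
        n_positives=n_pos_full,
        n_negatives_per_set=n_draw,
    )
    logger.info("benchmark %s: mean AUROC %.3f over %d resamples "
                "(%d positives)", prior_source, result.mean_auroc,
                n_resamples, n_pos_full)
    return result
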