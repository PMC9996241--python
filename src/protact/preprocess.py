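"""Normalisation and confounder removal for the multiomics matrices.

The order of operations mirrors the standard workflow: abundances are turned
into log2 fold-changes against the per-feature median, outlier samples with
extreme median fold-change distributions are dropped, phosphosite columns
are quantile normalised, and host-protein abundance (plus optional clinical
covariates, or the study batch) is regressed out row by row, keeping the
residuals as the abundance-independent phosphorylation signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    FUNCTIONAL_CLASSES,
    FeatureMatrix,
    MutationRecord,
    PhosphositeKey,
)

logger = logging.getLogger("protact")


@dataclass
class ResidualMatrix:
    """Residuals of per-row OLS fits, orthogonal to the removed covariates."""

    matrix: FeatureMatrix
    provenance: list[str]
    passthrough_rows: list[str] = field(default_factory=list)


@dataclass
class PhosphositeRecord:
    """One quantified phosphopeptide collapsed to a site."""

    key: PhosphositeKey
    multiplicity: int  # number of phosphorylated positions on the peptide
    values: pd.Series  # per-sample log2 fold-changes


def log2fc_from_abundance(matrix: FeatureMatrix,
                          pseudocount: float = 1.0) -> FeatureMatrix:
    """log2(v + pseudocount) centred on the per-feature median over samples.

    Medians ignore missing cells; negative abundances are rejected.
    """
    values = matrix.values
    if (values < 0).any().any():
        raise ValueError("abundances must be non-negative")
    logged = np.log2(values + pseudocount)
    centred = logged.sub(logged.median(axis=1, skipna=True), axis=0)
    return FeatureMatrix(centred, matrix.layer)


def remove_outlier_samples(matrix: FeatureMatrix,
                           threshold: float = 1.0
                           ) -> tuple[FeatureMatrix, list[str]]:
    """Drop samples whose |median log2FC over features| strictly exceeds
    `threshold` (default 1, i.e. a two-fold shift)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    medians = matrix.values.median(axis=0, skipna=True)
    dropped = list(medians.index[medians.abs() > threshold])
    if dropped:
        logger.info("dropping %d outlier samples: %s", len(dropped), dropped)
    kept = matrix.values.drop(columns=dropped)
    return FeatureMatrix(kept, matrix.layer), dropped


def quantile_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Force all sample columns onto a common value distribution.

    The reference distribution is the per-rank mean of the column quantiles.
    Missing cells stay missing: ranks are computed on observed values only
    and the reference is interpolated to each column's observed count.
    Ties receive the average of the reference values at their rank span.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    n_features = arr.shape[0]
    # Reference: mean across columns of each column's quantile function on a
    # common grid.  For complete equal-length columns this is exactly the
    # per-rank mean of the sorted values.
    n_grid = max(n_features, 2)
    grid = np.linspace(0.0, 1.0, n_grid)
    quantiles = np.full((n_grid, arr.shape[1]), np.nan)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        quantiles[:, j] = np.quantile(obs, grid)
    reference = np.nanmean(quantiles, axis=1)

    out = np.full_like(arr, np.nan)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        mask = ~np.isnan(col)
        m = int(mask.sum())
        if m == 0:
            continue
        # Interpolate the reference to this column's observed count.
        target = np.interp(np.linspace(0.0, 1.0, m) if m > 1 else [0.5],
                           grid, reference)
        ranks = stats.rankdata(col[mask], method="average")  # 1..m, ties averaged
        out[mask, j] = np.interp(ranks, np.arange(1, m + 1), target)
    return FeatureMatrix(pd.DataFrame(out, index=values.index,
                                      columns=values.columns), matrix.layer)


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def regress_out(
    target: FeatureMatrix,
    predictor: FeatureMatrix | None = None,
    row_map: Mapping[str, str] | None = None,
    covariates: pd.DataFrame | None = None,
    min_samples: int = 3,
) -> ResidualMatrix:
    """Per-row OLS residualisation on complete cases.

    Each target row is regressed on its matched predictor row (phosphosite on
    host protein, via `row_map` target-id -> predictor-id) together with any
    clinical covariates; in covariate-only mode (`predictor=None`) only the
    covariates enter, which is how study batch effects are removed.  Rows
    with fewer than `min_samples` usable samples, or with no matched
    predictor row, pass through unchanged and are flagged.  Categorical
    covariates are one-hot encoded; a covariate with a single observed level
    is dropped with a warning.
    """
    values = target.values
    samples = values.columns

    cov_frame = pd.DataFrame(index=samples)
    provenance: list[str] = []
    if covariates is not None:
        covariates = covariates.reindex(samples)
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = col.dropna().unique()
                if len(levels) < 2:
                    logger.warning("covariate %r has a single level; dropped", name)
                    continue
                dummies = pd.get_dummies(col, prefix=name, drop_first=True,
                                         dtype=float)
                cov_frame = cov_frame.join(dummies)
            else:
                if col.dropna().nunique() < 2:
                    logger.warning("covariate %r has a single level; dropped", name)
                    continue
                cov_frame[name] = col.astype(float)
            provenance.append(name)
    if predictor is not None:
        provenance.insert(0, f"{predictor.layer}_abundance")

    out = values.copy()
    passthrough: list[str] = []
    pred_values = predictor.values if predictor is not None else None
    for row_id in values.index:
        y_row = values.loc[row_id]
        design_cols = [cov_frame] if not cov_frame.empty else []
        if predictor is not None:
            pred_id = row_map.get(row_id) if row_map else row_id
            if pred_id is None or pred_id not in pred_values.index:
                passthrough.append(row_id)
                continue
            design_cols.append(pred_values.loc[pred_id].rename("_predictor")
                               .to_frame())
        design = pd.concat(design_cols, axis=1) if design_cols else pd.DataFrame(
            index=samples)
        usable = y_row.notna()
        if not design.empty:
            usable &= design.notna().all(axis=1)
        if int(usable.sum()) < max(min_samples, design.shape[1] + 2):
            passthrough.append(row_id)
            continue
        X = np.column_stack([np.ones(int(usable.sum()))]
                            + [design.loc[usable, c].to_numpy(dtype=float)
                               for c in design.columns])
        resid = _ols_residuals(y_row[usable].to_numpy(dtype=float), X)
        out.loc[row_id, usable[usable].index] = resid
    if passthrough:
        logger.info("regress_out: %d rows passed through unchanged",
                    len(passthrough))
    return ResidualMatrix(FeatureMatrix(out, target.layer), provenance,
                          passthrough)


def deduplicate_phosphosites(records: Sequence[PhosphositeRecord]
                             ) -> FeatureMatrix:
    """Collapse duplicated site quantifications to a single row per site.

    Peptides phosphorylated at more than one position are excluded outright.
    Duplicate keys collapse to one row only when their value vectors are
    identical (missing-aware); otherwise every copy of the site is dropped.
    """
    singles = [r for r in records if r.multiplicity == 1]
    by_key: dict[PhosphositeKey, list[PhosphositeRecord]] = {}
    for rec in singles:
        by_key.setdefault(rec.key, []).append(rec)
    rows: dict[str, pd.Series] = {}
    dropped = 0
    for key, recs in by_key.items():
        first = recs[0].values
        if all(_values_equal(first, r.values) for r in recs[1:]):
            rows[str(key)] = first
        else:
            dropped += 1
    if dropped:
        logger.info("deduplicate_phosphosites: dropped %d sites with "
                    "conflicting duplicates", dropped)
    frame = (pd.DataFrame(rows).T if rows
             else pd.DataFrame(dtype=float))
    frame = frame.sort_index()
    return FeatureMatrix(frame, "phospho")


def _values_equal(a: pd.Series, b: pd.Series) -> bool:
    a, b = a.align(b)
    both = a.notna() & b.notna()
    if (a.notna() != b.notna()).any():
        return False
    return bool(np.allclose(a[both], b[both], rtol=0, atol=0))


def validate_against_sequences(
    items: Sequence[PhosphositeKey | MutationRecord],
    fasta: Mapping[str, str],
) -> tuple[list, pd.DataFrame]:
    """Keep items whose declared residue matches the sequence at the position.

    Splice-site mutation records carry no residue and are kept unchecked.
    Proteins absent from the FASTA reject the item with reason
    ``no_sequence``.  Returns (kept items, report frame with a ``reason``
    per rejected or unchecked item).
    """
    kept: list = []
    report_rows: list[tuple[str, str]] = []
    for item in items:
        if isinstance(item, MutationRecord):
            if item.mclass == "splice_site":
                kept.append(item)
                report_rows.append((_item_id(item), "not_checked"))
                continue
            protein, position, residue = item.gene, item.position, item.ref_residue
        else:
            protein, position, residue = item.protein, item.position, item.residue
        seq = fasta.get(protein)
        if seq is None:
            report_rows.append((_item_id(item), "no_sequence"))
            continue
        if position > len(seq) or seq[position - 1] != residue:
            report_rows.append((_item_id(item), "residue_mismatch"))
            continue
        kept.append(item)
    report = pd.DataFrame(report_rows, columns=["item", "reason"])
    return kept, report


def _item_id(item) -> str:
    if isinstance(item, MutationRecord):
        return f"{item.sample_id}:{item.gene}:{item.mclass}:{item.position}"
    return str(item)


def build_mutation_matrix(records: Iterable[MutationRecord],
                          samples: Sequence[str] | None = None
                          ) -> FeatureMatrix:
    """Binary sample-coverage matrix M (gene x sample): M[g, s] = 1 if sample
    s carries a protein-affecting mutation in gene g.

    Silent and splice-site calls never set a cell; multiple qualifying
    mutations in one gene/sample still give 1.  Output is invariant to
    record order.
    """
    hits = sorted({(r.gene, r.sample_id) for r in records
                   if r.mclass in FUNCTIONAL_CLASSES})
    genes = sorted({g for g, _ in hits})
    if samples is None:
        samples = sorted({r.sample_id for r in records})
    frame = pd.DataFrame(0.0, index=genes, columns=list(samples))
    for g, s in hits:
        if s in frame.columns:
            frame.loc[g, s] = 1.0
    return FeatureMatrix(frame, "protein")


def impute_median(matrix: FeatureMatrix) -> FeatureMatrix:
    """Median-per-feature imputation (deterministic stand-in used before
    clustering); all-missing rows impute to 0."""
    values = matrix.values
    med = values.median(axis=1, skipna=True).fillna(0.0)
    filled = values.T.fillna(med).T
    return FeatureMatrix(filled, matrix.layer)
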