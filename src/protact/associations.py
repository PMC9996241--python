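"""Linear-model associations between mutations, activities and expression.

Three related ordinary-least-squares designs link the molecular layers:

* mutation -> activity:   Y_act = b0 + b1*Study + b2*X_mut + e
* kinase  -> TF activity: T_act = b0 + b1*Study + b2*K_act + e
* recurrent hotspots:     KinAct = b0 + b1*H1 + b2*H2 + ... + e

with the experimental study entered as one-hot indicators against a
reference level so that cross-study offsets cannot masquerade as effects.
p-values come from the coefficient t-statistics and are adjusted with
Benjamini-Hochberg within each response family.  Association sets are
validated by testing their enrichment in a confidence-filtered
protein-interaction network with one-sided Fisher exact tests along a grid
of significance cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import EdgeList, FeatureMatrix, LOF_CLASSES, MutationRecord

logger = logging.getLogger("protact")

P_FLOOR = 1e-300


@dataclass
class AssociationRecord:
    """One fitted predictor -> response effect."""

    predictor_id: str
    response_id: str
    beta: float
    se: float
    t: float
    p: float
    fdr: float
    n_samples: int
    model_tag: str  # eq2 | eq3 | eq4 | self


@dataclass
class EnrichmentCurve:
    """Fisher enrichment of significant associations in a network, per cutoff."""

    rows: pd.DataFrame  # columns: cutoff, p, a, b, c, d


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _study_design(study: pd.Series) -> pd.DataFrame:
    """One-hot study indicators, first level as reference; singleton studies
    are merged into the reference with a warning."""
    counts = study.value_counts()
    singletons = counts[counts < 2].index
    if len(singletons):
        logger.warning("merging singleton studies into reference: %s",
                       list(singletons))
        study = study.where(~study.isin(singletons), counts.index[0])
    levels = sorted(study.dropna().unique())
    if len(levels) < 2:
        return pd.DataFrame(index=study.index)
    return pd.get_dummies(pd.Categorical(study, categories=levels),
                          drop_first=True, dtype=float
                          ).set_axis(study.index, axis=0)


def _ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Coefficients, standard errors and residual dof via normal equations."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    if dof <= 0:
        return beta, np.full(k, np.nan), 0
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    return beta, se, dof


def _coef_test(beta: float, se: float, dof: int) -> tuple[float, float]:
    if not np.isfinite(se) or se == 0 or dof <= 0:
        return np.nan, np.nan
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return t, max(p, P_FLOOR)


def fit_activity_mutation(
    activity: pd.DataFrame,
    mutation_matrix: FeatureMatrix,
    study_labels: pd.Series,
    min_gene_mut: int = 20,
    min_act_samples: int = 10,
    min_pair_mut: int = 5,
) -> list[AssociationRecord]:
    """Associate each mutated gene with each protein activity (eq3 design).

    Only genes mutated in more than `min_gene_mut` samples and proteins with
    activity in at least `min_act_samples` samples enter; a (gene, protein)
    pair is tested only if the gene is mutated in at least `min_pair_mut` of
    the pair's complete-case samples.  Self pairs (gene == protein) are
    tagged ``self``.  BH adjustment runs across all tested pairs.
    """
    mut = mutation_matrix.values
    samples = activity.columns.intersection(mut.columns)
    act = activity[samples]
    mut = mut[samples]
    study = study_labels.reindex(samples)

    gene_totals = mut.sum(axis=1)
    genes = [g for g in mut.index if gene_totals[g] > min_gene_mut]
    proteins = [p for p in act.index
                if act.loc[p].notna().sum() >= min_act_samples]
    logger.info("fit_activity_mutation: %d genes x %d proteins after filters",
                len(genes), len(proteins))

    records: list[AssociationRecord] = []
    study_dummies = _study_design(study)
    for protein in proteins:
        y_full = act.loc[protein]
        for gene in genes:
            x_full = mut.loc[gene]
            usable = y_full.notna() & x_full.notna()
            if not study_dummies.empty:
                usable &= study_dummies.notna().all(axis=1)
            n = int(usable.sum())
            x = x_full[usable]
            if x.sum() < min_pair_mut:
                continue
            y = y_full[usable].to_numpy(dtype=float)
            if np.nanstd(y) == 0:
                logger.info("skipping zero-variance response %s ~ %s",
                            protein, gene)
                continue
            cols = [np.ones(n)]
            if not study_dummies.empty:
                cols += [study_dummies.loc[usable, c].to_numpy(dtype=float)
                         for c in study_dummies.columns]
            cols.append(x.to_numpy(dtype=float))
            X = np.column_stack(cols)
            if n < X.shape[1] + 1:
                continue
            beta, se, dof = _ols_fit(y, X)
            t, p = _coef_test(beta[-1], se[-1], dof)
            if not np.isfinite(p):
                continue
            records.append(AssociationRecord(
                predictor_id=gene, response_id=protein,
                beta=float(beta[-1]), se=float(se[-1]), t=float(t), p=float(p),
                fdr=np.nan, n_samples=n,
                model_tag="self" if gene == protein else "eq3"))
    _apply_fdr(records)
    return records


def fit_kinase_tf(
    tf_activity: pd.DataFrame,
    kinase_activity: pd.DataFrame,
    study_labels: pd.Series,
    min_samples: int | None = None,
) -> list[AssociationRecord]:
    """Regress each TF activity on each kinase activity plus study (eq4)."""
    samples = tf_activity.columns.intersection(kinase_activity.columns)
    tf_act = tf_activity[samples]
    kin_act = kinase_activity[samples]
    study_dummies = _study_design(study_labels.reindex(samples))
    records: list[AssociationRecord] = []
    for tf in tf_act.index:
        y_full = tf_act.loc[tf]
        for kin in kin_act.index:
            x_full = kin_act.loc[kin]
            usable = y_full.notna() & x_full.notna()
            n = int(usable.sum())
            n_params = 2 + study_dummies.shape[1]
            if n < (min_samples or n_params + 2):
                continue
            y = y_full[usable].to_numpy(dtype=float)
            if np.nanstd(y) == 0:
                continue
            cols = [np.ones(n)]
            if not study_dummies.empty:
                cols += [study_dummies.loc[usable, c].to_numpy(dtype=float)
                         for c in study_dummies.columns]
            cols.append(x_full[usable].to_numpy(dtype=float))
            X = np.column_stack(cols)
            beta, se, dof = _ols_fit(y, X)
            t, p = _coef_test(beta[-1], se[-1], dof)
            if not np.isfinite(p):
                continue
            records.append(AssociationRecord(
                predictor_id=kin, response_id=tf,
                beta=float(beta[-1]), se=float(se[-1]), t=float(t), p=float(p),
                fdr=np.nan, n_samples=n, model_tag="eq4"))
    _apply_fdr(records)
    return records


def fit_recurrent_mutations(
    activity: pd.DataFrame,
    hotspot_indicators: pd.DataFrame,
) -> list[AssociationRecord]:
    """Jointly regress each activity row on binary hotspot indicators (eq2).

    `hotspot_indicators` is sample x hotspot (e.g. BRAF_V600E, KRAS_G12C,
    KRAS_G12D).  Collinear (duplicate) indicator columns are dropped with a
    warning.  BH adjustment runs per coefficient family (per hotspot).
    """
    indicators = hotspot_indicators.copy()
    keep: list[str] = []
    for col in indicators.columns:
        dup = any(indicators[col].equals(indicators[k]) for k in keep)
        if dup:
            logger.warning("dropping collinear hotspot indicator %r", col)
        elif indicators[col].nunique() < 2:
            logger.warning("dropping constant hotspot indicator %r", col)
        else:
            keep.append(col)
    indicators = indicators[keep]
    if indicators.empty:
        return []
    samples = activity.columns.intersection(indicators.index)
    records: list[AssociationRecord] = []
    for protein in activity.index:
        y_full = activity.loc[protein, samples]
        usable = y_full.notna() & indicators.loc[samples].notna().all(axis=1)
        n = int(usable.sum())
        if n < indicators.shape[1] + 2:
            continue
        y = y_full[usable].to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            continue
        X = np.column_stack(
            [np.ones(n)] + [indicators.loc[usable[usable].index, c]
                            .to_numpy(dtype=float) for c in indicators.columns])
        beta, se, dof = _ols_fit(y, X)
        for ci, col in enumerate(indicators.columns, start=1):
            t, p = _coef_test(beta[ci], se[ci], dof)
            if not np.isfinite(p):
                continue
            records.append(AssociationRecord(
                predictor_id=col, response_id=protein,
                beta=float(beta[ci]), se=float(se[ci]), t=float(t),
                p=float(p), fdr=np.nan, n_samples=n, model_tag="eq2"))
    # BH per coefficient family
    for col in indicators.columns:
        family = [r for r in records if r.predictor_id == col]
        if family:
            adj = bh_adjust([r.p for r in family])
            for r, q in zip(family, adj):
                r.fdr = float(q)
    return records


def _apply_fdr(records: list[AssociationRecord]) -> None:
    if records:
        adj = bh_adjust([r.p for r in records])
        for r, q in zip(records, adj):
            r.fdr = float(q)


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def string_enrichment(
    records: list[AssociationRecord],
    edges: EdgeList,
    min_score: int = 850,
    cutoffs: np.ndarray | None = None,
) -> EnrichmentCurve:
    """Fisher enrichment of significant association pairs among network edges.

    At each -log10 FDR cutoff the tested pairs split into a 2x2 table of
    (significant vs not) x (edge in the score-filtered network vs not); the
    one-sided (greater) Fisher p-value asks whether significant pairs are
    over-represented among network edges.
    """
    network = edges.filtered(min_score)
    if len(network) == 0:
        raise ValueError(f"no edges with combined_score >= {min_score}")
    if cutoffs is None:
        cutoffs = np.arange(0.0, 5.5, 0.5)
    in_net = np.array([(r.predictor_id, r.response_id) in network
                       for r in records])
    neglog_fdr = -np.log10(np.maximum([r.fdr for r in records], P_FLOOR))
    rows = []
    for cut in cutoffs:
        sig = neglog_fdr >= cut
        a = int(np.sum(sig & in_net))
        b = int(np.sum(sig & ~in_net))
        c = int(np.sum(~sig & in_net))
        d = int(np.sum(~sig & ~in_net))
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((float(cut), float(p), a, b, c, d))
    return EnrichmentCurve(pd.DataFrame(
        rows, columns=["cutoff", "p", "a", "b", "c", "d"]))


def diff_expression_groups(
    expression: pd.DataFrame,
    group_labels: pd.Series,
) -> pd.DataFrame:
    """Two-group differential expression on a linear (FPKM-like) scale.

    `group_labels` maps samples to ``low`` / ``high``.  Per feature the
    effect is log2(mean(low) / mean(high)) and significance comes from a
    Wilcoxon rank-sum test, BH-adjusted across features.  Features with a
    zero or missing denominator mean keep their p-value but no ratio.
    """
    groups = group_labels.dropna()
    low = groups.index[groups == "low"]
    high = groups.index[groups == "high"]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for feature in expression.index:
        lo = expression.loc[feature, low].dropna().to_numpy(dtype=float)
        hi = expression.loc[feature, high].dropna().to_numpy(dtype=float)
        if len(lo) < 2 or len(hi) < 2:
            continue
        mean_lo, mean_hi = lo.mean(), hi.mean()
        log2fc = (np.log2(mean_lo / mean_hi)
                  if mean_hi > 0 and mean_lo > 0 else np.nan)
        try:
            _, p = stats.mannwhitneyu(lo, hi, alternative="two-sided",
                                      method="auto")
        except ValueError:
            p = 1.0
        rows.append((feature, log2fc, float(p)))
    frame = pd.DataFrame(rows, columns=["feature", "log2fc", "p"]
                         ).set_index("feature")
    frame["fdr"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else []
    return frame


def split_by_activity_sign(activity: pd.Series,
                           noise_gate: float = 0.15) -> pd.Series:
    """Label samples ``high`` / ``low`` by activity sign, dropping samples
    within the noise gate (|activity| <= noise_gate)."""
    confident = activity[activity.abs() > noise_gate]
    return pd.Series(np.where(confident > 0, "high", "low"),
                     index=confident.index)


def mutation_abundance_effect(
    protein_matrix: FeatureMatrix,
    records: list[MutationRecord],
) -> pd.DataFrame:
    """Average protein-abundance shift in mutation carriers, per class group.

    Classes group as LoF (frameshift, nonsense, splice site, stop loss),
    inframe and missense; silent calls are ignored.  For each group the
    carrier (gene, sample) cells are compared with the non-carrier cells of
    the same genes by mean difference and a rank-sum test.
    """
    groups = {"lof": LOF_CLASSES, "inframe": {"inframe_indel"},
              "missense": {"missense"}}
    values = protein_matrix.values
    rows = []
    for name, classes in groups.items():
        carrier_cells: dict[str, set[str]] = {}
        for r in records:
            if r.mclass in classes and r.gene in values.index:
                carrier_cells.setdefault(r.gene, set()).add(r.sample_id)
        carrier_vals: list[float] = []
        other_vals: list[float] = []
        for gene, carrier_samples in carrier_cells.items():
            row = values.loc[gene]
            for s in values.columns:
                v = row[s]
                if pd.isna(v):
                    continue
                (carrier_vals if s in carrier_samples else other_vals).append(
                    float(v))
        if not carrier_vals or not other_vals:
            continue
        effect = float(np.mean(carrier_vals) - np.mean(other_vals))
        _, p = stats.mannwhitneyu(carrier_vals, other_vals,
                                  alternative="two-sided")
        rows.append((name, effect, float(p), len(carrier_vals)))
    return pd.DataFrame(rows, columns=["class_group", "effect", "p",
                                       "n_carrier_cells"]
                        ).set_index("class_group")
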