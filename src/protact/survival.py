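"""Activity-stratified survival analysis.

Samples are classified per regulator as inactive (AS < -1.75), active
(AS > 1.75) or neutral (in between, boundaries inclusive of neutral), and
the Kaplan-Meier curves of the populated strata are compared with log-rank
tests per protein and tissue.  A multivariate Cox proportional-hazards
model then treats the activity score as a continuous predictor adjusted
for age, gender and the binary genotype of recurrently mutated genes,
reporting the hazard ratio per activity unit with its Wald 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .associations import bh_adjust
from .core_io import FeatureMatrix

logger = logging.getLogger("protact")

STRATA = ("inactive", "neutral", "active")


@dataclass
class SurvivalFit:
    protein: str
    tissue: str
    model: str  # "logrank" | "cox"
    statistic: float
    p: float
    fdr: float
    hr: float | None = None
    hr_ci_low: float | None = None
    hr_ci_high: float | None = None
    n: int = 0
    n_events: int = 0
    n_strata: int = 0


def stratify_by_activity(activity: pd.DataFrame,
                         cutoff: float = 1.75) -> pd.DataFrame:
    """Long table of (sample, protein, stratum); strict inequalities, so a
    score exactly at +/-cutoff is neutral."""
    rows = []
    for protein in activity.index:
        scores = activity.loc[protein].dropna()
        strata = np.where(scores < -cutoff, "inactive",
                          np.where(scores > cutoff, "active", "neutral"))
        rows.extend(zip(scores.index, [protein] * len(scores), strata))
    return pd.DataFrame(rows, columns=["sample", "protein", "stratum"])


def _gates(protein_class: str, tf_min_deaths: int, tf_min_group: int,
           kin_min_deaths: int, kin_min_group: int):
    if protein_class == "tf":
        # more than `tf_min_group` samples active AND inactive, > deaths
        def gate(n_active: int, n_inactive: int, n_deaths: int) -> bool:
            return (n_deaths > tf_min_deaths and n_active > tf_min_group
                    and n_inactive > tf_min_group)
    elif protein_class == "kinase":
        # more than `kin_min_group` samples active OR inactive, > deaths
        def gate(n_active: int, n_inactive: int, n_deaths: int) -> bool:
            return (n_deaths > kin_min_deaths
                    and (n_active > kin_min_group or n_inactive > kin_min_group))
    else:
        raise ValueError("protein_class must be 'tf' or 'kinase'")
    return gate


def km_logrank(
    strata: pd.DataFrame,
    clinical: pd.DataFrame,
    protein_class: str,
    tf_min_deaths: int = 10,
    tf_min_group: int = 10,
    kinase_min_deaths: int = 5,
    kinase_min_group: int = 5,
    emit_curves: bool = False,
) -> tuple[list[SurvivalFit], dict[tuple[str, str], pd.DataFrame]]:
    """Log-rank tests across activity strata, per protein and tissue.

    Gate for TFs: more than `tf_min_deaths` deaths and more than
    `tf_min_group` samples active and inactive.  Gate for kinases: more
    than `kinase_min_deaths` deaths and more than `kinase_min_group`
    samples active or inactive.  The chi-square statistic spans all
    populated strata.  BH runs over all tested (protein, tissue) pairs.
    """
    gate = _gates(protein_class, tf_min_deaths, tf_min_group,
                  kinase_min_deaths, kinase_min_group)
    surv = clinical[["tissue", "os_time_days", "os_event"]].dropna()
    fits: list[SurvivalFit] = []
    curves: dict[tuple[str, str], pd.DataFrame] = {}
    for (protein, tissue), grp in _iter_protein_tissue(strata, surv):
        counts = grp["stratum"].value_counts()
        n_deaths = int(grp["os_event"].sum())
        populated = [s for s in STRATA if counts.get(s, 0) > 0]
        if len(populated) < 2:
            logger.info("skipping %s/%s: all samples in one stratum",
                        protein, tissue)
            continue
        if not gate(int(counts.get("active", 0)),
                    int(counts.get("inactive", 0)), n_deaths):
            continue
        result = multivariate_logrank_test(
            grp["os_time_days"], grp["stratum"], grp["os_event"])
        fits.append(SurvivalFit(
            protein=protein, tissue=tissue, model="logrank",
            statistic=float(result.test_statistic), p=float(result.p_value),
            fdr=np.nan, n=len(grp), n_events=n_deaths,
            n_strata=len(populated)))
        if emit_curves:
            curves[(protein, tissue)] = _km_table(grp)
    _apply_fdr(fits)
    return fits, curves


def _iter_protein_tissue(strata: pd.DataFrame, surv: pd.DataFrame):
    merged = strata.merge(surv, left_on="sample", right_index=True)
    for key, grp in merged.groupby(["protein", "tissue"], sort=True):
        yield key, grp


def _km_table(grp: pd.DataFrame) -> pd.DataFrame:
    """Step-function survival estimates per stratum."""
    pieces = []
    for stratum, sub in grp.groupby("stratum"):
        km = KaplanMeierFitter()
        km.fit(sub["os_time_days"], sub["os_event"], label=stratum)
        step = km.survival_function_.reset_index()
        step.columns = ["time", "survival"]
        step["stratum"] = stratum
        pieces.append(step)
    return pd.concat(pieces, ignore_index=True)


def cox_activity(
    activity: pd.DataFrame,
    clinical: pd.DataFrame,
    genotype_matrix: FeatureMatrix | None = None,
    min_mut_for_genotype: int = 100,
    per_tissue: bool = True,
) -> list[SurvivalFit]:
    """Cox proportional-hazards fit of survival on continuous activity.

    Covariates: age, gender and the genotype (binary) of every gene with at
    least `min_mut_for_genotype` mutated samples in the cohort.  Ties are
    handled with the Efron approximation (lifelines default).  Constant
    covariates are dropped with a warning; non-convergent fits are flagged
    and excluded from the BH family.
    """
    surv_cols = ["os_time_days", "os_event", "age", "gender"]
    base = clinical[[c for c in surv_cols + ["tissue"]
                     if c in clinical.columns]].copy()
    base = base.dropna(subset=["os_time_days", "os_event"])
    if "gender" in base.columns:
        base["gender"] = (base["gender"].astype(str)
                          .str.lower().eq("male").astype(float))
    genotype = None
    if genotype_matrix is not None:
        geno = genotype_matrix.values
        recurrent = geno.index[geno.sum(axis=1) >= min_mut_for_genotype]
        if len(recurrent):
            genotype = geno.loc[recurrent].T  # sample x gene
            logger.info("cox genotype panel: %d genes with >= %d mutations",
                        len(recurrent), min_mut_for_genotype)

    fits: list[SurvivalFit] = []
    tissues = (sorted(base["tissue"].dropna().unique())
               if per_tissue and "tissue" in base.columns else [None])
    for protein in activity.index:
        act_row = activity.loc[protein]
        for tissue in tissues:
            sub = base if tissue is None else base[base["tissue"] == tissue]
            frame = sub.drop(columns=["tissue"], errors="ignore").copy()
            frame["activity"] = act_row.reindex(frame.index)
            if genotype is not None:
                frame = frame.join(genotype.reindex(frame.index))
            frame = frame.dropna()
            if len(frame) < 10 or frame["os_event"].sum() < 2:
                continue
            if frame["activity"].std() == 0:
                continue
            for col in list(frame.columns):
                if col in ("os_time_days", "os_event", "activity"):
                    continue
                if frame[col].nunique() < 2:
                    logger.warning("dropping constant covariate %r for %s/%s",
                                   col, protein, tissue)
                    frame = frame.drop(columns=[col])
            cph = CoxPHFitter(penalizer=0.0)
            try:
                cph.fit(frame, duration_col="os_time_days",
                        event_col="os_event")
            except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                logger.warning("cox fit failed for %s/%s: %s", protein,
                               tissue, exc)
                fits.append(SurvivalFit(
                    protein=protein, tissue=str(tissue), model="cox",
                    statistic=np.nan, p=np.nan, fdr=np.nan,
                    n=len(frame), n_events=int(frame["os_event"].sum())))
                continue
            coef = float(cph.params_["activity"])
            se = float(cph.standard_errors_["activity"])
            z = coef / se if se > 0 else np.nan
            p = float(cph.summary.loc["activity", "p"])
            fits.append(SurvivalFit(
                protein=protein, tissue=str(tissue), model="cox",
                statistic=float(z), p=p, fdr=np.nan,
                hr=float(np.exp(coef)),
                hr_ci_low=float(np.exp(coef - 1.959963984540054 * se)),
                hr_ci_high=float(np.exp(coef + 1.959963984540054 * se)),
                n=len(frame), n_events=int(frame["os_event"].sum())))
    _apply_fdr(fits)
    return fits


def _apply_fdr(fits: list[SurvivalFit]) -> None:
    tested = [f for f in fits if np.isfinite(f.p)]
    if tested:
        adj = bh_adjust([f.p for f in tested])
        for f, q in zip(tested, adj):
            f.fdr = float(q)


def fits_to_frame(fits: list[SurvivalFit]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in fits])
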