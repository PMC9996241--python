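"""File-level orchestration of the analysis stages.

Each stage reads its inputs from and writes its outputs to a working
directory with a fixed layout, so stages can be run independently from the
command line or chained end-to-end with :func:`run_all`.  All outputs are
TSV with a fixed float format, making repeated runs with the same seed
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    activity as activity_mod,
    associations as assoc_mod,
    benchmark as bench_mod,
    clustering as cluster_mod,
    landscape as landscape_mod,
    preprocess as prep_mod,
    survival as surv_mod,
)
from .core_io import (
    Config,
    FeatureMatrix,
    PhosphositeKey,
    read_clinical,
    read_edges,
    read_fasta,
    read_gold_standard,
    read_matrix,
    read_mutations,
    read_prior,
    write_clinical,
    write_edges,
    write_fasta,
    write_gold_standard,
    write_kinase_prior,
    write_matrix,
    write_mutations,
    write_regulons,
)
from .synthesize import SimConfig, simulate

logger = logging.getLogger("protact")

FLOAT_FMT = "%.10g"


def _write_frame(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT,
                 index=index)


def stage_simulate(outdir: Path, sim_config: SimConfig) -> None:
    """Generate the synthetic cohort and priors and write every fixture."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate(sim_config)
    cohort, priors = sim.cohort, sim.priors
    write_matrix(cohort.mrna, outdir / "mrna.tsv")
    write_matrix(cohort.protein, outdir / "protein.tsv")
    write_matrix(cohort.phospho, outdir / "phospho.tsv")
    write_matrix(cohort.cnv, outdir / "cnv.tsv")
    write_mutations(cohort.mutations, outdir / "mutations.tsv")
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    write_kinase_prior(priors.network.kinase_targets,
                       outdir / "kinase_prior.tsv")
    write_regulons(priors.network.regulons, outdir / "regulons.tsv")
    write_edges(priors.edges, outdir / "edges.tsv")
    write_gold_standard(priors.gold_standard, outdir / "gold_standard.tsv")
    write_fasta(priors.fasta, outdir / "sequences.fasta")
    truth = cohort.truth
    write_matrix(FeatureMatrix(truth.true_activity, "activity"),
                 outdir / "truth_activity.tsv")
    _write_frame(pd.DataFrame(truth.true_effects,
                              columns=["gene", "protein", "beta2"]),
                 outdir / "truth_effects.tsv")
    _write_frame(pd.DataFrame(truth.true_hazards,
                              columns=["protein", "log_hr"]),
                 outdir / "truth_hazards.tsv")
    _write_frame(truth.cluster_labels.rename("block").reset_index()
                 .rename(columns={"index": "sample_id"}),
                 outdir / "truth_clusters.tsv")


def _phospho_site_map(phospho: FeatureMatrix) -> dict[str, str]:
    """site row id -> host protein id (row ids are PROTEIN_R<pos>)."""
    mapping = {}
    for rid in phospho.values.index:
        protein, _, _ = rid.rpartition("_")
        mapping[rid] = protein
    return mapping


def stage_preprocess(outdir: Path, config: Config) -> None:
    """Outlier removal, quantile normalisation, residualisation, mutation
    matrix and sequence validation."""
    phospho = read_matrix(outdir / "phospho.tsv", "phospho")
    protein = read_matrix(outdir / "protein.tsv", "protein")
    mrna = read_matrix(outdir / "mrna.tsv", "mrna")
    clinical = read_clinical(outdir / "clinical.tsv")
    mutations = read_mutations(outdir / "mutations.tsv")
    fasta = read_fasta(outdir / "sequences.fasta")

    phospho, dropped = prep_mod.remove_outlier_samples(
        phospho, config.outlier_median_threshold)
    _write_frame(pd.DataFrame({"sample_id": dropped}),
                 outdir / "dropped_outlier_samples.tsv")
    phospho = prep_mod.quantile_normalize(phospho)

    study = clinical["study"]
    covariates = clinical[["age", "gender"]]
    resid = prep_mod.regress_out(
        phospho, predictor=protein, row_map=_phospho_site_map(phospho),
        covariates=covariates)
    write_matrix(resid.matrix, outdir / "phospho_residual.tsv")
    _write_frame(pd.DataFrame({"row_id": resid.passthrough_rows}),
                 outdir / "phospho_passthrough_rows.tsv")

    batch = pd.DataFrame({"study": study})
    protein_bf = prep_mod.regress_out(protein, covariates=batch)
    mrna_bf = prep_mod.regress_out(mrna, covariates=batch)
    write_matrix(protein_bf.matrix, outdir / "protein_batchfree.tsv")
    write_matrix(mrna_bf.matrix, outdir / "mrna_batchfree.tsv")

    kept_muts, report = prep_mod.validate_against_sequences(mutations, fasta)
    _write_frame(report, outdir / "mutation_validation_report.tsv")
    write_mutations(kept_muts, outdir / "mutations_validated.tsv")
    mut_matrix = prep_mod.build_mutation_matrix(
        kept_muts, samples=list(clinical.index))
    write_matrix(mut_matrix, outdir / "mutation_matrix.tsv")


def stage_activity(outdir: Path, config: Config) -> None:
    """Kinase z-test and TF regulon enrichment on the processed matrices."""
    phospho = read_matrix(outdir / "phospho_residual.tsv", "phospho")
    mrna = read_matrix(outdir / "mrna_batchfree.tsv", "mrna")
    prior = read_prior(outdir / "kinase_prior.tsv", outdir / "regulons.tsv")
    kin = activity_mod.kinase_activity_ztest(
        phospho, prior, min_targets=config.min_targets)
    tf = activity_mod.tf_activity_nes(mrna, prior,
                                      min_regulon=config.min_regulon)
    write_matrix(FeatureMatrix(kin.values, "activity"),
                 outdir / "kinase_activity.tsv")
    write_matrix(FeatureMatrix(kin.n_targets.astype(float), "activity"),
                 outdir / "kinase_activity_ntargets.tsv")
    write_matrix(FeatureMatrix(tf.values, "activity"),
                 outdir / "tf_activity.tsv")
    write_matrix(FeatureMatrix(tf.n_targets.astype(float), "activity"),
                 outdir / "tf_activity_ntargets.tsv")


def stage_benchmark(outdir: Path, config: Config, seed: int) -> None:
    kin = read_matrix(outdir / "kinase_activity.tsv", "activity")
    gold = read_gold_standard(outdir / "gold_standard.tsv")
    result = bench_mod.evaluate_prior(
        kin.values, gold, n_resamples=config.n_resamples, seed=seed,
        prior_source="simulated")
    _write_frame(pd.DataFrame({
        "prior_source": [result.prior_source],
        "mean_auroc": [result.mean_auroc],
        "n_positives": [result.n_positives],
        "n_negatives_per_set": [result.n_negatives_per_set],
        "n_resamples": [len(result.aurocs)],
    }), outdir / "benchmark.tsv")
    _write_frame(pd.DataFrame({"auroc": result.aurocs}),
                 outdir / "benchmark_resamples.tsv")


def stage_associate(outdir: Path, config: Config) -> None:
    kin = read_matrix(outdir / "kinase_activity.tsv", "activity").values
    tf = read_matrix(outdir / "tf_activity.tsv", "activity").values
    mut_matrix = read_matrix(outdir / "mutation_matrix.tsv", "protein")
    clinical = read_clinical(outdir / "clinical.tsv")
    edges = read_edges(outdir / "edges.tsv")
    study = clinical["study"]

    for name, act in (("kinase", kin), ("tf", tf)):
        records = assoc_mod.fit_activity_mutation(
            act, mut_matrix, study,
            min_gene_mut=config.min_gene_mutations,
            min_act_samples=config.min_activity_samples,
            min_pair_mut=config.min_pair_mutations)
        _write_frame(assoc_mod.records_to_frame(records),
                     outdir / f"associations_mut_{name}.tsv")
        if records:
            curve = assoc_mod.string_enrichment(
                records, edges, min_score=config.string_min_score)
            _write_frame(curve.rows, outdir / f"string_enrichment_{name}.tsv")

    records = assoc_mod.fit_kinase_tf(tf, kin, study)
    _write_frame(assoc_mod.records_to_frame(records),
                 outdir / "associations_kinase_tf.tsv")


def stage_landscape(outdir: Path, config: Config,
                    perturb_activity: pd.DataFrame | None = None) -> None:
    kin = read_matrix(outdir / "kinase_activity.tsv", "activity")
    kin_targets = read_matrix(outdir / "kinase_activity_ntargets.tsv",
                              "activity")
    prior = read_prior(outdir / "kinase_prior.tsv")
    phospho = read_matrix(outdir / "phospho_residual.tsv", "phospho")
    protein = read_matrix(outdir / "protein_batchfree.tsv", "protein")
    mrna = read_matrix(outdir / "mrna_batchfree.tsv", "mrna")
    cnv = read_matrix(outdir / "cnv.tsv", "cnv")

    act = activity_mod.ActivityMatrix(kin.values, kin_targets.values,
                                      "signed_log10p")
    # the phospho layer summary uses sites residing on the kinase itself
    site_map: dict[str, list[str]] = {}
    for rid, host in _phospho_site_map(phospho).items():
        site_map.setdefault(host, []).append(rid)
    corr = landscape_mod.correlate_activity_layers(
        act, {"cnv": cnv, "rna": mrna, "protein": protein,
              "phospho": phospho},
        n_min=config.layer_corr_min_n, site_map=site_map)
    _write_frame(corr, outdir / "layer_correlations.tsv")

    kept, cluster_map = landscape_mod.reduce_redundant_kinases(
        prior.substrate_sets(), height=config.redundancy_height)
    _write_frame(pd.DataFrame(
        sorted(cluster_map.items()), columns=["kinase", "cluster"]),
        outdir / "kinase_redundancy_clusters.tsv")
    variable = landscape_mod.select_variable_kinases(
        kin.values.loc[[k for k in kept if k in kin.values.index]])
    _write_frame(pd.DataFrame({"kinase": variable}),
                 outdir / "variable_kinases.tsv")

    if perturb_activity is not None:
        calls = landscape_mod.tumour_vs_perturbation(
            kin.values, perturb_activity,
            cutoff=config.activity_cutoff, z_thresh=config.specificity_z)
        _write_frame(pd.DataFrame([c.__dict__ for c in calls]),
                     outdir / "tumour_vs_perturbation.tsv")


def stage_survival(outdir: Path, config: Config) -> None:
    clinical = read_clinical(outdir / "clinical.tsv")
    mut_matrix = read_matrix(outdir / "mutation_matrix.tsv", "protein")
    for name, gates in (("tf", "tf"), ("kinase", "kinase")):
        act = read_matrix(outdir / f"{name}_activity.tsv", "activity").values
        strata = surv_mod.stratify_by_activity(act, config.activity_cutoff)
        fits, _ = surv_mod.km_logrank(
            strata, clinical, gates,
            tf_min_deaths=config.tf_survival_min_deaths,
            tf_min_group=config.tf_survival_min_group,
            kinase_min_deaths=config.kinase_survival_min_deaths,
            kinase_min_group=config.kinase_survival_min_group)
        _write_frame(surv_mod.fits_to_frame(fits),
                     outdir / f"survival_logrank_{name}.tsv")
        cox = surv_mod.cox_activity(
            act, clinical, genotype_matrix=mut_matrix,
            min_mut_for_genotype=config.min_mut_for_genotype)
        _write_frame(surv_mod.fits_to_frame(cox),
                     outdir / f"survival_cox_{name}.tsv")


def stage_cluster(outdir: Path, config: Config) -> None:
    kin = read_matrix(outdir / "kinase_activity.tsv", "activity").values
    tf = read_matrix(outdir / "tf_activity.tsv", "activity").values
    clinical = read_clinical(outdir / "clinical.tsv")
    combined = pd.concat([kin, tf])
    corr = cluster_mod.sample_cross_correlation(combined)
    result = cluster_mod.cluster_samples(corr, k=config.n_clusters)
    _write_frame(result.labels.rename("cluster").reset_index()
                 .rename(columns={"index": "sample_id"}),
                 outdir / "sample_clusters.tsv")
    scores = cluster_mod.cluster_activity_scores(
        combined, result.labels, dereg_threshold=config.dereg_threshold)
    out = scores.scores.copy()
    out.index.name = "protein"
    out.to_csv(outdir / "cluster_activity_scores.tsv", sep="\t", na_rep="NA",
               float_format=FLOAT_FMT)
    over = cluster_mod.clinical_overrepresentation(
        result.labels, clinical,
        min_level_count=config.min_level_count,
        bmi_cutoff=config.bmi_cutoff, age_cutoff=config.age_cutoff)
    _write_frame(over, outdir / "clinical_overrepresentation.tsv")


def run_all(outdir: Path, config: Config, sim_config: SimConfig,
            seed: int) -> None:
    """Chain every stage on a fresh synthetic cohort.

    A second, smaller cohort (seed offset by 1) stands in for the acute
    perturbation compendium in the tumour-vs-perturbation comparison.
    """
    outdir = Path(outdir)
    stage_simulate(outdir, sim_config)
    stage_preprocess(outdir, config)
    stage_activity(outdir, config)
    stage_benchmark(outdir, config, seed)
    stage_associate(outdir, config)

    import dataclasses

    perturb_cfg = dataclasses.replace(
        sim_config, n_samples=max(60, sim_config.n_samples // 4),
        seed=(sim_config.seed + 1) % (2 ** 31))
    perturb = simulate(perturb_cfg)
    perturb_resid = prep_mod.regress_out(
        prep_mod.quantile_normalize(perturb.cohort.phospho),
        predictor=perturb.cohort.protein,
        row_map=_phospho_site_map(perturb.cohort.phospho))
    perturb_act = activity_mod.kinase_activity_ztest(
        perturb_resid.matrix, perturb.priors.network,
        min_targets=config.min_targets)
    stage_landscape(outdir, config, perturb_activity=perturb_act.values)

    stage_survival(outdir, config)
    stage_cluster(outdir, config)
    logger.info("run_all complete in %s", outdir)
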