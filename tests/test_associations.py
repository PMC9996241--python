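"""Association models, multiple testing and enrichment exactness."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from protact.associations import (
    bh_adjust,
    diff_expression_groups,
    fit_activity_mutation,
    fit_kinase_tf,
    fit_recurrent_mutations,
    mutation_abundance_effect,
    split_by_activity_sign,
    string_enrichment,
    AssociationRecord,
)
from protact.core_io import EdgeList, MutationRecord
from protact.preprocess import build_mutation_matrix
from protact.synthesize import simulate_activity_given_mutations

from conftest import make_matrix


def brute_force_bh(p):
    """Step-up definition: q(i) = min_{j>=i} p(j) * m / j on sorted p."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBH:
    def test_frozen_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_all_one_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self, rng):
        # many vectors of varying length, ~10,000 p-values in total
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 100)))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestActivityMutationModel:
    def test_planted_beta_recovered(self):
        act, mut, study = simulate_activity_given_mutations(
            n_samples=200, beta2=1.5, noise_sd=0.5, seed=42)
        activity = pd.DataFrame([act], index=["PROT"])
        mm = make_matrix([mut.to_numpy(dtype=float)], layer="protein",
                         features=["GENE"], samples=list(mut.index))
        records = fit_activity_mutation(activity, mm, study,
                                        min_gene_mut=20, min_act_samples=10,
                                        min_pair_mut=5)
        assert len(records) == 1
        assert 1.3 <= records[0].beta <= 1.7
        assert records[0].fdr >= records[0].p

    def test_pair_mutation_filter(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(60)]
        study = pd.Series(["a"] * 30 + ["b"] * 30, index=samples)
        activity = pd.DataFrame([rng.normal(size=60)], index=["P"],
                                columns=samples)
        mut = np.zeros(60)
        mut[:30] = 1.0  # gene mutated in >20 samples overall
        mm = make_matrix([mut], layer="protein", features=["G"],
                         samples=samples)
        # restrict activity to samples where the gene has only 4 mutations
        activity.loc["P", samples[4:30]] = np.nan
        records = fit_activity_mutation(activity, mm, study,
                                        min_gene_mut=20, min_act_samples=10,
                                        min_pair_mut=5)
        assert records == []

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(7)
        n, n_pairs = 120, 200
        samples = [f"s{i}" for i in range(n)]
        study = pd.Series(rng.choice(["a", "b", "c"], size=n), index=samples)
        activity = pd.DataFrame(rng.normal(size=(n_pairs, n)),
                                index=[f"P{i}" for i in range(n_pairs)],
                                columns=samples)
        mut = (rng.random((1, n)) < 0.3).astype(float)
        mm = make_matrix(mut, layer="protein", features=["G"],
                         samples=samples)
        records = fit_activity_mutation(activity, mm, study,
                                        min_gene_mut=20, min_act_samples=10,
                                        min_pair_mut=5)
        assert len(records) == n_pairs
        frac = np.mean([r.p < 0.05 for r in records])
        assert 0.03 <= frac <= 0.07

    def test_self_pair_tagged(self):
        act, mut, study = simulate_activity_given_mutations(
            n_samples=100, beta2=1.0, seed=5)
        activity = pd.DataFrame([act], index=["GENE"])
        mm = make_matrix([mut.to_numpy(dtype=float)], layer="protein",
                         features=["GENE"], samples=list(mut.index))
        records = fit_activity_mutation(activity, mm, study,
                                        min_gene_mut=10, min_act_samples=10,
                                        min_pair_mut=5)
        assert records[0].model_tag == "self"


class TestKinaseTFModel:
    def test_identity_relation_hits_floor(self):
        rng = np.random.default_rng(1)
        n = 80
        samples = [f"s{i}" for i in range(n)]
        study = pd.Series(["a"] * 40 + ["b"] * 40, index=samples)
        kin = pd.DataFrame([rng.normal(size=n)], index=["K"], columns=samples)
        tf = pd.DataFrame(kin.to_numpy(), index=["T"], columns=samples)
        rec = fit_kinase_tf(tf, kin, study)[0]
        assert rec.beta == pytest.approx(1.0, abs=1e-10)
        assert rec.p <= 1e-50

    def test_independent_activities_small_beta(self):
        rng = np.random.default_rng(2)
        n = 300
        samples = [f"s{i}" for i in range(n)]
        study = pd.Series(rng.choice(["a", "b"], size=n), index=samples)
        kin = pd.DataFrame([rng.normal(size=n)], index=["K"], columns=samples)
        tf = pd.DataFrame([rng.normal(size=n)], index=["T"], columns=samples)
        rec = fit_kinase_tf(tf, kin, study)[0]
        assert abs(rec.beta) < 0.2

    def test_planted_slope_with_study_offsets(self):
        rng = np.random.default_rng(3)
        n = 400
        samples = [f"s{i}" for i in range(n)]
        study = pd.Series(np.repeat(["a", "b"], n // 2), index=samples)
        offsets = np.where(study == "a", 1.0, -1.0)
        k = rng.normal(size=n)
        t = 0.5 * k + offsets + rng.normal(scale=0.5, size=n)
        kin = pd.DataFrame([k], index=["K"], columns=samples)
        tf = pd.DataFrame([t], index=["T"], columns=samples)
        rec = fit_kinase_tf(tf, kin, study)[0]
        assert rec.beta == pytest.approx(0.5, abs=0.15)

    def test_ols_agrees_with_normal_equations(self, rng):
        """The reported beta/se match an explicit normal-equations solve."""
        n = 40
        samples = [f"s{i}" for i in range(n)]
        study = pd.Series(np.repeat(["a", "b"], n // 2), index=samples)
        k = rng.normal(size=n)
        t = rng.normal(size=n)
        rec = fit_kinase_tf(pd.DataFrame([t], index=["T"], columns=samples),
                            pd.DataFrame([k], index=["K"], columns=samples),
                            study)[0]
        X = np.column_stack([np.ones(n), (study == "b").astype(float), k])
        beta = np.linalg.solve(X.T @ X, X.T @ t)
        resid = t - X @ beta
        sigma2 = resid @ resid / (n - 3)
        se = math.sqrt(sigma2 * np.linalg.inv(X.T @ X)[2, 2])
        assert rec.beta == pytest.approx(beta[2], abs=1e-8)
        assert rec.se == pytest.approx(se, abs=1e-8)


class TestRecurrentMutations:
    def _activity(self, rng, values):
        return pd.DataFrame([values], index=["P"],
                            columns=[f"s{i}" for i in range(len(values))])

    def test_null_betas_near_zero(self, rng):
        n = 300
        y = rng.normal(size=n)
        hotspots = pd.DataFrame(
            (rng.random((n, 3)) < 0.2).astype(float),
            index=[f"s{i}" for i in range(n)],
            columns=["BRAF_V600E", "KRAS_G12C", "KRAS_G12D"])
        records = fit_recurrent_mutations(self._activity(rng, y), hotspots)
        assert len(records) == 3
        assert all(abs(r.beta) < 0.3 for r in records)

    def test_single_planted_hotspot(self, rng):
        n = 300
        hotspots = pd.DataFrame(
            (rng.random((n, 3)) < 0.2).astype(float),
            index=[f"s{i}" for i in range(n)],
            columns=["H1", "H2", "H3"])
        y = 2.0 * hotspots["H1"].to_numpy() + rng.normal(scale=0.5, size=n)
        records = {r.predictor_id: r
                   for r in fit_recurrent_mutations(self._activity(rng, y),
                                                    hotspots)}
        assert records["H1"].beta == pytest.approx(2.0, abs=0.25)
        assert abs(records["H2"].beta) < 0.25
        assert abs(records["H3"].beta) < 0.25

    def test_duplicate_indicator_dropped(self, rng):
        n = 50
        col = (rng.random(n) < 0.3).astype(float)
        hotspots = pd.DataFrame({"A": col, "B": col},
                                index=[f"s{i}" for i in range(n)])
        records = fit_recurrent_mutations(
            self._activity(rng, rng.normal(size=n)), hotspots)
        assert {r.predictor_id for r in records} == {"A"}


class TestFisherEnrichment:
    def _records(self, pairs, fdrs):
        return [AssociationRecord(a, b, 0.0, 0.0, 0.0, f, f, 10, "eq3")
                for (a, b), f in zip(pairs, fdrs)]

    def test_three_by_three_exact(self):
        # table [[3,0],[0,3]]: one-sided p = C(3,3)C(3,0)/C(6,3) = 1/20
        edges = EdgeList({(f"A{i}", f"B{i}"): 900 for i in range(3)})
        pairs = [(f"A{i}", f"B{i}") for i in range(3)] + \
                [(f"X{i}", f"Y{i}") for i in range(3)]
        fdrs = [1e-6] * 3 + [0.9] * 3
        curve = string_enrichment(self._records(pairs, fdrs), edges,
                                  cutoffs=np.array([2.0]))
        row = curve.rows.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (3, 0, 0, 3)
        assert row.p == pytest.approx(0.05, abs=1e-12)

    def test_empty_significant_set_p_one(self):
        edges = EdgeList({("A", "B"): 900})
        curve = string_enrichment(self._records([("A", "B")], [0.9]), edges,
                                  cutoffs=np.array([5.0]))
        assert curve.rows.iloc[0].p == 1.0

    def test_margin_sum_constant_across_cutoffs(self, rng):
        edges = EdgeList({(f"A{i}", f"B{i}"): 900 for i in range(5)})
        pairs = ([(f"A{i}", f"B{i}") for i in range(5)]
                 + [(f"U{i}", f"V{i}") for i in range(15)])
        fdrs = rng.random(20)
        curve = string_enrichment(self._records(pairs, fdrs), edges)
        totals = curve.rows[["a", "b", "c", "d"]].sum(axis=1)
        assert (totals == 20).all()

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            string_enrichment(self._records([("A", "B")], [0.1]),
                              EdgeList({("A", "B"): 400}), min_score=850)

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        """One-sided Fisher p equals the hypergeometric tail for all
        2x2 tables with total <= 30."""
        for total in (8, 12, 20, 30):
            for _ in range(20):
                a, b, c = rng.multinomial(total, [0.25, 0.25, 0.25])[:3]
                d = total - a - b - c
                if d < 0:
                    continue
                _, p = stats.fisher_exact([[a, b], [c, d]],
                                          alternative="greater")
                # enumeration: X ~ Hypergeom(N=total, K=a+c, n=a+b), P(X >= a)
                enum = sum(
                    math.comb(a + c, x) * math.comb(b + d, a + b - x)
                    for x in range(a, min(a + c, a + b) + 1)
                ) / math.comb(total, a + b)
                assert p == pytest.approx(enum, abs=1e-12)


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        expr = pd.DataFrame([[4.0, 4.0, 4.0, 4.0]], index=["g"],
                            columns=["a", "b", "c", "d"])
        labels = pd.Series(["low", "low", "high", "high"],
                           index=["a", "b", "c", "d"])
        out = diff_expression_groups(expr, labels)
        assert out.loc["g", "log2fc"] == 0.0
        assert out.loc["g", "p"] == 1.0

    def test_frozen_ratio(self):
        expr = pd.DataFrame([[8.0, 8.0, 2.0, 2.0]], index=["g"],
                            columns=["a", "b", "c", "d"])
        labels = pd.Series(["low", "low", "high", "high"],
                           index=["a", "b", "c", "d"])
        out = diff_expression_groups(expr, labels)
        assert out.loc["g", "log2fc"] == pytest.approx(2.0)

    def test_two_vs_two_separation_matches_enumeration(self):
        # complete separation of 2 vs 2: exact two-sided rank-sum p = 2/6
        expr = pd.DataFrame([[10.0, 9.0, 1.0, 2.0]], index=["g"],
                            columns=["a", "b", "c", "d"])
        labels = pd.Series(["low", "low", "high", "high"],
                           index=["a", "b", "c", "d"])
        out = diff_expression_groups(expr, labels)
        assert out.loc["g", "p"] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_zero_denominator_flagged(self):
        expr = pd.DataFrame([[5.0, 6.0, 0.0, 0.0]], index=["g"],
                            columns=["a", "b", "c", "d"])
        labels = pd.Series(["low", "low", "high", "high"],
                           index=["a", "b", "c", "d"])
        out = diff_expression_groups(expr, labels)
        assert np.isnan(out.loc["g", "log2fc"])
        assert np.isfinite(out.loc["g", "p"])

    def test_activity_sign_split_respects_noise_gate(self):
        act = pd.Series([0.4, -0.3, 0.1, -0.05],
                        index=["a", "b", "c", "d"])
        labels = split_by_activity_sign(act, noise_gate=0.15)
        assert labels.to_dict() == {"a": "high", "b": "low"}


class TestMutationAbundanceEffect:
    def test_planted_lof_shift_recovered(self, rng):
        n, n_genes = 60, 30
        samples = [f"s{i}" for i in range(n)]
        genes = [f"G{i}" for i in range(n_genes)]
        values = rng.normal(scale=0.3, size=(n_genes, n))
        records = []
        for gi in range(n_genes):
            for si in rng.choice(n, size=6, replace=False):
                values[gi, si] -= 0.5
                records.append(MutationRecord(samples[si], genes[gi],
                                              "frameshift_indel", 1, "M", "V"))
        table = mutation_abundance_effect(
            make_matrix(values, layer="protein", features=genes,
                        samples=samples), records)
        se = 0.3 * math.sqrt(1 / 180 + 1 / (n * n_genes - 180))
        assert table.loc["lof", "effect"] == pytest.approx(-0.5, abs=3 * se)
        assert table.loc["lof", "p"] < 1e-6

    def test_no_mutations_empty(self, rng):
        table = mutation_abundance_effect(
            make_matrix(rng.normal(size=(3, 4)), layer="protein"), [])
        assert table.empty

    def test_silent_only_empty(self, rng):
        records = [MutationRecord("s0", "f0", "silent", 1, "M", "M")]
        table = mutation_abundance_effect(
            make_matrix(rng.normal(size=(3, 4)), layer="protein"), records)
        assert table.empty


def test_mutation_matrix_feeds_association_model(small_sim):
    """End-to-end: planted mutation effects surface as top associations."""
    cohort = small_sim.cohort
    mm = build_mutation_matrix([r for r in cohort.mutations],
                               samples=list(cohort.clinical.index))
    truth = cohort.truth.true_activity
    # response = block activity plus the planted mutation effect in carriers
    rng = np.random.default_rng(0)
    activity = truth * 2.0 + rng.normal(scale=0.3, size=truth.shape)
    for gene, protein, beta in cohort.truth.true_effects:
        carriers = sorted({r.sample_id for r in cohort.mutations
                           if r.gene == gene})
        activity.loc[protein, carriers] += beta
    records = fit_activity_mutation(activity, mm, cohort.clinical["study"],
                                    min_gene_mut=5, min_act_samples=10,
                                    min_pair_mut=3)
    by_pair = {(r.predictor_id, r.response_id): r for r in records}
    planted = [(g, p) for g, p, _ in cohort.truth.true_effects
               if (g, p) in by_pair]
    assert planted, "planted pairs must be testable"
    planted_p = [by_pair[k].p for k in planted]
    assert np.median(planted_p) < 0.01
    betas = [by_pair[(g, p)].beta for g, p, _ in cohort.truth.true_effects
             if (g, p) in by_pair]
    assert np.mean(betas) == pytest.approx(1.0, abs=0.4)
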