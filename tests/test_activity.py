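"""Kinase z-test and TF enrichment scoring against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protact.activity import (
    ActivityMatrix,
    kinase_activity_ztest,
    regulation_percentage,
    select_regulated_proteins,
    tf_activity_nes,
)
from protact.core_io import PhosphositeKey, PriorNetwork

from conftest import make_matrix


def erf_oracle(x, mu, sigma, n):
    """High-precision z-test oracle built on the error function only."""
    z = (x - mu) / (sigma / math.sqrt(n))
    p = max(math.erfc(abs(z) / math.sqrt(2.0)), 1e-300)
    return z, p, math.copysign(-math.log10(p), z) if z != 0 else 0.0


def build_prior(target_ids):
    sites = {}
    for sid in target_ids:
        protein, _, rest = sid.rpartition("_")
        sites[PhosphositeKey(protein, int(rest[1:]), rest[0])] = "database"
    return PriorNetwork(kinase_targets={"KIN": sites})


def matrix_with_targets(target_values, background_values):
    """One sample: target sites plus background sites."""
    target_ids = [f"T{i}_S1" for i in range(len(target_values))]
    bg_ids = [f"B{i}_S1" for i in range(len(background_values))]
    values = pd.DataFrame(
        {"s0": list(target_values) + list(background_values)},
        index=target_ids + bg_ids)
    return make_matrix(values.to_numpy(), features=list(values.index),
                       samples=["s0"]), build_prior(target_ids)


class TestKinaseZTest:
    def test_frozen_example_three_targets(self):
        """Targets {1,1,1} against a background with mu=0, sigma=1."""
        # 40 background values with exact mean 0 and SD 1 (ddof=1)
        bg = np.concatenate([np.ones(20), -np.ones(20)])
        bg = bg / bg.std(ddof=1)
        matrix, prior = matrix_with_targets([1.0, 1.0, 1.0], bg)
        result, details = kinase_activity_ztest(
            matrix, prior, min_targets=3,
            exclude_targets_from_background=True, return_details=True)
        d = details[0]
        assert d.z == pytest.approx(math.sqrt(3.0), abs=1e-9)
        assert d.p == pytest.approx(0.0832645167, abs=1e-6)
        assert d.activity == pytest.approx(1.0795400346, abs=1e-6)

    def test_frozen_example_negative_z(self):
        """Mean -0.5, mu=0, sigma=2, N=16 -> z=-1, p=0.31731, AS=-0.49852."""
        bg = np.concatenate([np.ones(30), -np.ones(30)])
        bg = 2.0 * bg / bg.std(ddof=1)
        matrix, prior = matrix_with_targets([-0.5] * 16, bg)
        _, details = kinase_activity_ztest(
            matrix, prior, min_targets=3,
            exclude_targets_from_background=True, return_details=True)
        d = details[0]
        assert d.z == pytest.approx(-1.0, abs=1e-9)
        assert d.p == pytest.approx(0.3173105079, abs=1e-6)
        assert d.activity == pytest.approx(-0.4985155458, abs=1e-6)

    def test_x_equal_mu_gives_zero_activity(self):
        bg = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        matrix, prior = matrix_with_targets([0.0, 0.0, 0.0], bg)
        _, details = kinase_activity_ztest(
            matrix, prior, min_targets=3,
            exclude_targets_from_background=True, return_details=True)
        assert details[0].z == pytest.approx(0.0, abs=1e-12)
        assert details[0].p == pytest.approx(1.0)
        assert details[0].activity == pytest.approx(0.0)

    def test_oracle_equivalence_on_random_instances(self, rng):
        """z, p and signed -log10 p match the erf oracle to 1e-9."""
        n_sites, n_samples = 120, 25
        values = rng.normal(size=(n_sites, n_samples))
        values[rng.random(values.shape) < 0.1] = np.nan
        ids = [f"P{i}_S1" for i in range(n_sites)]
        matrix = make_matrix(values, features=ids)
        prior = PriorNetwork(kinase_targets={
            f"K{k}": {PhosphositeKey(f"P{i}", 1, "S"): "database"
                      for i in rng.choice(n_sites, size=8, replace=False)}
            for k in range(40)
        })
        _, details = kinase_activity_ztest(matrix, prior, min_targets=3,
                                           return_details=True)
        assert len(details) >= 1000
        for d in details:
            col = values[:, matrix.sample_ids.index(d.sample)]
            obs = col[~np.isnan(col)]
            sites = prior.kinase_targets[d.kinase]
            rows = [ids.index(str(s)) for s in sites]
            tvals = values[rows, matrix.sample_ids.index(d.sample)]
            tvals = tvals[~np.isnan(tvals)]
            z, p, act = erf_oracle(tvals.mean(), obs.mean(),
                                   obs.std(ddof=1), len(tvals))
            assert d.z == pytest.approx(z, abs=1e-9)
            assert d.p == pytest.approx(p, abs=1e-9)
            assert d.activity == pytest.approx(act, abs=1e-9)

    def test_min_targets_filter(self):
        bg = np.array([1.0, -1.0, 0.5, -0.5])
        matrix, prior = matrix_with_targets([1.0, 1.0], bg)
        result = kinase_activity_ztest(matrix, prior, min_targets=3)
        assert result.values.isna().all().all()
        assert result.n_targets.iloc[0, 0] == 2

    def test_degenerate_sample_skipped(self):
        matrix, prior = matrix_with_targets([1.0, 1.0, 1.0],
                                            [2.0, 2.0, 2.0, 2.0])
        result = kinase_activity_ztest(matrix, prior, min_targets=3,
                                       exclude_targets_from_background=True)
        assert result.values.isna().all().all()

    def test_monotonicity_in_target_values(self, rng):
        """Raising every target value in a sample never lowers activity."""
        values = rng.normal(size=(60, 4))
        ids = [f"P{i}_S1" for i in range(60)]
        prior = PriorNetwork(kinase_targets={
            "K": {PhosphositeKey(f"P{i}", 1, "S"): "database"
                  for i in range(6)}})
        base = kinase_activity_ztest(make_matrix(values, features=ids), prior,
                                     exclude_targets_from_background=True)
        bumped_vals = values.copy()
        bumped_vals[:6, 0] += 0.5
        bumped = kinase_activity_ztest(
            make_matrix(bumped_vals, features=ids), prior,
            exclude_targets_from_background=True)
        assert bumped.values.iloc[0, 0] >= base.values.iloc[0, 0]

    def test_self_sites_mode_uses_annotated_own_sites(self):
        ids = ["K_S2", "K_S4", "K_S6", "B0_S1", "B1_S1", "B2_S1", "B3_S1"]
        values = np.array([[2.0], [2.0], [2.0], [1.0], [-1.0], [0.5], [-0.5]])
        prior = PriorNetwork(kinase_targets={"K": {
            PhosphositeKey("K", 2, "S"): "database",
            PhosphositeKey("K", 4, "S"): "database",
            PhosphositeKey("K", 6, "S"): "database",
            PhosphositeKey("B0", 1, "S"): "database",
        }})
        annot = pd.DataFrame({
            "regulatory": [True, False, False],
            "functional_score": [np.nan, 0.9, 0.1],
        }, index=["K_S2", "K_S4", "K_S6"])
        result = kinase_activity_ztest(
            make_matrix(values, features=ids), prior, min_targets=2,
            mode="self_sites", self_site_annotations=annot)
        # only K_S2 (regulatory) and K_S4 (score > 0.4) qualify
        assert result.n_targets.loc["K", "s0"] == 2
        assert result.values.loc["K", "s0"] > 0


class TestTFEnrichment:
    def _regulon_prior(self, targets, modes):
        return PriorNetwork(regulons={
            "TF": [(t, m, "A") for t, m in zip(targets, modes)]})

    def test_top_rank_regulon_hits_closed_form(self, rng):
        n = 100
        values = rng.normal(size=(n, 1))
        order = np.argsort(values[:, 0])
        genes = [f"g{i}" for i in range(n)]
        top4 = [genes[i] for i in order[-4:]]
        prior = self._regulon_prior(top4, [1, 1, 1, 1])
        result = tf_activity_nes(make_matrix(values, features=genes), prior,
                                 min_regulon=4)
        expected = stats.norm.ppf(np.array([97, 98, 99, 100]) / 101.0).sum() / 2.0
        assert result.values.loc["TF", "s0"] == pytest.approx(expected,
                                                              abs=1e-9)
        assert expected == pytest.approx(4.014206218561824, abs=1e-9)

    def test_repressive_regulon_flips_sign(self, rng):
        n = 100
        values = rng.normal(size=(n, 1))
        order = np.argsort(values[:, 0])
        genes = [f"g{i}" for i in range(n)]
        top4 = [genes[i] for i in order[-4:]]
        up = tf_activity_nes(make_matrix(values, features=genes),
                             self._regulon_prior(top4, [1] * 4), min_regulon=4)
        down = tf_activity_nes(make_matrix(values, features=genes),
                               self._regulon_prior(top4, [-1] * 4),
                               min_regulon=4)
        assert down.values.loc["TF", "s0"] == pytest.approx(
            -up.values.loc["TF", "s0"], abs=1e-12)

    def test_symmetric_targets_near_zero(self):
        n = 101
        values = np.arange(n, dtype=float).reshape(-1, 1)
        genes = [f"g{i}" for i in range(n)]
        # ranks 26 and 76 sit symmetrically around the median rank 51
        prior = self._regulon_prior([genes[25], genes[75]], [1, 1])
        result = tf_activity_nes(make_matrix(values, features=genes), prior,
                                 min_regulon=2)
        assert result.values.loc["TF", "s0"] == pytest.approx(0.0, abs=1e-9)

    def test_null_calibration(self, rng):
        """Random gene statistics: NES is ~standard normal over many draws."""
        n_genes, n_draws = 200, 1200
        values = rng.normal(size=(n_genes, n_draws))
        genes = [f"g{i}" for i in range(n_genes)]
        targets = [genes[i] for i in rng.choice(n_genes, 10, replace=False)]
        prior = self._regulon_prior(targets, [1] * 10)
        result = tf_activity_nes(make_matrix(values, features=genes), prior)
        scores = result.values.loc["TF"].to_numpy()
        assert abs(scores.mean()) < 0.05
        assert 0.9 < scores.std(ddof=1) < 1.1

    def test_small_regulon_not_scored(self, rng):
        values = rng.normal(size=(50, 2))
        genes = [f"g{i}" for i in range(50)]
        prior = self._regulon_prior(genes[:3], [1, 1, 1])
        result = tf_activity_nes(make_matrix(values, features=genes),
                                 prior, min_regulon=5)
        assert result.values.isna().all().all()


class TestRegulationSummaries:
    def _activity(self, values, proteins):
        frame = pd.DataFrame(values, index=proteins,
                             columns=[f"s{j}" for j in
                                      range(np.asarray(values).shape[1])])
        return ActivityMatrix(frame, frame.notna().astype(int) * 5,
                              "signed_log10p")

    def test_regulation_percentage_frozen(self):
        act = self._activity([[2.0, -2.0, 0.0, 0.0]], ["K"])
        assert regulation_percentage(act, 1.75)["K"] == 0.5

    def test_regulation_percentage_zero_cutoff_counts_nonzero(self):
        act = self._activity([[0.0, 0.0, 1.0, -1.0]], ["K"])
        assert regulation_percentage(act, 0.0)["K"] == 0.5

    def test_all_zero_gives_zero(self):
        act = self._activity([[0.0, 0.0]], ["K"])
        assert regulation_percentage(act, 1.75)["K"] == 0.0

    def test_select_regulated_matches_brute_force(self, rng):
        values = rng.normal(scale=2.0, size=(12, 40))
        act = self._activity(values, [f"P{i}" for i in range(12)])
        kept = select_regulated_proteins(act, percentile=90.0,
                                         min_fraction=0.1)
        thr = np.percentile(np.abs(values).ravel(), 90.0)
        expected = [f"P{i}" for i in range(12)
                    if (np.abs(values[i]) > thr).mean() >= 0.1]
        assert kept == expected

    def test_never_exceeding_protein_dropped(self):
        act = self._activity([[3.0, 4.0, 5.0, 0.1], [0.1, 0.2, 0.1, 0.2]],
                             ["hot", "cold"])
        kept = select_regulated_proteins(act, percentile=75.0,
                                         min_fraction=0.05)
        assert "cold" not in kept and "hot" in kept

    def test_empty_matrix_empty_list(self):
        act = ActivityMatrix(pd.DataFrame(dtype=float),
                             pd.DataFrame(dtype=int), "nes")
        assert select_regulated_proteins(act) == []
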