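"""Kinase-group distributions and profile-correlation substrate inference."""

import numpy as np
import pandas as pd
import pytest

from phosphodyn.kinase import (
    candidate_substrates,
    cluster_kinase_composition,
    kinase_group_distribution,
    profile_similarity,
    rank_interactors_by_similarity,
)
from phosphodyn.simulate import (
    SimulationConfig,
    random_group_predictions,
    simulate_dataset,
    simulate_kinase_network,
)
from phosphodyn.types import TIME_GRID


class TestProfileSimilarity:
    def test_identical_profiles_one(self):
        v = np.sin(TIME_GRID / 5.0)
        assert profile_similarity(v, v) == pytest.approx(1.0)

    def test_negated_profile_minus_one(self):
        v = np.sin(TIME_GRID / 5.0)
        assert profile_similarity(v, -v) == pytest.approx(-1.0)

    def test_quadrature_phase_near_zero(self):
        # a full period sampled on the grid: sine vs cosine are orthogonal
        w = 2 * np.pi / 30.0
        assert abs(profile_similarity(np.sin(w * TIME_GRID),
                                      np.cos(w * TIME_GRID))) < 0.1

    def test_fewer_than_three_shared_points_undefined(self):
        a = np.full(15, np.nan)
        b = np.full(15, np.nan)
        a[:2] = [1.0, 2.0]
        b[:2] = [1.0, 2.0]
        assert np.isnan(profile_similarity(a, b))

    def test_zero_variance_undefined(self):
        assert np.isnan(profile_similarity(np.ones(15), np.arange(15.0)))

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(15), rng.standard_normal(15)
        r = profile_similarity(a, b)
        assert profile_similarity(b, a) == pytest.approx(r)
        assert profile_similarity(2.5 * a + 1.0, b) == pytest.approx(r)


class TestGroupDistribution:
    def _classes(self, categories):
        return pd.DataFrame({
            "site_id": [f"P{i}_S1_m1" for i in range(len(categories))],
            "category": categories,
        })

    def test_all_dynamic_in_one_group(self):
        classes = self._classes(["heat_specific", "heat_specific", "static"])
        preds = pd.DataFrame({
            "site_id": ["P0_S1_m1", "P1_S1_m1", "P2_S1_m1"],
            "kinase": ["cdc28"] * 3,
            "kinase_group": ["CDK", "CDK", "CK1_2"],
            "score": [1.0] * 3,
        })
        out = kinase_group_distribution(classes, preds).set_index("kinase_group")
        assert out.loc["CDK", "prop_dynamic"] == 1.0
        assert out.loc["CDK", "dynamic"] == 2
        assert out.loc["CK1_2", "static"] == 1

    def test_empty_predictions_empty_table(self):
        out = kinase_group_distribution(self._classes(["static"]), pd.DataFrame())
        assert out.empty

    def test_planted_mixture_counts_exact(self):
        config = SimulationConfig(n_sites=600, frac_dynamic=0.3, n_kinases=0, seed=59)
        _, _, truth = simulate_dataset(config)
        preds = random_group_predictions(truth, seed=60,
                                         dynamic_bias={"CDK": 4.0, "MAPK": 3.0})
        classes = truth.sites.rename(columns={})[["site_id", "category"]]
        out = kinase_group_distribution(classes, preds).set_index("kinase_group")
        # counts conserve the input: every site predicted exactly once
        assert out[["dynamic", "static"]].to_numpy().sum() == len(truth.sites)
        # planted enrichment of CDK/MAPK among dynamic sites is recovered
        assert out.loc["CDK", "prop_dynamic"] > out.loc["CDK", "prop_static"]
        assert out.loc["CK1_2", "prop_static"] > out.loc["CK1_2", "prop_dynamic"]


class TestClusterComposition:
    def test_single_cell_and_marginals(self):
        dyn = pd.DataFrame({"site_id": ["A_S1_m1", "B_S2_m1"], "cluster": [5, 5]})
        preds = pd.DataFrame({"site_id": ["A_S1_m1", "B_S2_m1"],
                              "kinase": ["cdc28"] * 2,
                              "kinase_group": ["CDK", "CDK"], "score": [1, 1]})
        out = cluster_kinase_composition(dyn, preds)
        assert out.loc["CDK", 5] == 2
        assert out.to_numpy().sum() == 2

    def test_planted_concentration_is_row_maximum(self):
        rng = np.random.default_rng(61)
        site_ids = [f"P{i}_S1_m1" for i in range(120)]
        clusters = np.where(np.arange(120) < 60, 5, rng.integers(1, 5, 120))
        groups = np.where(np.arange(120) < 60, "CDK", "OTHER")
        dyn = pd.DataFrame({"site_id": site_ids, "cluster": clusters})
        preds = pd.DataFrame({"site_id": site_ids, "kinase": "x",
                              "kinase_group": groups, "score": 1.0})
        out = cluster_kinase_composition(dyn, preds)
        assert out.loc["CDK"].idxmax() == 5


def _network_fixture(seed=67, decoys=20, frac_high=1.0, cv=0.05, jitter=0.05):
    config = SimulationConfig(n_sites=400, frac_dynamic=0.5, cv_noise=cv,
                              missing_rate=0.0, n_kinases=1,
                              substrates_per_kinase=5,
                              n_decoy_edges_per_kinase=decoys,
                              frac_high_score_decoys=frac_high,
                              substrate_timescale_jitter=jitter,
                              substrate_amplitude_jitter=jitter,
                              category_mix=(0.0, 0.0, 1.0, 0.0),  # heat responses
                              seed=seed)
    matrix, _, truth = simulate_dataset(config)
    predictions, edges, known = simulate_kinase_network(config, truth)
    k_site_id = truth.sites.loc[truth.sites["kinase"] == "KIN1:self",
                                "site_id"].iloc[0]
    ref = matrix.get(k_site_id, "heat").log2fc
    dynamic = pd.DataFrame({
        "profile_id": [f"{s}|heat" for s in truth.dynamic_site_ids],
        "cluster": 1, "membership": 1.0})
    return config, matrix, truth, edges, known, ref, dynamic


class TestCandidateSubstrates:
    def test_true_substrates_occupy_top_ranks(self):
        _, matrix, truth, edges, known, ref, dynamic = _network_fixture()
        out = candidate_substrates("KIN1", ref, edges, known, dynamic, matrix,
                                   kinase_protein=truth.kinase_proteins["KIN1"],
                                   min_abs_similarity=0.0)
        true_set = set(truth.kinase_substrates["KIN1"])
        assert set(out.head(5)["site_id"]) == true_set

    def test_empty_edge_list_empty_result(self):
        _, matrix, truth, _, known, ref, dynamic = _network_fixture()
        empty = pd.DataFrame(columns=["protein_a", "protein_b", "combined_score"])
        out = candidate_substrates("KIN1", ref, empty, known, dynamic, matrix,
                                   kinase_protein=truth.kinase_proteins["KIN1"])
        assert out.empty

    def test_anticorrelated_mode_finds_negated_substrates(self):
        """Substrates built as the negated kinase template pass with r <= -0.99."""
        config, matrix, truth, edges, known, ref, dynamic = _network_fixture(
            seed=71, cv=0.0, jitter=0.0)
        # flip every substrate profile: inhibitory-site logic
        for site_id in truth.kinase_substrates["KIN1"]:
            profile = matrix.get(site_id, "heat")
            profile.log2fc = -profile.log2fc
        out = candidate_substrates("KIN1", ref, edges, known, dynamic, matrix,
                                   kinase_protein=truth.kinase_proteins["KIN1"],
                                   mode="anticorrelated")
        got = out[out["site_id"].isin(truth.kinase_substrates["KIN1"])]
        assert len(got) == 5
        assert (got["similarity"] <= -0.99).all()

    def test_known_site_flag_set(self):
        config, matrix, truth, edges, known, ref, dynamic = _network_fixture(seed=73)
        out = candidate_substrates("KIN1", ref, edges, known, dynamic, matrix,
                                   kinase_protein=truth.kinase_proteins["KIN1"],
                                   min_abs_similarity=0.0)
        flagged = set(out.loc[out["evidence_known_site"], "site_id"])
        known_ids = {f"{r.protein}_{r.residue}{r.position}_m1"
                     for r in known.itertuples()}
        assert flagged == known_ids & set(out["site_id"])

    def test_output_invariant_to_input_row_order(self):
        _, matrix, truth, edges, known, ref, dynamic = _network_fixture(seed=79)
        shuffled = dynamic.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = candidate_substrates("KIN1", ref, edges, known, dynamic, matrix,
                                 kinase_protein=truth.kinase_proteins["KIN1"],
                                 min_abs_similarity=0.0)
        b = candidate_substrates("KIN1", ref, edges.sample(frac=1.0, random_state=2),
                                 known, shuffled, matrix,
                                 kinase_protein=truth.kinase_proteins["KIN1"],
                                 min_abs_similarity=0.0)
        pd.testing.assert_frame_equal(a, b)


class TestRankingAUROC:
    def test_planted_network_auroc(self):
        """True substrates rank above decoy interactors by |similarity|."""
        _, matrix, truth, edges, known, ref, dynamic = _network_fixture(
            seed=83, decoys=40, frac_high=1.0, cv=0.29, jitter=0.15)
        ranked = rank_interactors_by_similarity(
            "KIN1", ref, edges, matrix,
            kinase_protein=truth.kinase_proteins["KIN1"], min_edge_score=0.9)
        truth_set = set(truth.kinase_substrates["KIN1"])
        ranked = ranked.dropna(subset=["similarity"])
        labels = ranked["site_id"].isin(truth_set).to_numpy()
        scores = ranked["similarity"].abs().to_numpy()
        pos = scores[labels]
        neg = scores[~labels]
        auroc = np.mean([(p > neg).mean() + 0.5 * (p == neg).mean() for p in pos])
        assert auroc >= 0.9
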