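"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest
from rdkit import Chem

from latentgan.data import series_split, standardize
from latentgan.scoring import (
    fcfp6,
    mqn,
    murcko_scaffold,
    overlap_analysis,
    pca_projection,
    qed_score,
    sa_score,
    sample_report,
    similarity_profile,
    tanimoto,
    train_target_model,
)


class TestFingerprints:
    def test_fcfp6_invariant_to_rendering(self):
        np.testing.assert_array_equal(fcfp6("CCO"), fcfp6("OCC"))

    def test_fcfp6_distinguishes_molecules(self):
        assert (fcfp6("C") != fcfp6("c1ccccc1")).any()

    def test_fcfp6_shape_and_regression_locked_popcount(self):
        fp = fcfp6("CCO")
        assert fp.shape == (2048,)
        assert int(fp.sum()) == 5  # ethanol FCFP6 on-bit count, locked

    def test_mqn_basics(self):
        m = mqn("C")
        assert m.shape == (42,)
        assert (m >= 0).all()
        assert m[0] == 1  # single carbon

    def test_mqn_separates_constitutional_isomers(self):
        assert (mqn("CCO") != mqn("COC")).any()


class TestTanimoto:
    def test_identity_disjoint_and_hand_count(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        assert tanimoto(a, a) == 1.0
        assert tanimoto(np.array([1, 0]), np.array([0, 1])) == 0.0
        assert tanimoto(a, b) == pytest.approx(1 / 3)

    def test_symmetry_and_empty_convention(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 2, 32)
            b = rng.integers(0, 2, 32)
            assert tanimoto(a, b) == tanimoto(b, a)
        assert tanimoto(np.zeros(8), np.zeros(8)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.ones(4), np.ones(5))


class TestMurcko:
    def test_side_chains_removed(self):
        benzene = Chem.CanonSmiles("c1ccccc1")
        assert murcko_scaffold("Cc1ccccc1") == benzene
        assert murcko_scaffold("CCc1ccccc1") == murcko_scaffold("CCCc1ccccc1")

    def test_acyclic_molecule_has_empty_scaffold(self):
        assert murcko_scaffold("CCCCCC") == ""


class TestTargetModel:
    def test_separable_series_reach_perfect_scores(self):
        """Two widely separated scaffold families are classified perfectly."""
        from latentgan.fixtures import FixtureSpec, generate_library, plant_actives

        spec = FixtureSpec(n_molecules=120, n_series=4, actives_fraction=0.5, seed=17)
        labeled = plant_actives(generate_library(spec), spec)
        split = series_split(labeled, seed=0)
        model = train_target_model(labeled, split, seed=0)
        assert model.roc_auc == 1.0
        assert model.kappa == 1.0

    def test_realistic_fixture_reaches_high_auc(self, labeled200):
        split = series_split(labeled200, seed=0)
        model = train_target_model(labeled200, split, seed=0)
        assert model.roc_auc >= 0.95
        assert model.kappa >= 0.8

    def test_probabilities_are_calibrated_scores(self, labeled200):
        split = series_split(labeled200, seed=0)
        model = train_target_model(labeled200, split, seed=0)
        probs = model.probability_active([r.canonical_smiles for r in labeled200[:10]])
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_single_class_rejected(self, labeled200):
        split = series_split(labeled200, seed=0)
        actives_only = []
        for r in labeled200:
            r2 = standardize(r.canonical_smiles)
            r2.activity_label = "active"
            actives_only.append(r2)
        with pytest.raises(ValueError):
            train_target_model(actives_only, split, seed=0)


def brute_force_report(sampled, train, test_actives, nn_threshold=0.7):
    """Independent nested-loop implementation of the sampled-set metrics."""
    canon = []
    for s in sampled:
        mol = Chem.MolFromSmiles(s) if s else None
        canon.append(Chem.MolToSmiles(mol) if mol else None)
    valid = [c for c in canon if c is not None]
    unique = []
    for c in valid:
        if c not in unique:
            unique.append(c)
    train_canon = []
    for s in train:
        t = Chem.MolToSmiles(Chem.MolFromSmiles(s))
        if t not in train_canon:
            train_canon.append(t)
    novel = [u for u in unique if u not in train_canon]
    tests = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in test_actives]
    recovered = sum(1 for t in tests if t in unique)
    neighbors = 0
    for t in tests:
        best = 0.0
        for u in unique:
            best = max(best, tanimoto(fcfp6(t), fcfp6(u)))
        if best >= nn_threshold:
            neighbors += 1
    return {
        "valid_pct": 100.0 * len(valid) / len(sampled),
        "unique_pct": 100.0 * len(unique) / len(valid) if valid else 0.0,
        "novel_pct": 100.0 * len(novel) / len(unique) if unique else 0.0,
        "recovered_actives_pct": 100.0 * recovered / len(tests) if tests else 0.0,
        "recovered_neighbors": neighbors,
    }


class TestSampleReport:
    def test_matches_brute_force_oracle(self, labeled200):
        rng = np.random.default_rng(1)
        pool = [r.canonical_smiles for r in labeled200]
        sampled = list(rng.choice(pool, 40)) + ["xxx", "", "C((C"] + pool[:5]
        train = pool[:30]
        test_actives = pool[150:160]
        report = sample_report(sampled, train, test_actives)
        oracle = brute_force_report(sampled, train, test_actives)
        for key, expected in oracle.items():
            assert getattr(report, key) == pytest.approx(expected), key

    def test_sample_equal_to_training_set_has_zero_novelty(self, library50):
        smiles = [r.canonical_smiles for r in library50]
        report = sample_report(smiles, smiles, [])
        assert report.novel_pct == 0.0
        assert report.valid_pct == 100.0

    def test_recovered_actives_counting(self):
        test_actives = [f"{'C' * n}O" for n in range(2, 12)]  # 10 actives
        sampled = [test_actives[0], "CCC"]
        report = sample_report(sampled, ["CCCCN"], test_actives)
        assert report.recovered_actives_pct == pytest.approx(10.0)

    def test_chain_constraints_and_neighbor_bound(self, labeled200):
        rng = np.random.default_rng(2)
        pool = [r.canonical_smiles for r in labeled200]
        sampled = list(rng.choice(pool, 60)) + ["bad_smiles"]
        report = sample_report(sampled, pool[:50], pool[150:170])
        assert report.n_unique <= report.n_valid <= report.n_sampled
        assert report.n_novel <= report.n_unique
        exact = round(report.recovered_actives_pct * 20 / 100)
        assert report.recovered_neighbors >= exact

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sample_report([], ["CCO"], [])


class TestSimilarityProfile:
    def test_query_in_reference_scores_one(self, library50):
        smiles = [r.canonical_smiles for r in library50]
        profile = similarity_profile(smiles[:10], smiles)
        assert profile.values == [1.0] * 10
        assert profile.bins["identical"] == 1.0

    def test_singleton_reduces_to_tanimoto(self):
        value = similarity_profile(["CCO"], ["CCN"]).values[0]
        assert value == pytest.approx(tanimoto(fcfp6("CCO"), fcfp6("CCN")))

    def test_matches_nested_loop_oracle(self, labeled200):
        queries = [r.canonical_smiles for r in labeled200[:30]]
        refs = [r.canonical_smiles for r in labeled200[100:130]]
        profile = similarity_profile(queries, refs)
        for q, got in zip(queries, profile.values):
            best = max(tanimoto(fcfp6(q), fcfp6(r)) for r in refs)
            assert got == pytest.approx(best)

    def test_scaffold_level_excludes_acyclic(self):
        profile = similarity_profile(
            ["CCCC", "Cc1ccccc1"], ["c1ccccc1"], level="scaffold"
        )
        assert profile.n_excluded == 1
        assert profile.values == [1.0]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            similarity_profile(["CCO"], [])


class TestOverlap:
    def test_identical_sets(self):
        counts = overlap_analysis(["CCO", "c1ccccc1C"], ["OCC", "Cc1ccccc1"])
        assert counts.compounds_shared == 2
        assert counts.compounds_only_a == counts.compounds_only_b == 0

    def test_disjoint_compounds_sharing_scaffold(self):
        counts = overlap_analysis(["Cc1ccccc1"], ["CCc1ccccc1"])
        assert counts.compounds_shared == 0
        assert counts.scaffolds_shared == 1

    def test_union_identity(self, labeled200):
        a = [r.canonical_smiles for r in labeled200[:40]]
        b = [r.canonical_smiles for r in labeled200[20:60]]
        c = overlap_analysis(a, b)
        union = len(set(a) | set(b))
        assert c.compounds_only_a + c.compounds_only_b + c.compounds_shared == union


class TestDruglikenessScores:
    def test_qed_bounded_on_library(self, library50):
        for rec in library50:
            assert 0.0 <= qed_score(rec.canonical_smiles) <= 1.0

    def test_sa_monotone_on_constructed_pair(self):
        simple = sa_score("CCO")
        complex_mol = sa_score("CC1(C)C2CCC1(C)C(=O)C2C3CC4CC(C3)CC4O")
        assert simple < complex_mol

    def test_scores_invariant_to_rendering(self):
        assert qed_score("CCO") == qed_score("OCC")
        assert sa_score("CCO") == sa_score("OCC")


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        t = np.linspace(0, 1, 30)[:, None]
        direction = np.ones((1, 42))
        X = t @ direction
        scores, evr, _ = pca_projection(X, k=2, standardize_features=False)
        assert evr[0] == pytest.approx(100.0, abs=1e-6)

    def test_explained_variance_ordering_and_bound(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 10)) * np.arange(1, 11)
        _, evr, _ = pca_projection(X, k=5)
        assert (np.diff(evr) <= 1e-9).all()
        assert evr.sum() <= 100.0 + 1e-9

    def test_isotropic_gaussian_splits_variance_evenly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20000, 3))
        _, evr, _ = pca_projection(X, k=3, standardize_features=False)
        np.testing.assert_allclose(evr, 100 / 3, atol=2.0)

    def test_full_projection_reconstructs_centered_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 5))
        scores, _, components = pca_projection(X, k=5, standardize_features=False)
        centered = X - X.mean(axis=0)
        np.testing.assert_allclose(scores @ components, centered, atol=1e-8)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        s1, _, c1 = pca_projection(X)
        s2, _, c2 = pca_projection(X.copy())
        np.testing.assert_array_equal(s1, s2)
        for row in c1:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_projection(np.zeros((2, 5)), k=2)
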