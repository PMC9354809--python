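import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from sklearn.metrics import adjusted_rand_score

from enteropipe import (
    CohortConfig,
    ch_index,
    driver_genera,
    fit_enterotypes,
    pam_cluster,
    prediction_strength,
    silhouette,
    simulate_cohort,
)
from enteropipe.enterotype import ParameterError, pam_objective
from enteropipe.preprocess import RelAbundanceTable
from conftest import euclid_dm


class TestPAM:
    def test_two_clusters_vs_exhaustive_medoid_search(self, four_point_dm):
        labels, medoids = pam_cluster(four_point_dm, 2)
        assert {tuple(np.flatnonzero(labels == c)) for c in (0, 1)} == {(0, 1), (2, 3)}
        # oracle: best medoid pair by exhaustive search over all C(4,2) pairs
        d = four_point_dm.data
        best = min(
            itertools.combinations(range(4), 2),
            key=lambda pair: d[:, pair].min(axis=1).sum(),
        )
        obj = pam_objective(four_point_dm, labels, medoids)
        assert obj == pytest.approx(d[:, best].min(axis=1).sum())

    def test_k_equals_n_zero_objective(self, four_point_dm):
        labels, medoids = pam_cluster(four_point_dm, 4)
        assert sorted(labels) == [0, 1, 2, 3]
        assert pam_objective(four_point_dm, labels, medoids) == 0.0

    def test_duplicate_of_medoid_joins_its_cluster(self):
        pts = np.array([0.0, 0.0, 10.0, 10.5])
        dm = euclid_dm(pts)
        labels, _ = pam_cluster(dm, 2)
        assert labels[0] == labels[1]

    def test_k_out_of_range(self, four_point_dm):
        with pytest.raises(ParameterError):
            pam_cluster(four_point_dm, 1)

    def test_deterministic_without_seed(self, four_point_dm):
        a = pam_cluster(four_point_dm, 2)
        b = pam_cluster(four_point_dm, 2)
        assert (a[0] == b[0]).all() and a[1] == b[1]

    def test_swap_local_optimality(self):
        # PAM's guarantee: no single medoid<->non-medoid exchange improves
        # the objective (brute force over all exchanges)
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(9, 2))
        dm = euclid_dm(pts)
        labels, medoid_ids = pam_cluster(dm, 3)
        d = dm.data
        ids = list(dm.ids)
        med = [ids.index(m) for m in medoid_ids]
        obj = pam_objective(dm, labels, medoid_ids)
        for mi in range(3):
            for h in range(9):
                if h in med:
                    continue
                cand = med.copy()
                cand[mi] = h
                alt = d[:, cand].min(axis=1).sum()
                assert alt >= obj - 1e-12


class TestIndices:
    def test_ch_hand_value(self, four_point_dm):
        labels = np.array([0, 0, 1, 1])
        # 1-D embedding: SSB=100, SSW=1 -> CH = (100/1)/(1/2) = 200
        assert ch_index(four_point_dm, labels) == pytest.approx(200.0, rel=1e-9)

    def test_ch_infinite_when_within_zero(self):
        pts = np.array([0.0, 0.0, 5.0, 5.0])
        dm = euclid_dm(pts)
        assert np.isinf(ch_index(dm, np.array([0, 0, 1, 1])))

    def test_silhouette_hand_value(self, four_point_dm):
        labels = np.array([0, 0, 1, 1])
        got = silhouette(four_point_dm, labels)
        assert got == pytest.approx(0.8997, abs=5e-4)
        # hand widths: a(i)=1 for all; b = mean distance to the other pair
        # point 0: b=(10+11)/2; point 1: b=(9+10)/2; symmetric for 10, 11
        hand = np.mean([
            (10.5 - 1) / 10.5, (9.5 - 1) / 9.5, (9.5 - 1) / 9.5, (10.5 - 1) / 10.5,
        ])
        assert got == pytest.approx(hand)

    def test_silhouette_perfect_separation(self):
        pts = np.array([0.0, 0.0, 8.0, 8.0])
        dm = euclid_dm(pts)
        assert silhouette(dm, np.array([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_silhouette_coincident_data_zero_by_convention(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        assert silhouette(dm, np.array([0, 1, 0, 1])) == 0.0

    def test_single_cluster_errors(self, four_point_dm):
        with pytest.raises(ParameterError):
            silhouette(four_point_dm, np.zeros(4, dtype=int))


class TestPredictionStrength:
    def test_perfect_clusters_give_one(self):
        rng = np.random.default_rng(0)
        pts = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(50, 0.1, 20)])
        dm = euclid_dm(pts)
        assert prediction_strength(dm, 2, n_splits=5, seed=1) == pytest.approx(1.0)

    def test_exchangeable_data_low_ps(self):
        rng = np.random.default_rng(3)
        dm = euclid_dm(rng.normal(size=40))
        assert prediction_strength(dm, 2, n_splits=10, seed=2) < 0.9

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(5)
        dm = euclid_dm(rng.normal(size=(20, 2)))
        a = prediction_strength(dm, 3, n_splits=6, seed=9)
        b = prediction_strength(dm, 3, n_splits=6, seed=9)
        assert a == b

    def test_k_larger_than_half_errors(self, four_point_dm):
        with pytest.raises(ParameterError):
            prediction_strength(four_point_dm, 3, seed=0)


class TestDrivers:
    def test_clear_driver(self):
        rel = RelAbundanceTable(
            ["s1", "s2"], ["gA", "gB"], np.array([[0.7, 0.3], [0.6, 0.4]])
        )
        drivers, ties = driver_genera(rel, np.array([0, 0]))
        assert drivers[0] == "gA" and not ties

    def test_exact_tie_lexicographic_and_flagged(self):
        rel = RelAbundanceTable(
            ["s1"], ["gB", "gA"], np.array([[0.5, 0.5]])
        )
        drivers, ties = driver_genera(rel, np.array([0]))
        assert drivers[0] == "gA"
        assert ties and ties[0][0] == 0


class TestFit:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        cfg = CohortConfig(
            n_samples=90, n_taxa=25, k=3, driver_boost=30,
            depth_log_mean=np.log(1e4), depth_log_sd=0.3, seed=5,
        )
        return simulate_cohort(cfg)

    def test_recovers_k_and_labels(self, cohort):
        table, truth = cohort
        fit = fit_enterotypes(table, k_max=6, seed=5)
        assert fit.chosen_k == 3
        assert adjusted_rand_score(truth, fit.labels.astype(int)) >= 0.9

    def test_driver_recovered(self, cohort):
        table, truth = cohort
        fit = fit_enterotypes(table, k_max=6, seed=5)
        # simulated drivers are taxa g000..g002, one per component
        assert sorted(fit.drivers.values()) == ["g000", "g001", "g002"]

    def test_chosen_k_invariant_to_sample_order(self, cohort):
        table, _ = cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_samples)
        shuffled = table.select_samples([table.sample_ids[i] for i in perm])
        fit_a = fit_enterotypes(table, k_max=5, seed=1)
        fit_b = fit_enterotypes(shuffled, k_max=5, seed=1)
        assert fit_a.chosen_k == fit_b.chosen_k
        # same partition up to label renaming
        la = fit_a.labels[shuffled.sample_ids].astype(int)
        lb = fit_b.labels[shuffled.sample_ids].astype(int)
        assert adjusted_rand_score(la, lb) == pytest.approx(1.0)

    def test_medoids_belong_to_their_clusters(self, cohort):
        table, _ = cohort
        fit = fit_enterotypes(table, k_max=5, seed=1)
        for c, m in enumerate(fit.medoids):
            assert int(fit.labels[m]) == c

    def test_low_biomass_class_appended(self, cohort):
        table, _ = cohort
        counts = table.counts.copy()
        counts[:4] = 0
        counts[:4, 0] = 5  # 5 reads: below threshold
        from enteropipe import CountTable

        t = CountTable(table.sample_ids, table.taxon_ids, counts)
        fit = fit_enterotypes(t, k_max=4, seed=1, low_biomass_threshold=100)
        assert fit.low_biomass_samples == table.sample_ids[:4]
        assert (fit.labels[table.sample_ids[:4]] == "low_biomass").all()
        assert fit.n_classes == fit.chosen_k + 1

    def test_summary_mentions_chosen_k(self, cohort):
        table, _ = cohort
        fit = fit_enterotypes(table, k_max=4, seed=1)
        text = fit.summary()
        assert f"chosen k (argmax CH): {fit.chosen_k}" in text
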