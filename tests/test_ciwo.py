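"""Weed-colony feature selection: chaos, schedules, fitness, colony dynamics."""
import dataclasses

import numpy as np
import pytest

import weedfs as w
from weedfs import ciwo


class TestLogisticMap:
    def test_fixed_point_three_quarters(self):
        seq = ciwo.logistic_map(0.75, 4.0, 5, _unsafe=True)
        np.testing.assert_allclose(seq, 0.75)

    def test_single_step(self):
        seq = ciwo.logistic_map(0.2, 4.0, 2)
        np.testing.assert_allclose(seq, [0.2, 0.64])

    def test_orbit_stays_in_unit_interval(self):
        seq = ciwo.logistic_map(0.123, 4.0, 10_000)
        assert seq.min() >= 0.0 and seq.max() <= 1.0

    @pytest.mark.parametrize("x0", [0.25, 0.5, 0.75, 0.0, 1.0, -0.1])
    def test_degenerate_starts_rejected(self, x0):
        with pytest.raises(ValueError):
            ciwo.logistic_map(x0, 4.0, 3)

    def test_control_parameter_range(self):
        with pytest.raises(ValueError):
            ciwo.logistic_map(0.3, 4.5, 3)


class TestSeedSchedule:
    def test_best_rank_gets_s_max(self):
        assert ciwo.seeds_for_rank(1, 10, 0, 5) == 5

    def test_worst_rank_gets_s_min(self):
        assert ciwo.seeds_for_rank(10, 10, 0, 5) == 0

    def test_interior_value(self):
        assert ciwo.seeds_for_rank(3, 5, 2, 6) == 4

    def test_half_up_rounding(self):
        # s_min=0, s_max=1, n_weed=3, rank=2 -> 0.5 rounds up to 1
        assert ciwo.seeds_for_rank(2, 3, 0, 1) == 1

    def test_single_weed_rejected(self):
        with pytest.raises(ValueError):
            ciwo.seeds_for_rank(1, 1, 0, 5)


class TestDispersalSchedule:
    def setup_method(self):
        self.p = w.CIWOParams(sigma_initial=1.0, sigma_final=0.0 + 1e-12,
                              modulation_n=2, max_iter=10)

    def test_endpoints(self):
        assert ciwo.dispersal_sd(0, self.p) == pytest.approx(1.0)
        assert ciwo.dispersal_sd(10, self.p) == pytest.approx(1e-12)

    def test_interior_value(self):
        assert ciwo.dispersal_sd(5, self.p) == pytest.approx(0.25, rel=1e-9)

    def test_monotone_decay(self):
        sds = [ciwo.dispersal_sd(i, self.p) for i in range(11)]
        assert all(a >= b for a, b in zip(sds, sds[1:]))


class TestChaoticInit:
    def test_shapes_range_and_mask_consistency(self):
        params = w.CIWOParams(rng_seed=5)
        pop = ciwo.init_chaotic_population(10, 2135, params)
        assert len(pop) == 10
        for weed in pop:
            assert weed.position.shape == (2135,)
            assert weed.position.min() >= 0 and weed.position.max() <= 1
            np.testing.assert_array_equal(weed.mask, weed.position >= 0.5)

    def test_determinism(self):
        params = w.CIWOParams(rng_seed=5)
        a = ciwo.init_chaotic_population(5, 100, params)
        b = ciwo.init_chaotic_population(5, 100, params)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.position, wb.position)

    def test_initial_mask_density_matches_modulated_cdf(self):
        # Monte-Carlo estimate of P(chaotic * uniform >= 0.5) from 1e5 draws
        rng = np.random.default_rng(0)
        chaos = ciwo.logistic_map(0.7, 4.0, 100_000)
        p_sel = float((chaos * rng.uniform(size=100_000) >= 0.5).mean())
        params = w.CIWOParams(rng_seed=11)
        pop = ciwo.init_chaotic_population(20, 2000, params)
        density = np.mean([wd.mask.mean() for wd in pop])
        assert density == pytest.approx(p_sel, abs=0.02)


class TestFitness:
    def test_empty_mask_worst_case_error(self, clean_dataset):
        m = w.standardize(clean_dataset.matrix)
        cfg = w.FitnessConfig(alpha=0.99, beta=0.01)
        f = w.evaluate_fitness(np.zeros(m.n_genes, bool), m, cfg)
        assert f == pytest.approx(0.99)

    def test_scalarization_formula(self, clean_dataset, monkeypatch):
        m = w.standardize(clean_dataset.matrix)
        ev = ciwo.FitnessEvaluator(m.subset_genes(np.arange(20)), w.FitnessConfig())
        monkeypatch.setattr(ev, "_cv_error", lambda mask: 0.1)
        mask = np.zeros(20, bool)
        mask[:5] = True
        assert ev(mask) == pytest.approx(0.99 * 0.1 + 0.01 * 5 / 20)
        assert ev(mask) == pytest.approx(0.1015)

    def test_monotone_in_subset_size_at_fixed_error(self, clean_dataset, monkeypatch):
        m = w.standardize(clean_dataset.matrix)
        ev = ciwo.FitnessEvaluator(m, w.FitnessConfig())
        monkeypatch.setattr(ev, "_cv_error", lambda mask: 0.2)
        masks = []
        for k in (1, 5, 50):
            mk = np.zeros(m.n_genes, bool)
            mk[:k] = True
            masks.append(ev(mk))
        assert masks[0] < masks[1] < masks[2]

    def test_bounded_when_weights_sum_to_one(self, strong_signal_8gene):
        _, m = strong_signal_8gene
        ev = ciwo.FitnessEvaluator(m, w.FitnessConfig())
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = ev(rng.uniform(size=8) >= 0.5)
            assert 0.0 <= f <= 1.0

    def test_planted_mask_beats_full_mask(self, clean_dataset):
        m = w.standardize(clean_dataset.matrix)
        truth_mask = np.array([g in clean_dataset.truth_informative for g in m.gene_ids])
        cfg = w.FitnessConfig(cv_seed=1)
        ev = ciwo.FitnessEvaluator(m, cfg)
        assert ev(truth_mask) < ev(np.ones(m.n_genes, bool))

    def test_agrees_with_sklearn_nearest_centroid(self, clean_dataset):
        from sklearn.neighbors import NearestCentroid

        m = w.standardize(clean_dataset.matrix)
        cfg = w.FitnessConfig(cv_seed=7)
        ev = ciwo.FitnessEvaluator(m, cfg)
        X, y = m.sample_matrix(), m.label_codes()
        rng = np.random.default_rng(0)
        for _ in range(5):
            mask = rng.uniform(size=m.n_genes) < 0.1
            if not mask.any():
                continue
            wrong = 0
            for train, test in ev._folds:
                clf = NearestCentroid().fit(X[train][:, mask], y[train])
                wrong += int((clf.predict(X[test][:, mask]) != y[test]).sum())
            assert ev._cv_error(mask) == pytest.approx(wrong / len(y))

    def test_mask_length_mismatch(self, strong_signal_8gene):
        _, m = strong_signal_8gene
        with pytest.raises(ValueError, match="mask length"):
            w.evaluate_fitness(np.zeros(5, bool), m)


class TestColonyDynamics:
    def _pop(self, fitnesses, n_features=6):
        rng = np.random.default_rng(0)
        pop = []
        for f in fitnesses:
            pos = rng.uniform(size=n_features)
            pop.append(ciwo.Weed(position=pos, mask=pos >= 0.5, fitness=f))
        return pop

    def test_constant_seed_count(self):
        params = w.CIWOParams(s_min=3, s_max=3, max_iter=10)
        pop = self._pop([0.5, 0.2, 0.9])
        out = ciwo.reproduce(pop, 5, params, lambda m: 0.1, np.random.default_rng(1))
        assert len(out) == 3 + 3 * 3

    def test_rank_proportional_offspring_total(self):
        params = w.CIWOParams(n_weed=5, s_min=2, s_max=6, max_iter=10, p_max=40)
        pop = self._pop([0.1, 0.2, 0.3, 0.4, 0.5])
        out = ciwo.reproduce(pop, 1, params, lambda m: 0.1, np.random.default_rng(1))
        assert len(out) - len(pop) == 2 + 3 + 4 + 5 + 6

    def test_zero_dispersal_limit_preserves_masks(self):
        params = w.CIWOParams(s_min=2, s_max=2, sigma_initial=1e-12, sigma_final=1e-13,
                              max_iter=10)
        pop = self._pop([0.3, 0.1])
        out = ciwo.reproduce(pop, 10, params, lambda m: 0.5, np.random.default_rng(2))
        masks = {tuple(weed.mask.tolist()) for weed in pop}
        for child in out[len(pop):]:
            assert tuple(child.mask.tolist()) in masks

    def test_exclusion_keeps_fittest(self):
        pop = self._pop([0.3, 0.1, 0.2])
        kept = ciwo.exclude_weakest(pop, 2)
        assert sorted(weed.fitness for weed in kept) == [0.1, 0.2]

    def test_exclusion_noop_when_under_cap(self):
        pop = self._pop([0.3, 0.1])
        assert ciwo.exclude_weakest(pop, 5) == pop

    def test_exclusion_tie_breaks_on_subset_size(self):
        a = ciwo.Weed(position=np.full(10, 0.9), mask=np.ones(10, bool), fitness=0.5)
        small = np.zeros(10, bool)
        small[:3] = True
        b = ciwo.Weed(position=np.where(small, 0.9, 0.1), mask=small, fitness=0.5)
        kept = ciwo.exclude_weakest([a, b], 1)
        assert kept[0] is b


class TestRunCIWO:
    def test_zero_iterations_returns_initial_best(self, strong_signal_8gene):
        _, m = strong_signal_8gene
        params = w.CIWOParams(max_iter=0, rng_seed=1)
        res = w.run_ciwo(m, params, w.FitnessConfig())
        assert len(res.history) == 1
        assert res.evaluations == params.n_weed

    def test_history_length_and_elitism(self, strong_signal_8gene):
        _, m = strong_signal_8gene
        params = w.CIWOParams(max_iter=15, rng_seed=2)
        res = w.run_ciwo(m, params, w.FitnessConfig())
        assert len(res.history) == params.max_iter + 1
        best = [row.best_fitness for row in res.history]
        assert all(a >= b for a, b in zip(best, best[1:]))
        assert all(row.population_size <= params.p_max for row in res.history)

    def test_determinism(self, strong_signal_8gene):
        _, m = strong_signal_8gene
        params = w.CIWOParams(max_iter=10, rng_seed=3)
        r1 = w.run_ciwo(m, params, w.FitnessConfig())
        r2 = w.run_ciwo(m, params, w.FitnessConfig())
        np.testing.assert_array_equal(r1.best_mask, r2.best_mask)
        assert r1.best_fitness == r2.best_fitness
        assert r1.evaluations == r2.evaluations

    def test_reaches_brute_force_optimum(self, strong_signal_8gene):
        _, m = strong_signal_8gene
        cfg = w.FitnessConfig(cv_seed=0)
        _, best_f = w.brute_force_best_subset(m, cfg)
        res = w.run_ciwo(m, w.CIWOParams(rng_seed=0), cfg)
        assert res.best_fitness == pytest.approx(best_f, abs=1e-12)


class TestBruteForce:
    def test_enumeration_count(self, strong_signal_8gene):
        _, m = strong_signal_8gene
        m3 = m.subset_genes(np.arange(3))
        ev_count = {}
        cfg = w.FitnessConfig()
        mask, fit = w.brute_force_best_subset(m3, cfg)
        # 2^3 masks: verify by recomputing with a counting evaluator
        ev = ciwo.FitnessEvaluator(m3, cfg)
        for code in range(8):
            ev(np.array([(code >> i) & 1 for i in range(3)], dtype=bool))
        assert ev.evaluations == 8

    def test_single_feature_case(self, strong_signal_8gene):
        _, m = strong_signal_8gene
        m1 = m.subset_genes(np.arange(1))
        mask, fit = w.brute_force_best_subset(m1, w.FitnessConfig())
        ev = ciwo.FitnessEvaluator(m1, w.FitnessConfig())
        candidates = [ev(np.array([False])), ev(np.array([True]))]
        assert fit == pytest.approx(min(candidates))

    def test_refuses_large_spaces(self, clean_dataset):
        with pytest.raises(ValueError, match="refusing"):
            w.brute_force_best_subset(w.standardize(clean_dataset.matrix))

    def test_optimum_contains_planted_pair(self, strong_signal_8gene):
        ds, m = strong_signal_8gene
        mask, _ = w.brute_force_best_subset(m, w.FitnessConfig(cv_seed=1))
        selected = {m.gene_ids[i] for i in np.flatnonzero(mask)}
        assert ds.truth_informative <= selected
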