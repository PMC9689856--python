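"""Whale/hawk hybrid selection: update rules, fitness, recovery."""

import numpy as np
import pytest

from endoml.selection import (SPIRAL_A, HybridWOAHHOSelector, SelectionConfig,
                              SwarmState, binarize_position, coefficient_c,
                              compute_md, fitness, hho_refine, hho_step,
                              hybrid_select, woa_update)
from endoml.synthdata import TableRecipe, make_table


def small_cfg(**kw):
    defaults = dict(population=4, iterations=10, hho_iterations=5,
                    fitness_hidden=40, seed=0)
    defaults.update(kw)
    return SelectionConfig(**defaults)


class TestCoefficient:
    @pytest.mark.parametrize("v,V,expected", [(0, 200, 2.0), (200, 200, 0.0),
                                              (50, 200, 1.5), (3, 4, 0.5)])
    def test_linear_decline(self, v, V, expected):
        assert coefficient_c(v, V) == pytest.approx(expected)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            coefficient_c(0, 0)


class TestMedian:
    def test_odd_takes_middle(self):
        assert compute_md([3, 1, 2]) == 2

    def test_even_averages_middles(self):
        assert compute_md([1, 2, 3, 4]) == 2.5

    def test_matches_sorting_oracle_both_parities(self, rng):
        for n in (999, 1000):
            vals = rng.random(n)
            srt = np.sort(vals)
            expect = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
            assert compute_md(vals) == pytest.approx(expect)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_md([])


class TestBinarizePosition:
    def test_all_ones_selects_everything(self):
        assert binarize_position(np.ones(7)).all()

    def test_all_zeros_forces_single_dimension(self):
        mask = binarize_position(np.zeros(7))
        assert mask.sum() == 1

    def test_matches_threshold_oracle(self, rng):
        pos = rng.random(40)
        mask = binarize_position(pos)
        if (pos >= 0.5).any():
            assert np.array_equal(mask, pos >= 0.5)


class TestFitness:
    def test_informative_mask_beats_noise_mask(self, planted_table):
        x, y, info = planted_table
        cfg = small_cfg()
        mask = np.zeros(50, dtype=bool)
        mask[info] = True
        assert fitness(mask, x, y, cfg) < 0.1
        noise_mask = ~mask
        assert abs(fitness(noise_mask, x, y, cfg) - 0.5) <= 0.15

    def test_deterministic_given_seed(self, planted_table):
        x, y, _ = planted_table
        cfg = small_cfg()
        mask = np.zeros(50, dtype=bool)
        mask[:7] = True
        assert fitness(mask, x, y, cfg) == fitness(mask, x, y, cfg)

    def test_single_class_rejected(self, planted_table):
        x, _, _ = planted_table
        with pytest.raises(ValueError):
            fitness(np.ones(50, bool), x, np.zeros(len(x)), small_cfg())


def make_state(positions, fit_fn, cfg, v=0, V=10):
    positions = np.asarray(positions, dtype=float)
    errs = np.array([fit_fn(binarize_position(p, cfg.transfer))
                     for p in positions])
    best = int(np.argmin(errs))
    return SwarmState(positions=positions.copy(), fitnesses=errs,
                      best_position=positions[best].copy(),
                      best_mask=binarize_position(positions[best], cfg.transfer),
                      best_fitness=errs[best], v=v, V=V)


class TestWOAUpdate:
    def test_population_collapsed_on_best_is_fixed_point(self, planted_table):
        x, y, _ = planted_table
        cfg = small_cfg()
        fit = lambda m: fitness(m, x, y, cfg)
        pos = np.tile(np.linspace(0.1, 0.9, 50), (4, 1))
        state = make_state(pos, fit, cfg, v=10, V=10)  # c = 0
        woa_update(state, np.random.default_rng(0), fit, cfg)
        assert np.allclose(state.positions, pos, atol=1e-12)

    def test_elitism_never_worsens_best(self, planted_table):
        x, y, _ = planted_table
        cfg = small_cfg()
        fit = lambda m: fitness(m, x, y, cfg)
        rng = np.random.default_rng(4)
        state = make_state(rng.random((4, 50)), fit, cfg, V=5)
        prev = state.best_fitness
        for _ in range(5):
            woa_update(state, rng, fit, cfg)
            assert state.best_fitness <= prev
            prev = state.best_fitness

    def test_positions_stay_clipped(self, planted_table):
        x, y, _ = planted_table
        cfg = small_cfg()
        fit = lambda m: fitness(m, x, y, cfg)
        rng = np.random.default_rng(7)
        state = make_state(rng.random((4, 50)), fit, cfg, V=3)
        for _ in range(3):
            woa_update(state, rng, fit, cfg)
            assert state.positions.min() >= 0 and state.positions.max() <= 1

    def test_reproduces_hand_stepped_trace(self):
        """Scalar re-derivation of one generation at D=2, pop=2."""
        cfg = SelectionConfig(population=2, iterations=4, seed=0)
        fit = lambda mask: 1.0 - mask.sum() / 2.0  # more columns = better
        pos = np.array([[0.6, 0.2], [0.3, 0.8]])
        state = make_state(pos, fit, cfg, v=1, V=4)
        best_before = state.best_position.copy()
        seed_rng = np.random.default_rng(99)
        woa_update(state, seed_rng, fit, cfg)

        oracle = np.random.default_rng(99)
        c = 2 - 2 * 1 / 4
        expect = np.empty((2, 2))
        for i in range(2):
            y = pos[i]
            p = oracle.random()
            md = np.median(y)
            if p >= md:
                ell = oracle.uniform(-1, 1)
                expect[i] = (np.abs(best_before - y)
                             * np.exp(SPIRAL_A * ell) * np.cos(2 * np.pi * ell)
                             + best_before)
            else:
                d = oracle.random(2)
                w = 2 * c * d - c
                u = 2 * oracle.random(2)
                if np.abs(w).mean() < 1:
                    expect[i] = best_before - w * np.abs(
                        u * best_before - y)
                else:
                    j = int(oracle.integers(2))
                    expect[i] = pos[j] - w * np.abs(u * pos[j] - y)
        assert np.allclose(state.positions, np.clip(expect, 0, 1))


class TestHHO:
    def test_step_reproduces_hand_computation_both_branches(self):
        pos = np.array([0.2, 0.4, 0.9])
        y_rand = np.array([0.5, 0.1, 0.3])
        y_rabbit = np.array([0.8, 0.2, 0.6])
        y_mean = np.array([0.4, 0.4, 0.4])
        d = (0.5, 0.25, 0.3, 0.8)
        # q >= mean(pos) = 0.5 -> perch on random agent
        out = hho_step(pos, y_rand, y_rabbit, y_mean, q=0.6, d=d)
        expect = np.clip(y_rand - 0.5 * np.abs(y_rand - 2 * 0.25 * pos), 0, 1)
        assert np.allclose(out, expect)
        # q < mean -> rabbit-minus-mean branch
        out2 = hho_step(pos, y_rand, y_rabbit, y_mean, q=0.1, d=d)
        expect2 = np.clip((y_rabbit - y_mean) - 0.3 * (0.0 + 0.8 * 1.0), 0, 1)
        assert np.allclose(out2, expect2)

    def test_zero_iterations_returns_start(self, planted_table):
        x, y, _ = planted_table
        cfg = small_cfg()
        start = np.zeros(50, dtype=bool)
        start[[1, 5, 9]] = True
        mask, history = hho_refine(x, y, start, cfg, np.random.default_rng(0),
                                   n_iter=0)
        assert np.array_equal(mask, start)
        assert len(history) == 1

    def test_refinement_never_worse_than_start(self, planted_table):
        x, y, _ = planted_table
        cfg = small_cfg()
        start = binarize_position(np.random.default_rng(3).random(50))
        mask, history = hho_refine(x, y, start, cfg, np.random.default_rng(1))
        assert fitness(mask, x, y, cfg) <= fitness(start, x, y, cfg)
        assert all(a >= b for a, b in zip(history, history[1:]))


class TestHybridSelect:
    def test_recovers_planted_columns_quickly(self):
        x, y, info = make_table(TableRecipe(n=120, d=20, k=3, effect=2.0, seed=1))
        cfg = SelectionConfig(population=8, iterations=15, hho_iterations=5,
                              fitness_hidden=60, seed=1)
        mask, sub, history = hybrid_select(x, y, cfg)
        assert np.isin(info, np.flatnonzero(mask)).sum() >= 2
        assert sub.shape == (120, mask.sum())
        assert all(a >= b for a, b in zip(history, history[1:]))

    def test_selector_estimator_surface(self, planted_table):
        x, y, _ = planted_table
        sel = HybridWOAHHOSelector(population=6, iterations=8,
                                   hho_iterations=4, fitness_hidden=40,
                                   random_state=0).fit(x, y)
        assert sel.transform(x).shape[1] == sel.get_support().sum()
        assert sel.history_[-1] == sel.best_error_

    def test_all_informative_subset_close_to_full(self):
        x, y, _ = make_table(TableRecipe(n=300, d=10, k=10, effect=2.0, seed=4))
        cfg = SelectionConfig(population=6, iterations=10, hho_iterations=4,
                              fitness_hidden=60, seed=4)
        mask, _, history = hybrid_select(x, y, cfg)
        full_err = fitness(np.ones(10, bool), x, y, cfg)
        assert history[-1] <= full_err + 0.05

    def test_input_validation(self, planted_table):
        x, y, _ = planted_table
        with pytest.raises(ValueError):
            hybrid_select(x[:5], y[:5], small_cfg())
        with pytest.raises(ValueError):
            hybrid_select(x, np.zeros(len(x)), small_cfg())
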