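"""Technical-noise model: inflation, draws, envelopes and coverage."""

import numpy as np
import pandas as pd
import pytest

from cotype.io import EdgeTable
from cotype.noise import (
    NoiseModelConfig,
    TechnicalNoiseModel,
    explainable_fraction,
    inflate_to_ground_truth,
    noise_envelope,
    paired_draws,
    simulate_draw,
    stochastic_round,
)


def _table(rows):
    return EdgeTable.from_records(rows)


class TestInflation:
    def test_calyx_worked_example_factor_1_9(self):
        # 52.5% postsynaptic completion -> scale factor 100/52.5 = 1.9
        t = _table([("a", "b", 10, "CA")])
        fictive = inflate_to_ground_truth(t, {"CA": 0.525})
        factor = fictive["fictive"].iloc[0] / 10
        assert factor == pytest.approx(100 / 52.5)
        assert round(factor, 1) == 1.9

    def test_full_completion_leaves_weights(self):
        t = _table([("a", "b", 7, "X")])
        fictive = inflate_to_ground_truth(t, {"X": 1.0})
        assert fictive["fictive"].iloc[0] == 7.0

    def test_half_completion_doubles(self):
        t = _table([("a", "b", 4, "X")])
        assert inflate_to_ground_truth(t, {"X": 0.5})["fictive"].iloc[0] == 8.0

    def test_missing_neuropil_named_in_error(self):
        t = _table([("a", "b", 4, "LH")])
        with pytest.raises(ValueError, match="LH"):
            inflate_to_ground_truth(t, {"CA": 0.5})


class TestStochasticRound:
    def test_integers_unchanged(self, rng):
        x = np.array([1.0, 5.0, 30.0])
        assert np.array_equal(stochastic_round(x, rng), [1, 5, 30])

    def test_expectation_preserved(self, rng):
        x = np.full(20000, 2.3)
        assert stochastic_round(x, rng).mean() == pytest.approx(2.3, abs=0.02)


class TestSimulateDraw:
    def test_identity_limit_reproduces_ground_truth(self, rng):
        t = _table([("a", "b", 12, "X"), ("c", "d", 3, "X"), ("e", "f", 9, "Y")])
        fictive = inflate_to_ground_truth(t, {"X": 1.0, "Y": 1.0})
        out = simulate_draw(fictive, {"X": 1.0, "Y": 1.0}, 1.0, 1.0, rng)
        assert np.array_equal(out, t.df["weight"].to_numpy())

    def test_completion_draw_matches_binomial_expectation(self):
        rng = np.random.default_rng(0)
        t = _table([("a", "b", 40, "X")])
        fictive = inflate_to_ground_truth(t, {"X": 1.0})
        q = 0.5
        draws = [
            simulate_draw(fictive, {"X": q}, 1.0, 1.0, rng)[0] for _ in range(10000)
        ]
        mean = np.mean(draws)
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(mean - 40 * q) < 4 * max(se, 1e-9) + 0.05

    def test_false_positive_budget_at_half_precision(self):
        rng = np.random.default_rng(1)
        t = _table([(f"a{i}", f"b{i}", 10, "X") for i in range(50)])
        fictive = inflate_to_ground_truth(t, {"X": 1.0})
        totals = []
        for _ in range(300):
            out = simulate_draw(fictive, {"X": 1.0}, 0.5, 1.0, rng)
            totals.append(out.sum())
        # at precision 0.5, E[FP] = TP, so total should double
        assert np.mean(totals) == pytest.approx(2 * 500, rel=0.03)


class TestPairedDraws:
    def test_symmetric_completion_mean_difference_zero(self):
        t = _table([(f"a{i}", f"b{i}", 20, "L") for i in range(30)]
                   + [(f"c{i}", f"d{i}", 20, "R") for i in range(30)])
        completion = {"L": 0.6, "R": 0.6}
        fictive = inflate_to_ground_truth(t, completion)
        a, b = paired_draws(fictive, completion, {"L": "R", "R": "L"}, 400, seed=3,
                           precision=1.0, recall=1.0)
        assert abs((b - a).mean()) < 0.1

    def test_seeded_reproducibility(self):
        t = _table([("a", "b", 15, "L")])
        fictive = inflate_to_ground_truth(t, {"L": 0.7})
        d1 = paired_draws(fictive, {"L": 0.7}, {"L": "L"}, 20, seed=9)
        d2 = paired_draws(fictive, {"L": 0.7}, {"L": "L"}, 20, seed=9)
        assert np.array_equal(d1[0], d2[0]) and np.array_equal(d1[1], d2[1])

    def test_non_involutive_flip_rejected(self):
        t = _table([("a", "b", 15, "L")])
        fictive = inflate_to_ground_truth(t, {"L": 0.7, "M": 0.5, "R": 0.6})
        with pytest.raises(ValueError, match="involution"):
            paired_draws(fictive, {"L": 0.7, "M": 0.5, "R": 0.6},
                         {"L": "M", "M": "R", "R": "L"}, 5, seed=0)

    def test_focal_edge_difference_distribution_matches_enumeration(self):
        # a weight-6 focal edge embedded in a large neuropil: the draw
        # without replacement has a near-binomial marginal for the focal
        # edge, so the difference of two independent draws follows the
        # binomial self-convolution pmf
        w, q = 6, 0.5
        rows = [("a", "b", w, "L")] + [(f"x{i}", f"y{i}", 6, "L") for i in range(300)]
        fictive = inflate_to_ground_truth(_table(rows), {"L": 1.0})
        focal = int(
            fictive.index[(fictive["pre_id"] == "a") & (fictive["post_id"] == "b")][0]
        )
        a, b = paired_draws(fictive, {"L": q}, {"L": "L"}, 4000, seed=7,
                           precision=1.0, recall=1.0)
        diffs = b[:, focal] - a[:, focal]
        from scipy.stats import binom
        pmf = binom.pmf(np.arange(w + 1), w, q)
        conv = np.convolve(pmf, pmf[::-1])  # support -w..w
        for d in range(-w, w + 1):
            emp = (diffs == d).mean()
            assert abs(emp - conv[d + w]) < 0.03


class TestEnvelope:
    def test_zero_noise_envelope_width_zero(self):
        t = _table([(f"a{i}", f"b{i}", w, "L") for i, w in enumerate([3, 5, 9] * 20)])
        fictive = inflate_to_ground_truth(t, {"L": 1.0})
        draws = paired_draws(fictive, {"L": 1.0}, {"L": "L"}, 50, seed=1,
                            precision=1.0, recall=1.0)
        env = noise_envelope(draws)
        assert (env.table["lo"] == 0).all() and (env.table["hi"] == 0).all()

    def test_quantiles_match_sort_oracle(self):
        t = _table([(f"a{i}", f"b{i}", 8, "L") for i in range(40)])
        fictive = inflate_to_ground_truth(t, {"L": 0.8})
        draws = paired_draws(fictive, {"L": 0.8}, {"L": "L"}, 200, seed=2)
        env = noise_envelope(draws)
        a, b = draws
        diff = (b - a).ravel()
        w = a.ravel()
        for weight, row in env.table.iterrows():
            d = diff[w == weight]
            assert row["lo"] == pytest.approx(np.quantile(d, 0.05))
            assert row["hi"] == pytest.approx(np.quantile(d, 0.95))
            assert row["mean_diff"] == pytest.approx(d.mean())

    def test_left_right_rate_asymmetry_widens_envelope(self):
        # edges pooled over two neuropils; with asymmetric left/right
        # completion the flipped draws acquire neuropil-dependent systematic
        # shifts, spreading the pooled per-weight difference distribution
        t = _table(
            [(f"a{i}", f"b{i}", 15, "L1") for i in range(100)]
            + [(f"c{i}", f"d{i}", 15, "L2") for i in range(100)]
        )
        sym = {"L1": 0.7, "R1": 0.7, "L2": 0.7, "R2": 0.7}
        asym = {"L1": 0.9, "R1": 0.5, "L2": 0.5, "R2": 0.9}
        flip = {"L1": "R1", "R1": "L1", "L2": "R2", "R2": "L2"}
        d_sym = paired_draws(inflate_to_ground_truth(t, sym), sym, flip, 150, seed=4)
        d_asym = paired_draws(inflate_to_ground_truth(t, asym), asym, flip, 150, seed=4)
        env_sym = noise_envelope(d_sym)
        env_asym = noise_envelope(d_asym)
        shared = env_sym.table.index.intersection(env_asym.table.index)
        width_sym = (env_sym.table.loc[shared, "hi"] - env_sym.table.loc[shared, "lo"]).mean()
        width_asym = (env_asym.table.loc[shared, "hi"] - env_asym.table.loc[shared, "lo"]).mean()
        assert width_asym >= width_sym


class TestExplainableFraction:
    def test_all_zero_differences_inside_envelope(self):
        env = noise_envelope(
            (np.tile(np.arange(1, 6), (50, 1)), np.tile(np.arange(1, 6), (50, 1)) + 0)
        )
        obs = pd.DataFrame({"left": [1, 2, 3], "right": [1, 2, 3]})
        out = explainable_fraction(obs, env)
        assert out["fraction_explained"] == 1.0

    def test_far_outliers_outside_envelope(self):
        a = np.tile(np.arange(1, 6), (50, 1))
        env = noise_envelope((a, a))
        obs = pd.DataFrame({"left": [1, 2, 3], "right": [50, 60, 70]})
        out = explainable_fraction(obs, env)
        assert out["fraction_explained"] == 0.0

    def test_out_of_range_weights_excluded_with_count(self):
        a = np.tile(np.arange(1, 6), (50, 1))
        env = noise_envelope((a, a))
        obs = pd.DataFrame({"left": [2, 500], "right": [2, 500]})
        out = explainable_fraction(obs, env)
        assert out["n_excluded"] == 1 and out["n_edges"] == 1


class TestModelSelfConsistency:
    def test_coverage_matches_nominal_quantile_mass(self):
        rng = np.random.default_rng(7)
        npils = [f"{s}{i}" for i in range(3) for s in "lr"]
        rows = [
            (f"t{i}", f"u{i}", int(w), npils[i % 6])
            for i, w in enumerate(np.clip(rng.lognormal(1.5, 1.0, 550).round(), 1, None))
        ]
        completion = {n: float(rng.uniform(0.4, 0.9)) for n in npils}
        flip = {f"l{i}": f"r{i}" for i in range(3)} | {f"r{i}": f"l{i}" for i in range(3)}
        cfg = NoiseModelConfig(
            completion=completion, rounds=300, seed=5, continuity_correction=True
        )
        res = TechnicalNoiseModel(_table(rows), cfg, flip).fit()
        a, b = paired_draws(res.model.fictive, completion, flip, 20, seed=999)
        fracs = []
        for r in range(20):
            obs = pd.DataFrame({"left": a[r], "right": b[r]})
            obs = obs[obs["left"] > 0]
            fracs.append(res.score(obs, seed=100 + r)["fraction_explained"])
        assert np.mean(fracs) == pytest.approx(0.90, abs=0.02)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="precision"):
            NoiseModelConfig(completion={"X": 0.5}, precision=0.0)
        with pytest.raises(ValueError, match="completion"):
            NoiseModelConfig(completion={"X": 1.5})
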