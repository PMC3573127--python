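"""Model presets, rejection, posterior estimation, AIC and weights."""

import math
from collections import OrderedDict

import numpy as np
import pytest

from paleomt.abc import (
    AbcResult,
    abc_reject,
    akaike_weights,
    estimate_posterior,
    model_fit,
    preset_models,
    run_model_comparison,
)
from paleomt.stats import SummaryStatVector
from paleomt.synthetic import recovery_model_pair


class TestPresets:
    def test_h0a_sampling_schedule(self):
        model = preset_models()["H0a"]
        demes, events = model.builder({"ne_modern": 1e6})
        assert events == []
        (deme,) = demes
        schedule = {(s.label, s.age, s.size) for s in deme.samples}
        assert schedule == {("NEE", 0.0, 621), ("aUzPo", 300.0, 11)}
        assert model.k == 1

    def test_h1_priors(self):
        model = preset_models()["H1a-10"]
        assert model.priors["t_migration"] == (2.0, 139.0)
        assert model.priors["t_divergence"] == (620.0, 2600.0)
        assert model.priors["ne_sink"] == (1e5, 1.5e7)
        assert model.fixed["migrant_fraction"] == pytest.approx(0.10)
        assert model.k == 4

    def test_every_continuity_trajectory_anchors_at_palaeolithic_size(self):
        presets = preset_models()
        for name in ("H0a", "H0b", "H0c", "H0d", "H0e"):
            model = presets[name]
            low, high = model.priors["ne_modern"]
            for ne in (low, math.sqrt(low * high), high):
                demes, _ = model.builder({"ne_modern": ne})
                assert demes[0].size_at(1500.0) == pytest.approx(5000.0)

    def test_saami_prior_narrower_than_nee(self):
        presets = preset_models()
        assert presets["H0c"].priors["ne_modern"] == (1e3, 5e5)
        assert presets["H0a"].priors["ne_modern"] == (1e5, 3e7)

    def test_h1_stat_names_cover_six_observed_statistics(self):
        model = preset_models()["H1a-10"]
        assert model.stat_names == [
            "h_NEE",
            "h_CE",
            "h_aUzPo",
            "fst_NEE_CE",
            "fst_NEE_aUzPo",
            "fst_CE_aUzPo",
        ]

    def test_heterochronous_hunter_gatherer_series(self):
        model = preset_models()["H0d"]
        demes, _ = model.builder({"ne_modern": 1e6})
        ahg = [s for s in demes[0].samples if s.label == "aHG"]
        assert len(ahg) == 20
        ages = sorted(s.age for s in ahg)
        assert ages[0] == pytest.approx(168.0)
        assert ages[-1] == pytest.approx(614.0)


def _fake_sims(n, rng, spread=1.0):
    sims = []
    for i in range(n):
        stats = SummaryStatVector(
            OrderedDict(
                h_A=float(rng.normal(0.5, 0.1 * spread)),
                fst_A_B=float(rng.normal(0.1, 0.05 * spread)),
            )
        )
        sims.append(({"p": float(rng.uniform(0, 1))}, stats))
    return sims


class TestAbcReject:
    def test_retained_count_and_tolerance(self):
        rng = np.random.default_rng(0)
        sims = _fake_sims(1000, rng)
        obs = SummaryStatVector(OrderedDict(h_A=0.5, fst_A_B=0.1))
        res = abc_reject(obs, sims, fraction=0.01)
        assert len(res.retained_distances) == 10
        assert res.tolerance == pytest.approx(res.retained_distances.max())
        assert (res.retained_distances <= res.tolerance).all()

    def test_exact_match_simulation_always_retained(self):
        rng = np.random.default_rng(1)
        sims = _fake_sims(500, rng)
        sims[250] = (
            {"p": 0.123},
            SummaryStatVector(OrderedDict(h_A=0.5, fst_A_B=0.1)),
        )
        obs = SummaryStatVector(OrderedDict(h_A=0.5, fst_A_B=0.1))
        res = abc_reject(obs, sims, fraction=0.01)
        assert res.retained_distances[0] == 0.0
        assert 0.123 in res.retained_params["p"]

    def test_zero_variance_statistic_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        sims = []
        for _ in range(200):
            sims.append(
                (
                    {"p": 0.0},
                    SummaryStatVector(
                        OrderedDict(h_A=float(rng.random()), fst_A_B=0.25)
                    ),
                )
            )
        obs = SummaryStatVector(OrderedDict(h_A=0.5, fst_A_B=0.1))
        with pytest.warns(UserWarning, match="zero simulated variance"):
            abc_reject(obs, sims, fraction=0.05)

    def test_too_few_simulations_rejected(self):
        rng = np.random.default_rng(3)
        obs = SummaryStatVector(OrderedDict(h_A=0.5, fst_A_B=0.1))
        with pytest.raises(ValueError):
            abc_reject(obs, _fake_sims(50, rng), fraction=0.01)


class TestPosterior:
    def test_degenerate_draws(self):
        est = estimate_posterior({"p": np.full(100, 3.25)})
        assert est["p"] == 3.25

    def test_uniform_median_recovery(self):
        rng = np.random.default_rng(4)
        est = estimate_posterior({"p": rng.uniform(0, 1, 10_000)})
        assert abs(est["p"] - 0.5) < 0.02

    def test_estimates_inside_support(self):
        rng = np.random.default_rng(5)
        draws = rng.uniform(2.0, 139.0, 500)
        for method in ("median", "mode"):
            est = estimate_posterior({"t": draws}, method=method)
            assert 2.0 <= est["t"] <= 139.0

    def test_empty_retained_set_rejected(self):
        with pytest.raises(ValueError):
            estimate_posterior({"p": np.array([])})


class _ConstantModel:
    """Duck-typed model whose simulations always return a fixed vector."""

    def __init__(self, vec):
        self.name = "const"
        self.fixed = {}
        self._vec = vec

    def simulate(self, params, seed):
        return self._vec


def _result_with(k, tol, names=("h_A",)):
    return AbcResult(
        model_name="const",
        k=k,
        n_sims=100,
        stat_names=list(names),
        scale=np.ones(len(names)),
        retained_params={"p": np.full(5, 1.0)},
        retained_distances=np.zeros(5),
        tolerance=tol,
        point_estimates=OrderedDict(p=1.0),
    )


class TestModelFit:
    def test_perfect_fit_aic_is_twice_k(self):
        obs = SummaryStatVector(OrderedDict(h_A=0.5))
        model = _ConstantModel(SummaryStatVector(OrderedDict(h_A=0.5)))
        res = model_fit(model, _result_with(1, tol=0.1), obs, n_final=200, likelihood="fraction")
        assert res.likelihood == 1.0
        assert res.aic == pytest.approx(2.0)

    def test_zero_hits_floors_the_likelihood(self):
        obs = SummaryStatVector(OrderedDict(h_A=0.5))
        model = _ConstantModel(SummaryStatVector(OrderedDict(h_A=5.0)))
        res = model_fit(model, _result_with(1, tol=0.1), obs, n_final=200, likelihood="fraction")
        assert res.likelihood == pytest.approx(1 / 201)
        assert res.aic == pytest.approx(-2 * math.log(1 / 201) + 2)

    def test_aic_decreases_with_hit_fraction(self):
        aics = [
            -2 * math.log(frac) + 2 for frac in (0.01, 0.1, 0.5, 1.0)
        ]
        assert aics == sorted(aics, reverse=True)

    def test_small_final_batch_rejected(self):
        obs = SummaryStatVector(OrderedDict(h_A=0.5))
        model = _ConstantModel(SummaryStatVector(OrderedDict(h_A=0.5)))
        with pytest.raises(ValueError):
            model_fit(model, _result_with(1, tol=0.1), obs, n_final=50, likelihood="fraction")


class TestAkaikeWeights:
    def test_equal_aics_split_evenly(self):
        assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two(self):
        w = akaike_weights([8.0, 10.0])
        e = math.exp(-1.0)
        assert w == pytest.approx([1 / (1 + e), e / (1 + e)], abs=1e-12)
        assert w[0] == pytest.approx(0.731, abs=5e-4)

    def test_sum_to_one_and_shift_invariance(self):
        rng = np.random.default_rng(6)
        aics = rng.uniform(10, 40, 5)
        w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, akaike_weights(aics + 123.4))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])


class TestRunModelComparison:
    def test_identical_models_balanced_on_average_and_rerun_identical(self):
        # the tolerance-threshold likelihood estimate is noisy replicate to
        # replicate, so symmetry between identical models is checked on the
        # average weight over several seeds
        h0, _ = recovery_model_pair(n_modern=12, n_ancient=6)
        twin = recovery_model_pair(n_modern=12, n_ancient=6)[0]
        twin.name = "H0-twin"
        weights = []
        for seed in range(12):
            res = run_model_comparison(
                [h0, twin], n_sims=300, fraction=0.02, n_final=150, seed=seed
            )
            assert sum(r.akaike_weight for r in res) == pytest.approx(1.0)
            weights.append(
                next(r.akaike_weight for r in res if r.model_name == "H0-toy")
            )
        # individual comparisons behave like fair coin flips (noise-dominated
        # |delta AIC|), so the mean weight has sd ~0.5/sqrt(12) ~ 0.14
        assert 0.12 < float(np.mean(weights)) < 0.88
        kwargs = dict(n_sims=300, fraction=0.02, n_final=150, seed=3)
        res1 = run_model_comparison([h0, twin], **kwargs)
        res2 = run_model_comparison([h0, twin], **kwargs)
        assert [r.model_name for r in res1] == [r.model_name for r in res2]
        assert [r.aic for r in res1] == [r.aic for r in res2]
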