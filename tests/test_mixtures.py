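"""EM mixture fitting, BIC model selection and bootstrap competition."""

import math

import numpy as np
import pytest

from ploidymix.depth_io import AllelicSample
from ploidymix.mixtures import (
    MODEL_SHAPES,
    MixtureFit,
    ModelShape,
    _argmin_bic,
    attach_bootstrap,
    bic,
    bootstrap_ploidy,
    calibrate_model,
    component_layout,
    default_spec,
    em_fit,
    fit_model_grid,
    select_ploidy,
)
from tests.conftest import make_sample, ratio_sample

NU_FIXED2 = ModelShape("normal", True, "fixed_2")


class TestLayoutAndBic:
    @pytest.mark.parametrize(
        "ploidy,means",
        [
            ("diploid", (0.5,)),
            ("triploid", (1 / 3, 2 / 3)),
            ("tetraploid", (0.25, 0.50, 0.75)),
        ],
    )
    def test_component_layout(self, ploidy, means):
        assert component_layout(ploidy) == pytest.approx(means)

    def test_unknown_ploidy(self):
        with pytest.raises(ValueError, match="unknown ploidy"):
            component_layout("hexaploid")

    def test_bic_arithmetic(self):
        assert bic(0.0, 0, 10) == 0.0
        assert bic(-100.0, 3, 1000) == pytest.approx(3 * math.log(1000) + 200)
        # penalty monotonicity at equal fit
        assert bic(-50.0, 3, 500) < bic(-50.0, 5, 500)
        with pytest.raises(ValueError):
            bic(-1.0, 2, 0)


class TestEmFit:
    def test_degenerate_concentration_kills_uniform_weight(self):
        n = 400
        sample = AllelicSample(
            "const",
            ratios=np.full(n, 0.5),
            totals=np.full(n, 50),
            b_counts=np.full(n, 25),
        )
        spec = default_spec(NU_FIXED2, "diploid")
        fit = em_fit(sample, spec)
        assert fit.fitted_avec[-1] == pytest.approx(0.0, abs=1e-3)
        assert fit.fitted_avec[0] == pytest.approx(1.0, abs=1e-3)

    def test_default_tetraploid_initialization(self):
        spec = default_spec(NU_FIXED2, "tetraploid")
        assert spec.avec == pytest.approx((0.3, 0.3, 0.3, 0.1))
        assert spec.mvec == pytest.approx((0.25, 0.50, 0.75))
        assert spec.svec == pytest.approx((0.01, 0.01, 0.01))

    def test_weight_recovery_from_generative_mixture(self):
        # the generative parameters are the oracle
        truth = (0.35, 0.40, 0.15, 0.10)
        sample = ratio_sample(truth, (0.25, 0.5, 0.75), sd=0.03, n_sites=2000, seed=9)
        fit = em_fit(sample, default_spec(NU_FIXED2, "tetraploid"))
        assert fit.converged
        assert np.allclose(fit.fitted_avec, truth, atol=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            em_fit(AllelicSample("e"), default_spec(NU_FIXED2, "diploid"))

    @pytest.mark.parametrize("shape", MODEL_SHAPES, ids=lambda s: s.label)
    def test_monotone_loglik_and_normalized_weights(self, shape, diploid_sample):
        """Per-iteration log likelihood never decreases; weights stay simplex."""
        fit = em_fit(diploid_sample, default_spec(shape, "triploid"), max_iter=150)
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert sum(fit.fitted_avec) == pytest.approx(1.0, abs=1e-8)
        assert min(fit.fitted_avec) >= 0.0

    def test_scheme_nesting(self, tetraploid_sample):
        # freeing the scales can only improve the optimum
        shape_a = ModelShape("normal", True, "fixed")
        shape_av = ModelShape("normal", True, "fixed_2")
        fit_a = em_fit(tetraploid_sample, default_spec(shape_a, "tetraploid"))
        fit_av = em_fit(tetraploid_sample, default_spec(shape_av, "tetraploid"))
        assert fit_av.loglik >= fit_a.loglik - 1e-6

    def test_only_free_parameters_move(self, diploid_sample):
        spec = default_spec(ModelShape("normal", True, "fixed"), "tetraploid")
        fit = em_fit(diploid_sample, spec)
        assert fit.fitted_svec == pytest.approx(spec.svec)  # scales frozen
        spec3 = default_spec(ModelShape("normal", True, "fixed_3"), "tetraploid")
        fit3 = em_fit(diploid_sample, spec3)
        assert fit3.fitted_avec == pytest.approx(spec3.avec)  # weights frozen

    def test_site_order_permutation_leaves_fit_identical(self, diploid_sample):
        rng = np.random.default_rng(4)
        perm = rng.permutation(diploid_sample.n_sites)
        shuffled = AllelicSample(
            diploid_sample.sample_id,
            ratios=diploid_sample.ratios[perm],
            totals=diploid_sample.totals[perm],
            b_counts=diploid_sample.b_counts[perm],
        )
        spec = default_spec(NU_FIXED2, "tetraploid")
        f1, f2 = em_fit(diploid_sample, spec), em_fit(shuffled, spec)
        # identical data, reordered: agreement to summation round-off
        assert f1.loglik == pytest.approx(f2.loglik, rel=1e-12)
        assert f1.fitted_avec == pytest.approx(f2.fitted_avec, rel=1e-9)
        assert f1.fitted_svec == pytest.approx(f2.fitted_svec, rel=1e-9)


class TestGridAndCalibration:
    def test_grid_has_18_shapes_and_normalized_fits(self, diploid_sample):
        fits, errors = fit_model_grid(diploid_sample, max_iter=120)
        assert len(MODEL_SHAPES) == 18
        assert len(fits) == 18 and not errors
        for per_ploidy in fits.values():
            for fit in per_ploidy.values():
                assert sum(fit.fitted_avec) == pytest.approx(1.0, abs=1e-8)

    def test_most_shapes_call_simulated_diploid_correctly(self):
        # noise-free draw: the no-uniform shapes have no noise tails to absorb
        sample = make_sample("diploid", seed=11, n_sites=600, noise_prob=0.0)
        fits, _ = fit_model_grid(sample, max_iter=300)
        calls = [
            _argmin_bic({p: f.bic for p, f in fits[sh].items()})
            for sh in MODEL_SHAPES
        ]
        assert calls.count("diploid") >= 16

    def test_calibration_tiebreak_prefers_simplest_shape(self):
        # one known diploid called correctly by every shape
        fake = {}
        for shape in MODEL_SHAPES:
            per = {}
            for ploidy, b in (("diploid", 1.0), ("triploid", 2.0), ("tetraploid", 3.0)):
                spec = default_spec(shape, ploidy)
                per[ploidy] = MixtureFit(
                    spec, spec.avec, spec.svec, -b, spec.n_free, 100, b, 1, True
                )
            fake[shape] = per
        best = calibrate_model({"s": fake}, {"s": "diploid"})
        assert best == ModelShape("normal", False, "fixed")

    def test_calibration_recovers_generative_family(self):
        # panel generated from a normal-uniform mixture
        grids = {}
        truth = {}
        for i in range(3):
            dip = ratio_sample((0.8, 0.2), (0.5,), 0.05, 500, seed=40 + i,
                               sample_id=f"dip{i}")
            tet = ratio_sample((0.25, 0.3, 0.25, 0.2), (0.25, 0.5, 0.75), 0.04,
                               500, seed=50 + i, sample_id=f"tet{i}")
            grids[f"dip{i}"], _ = fit_model_grid(dip, max_iter=150)
            grids[f"tet{i}"], _ = fit_model_grid(tet, max_iter=150)
            truth[f"dip{i}"] = "diploid"
            truth[f"tet{i}"] = "tetraploid"
        best = calibrate_model(grids, truth)
        assert best.family == "normal"

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            calibrate_model({}, {})


class TestSelectAndBootstrap:
    @pytest.mark.parametrize(
        "ploidy,inheritance",
        [("diploid", None), ("tetraploid", "tetrasomic")],
    )
    def test_select_ploidy_recovers_simulation_truth(self, ploidy, inheritance):
        sample = make_sample(ploidy, seed=77, inheritance=inheritance)
        call = select_ploidy(sample, NU_FIXED2)
        assert call.best_ploidy == ploidy

    def test_exact_bic_tie_prefers_lower_ploidy(self):
        assert _argmin_bic({"diploid": 5.0, "tetraploid": 5.0}) == "diploid"
        assert _argmin_bic({"triploid": 4.0, "tetraploid": 4.0}) == "triploid"

    def test_bootstrap_tally_conservation_and_strong_diploid(self):
        sample = make_sample("diploid", seed=88, n_sites=800, depth_mean=100)
        tally = bootstrap_ploidy(sample, NU_FIXED2, n_boot=40, seed=3)
        assert sum(tally.values()) == 40
        assert tally["diploid"] >= 38  # >= 95% of replicates at this seed

    def test_confidence_threshold_is_60_percent(self):
        call = select_ploidy(make_sample("diploid", seed=5, n_sites=300), NU_FIXED2)
        strong = attach_bootstrap(call, {"diploid": 601, "triploid": 0, "tetraploid": 399})
        weak = attach_bootstrap(call, {"diploid": 600, "triploid": 0, "tetraploid": 400})
        assert strong.confident and not weak.confident

    def test_bootstrap_rejects_bad_inputs(self):
        sample = make_sample("diploid", seed=5, n_sites=200)
        with pytest.raises(ValueError):
            bootstrap_ploidy(sample, NU_FIXED2, n_boot=0)
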