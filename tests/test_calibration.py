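import random

import numpy as np
import pytest

import formadose as fd
from formadose.calibration import (
    FitSpec,
    TABLE1_PROTOCOLS,
    cost,
    default_recovery_protocols,
    fit,
    generate_synthetic_observations,
    two_stage_fit,
)

RTOL_FAST = 1e-6  # ODE tolerance for fitting tests; the cost is insensitive below this


@pytest.fixture(scope="module")
def truth():
    return fd.KineticParameters()


@pytest.fixture(scope="module")
def recovery_setup(truth):
    protocols, registry = default_recovery_protocols()
    exact = generate_synthetic_observations(truth, protocols, noise_cv=0.0, seed=7)
    return protocols, registry, exact


class TestCost:
    def test_zero_when_predictions_match_observations(self, truth, recovery_setup):
        protocols, registry, exact = recovery_setup
        assert cost(truth, exact, registry) < 1e-12

    def test_one_unit_per_observation_at_twofold_error(self, truth, recovery_setup):
        """Relative least squares: predictions exactly double each observation
        contribute ((2x - x)/x)^2 = 1 apiece."""
        protocols, registry, exact = recovery_setup
        halved = [
            fd.AdductObservation(o.study, o.ppm, o.time_h, o.species, o.value / 2.0)
            for o in exact
        ]
        assert cost(truth, halved, registry) == pytest.approx(len(halved), rel=1e-9)

    def test_invariant_to_observation_ordering(self, truth, recovery_setup):
        protocols, registry, exact = recovery_setup
        shuffled = list(exact)
        random.Random(3).shuffle(shuffled)
        assert cost(truth, shuffled, registry) == cost(truth, exact, registry)

    def test_unmappable_observation_names_the_row(self, truth):
        stray = fd.AdductObservation("NoSuchStudy2020", 1.0, 7.0, "exogDG", 1e-4)
        with pytest.raises(ValueError, match="NoSuchStudy2020"):
            cost(truth, [stray], TABLE1_PROTOCOLS)

    def test_below_lod_and_dpc_rows_excluded(self, truth):
        """Only the monoadduct and whole-DNA crosslink data enter the cost; the
        dG-specific crosslink rows and non-detects are fixtures."""
        obs = fd.load_observations(study=("Leng2019", "Moeller2011"))
        with pytest.raises(ValueError):
            # nothing fittable remains, so selection must come up empty
            fit(FitSpec(free=(), bounds={}, studies=("Leng2019",)), obs)

    def test_log_residual_variant(self, truth, recovery_setup):
        protocols, registry, exact = recovery_setup
        halved = [
            fd.AdductObservation(o.study, o.ppm, o.time_h, o.species, o.value / 2.0)
            for o in exact
        ]
        expected = len(halved) * np.log(2.0) ** 2
        assert cost(truth, halved, registry, residual="log") == pytest.approx(
            expected, rel=1e-9
        )


class TestFit:
    def test_empty_free_set_returns_initial(self, truth, recovery_setup):
        protocols, registry, exact = recovery_setup
        spec = FitSpec(
            free=(), bounds={}, initial=truth,
            studies=tuple(p.label for p in protocols), rtol=RTOL_FAST,
        )
        res = fit(spec, exact, registry)
        assert res.params == truth
        assert res.final_cost == res.initial_cost
        assert res.converged

    def test_descent_and_single_parameter_recovery(self, truth, recovery_setup):
        protocols, registry, exact = recovery_setup
        start = truth.replace(thick=1.4 * truth.thick)
        spec = FitSpec(
            free=("thick",), bounds={"thick": (0.05, 0.25)}, initial=start,
            studies=tuple(p.label for p in protocols), rtol=RTOL_FAST, max_iter=80,
        )
        res = fit(spec, exact, registry)
        assert res.final_cost <= res.initial_cost
        assert 0.05 < res.params.thick < 0.25
        assert res.params.thick == pytest.approx(truth.thick, rel=0.05)

    def test_initial_outside_bounds_rejected(self, truth):
        with pytest.raises(ValueError):
            FitSpec(free=("thick",), bounds={"thick": (0.2, 0.25)}, initial=truth)


class TestSyntheticObservations:
    def test_zero_noise_equals_model_predictions(self, truth, recovery_setup):
        protocols, registry, exact = recovery_setup
        table = fd.predictions(truth, exact, registry)
        assert np.allclose(table["observed"], table["predicted"], rtol=1e-9)

    def test_same_seed_reproduces_dataset(self, truth, recovery_setup):
        protocols, _, _ = recovery_setup
        a = generate_synthetic_observations(truth, protocols, 0.2, seed=11, rtol=RTOL_FAST)
        b = generate_synthetic_observations(truth, protocols, 0.2, seed=11, rtol=RTOL_FAST)
        c = generate_synthetic_observations(truth, protocols, 0.2, seed=12, rtol=RTOL_FAST)
        assert [o.value for o in a] == [o.value for o in b]
        assert [o.value for o in a] != [o.value for o in c]

    def test_noise_is_multiplicative_lognormal(self, truth, recovery_setup):
        protocols, _, exact = recovery_setup
        noisy = generate_synthetic_observations(truth, protocols, 0.3, seed=5, rtol=RTOL_FAST)
        logratio = np.log([n.value / e.value for n, e in zip(noisy, exact)])
        sigma = np.sqrt(np.log1p(0.3**2))
        assert np.all(np.isfinite(logratio))
        # median-unbiased: log-ratios scatter around zero at the expected scale
        assert abs(np.mean(logratio)) < 3 * sigma / np.sqrt(len(logratio))


class TestTwoStageFit:
    def test_stage2_thick_brackets_truth_on_noisy_synthetic_data(
        self, truth, recovery_setup
    ):
        protocols, registry, _ = recovery_setup
        noisy = generate_synthetic_observations(
            truth, protocols, noise_cv=0.15, seed=42, rtol=RTOL_FAST
        )
        dg_labels = tuple(p.label for p in protocols if p.site is fd.DG_SITE)
        dpx_labels = tuple(p.label for p in protocols if p.site is fd.DPX_SITE)
        start = truth.replace(thick=1.3 * truth.thick)
        stage1, stage2 = two_stage_fit(
            noisy, free=("thick",), initial=start, registry=registry,
            dg_studies=dg_labels, dpx_studies=dpx_labels,
            rtol=RTOL_FAST, max_iter=80,
        )
        assert 0.05 < stage2.params.thick < 0.25
        assert stage2.params.thick == pytest.approx(truth.thick, rel=0.25)
        # a shared thick cannot beat the two per-site optima combined
        total_stage1 = stage1["DG"].final_cost + stage1["DPX"].final_cost
        assert stage2.final_cost >= total_stage1 * (1 - 1e-6)

    def test_duplicated_datasets_give_matching_stage1_estimates(
        self, truth, recovery_setup
    ):
        protocols, registry, exact = recovery_setup
        dg_labels = tuple(p.label for p in protocols if p.site is fd.DG_SITE)
        start = truth.replace(thick=1.2 * truth.thick)
        stage1, _ = two_stage_fit(
            exact, free=("thick",), initial=start, registry=registry,
            dg_studies=dg_labels, dpx_studies=dg_labels,
            rtol=RTOL_FAST, max_iter=40,
        )
        assert stage1["DG"].params.thick == pytest.approx(
            stage1["DPX"].params.thick, rel=0.01
        )
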