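import itertools
import math

import numpy as np
import pytest

from repsecr import (
    CaptureData,
    DetectionParams,
    Detector,
    DetectorArray,
    ModelSpec,
    build_mask,
    conditional_nll,
    effective_area,
    fit_array,
    fit_pooled,
    half_normal_g,
    history_prob,
    p_dot,
)
from repsecr.simulate import Band, Region, ScenarioSpec, make_scenario, sample_population, simulate_captures
from repsecr.study import simulate_iteration


def brute_force_nll(theta_link, data, array, mask):
    """Naive double-loop conditional likelihood, independent of the package
    internals: per-cell, per-occasion, per-detector products throughout."""
    params = DetectionParams.from_link(np.asarray(theta_link))
    S, K = array.n_occasions, array.n_detectors
    cells = mask.cell_centers
    # effective area by the same naive loop
    a = 0.0
    for cx, cy in cells:
        surv = 1.0
        for s in range(S):
            for k, det in enumerate(array.detectors):
                d = math.hypot(cx - det.x, cy - det.y)
                surv *= 1.0 - params.g0 * math.exp(-(d**2) / (2 * params.sigma**2))
        a += (1.0 - surv) * mask.cell_area
    nll = 0.0
    for i in range(data.n):
        integral = 0.0
        for cx, cy in cells:
            pr = 1.0
            for s in range(S):
                for k, det in enumerate(array.detectors):
                    d = math.hypot(cx - det.x, cy - det.y)
                    g = params.g0 * math.exp(-(d**2) / (2 * params.sigma**2))
                    pr *= g if data.omega[i, s, k] else 1.0 - g
            integral += pr * mask.cell_area
        nll -= math.log(integral / a)
    return nll


class TestHistoryProb:
    def test_single_detection_at_detector(self):
        arr = DetectorArray(
            "a", (Detector("d1", 0.0, 0.0), Detector("d2", 1e6, 0.0)), n_occasions=1
        )
        om = np.array([[1, 0]])
        p = history_prob((0.0, 0.0), om, arr, DetectionParams(0.3, 1500.0))
        assert p == pytest.approx(0.3, abs=1e-12)

    def test_detection_then_miss(self):
        arr = DetectorArray(
            "a", (Detector("d1", 0.0, 0.0), Detector("d2", 1e6, 0.0)), n_occasions=2
        )
        om = np.array([[1, 0], [0, 0]])
        p = history_prob((0.0, 0.0), om, arr, DetectionParams(0.3, 1500.0))
        assert p == pytest.approx(0.3 * 0.7, abs=1e-12)

    def test_all_zero_history_rejected(self, toy_array, toy_params):
        with pytest.raises(ValueError):
            history_prob((0.0, 0.0), np.zeros((2, 2)), toy_array, toy_params)

    def test_histories_sum_to_p_dot(self, toy_array, toy_params):
        # exhaustive enumeration over all 2^(S*K) - 1 = 15 nonzero histories
        x = (250.0, 400.0)
        total = 0.0
        for bits in itertools.product([0, 1], repeat=4):
            if not any(bits):
                continue
            om = np.array(bits).reshape(2, 2)
            total += history_prob(x, om, toy_array, toy_params)
        assert total == pytest.approx(p_dot(x, toy_array, toy_params), abs=1e-12)


class TestConditionalNll:
    def test_matches_brute_force_oracle(self, toy_array, toy_mask, toy_captures):
        theta = DetectionParams(0.25, 700.0).to_link()
        ours = conditional_nll(theta, toy_captures, toy_array, toy_mask)
        oracle = brute_force_nll(theta, toy_captures, toy_array, toy_mask)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_additive_in_animals(self, toy_array, toy_mask, toy_captures):
        theta = DetectionParams(0.3, 800.0).to_link()
        doubled = CaptureData(
            array_id="toy",
            individuals=tuple(toy_captures.individuals) + tuple(f"{i}'" for i in toy_captures.individuals),
            omega=np.concatenate([toy_captures.omega, toy_captures.omega]),
        )
        one = conditional_nll(theta, toy_captures, toy_array, toy_mask)
        two = conditional_nll(theta, doubled, toy_array, toy_mask)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_invariant_to_individual_and_occasion_permutation(
        self, toy_array, toy_mask, toy_captures
    ):
        theta = DetectionParams(0.3, 800.0).to_link()
        base = conditional_nll(theta, toy_captures, toy_array, toy_mask)
        perm = CaptureData(
            array_id="toy",
            individuals=toy_captures.individuals[::-1],
            omega=toy_captures.omega[::-1, ::-1, :],
        )
        assert conditional_nll(theta, perm, toy_array, toy_mask) == pytest.approx(
            base, rel=1e-12
        )

    def test_nonfinite_parameters_rejected(self, toy_array, toy_mask, toy_captures):
        with pytest.raises(ValueError):
            conditional_nll(np.array([np.nan, 7.0]), toy_captures, toy_array, toy_mask)


class TestEffectiveArea:
    def test_vanishes_with_g0(self, toy_array, toy_mask):
        a, _ = effective_area(DetectionParams(1e-6, 800.0), toy_array, toy_mask)
        assert a < 1e-4

    def test_monotone_in_parameters(self, toy_array, toy_mask):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g0, sig = rng.uniform(0.05, 0.6), rng.uniform(300, 1500)
            a0, _ = effective_area(DetectionParams(g0, sig), toy_array, toy_mask)
            a1, _ = effective_area(DetectionParams(g0 * 1.2, sig), toy_array, toy_mask)
            a2, _ = effective_area(DetectionParams(g0, sig * 1.2), toy_array, toy_mask)
            assert a1 > a0 and a2 > a0

    def test_agrees_with_finer_quadrature(self):
        array = make_scenario(1).design[0]
        p = DetectionParams(0.30, 1500.0)
        coarse = build_mask(array, 6000.0, 750.0)
        fine = build_mask(array, 6000.0, 150.0)
        a_c, _ = effective_area(p, array, coarse)
        a_f, _ = effective_area(p, array, fine)
        assert a_c == pytest.approx(a_f, rel=0.005)

    def test_gradient_positive(self, toy_array, toy_mask):
        _, grad = effective_area(DetectionParams(0.3, 800.0), toy_array, toy_mask)
        assert (grad > 0).all()


def _dense_single_array_spec(density, sigma=1500.0, g0=0.3):
    array = make_scenario(1).design[0]
    band = Band("whole", 0.0, 300e3, density, DetectionParams(g0, sigma))
    region = Region(200e3, 300e3, (band,))
    return ScenarioSpec(scenario_id=1, region=region, design=(array,), n_occasions=6)


class TestFitArray:
    @pytest.mark.parametrize("density", [30.0, 60.0])
    def test_parameter_recovery_within_3_se(self, density):
        # detection-parameter MLEs do not depend on the (unmodelled) density
        # level: recovery holds at both densities, precision differs
        spec = _dense_single_array_spec(density)
        pop = sample_population(spec, 100 + int(density))
        data = simulate_captures(pop, spec, seed=200 + int(density))[0]
        fit = fit_array(data, spec.design[0])
        assert fit.converged
        th = fit.theta[spec.design[0].array_id]
        se = np.sqrt(np.diag(fit.vcov_link))
        true_link = DetectionParams(0.3, 1500.0).to_link()
        assert abs(fit.params_link[0] - true_link[0]) < 3 * se[0]
        assert abs(fit.params_link[1] - true_link[1]) < 3 * se[1]
        assert fit.D_local == pytest.approx(density, rel=0.35)
        assert th.g0 > 0 and th.sigma > 0

    def test_zero_spatial_recaptures_is_failure(self):
        array = make_scenario(1).design[0]
        omega = np.zeros((6, 6, 40), dtype=np.int8)
        for i in range(6):
            omega[i, 0, i] = 1  # six animals, one detection each
        data = CaptureData(array.array_id, tuple("abcdef"), omega)
        res = fit_array(data, array)
        assert not res.converged
        assert "spatial recaptures" in res.message
        assert math.isnan(res.D_local)

    def test_too_few_animals_is_failure(self):
        array = make_scenario(1).design[0]
        omega = np.zeros((2, 6, 40), dtype=np.int8)
        omega[0, 0, 0] = omega[0, 1, 1] = 1
        omega[1, 0, 5] = omega[1, 2, 6] = 1
        data = CaptureData(array.array_id, ("a", "b"), omega)
        res = fit_array(data, array)
        assert not res.converged and "n=2" in res.message

    def test_variance_identities(self):
        spec = _dense_single_array_spec(40.0)
        pop = sample_population(spec, 7)
        data = simulate_captures(pop, spec, seed=8)[0]
        fit = fit_array(data, spec.design[0])
        assert fit.converged
        # var(D) = D^2 (1/n + var(a)/a^2); forcing var(a)=0 leaves D^2/n
        expected = fit.D_local**2 * (1 / fit.n + fit.var_a_total / fit.a_total**2)
        assert fit.var_D_local == pytest.approx(expected, rel=1e-12)
        assert fit.aicc == pytest.approx(
            -2 * fit.loglik + 4 + 12 / (fit.n - 3), rel=1e-12
        )

    def test_delta_method_variance_matches_parametric_bootstrap(self):
        spec = _dense_single_array_spec(30.0)
        pop = sample_population(spec, 21)
        data = simulate_captures(pop, spec, seed=22)[0]
        fit = fit_array(data, spec.design[0])
        assert fit.converged
        rng = np.random.default_rng(5)
        draws = rng.multivariate_normal(fit.params_link, fit.vcov_link, size=200)
        mask = fit.masks[spec.design[0].array_id]
        areas = [
            effective_area(DetectionParams.from_link(t), spec.design[0], mask)[0]
            for t in draws
        ]
        boot = np.var(areas, ddof=1)
        assert abs(fit.var_a_total - boot) / boot < 0.25


class TestFitPooled:
    def test_duplicated_data_matches_single_fit(self):
        spec = _dense_single_array_spec(30.0)
        array = spec.design[0]
        pop = sample_population(spec, 31)
        data = simulate_captures(pop, spec, seed=32)[0]
        single = fit_array(data, array)
        # a far-away clone of the same array with a copy of the same data
        clone = DetectorArray(
            "clone",
            tuple(Detector(d.id, d.x + 5e5, d.y) for d in array.detectors),
            array.n_occasions,
        )
        data2 = CaptureData("clone", data.individuals, data.omega.copy())
        pooled = fit_pooled([data, data2], [array, clone], ModelSpec(sharing="pooled_constant"))
        assert pooled.converged and single.converged
        th_s, th_p = single.theta[array.array_id], pooled.theta[array.array_id]
        assert th_p.g0 == pytest.approx(th_s.g0, rel=1e-4)
        assert th_p.sigma == pytest.approx(th_s.sigma, rel=1e-4)
        assert pooled.D_local == pytest.approx(single.D_local, rel=1e-3)

    def test_interactive_pooling_equals_independent_fits(self):
        spec = make_scenario(1)
        caps = simulate_iteration(spec, 3, 1)
        arrays, data = list(spec.design)[:2], list(caps)[:2]
        independent = [fit_array(d, a) for d, a in zip(data, arrays)]
        joint = fit_pooled(data, arrays, ModelSpec(sharing="pooled_interactive"))
        assert joint.converged
        for a, f in zip(arrays, independent):
            assert f.converged
            ti, tj = f.theta[a.array_id], joint.theta[a.array_id]
            assert tj.g0 == pytest.approx(ti.g0, rel=1e-4)
            assert tj.sigma == pytest.approx(ti.sigma, rel=1e-4)
            assert joint.a_by_array[a.array_id] == pytest.approx(
                f.a_total, rel=1e-4
            )
        assert joint.n_params == 4

    def test_additive_offsets_parameter_count(self):
        spec = make_scenario(1)
        caps = simulate_iteration(spec, 3, 2)
        arrays, data = list(spec.design)[:2], list(caps)[:2]
        res = fit_pooled(data, arrays, ModelSpec(sharing="pooled_additive"))
        assert res.converged
        assert res.n_params == 4  # base (2) + one offset pair for the 2nd array

    def test_requires_two_arrays(self, toy_array, toy_captures):
        with pytest.raises(ValueError):
            fit_pooled([toy_captures], [toy_array], ModelSpec(sharing="pooled_constant"))
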