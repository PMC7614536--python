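"""Kinetic model: rate terms, mass balances, steady states, parametrisation.

Oracles are kept independent of the implementation: the rate laws are
transcribed a second time as plain lambdas, the ODE right-hand sides are
rebuilt as stoichiometry-matrix x rate-vector products, and the closed-form
steady state is checked against long-horizon numerical integration.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_full_params
from vitdmet.kinetic_model import (
    FullState,
    IntegrationError,
    KineticModelError,
    ReducedParams,
    ReducedState,
    full_ode_rhs,
    full_rate_terms,
    halflife_from_rate,
    integrate,
    rate_from_halflife,
    reduce_full_params,
    reduced_ode_rhs,
    reduced_rate_terms,
    reduced_steady_state,
)
from vitdmet.simulate import random_reduced_params

# --- independent transcriptions of the reaction rate laws -------------------

FULL_RATE_ORACLE = {
    "R1": lambda s, p: p.P25,
    "R2": lambda s, p: p.a * s.c25 / (p.K + s.c25),
    "R3": lambda s, p: p.k3 * s.c25,
    "R4": lambda s, p: p.V4 * s.cEnz * s.c25,
    "R5": lambda s, p: p.k5 * s.c25,
    "R6": lambda s, p: p.k6 * s.c2425,
    "R7": lambda s, p: p.V7 * s.cEnz * s.c125,
    "R8": lambda s, p: p.k8 * s.cEpi25,
    "R9": lambda s, p: p.k9 * s.c125,
    "R10": lambda s, p: p.k10 * s.c125,
    "R11": lambda s, p: p.k11 * s.cEpi125,
    "R12": lambda s, p: p.k12 * s.c125,
    "R13": lambda s, p: p.p24,
    "R14": lambda s, p: p.k14 * s.cEnz,
}

REDUCED_RATE_ORACLE = {
    "R1": lambda s, p: p.P25,
    "R2": lambda s, p: p.a * s.c25 / (p.K + s.c25),
    "R3": lambda s, p: p.k3 * s.c25,
    "R4": lambda s, p: p.k4 * s.c25,
    "R5": lambda s, p: p.k5 * s.c25,
    "R6": lambda s, p: p.k6 * s.c2425,
    "R7": lambda s, p: p.k7 * s.c125,
    "R8": lambda s, p: p.k8 * s.cEpi25,
}

# stoichiometry of the mass balances, one row per species
FULL_SIGNS = np.array(
    [
        # R1 R2 R3 R4 R5 R6 R7 R8 R9 R10 R11 R12 R13 R14
        [1, -1, -1, -1, -1, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # c25
        [0, 1, 0, 0, 0, 0, -1, 0, -1, -1, 0, 0, 0, 0],  # c125
        [0, 0, 0, 1, 0, -1, 0, 0, 0, 0, 0, 0, 0, 0],  # c2425
        [0, 0, 1, 0, 0, 0, 0, -1, 0, 0, 0, 0, 0, 0],  # cEpi25
        [0, 0, 0, 0, 0, 0, 0, 1, 0, 1, -1, 0, 0, 0],  # cEpi125
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, -1],  # cEnz
    ]
)
REDUCED_SIGNS = np.array(
    [
        [1, -1, -1, -1, -1, 0, 0, 0],
        [0, 1, 0, 0, 0, 0, -1, 0],
        [0, 0, 0, 1, 0, -1, 0, 0],
        [0, 0, 1, 0, 0, 0, 0, -1],
    ]
)


def random_full_state(rng):
    return FullState(*np.exp(rng.uniform(np.log(0.01), np.log(200.0), size=6)))


def random_reduced_state(rng):
    return ReducedState(*np.exp(rng.uniform(np.log(0.01), np.log(200.0), size=4)))


class TestRateTerms:
    def test_full_rates_match_independent_transcription(self, rng):
        for _ in range(50):
            state, params = random_full_state(rng), random_full_params(rng)
            rates = full_rate_terms(state, params)
            for name, oracle in FULL_RATE_ORACLE.items():
                assert rates[name] == pytest.approx(oracle(state, params), rel=1e-12)
                assert rates[name] >= 0.0

    def test_reduced_rates_match_independent_transcription(self, rng):
        for _ in range(50):
            state, params = random_reduced_state(rng), random_reduced_params(rng)
            rates = reduced_rate_terms(state, params)
            for name, oracle in REDUCED_RATE_ORACLE.items():
                assert rates[name] == pytest.approx(oracle(state, params), rel=1e-12)

    def test_zero_state_leaves_only_production_terms(self, rng):
        fp = random_full_params(rng)
        rates = full_rate_terms(FullState(0, 0, 0, 0, 0, 0), fp)
        assert rates["R1"] == fp.P25 and rates["R13"] == fp.p24
        assert all(v == 0.0 for k, v in rates.items() if k not in ("R1", "R13"))
        rp = random_reduced_params(rng)
        rrates = reduced_rate_terms(ReducedState(0, 0, 0, 0), rp)
        assert rrates["R1"] == rp.P25
        assert all(v == 0.0 for k, v in rrates.items() if k != "R1")

    def test_michaelis_menten_half_saturation_and_limit(self, rng):
        p = random_reduced_params(rng)
        at_K = reduced_rate_terms(ReducedState(p.K, 1, 1, 1), p)["R2"]
        assert at_K == pytest.approx(p.a / 2.0, rel=1e-12)
        saturated = reduced_rate_terms(ReducedState(1e6 * p.K, 1, 1, 1), p)["R2"]
        assert saturated == pytest.approx(p.a, rel=1e-4)

    def test_r10_variant_uses_2425_species(self, rng):
        state, params = random_full_state(rng), random_full_params(rng)
        default = full_rate_terms(state, params)
        literal = full_rate_terms(state, params, r10_from_2425=True)
        assert default["R10"] == pytest.approx(params.k10 * state.c125)
        assert literal["R10"] == pytest.approx(params.k10 * state.c2425)
        assert all(default[k] == literal[k] for k in default if k != "R10")

    def test_negative_state_rejected(self, rng):
        with pytest.raises(KineticModelError):
            full_rate_terms([-1, 1, 1, 1, 1, 1], random_full_params(rng))


class TestRightHandSides:
    def test_full_rhs_is_signs_times_rates(self, rng):
        for _ in range(25):
            state, params = random_full_state(rng), random_full_params(rng)
            rates = np.array(list(full_rate_terms(state, params).values()))
            np.testing.assert_allclose(
                full_ode_rhs(state, params), FULL_SIGNS @ rates, rtol=1e-12
            )

    def test_reduced_rhs_is_signs_times_rates(self, rng):
        for _ in range(25):
            state, params = random_reduced_state(rng), random_reduced_params(rng)
            rates = np.array(list(reduced_rate_terms(state, params).values()))
            np.testing.assert_allclose(
                reduced_ode_rhs(state, params), REDUCED_SIGNS @ rates, rtol=1e-12
            )

    def test_zero_state_rhs_is_pure_production(self, rng):
        fp = random_full_params(rng)
        np.testing.assert_array_equal(
            full_ode_rhs(FullState(0, 0, 0, 0, 0, 0), fp),
            [fp.P25, 0, 0, 0, 0, fp.p24],
        )
        rp = random_reduced_params(rng)
        np.testing.assert_array_equal(
            reduced_ode_rhs(ReducedState(0, 0, 0, 0), rp), [rp.P25, 0, 0, 0]
        )

    def test_2425_balance_identity(self, rng):
        state, params = random_full_state(rng), random_full_params(rng)
        rates = full_rate_terms(state, params)
        d2425 = full_ode_rhs(state, params)[2]
        assert d2425 + rates["R6"] - rates["R4"] == pytest.approx(0.0, abs=1e-12)

    def test_rhs_vanishes_at_steady_state(self, rng):
        for _ in range(25):
            p = random_reduced_params(rng)
            ss = reduced_steady_state(p)
            rhs = reduced_ode_rhs(ReducedState(*ss.as_array()), p)
            np.testing.assert_allclose(rhs, 0.0, atol=1e-10 * p.P25)


class TestSteadyState:
    def test_a_zero_closed_form(self, rng):
        for _ in range(100):
            p = random_reduced_params(rng)
            p = ReducedParams(**{**p.__dict__, "a": 0.0})
            ss = reduced_steady_state(p)
            s = p.k3 + p.k4 + p.k5
            assert ss.c25 == pytest.approx(p.P25 / s, rel=1e-10)

    def test_p25_zero_gives_empty_system(self, rng):
        p = random_reduced_params(rng)
        p = ReducedParams(**{**p.__dict__, "P25": 0.0})
        ss = reduced_steady_state(p)
        np.testing.assert_array_equal(ss.as_array(), 0.0)

    def test_downstream_species_follow_closed_forms(self, rng):
        for _ in range(50):
            p = random_reduced_params(rng)
            ss = reduced_steady_state(p)
            x = ss.c25
            assert ss.c125 == pytest.approx((p.a / p.k7) * x / (p.K + x), rel=1e-12)
            assert ss.c2425 == pytest.approx((p.k4 / p.k6) * x, rel=1e-12)
            assert ss.cEpi25 == pytest.approx((p.k3 / p.k8) * x, rel=1e-12)

    def test_matches_long_horizon_integration(self, rng):
        for _ in range(5):
            p = random_reduced_params(rng)
            ss = reduced_steady_state(p)
            horizon = 40.0 / min(p.k3 + p.k4 + p.k5, p.k6, p.k7, p.k8)
            traj = integrate(
                "reduced", p, np.zeros(4), [0.0, horizon], rtol=1e-10, atol=1e-12
            )
            np.testing.assert_allclose(traj.terminal(), ss.as_array(), rtol=1e-6)

    def test_example_params_integration(self):
        p = ReducedParams(P25=10, a=5, K=20, k3=0.3, k4=0.2, k5=0.1, k6=0.5, k7=2.0, k8=0.4)
        ss = reduced_steady_state(p)
        traj = integrate("reduced", p, np.zeros(4), [0.0, 200.0], rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(traj.terminal(), ss.as_array(), rtol=1e-6)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_quadratic_has_unique_nonnegative_root(self, seed):
        p = random_reduced_params(np.random.default_rng(seed))
        s = p.k3 + p.k4 + p.k5
        roots = np.roots([s, p.K * s + p.a - p.P25, -p.K * p.P25])
        nonneg = roots[roots >= -1e-12 * max(1.0, abs(roots).max())]
        assert len(nonneg) == 1
        assert reduced_steady_state(p).c25 == pytest.approx(
            float(nonneg[0].real), rel=1e-9, abs=1e-12
        )

    def test_stable_when_p25_dominates_a(self):
        # cancellation regime: P25 >> a
        p = ReducedParams(P25=1e8, a=1e-6, K=10.0, k3=1, k4=1, k5=1, k6=1, k7=1, k8=1)
        ss = reduced_steady_state(p)
        # here x ~ P25/s since the saturable sink is negligible
        assert ss.c25 == pytest.approx(p.P25 / 3.0, rel=1e-6)

    def test_monotone_in_p25_and_a(self):
        base = dict(a=1.0, K=20.0, k3=0.1, k4=0.1, k5=0.1, k6=0.5, k7=1.0, k8=0.5)
        c25s = [reduced_steady_state(ReducedParams(P25=P, **base)).c25 for P in (1, 2, 5, 10)]
        assert np.all(np.diff(c25s) > 0)
        base2 = dict(P25=5.0, K=20.0, k3=0.1, k4=0.1, k5=0.1, k6=0.5, k7=1.0, k8=0.5)
        c25a = [reduced_steady_state(ReducedParams(a=a, **base2)).c25 for a in (0.1, 1, 5, 20)]
        assert np.all(np.diff(c25a) < 0)

    def test_linear_in_p25_when_a_zero(self):
        base = dict(a=0.0, K=20.0, k3=0.1, k4=0.2, k5=0.3, k6=0.5, k7=1.0, k8=0.5)
        ss1 = reduced_steady_state(ReducedParams(P25=2.0, **base)).as_array()
        ss3 = reduced_steady_state(ReducedParams(P25=6.0, **base)).as_array()
        np.testing.assert_allclose(ss3, 3.0 * ss1, rtol=1e-12)

    def test_no_finite_steady_state_error(self):
        # k-rates may be zero individually, but s = 0 with a <= P25 blows up;
        # the parameter container itself already rejects s = 0
        with pytest.raises(KineticModelError):
            ReducedParams(P25=1.0, a=0.0, K=10.0, k3=0, k4=0, k5=0, k6=1, k7=1, k8=1)


class TestIntegrate:
    def test_empty_system_stays_zero(self):
        p = ReducedParams(P25=0.0, a=1.0, K=10.0, k3=0.1, k4=0.1, k5=0.1, k6=1, k7=1, k8=1)
        traj = integrate("reduced", p, np.zeros(4), np.linspace(0, 50, 20))
        np.testing.assert_array_equal(traj.states, 0.0)

    def test_step_halving_self_consistency(self, rng):
        p = random_reduced_params(rng)
        grid = np.linspace(0.0, 30.0, 31)
        t1 = integrate("reduced", p, np.zeros(4), grid, rtol=1e-8)
        t2 = integrate("reduced", p, np.zeros(4), np.linspace(0.0, 30.0, 61), rtol=1e-8)
        np.testing.assert_allclose(t1.terminal(), t2.terminal(), rtol=1e-7, atol=1e-10)

    def test_nonnegativity_from_nonnegative_start(self, rng):
        for _ in range(5):
            p = random_reduced_params(rng)
            y0 = np.exp(rng.uniform(np.log(0.1), np.log(100.0), 4))
            traj = integrate("reduced", p, y0, np.linspace(0, 100, 50))
            assert np.all(traj.states >= 0.0)

    def test_full_model_nonnegativity(self, rng):
        p = random_full_params(rng)
        traj = integrate("full", p, np.zeros(6), np.linspace(0, 50, 25))
        assert np.all(traj.states >= 0.0)

    def test_bad_inputs_rejected(self, rng):
        p = random_reduced_params(rng)
        with pytest.raises(KineticModelError):
            integrate("reduced", p, np.zeros(4), [1.0, 0.5])
        with pytest.raises(KineticModelError):
            integrate("reduced", p, -np.ones(4), [0.0, 1.0])
        with pytest.raises(KineticModelError):
            integrate("sideways", p, np.zeros(4), [0.0, 1.0])


class TestParametrisation:
    def test_rate_from_halflife_values(self):
        assert rate_from_halflife(math.log(2.0)) == pytest.approx(1.0, rel=1e-12)
        assert rate_from_halflife(1.0) == pytest.approx(0.6931471805599453, rel=1e-12)
        with pytest.raises(KineticModelError):
            rate_from_halflife(0.0)
        with pytest.raises(KineticModelError):
            rate_from_halflife(-2.0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_halflife_rate_inverse_pair(self, k):
        assert rate_from_halflife(halflife_from_rate(k)) == pytest.approx(k, rel=1e-12)

    def test_reduce_full_params_mapping(self, rng):
        fp = random_full_params(rng)
        red = reduce_full_params(fp, 0.0)
        assert red.k4 == 0.0 and red.k7 == pytest.approx(fp.k9 + fp.k10)
        fp2 = random_full_params(rng)
        fp2 = type(fp2)(**{**fp2.__dict__, "V4": 1.0})
        assert reduce_full_params(fp2, 2.0).k4 == pytest.approx(2.0)
        for key in ("P25", "a", "K", "k3", "k5", "k6", "k8"):
            assert getattr(reduce_full_params(fp, 3.0), key) == getattr(fp, key)

    def test_clamped_enzyme_full_model_equals_reduced(self, rng):
        """With 24-hydroxylase frozen, the full model restricted to the four
        measured species is exactly the reduced model under the parameter map."""
        for _ in range(3):
            fp = random_full_params(rng, no_enzyme_dynamics=True)
            enzyme = float(np.exp(rng.uniform(np.log(0.5), np.log(20.0))))
            red = reduce_full_params(fp, enzyme)
            y0_shared = np.exp(rng.uniform(np.log(0.1), np.log(50.0), 4))
            grid = np.linspace(0.0, 60.0, 40)
            # shared species order: c25, c125, c2425, cEpi25
            y0_full = np.array([*y0_shared, 0.0, enzyme])
            tf = integrate("full", fp, y0_full, grid, rtol=1e-10, atol=1e-12)
            tr = integrate("reduced", red, y0_shared, grid, rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(
                tf.states[:, :4], tr.states, rtol=1e-6, atol=1e-9
            )
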