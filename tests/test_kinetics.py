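"""Markov scheme construction, propagation, and kinetic readouts."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from statenav.inference import AvailabilityCurve, fit_boltzmann
from statenav.kinetics import (
    DrugParams,
    GatingParams,
    KineticScheme,
    VoltageProtocol,
    build_scheme,
    protocol_availability_curve,
    relative_current_after_application,
    simulate_protocol,
    slowly_recovering_fraction,
    steady_state_availability_curve,
)
from statenav.model import BoltzmannParams, StateBindingModel, boltzmann_availability, coupled_shift

from conftest import random_scheme


def two_state(a: float, b: float) -> KineticScheme:
    return KineticScheme(
        ("R", "IF"),
        {("R", "IF"): lambda v, d: a, ("IF", "R"): lambda v, d: b},
    )


class TestPropagation:
    @pytest.mark.parametrize("mult", [1.0, 5.0])
    def test_two_state_closed_form_relaxation(self, mult):
        # R(t) = b/(a+b) + a/(a+b) * exp(-(a+b) t), starting all-R
        a, b = 0.37, 0.12
        tau = 1.0 / (a + b)
        t = mult * tau
        proto = VoltageProtocol(epochs=((0.0, t),), measure_epochs=(0,))
        traj = simulate_protocol(two_state(a, b), proto, initial=np.array([1.0, 0.0]))
        expected = b / (a + b) + a / (a + b) * math.exp(-(a + b) * t)
        assert traj.readouts[0][1] == pytest.approx(expected, abs=1e-12)

    def test_zero_duration_is_identity(self, default_scheme):
        p0 = default_scheme.steady_state(-100.0, 300.0)
        proto = VoltageProtocol(epochs=((-40.0, 0.0),), measure_epochs=(0,))
        traj = simulate_protocol(default_scheme, proto, 300.0, initial=p0)
        assert np.abs(traj.final() - p0).max() < 1e-9

    def test_occupancy_conserved_on_random_schemes(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            scheme = random_scheme(rng)
            proto = VoltageProtocol(
                epochs=((-100.0, 50.0), (-40.0, 300.0), (-100.0, 1000.0)),
                measure_epochs=(2,),
            )
            traj = simulate_protocol(scheme, proto, 300.0, sample_dt=25.0)
            sums = traj.occupancy.sum(axis=1)
            assert np.abs(sums - 1.0).max() < 1e-9
            assert traj.occupancy.min() > -1e-12

    def test_matrix_exponential_matches_fine_step_integrator(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            scheme = random_scheme(rng)
            v, d, t = -60.0, 200.0, 500.0
            q = scheme.rate_matrix(v, d)
            p0 = scheme.steady_state(-100.0, d)
            proto = VoltageProtocol(epochs=((v, t),))
            p_exp = simulate_protocol(scheme, proto, d, initial=p0).final()
            sol = solve_ivp(
                lambda _, p: q.T @ p, (0, t), p0, rtol=1e-11, atol=1e-12,
            )
            assert np.abs(p_exp - sol.y[:, -1]).max() < 1e-6

    def test_invalid_initial_occupancy_rejected(self, default_scheme):
        proto = VoltageProtocol(epochs=((-40.0, 1.0),))
        with pytest.raises(ValueError):
            simulate_protocol(default_scheme, proto, 0.0, initial=np.array([2.0, 0, 0, 0, 0, 0]))


class TestSchemeConstruction:
    def test_midpoint_by_construction(self, default_scheme):
        # the R<->IF equilibrium alone is half-and-half at v_half
        pi = default_scheme.steady_state(-75.2, 0.0)
        r, i_f = pi[0], pi[1]
        assert r / (r + i_f) == pytest.approx(0.5, abs=1e-6)

    def test_tau_anchors_reproduced(self):
        g = GatingParams()
        a0, delta = g.solve_barrier()
        for v, tau in g.tau_anchors:
            x = (v - g.v_half) / g.slope
            rate = a0 * math.exp(delta * x) * (1 + math.exp(-x))
            assert 1.0 / rate == pytest.approx(tau, rel=1e-12)

    def test_drug_free_reduction(self, default_scheme):
        # without drug the bound states are unreachable
        proto = VoltageProtocol(epochs=((-100.0, 0.0), (-40.0, 500.0)))
        traj = simulate_protocol(default_scheme, proto, 0.0)
        assert np.abs(traj.occupancy[:, 3:]).max() < 1e-12

    def test_zero_on_rate_steady_state_is_drug_free_boltzmann(self):
        scheme = build_scheme(drug=DrugParams(k_on=0.0))
        p0 = np.array([1.0, 0, 0, 0, 0, 0])
        volts = np.arange(-130.0, -15.0, 5.0)
        h = np.array(
            [scheme.availability(scheme.steady_state(v, 300.0, p0=p0)) for v in volts]
        )
        hb = boltzmann_availability(volts, BoltzmannParams(-75.2, 7.9))
        # small slow-inactivated occupancy is the only deviation
        assert np.abs(h / h.max() - hb).max() < 0.005

    def test_detailed_balance_at_equilibrium(self, default_scheme):
        for v in (-120.0, -75.0, -40.0):
            for d in (0.0, 300.0, 3000.0):
                assert default_scheme.detailed_balance_residual(v, d) < 1e-8

    def test_cycle_products_balance(self, default_scheme):
        for cyc, err in default_scheme.cycle_imbalance(-70.0, 300.0):
            assert err < 1e-8, cyc

    def test_inconsistent_rates_rejected_with_cycle_named(self):
        scheme = build_scheme()
        # break one drug-bound gating rate: detailed balance must fail
        scheme.rates[("IFD", "RD")] = lambda v, d: 1.0
        with pytest.raises(ValueError, match="cycle"):
            scheme.validate()

    def test_bad_gating_params_rejected(self):
        with pytest.raises(ValueError):
            GatingParams(slope=-1.0)
        with pytest.raises(ValueError):
            GatingParams(tau_anchors=((-40.0, -3.0), (-100.0, 2.0)))
        with pytest.raises(ValueError):
            DrugParams(kd_inact=-5.0)


class TestAvailabilityReadouts:
    def test_five_second_prepulse_reaches_boltzmann(self, default_scheme):
        volts = np.arange(-130.0, -15.0, 5.0)
        h = protocol_availability_curve(default_scheme, volts, 0.0)
        hb = boltzmann_availability(volts, BoltzmannParams(-75.2, 7.9))
        assert np.abs(h - hb / hb.max()).max() < 0.005

    def test_steady_state_midpoint_shift_matches_two_state_model(self, default_scheme):
        volts = np.arange(-130.0, -15.0, 2.5)
        fits = []
        for d in (0.0, 300.0):
            h = steady_state_availability_curve(default_scheme, volts, d)
            fit = fit_boltzmann(AvailabilityCurve(volts, h, drug_conc=d))
            assert fit.converged
            fits.append(fit.params.v_half)
        kinetic_shift = fits[1] - fits[0]
        analytic = coupled_shift(StateBindingModel(300.0, 360.0, 50.0, 7.9))
        assert kinetic_shift == pytest.approx(analytic, abs=0.1)

    def test_shift_grows_with_concentration(self, default_scheme):
        volts = np.arange(-130.0, -15.0, 5.0)
        mids = []
        for d in (0.0, 100.0, 300.0, 1000.0):
            h = steady_state_availability_curve(default_scheme, volts, d)
            mids.append(fit_boltzmann(AvailabilityCurve(volts, h)).params.v_half)
        assert np.all(np.diff(mids) < 0)


class TestSlowRecovery:
    def test_no_conditioning_equals_baseline_unavailability(self, default_scheme):
        frac = slowly_recovering_fraction(default_scheme, 300.0, conditioning_ms=0.0)
        p = default_scheme.steady_state(-100.0, 300.0)
        baseline = 1.0 - default_scheme.availability(p)
        # 100 ms at holding keeps the system at its holding equilibrium
        assert frac == pytest.approx(baseline, abs=5e-3)

    def test_drug_free_entry_at_20ms_is_minimal(self, default_scheme):
        assert slowly_recovering_fraction(default_scheme, 0.0, 20.0) < 0.05

    def test_drug_produces_large_slowly_recovering_pool(self, default_scheme):
        assert slowly_recovering_fraction(default_scheme, 300.0, 20.0) > 0.15

    def test_invalid_criterion_time(self, default_scheme):
        with pytest.raises(ValueError):
            slowly_recovering_fraction(default_scheme, 0.0, 20.0, criterion_time=0.0)


def test_two_minute_application_blocks_most_current(default_scheme):
    r = relative_current_after_application(default_scheme, 300.0, -70.0, 120_000.0)
    assert 0.2 < r < 0.4  # strong but incomplete block at 2 minutes


def test_protocol_validation():
    with pytest.raises(ValueError):
        VoltageProtocol(epochs=())
    with pytest.raises(ValueError):
        VoltageProtocol(epochs=((-40.0, -1.0),))
    with pytest.raises(ValueError):
        VoltageProtocol(epochs=((-40.0, 1.0),), measure_epochs=(3,))
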