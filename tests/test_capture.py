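"""Capture-time analytics vs Monte Carlo, optima and benefit/risk ratios."""

import math

import numpy as np
import pytest

from tcellsim import capture as cap
from tcellsim import geometry
from tcellsim.circulation import BodyConfig, TransitMode
from tcellsim.priming import PrimingParams


SI8 = PrimingParams.signal_integration(8.0, 1.0)


class TestProbRetainedPerVisit:
    def test_limits(self, default_ln):
        tiny = PrimingParams(contact_rate=1e-9, success_prob=1.0, required_contacts=1)
        assert cap.prob_retained_per_visit(tiny, TransitMode.stochastic(), default_ln) < 1e-6
        assert cap.prob_retained_per_visit(
            SI8, TransitMode.deterministic(1e5)
        ) == pytest.approx(1.0)

    def test_closed_form_z1(self, default_ln):
        """Probabilistic priming with z = 1: P = 1 - csch(1)."""
        mu = default_ln.tau_per_hour  # makes z = R*sqrt(mu/M) = 1
        p = PrimingParams(contact_rate=mu, success_prob=1.0, required_contacts=1)
        val = cap.prob_retained_per_visit(p, TransitMode.stochastic(), default_ln)
        assert val == pytest.approx(1 - 1 / math.sinh(1), abs=1e-9)
        assert val == pytest.approx(0.1491, abs=1e-4)

    def test_deterministic_poisson_tail(self):
        """P for n=8, mu=1/h, T=12 h equals the Poisson tail P(Pois(12) >= 8)."""
        from scipy.stats import poisson

        val = cap.prob_retained_per_visit(SI8, TransitMode.deterministic(12.0))
        assert val == pytest.approx(1 - poisson.cdf(7, 12.0), abs=1e-10)
        assert val == pytest.approx(0.9105, abs=5e-5)

    def test_closed_form_matches_monte_carlo_over_z(self, default_ln, rng):
        """Eq.-7 closed form within 0.01 of Monte Carlo across z in [0.1, 5]."""
        draws = geometry.sample_ln_transit(default_ln, rng, size=100_000)
        for z in (0.1, 0.5, 1.0, 2.0, 5.0):
            mu = z**2 * default_ln.tau_per_hour
            p = PrimingParams(contact_rate=mu, success_prob=1.0, required_contacts=1)
            analytic = cap.prob_retained_per_visit(p, TransitMode.stochastic(), default_ln)
            mc = np.mean(1.0 - np.exp(-mu * draws))
            assert abs(analytic - mc) < 0.01

    def test_numeric_integral_consistent_with_laplace(self, default_ln):
        """For n=1 the quadrature route must agree with the csch closed form."""
        mu = 0.3
        p1 = PrimingParams(contact_rate=mu, success_prob=1.0, required_contacts=1)
        closed = cap.prob_retained_per_visit(p1, TransitMode.stochastic(), default_ln)
        assert closed == pytest.approx(
            1.0 - geometry.ln_transit_laplace(mu, default_ln), abs=1e-9
        )


class TestExpectedCaptureTime:
    def test_no_failure_limit(self):
        """f=1, P~1: capture reduces to t0 + truncated retention mean."""
        scen = cap.CaptureScenario(
            dln_fraction=1.0,
            priming=PrimingParams.signal_integration(1.0, 50.0),
            transit=TransitMode.deterministic(5.0),
        )
        sol = cap.expected_capture_time(scen, t0=0.0, tau_b=3.0)
        assert sol.retention_prob == pytest.approx(1.0)
        assert sol.expected_failed_visits == pytest.approx(0.0, abs=1e-6)
        assert sol.expected_capture == pytest.approx(sol.theta)
        assert sol.theta == pytest.approx(1.0 / 50.0, rel=0.05)

    def test_components_n8(self):
        scen = cap.CaptureScenario(0.25, SI8, TransitMode.deterministic(12.0))
        sol = cap.expected_capture_time(scen, t0=0.0)
        assert sol.retention_prob == pytest.approx(0.9105, abs=1e-3)
        assert sol.expected_failed_visits == pytest.approx(
            (1 - 0.25 * 0.9105) / (0.25 * 0.9105), rel=1e-3
        )

    def test_zero_retention_flagged_infinite(self):
        scen = cap.CaptureScenario(
            0.25,
            PrimingParams(contact_rate=1e-300, success_prob=1.0, required_contacts=8),
            TransitMode.deterministic(1e-6),
        )
        sol = cap.expected_capture_time(scen, t0=0.0, tau_b=1.0)
        assert math.isinf(sol.expected_capture)

    def test_requires_deterministic_transit(self):
        scen = cap.CaptureScenario(0.25, SI8, TransitMode.stochastic())
        with pytest.raises(ValueError):
            cap.expected_capture_time(scen)

    @pytest.mark.parametrize(
        "f,n,t_det", [(10 / 39, 8.0, 12.0), (20 / 39, 2.0, 4.0), (4 / 39, 1.0, 24.0)]
    )
    def test_analytic_matches_monte_carlo(self, f, n, t_det):
        """Closed form within 10% of simulated capture across a parameter grid."""
        scen = cap.CaptureScenario(
            f, PrimingParams.signal_integration(n, 1.0), TransitMode.deterministic(t_det)
        )
        sol = cap.expected_capture_time(scen)
        mc = cap.capture_time_mc(scen, 800, np.random.default_rng(50))
        assert np.mean(mc) == pytest.approx(sol.expected_capture, rel=0.10)


class TestStochasticCapture:
    def test_quadrature_matches_monte_carlo(self):
        scen = cap.CaptureScenario(0.25, SI8, TransitMode.stochastic())
        ana = cap.expected_capture_time_stochastic(scen)
        mc = cap.capture_time_mc(scen, 800, np.random.default_rng(51))
        assert np.mean(mc) == pytest.approx(ana, rel=0.10)

    def test_capture_on_the_order_of_days(self):
        """Stochastic transit, f=0.25, n=8: mean capture in the 4-6 day band."""
        scen = cap.CaptureScenario(0.25, SI8, TransitMode.stochastic())
        mc = cap.capture_time_mc(scen, 1200, np.random.default_rng(52))
        assert 4.0 * 24 * 0.8 < np.mean(mc) < 6.0 * 24 * 1.2

    def test_u_shaped_transit_dependence(self):
        """Capture at 6 h and 24 h deterministic transit both exceed 12 h."""
        mc = {}
        for t_det in (6.0, 12.0, 24.0):
            scen = cap.CaptureScenario(0.25, SI8, TransitMode.deterministic(t_det))
            mc[t_det] = np.mean(cap.capture_time_mc(scen, 800, np.random.default_rng(53)))
        assert mc[6.0] > mc[24.0] > mc[12.0]

    def test_instant_priming_captures_at_first_ln(self):
        """f=1 with near-instant priming: capture ~ first LN arrival time."""
        scen = cap.CaptureScenario(
            1.0,
            PrimingParams(contact_rate=1e4, success_prob=1.0, required_contacts=1),
            TransitMode.stochastic(),
        )
        mc = cap.capture_time_mc(scen, 600, np.random.default_rng(54))
        t0 = cap.mean_time_to_first_ln(
            scen.resolved_body(), np.random.default_rng(55), n_cells=3000
        )
        assert np.mean(mc) == pytest.approx(t0, rel=0.10)

    def test_dose_robustness_at_24_contacts(self):
        """At n=24, stochastic transit beats deterministic ~11 h transit."""
        si24 = PrimingParams.signal_integration(24.0, 1.0)
        stoch = np.mean(
            cap.capture_time_mc(
                cap.CaptureScenario(0.25, si24, TransitMode.stochastic()),
                300,
                np.random.default_rng(56),
            )
        )
        det = cap.expected_capture_time(
            cap.CaptureScenario(0.25, si24, TransitMode.deterministic(11.0))
        ).expected_capture
        assert stoch < det


class TestOptimalTransit:
    def test_paper_optima(self):
        """~3.7 h optimum for 2 contacts; ~11.7 h for 8 contacts (f=0.25)."""
        t2 = cap.optimal_transit_time(0.25, PrimingParams.signal_integration(2.0, 1.0))
        t8 = cap.optimal_transit_time(0.25, SI8)
        assert t2 == pytest.approx(3.7, rel=0.15)
        assert t8 == pytest.approx(11.7, rel=0.15)

    def test_instant_priming_favors_fast_transit(self):
        fast = PrimingParams(contact_rate=1000.0, success_prob=1.0, required_contacts=1)
        t = cap.optimal_transit_time(0.25, fast)
        assert t < 0.1


@pytest.fixture(scope="module")
def matrix():
    return cap.benefit_risk_matrix([2, 8], [2, 8, 10], 0.25, t0=12.7)


class TestBenefitRisk:
    def test_diagonal_benefit(self, matrix):
        """Optimized deterministic transit beats stochastic at its own dose."""
        assert matrix.loc[2].iloc[0][2] < 1.0
        assert matrix.loc[8].iloc[0][8] < 1.0

    def test_off_diagonal_risk(self, matrix):
        """Transit tuned for 2 contacts is far slower at a 10-contact dose."""
        assert matrix.loc[2].iloc[0][10] > 10.0

    def test_stochastic_vs_itself_is_unity(self):
        scen = cap.CaptureScenario(0.25, SI8, TransitMode.stochastic())
        a = cap.expected_capture_time_stochastic(scen, t0=10.0)
        b = cap.expected_capture_time_stochastic(scen, t0=10.0)
        assert a / b == pytest.approx(1.0)


class TestTauB:
    def test_analytic_value(self, body):
        """tau_b = (1/q)/Lambda + ((1-q)/q)*spleen mean at baseline rates."""
        tau = cap.mean_blood_spleen_gap(body)
        spleen_mean = geometry.spleen_transit_table(body.spleen_geometry).mean
        q = 1.5 / 2.5
        assert tau == pytest.approx((1 / q) * (1 / 2.5) + ((1 - q) / q) * spleen_mean)

    def test_brute_force_simulated_gap(self, body, rng):
        """Simulated mean organ-gap between LN visits matches the formula."""
        from tcellsim.circulation import TransitMode, simulate_cell

        gaps = []
        for _ in range(300):
            traj = simulate_cell(body, TransitMode.stochastic(), 600.0, rng)
            t_ln_exit = None
            for ep in traj.episodes:
                if ep.compartment.startswith("LN"):
                    if t_ln_exit is not None:
                        gaps.append(ep.t_entry - t_ln_exit)
                    t_ln_exit = ep.t_exit
        assert np.mean(gaps) == pytest.approx(cap.mean_blood_spleen_gap(body), rel=0.05)
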