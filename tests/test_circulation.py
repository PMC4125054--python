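"""Kinetic Monte Carlo circulation: rates, occupancy, arrivals, ramps."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import chisquare

from tcellsim import geometry
from tcellsim.circulation import (
    BLOOD,
    N_SPHERES,
    BodyConfig,
    EntryRateRamp,
    TransitMode,
    arrival_times,
    default_sphere_map,
    initialize_steady_state,
    ndln_depletion_curve,
    occupancy_fractions,
    simulate_cell,
    simulate_cohort,
    step_blood,
)
from tcellsim.priming import PrimingParams


class TestBodyConfig:
    def test_default_rates(self, body):
        assert body.baseline_total_rate == pytest.approx(2.5)
        assert body.total_ln_rate == pytest.approx(1.5)

    def test_sphere_map_counts(self):
        m = default_sphere_map()
        assert len(m) == 30  # named LNs
        spheres = [i for v in m.values() for i in v]
        assert sorted(spheres) == list(range(N_SPHERES))
        assert len(m["mesenteric"]) == 4
        assert len(m["axillary_left"]) == 2

    def test_ramp_factor(self):
        r = EntryRateRamp(fold_increase=9.0, ramp_end_days=4.5)
        assert r.factor(0.0) == 1.0
        assert r.factor(4.5 * 24) == pytest.approx(9.0)
        assert r.factor(4.5 * 12) == pytest.approx(5.0)
        assert r.factor(10 * 24) == pytest.approx(9.0)

    def test_ramped_total_rate(self):
        body = BodyConfig().with_dlns(2, ramp=EntryRateRamp(9.0, 4.5))
        base = BodyConfig().baseline_total_rate
        assert body.total_rate(0.0) == pytest.approx(base)
        assert body.total_rate(4.5 * 24) == pytest.approx(base + 8 * 2 * 1.5 / 39)
        assert body.max_total_rate == pytest.approx(body.total_rate(4.5 * 24))


class TestStepBlood:
    def test_spleen_probability_and_dwell(self, body, rng):
        organs, dwells = [], []
        for _ in range(20_000):
            (organ, dwell) = step_blood(body, 0.0, rng)
            organs.append(organ[0])
            dwells.append(dwell)
        p_spleen = np.mean([o == "spleen" for o in organs])
        assert p_spleen == pytest.approx(0.4, abs=0.01)
        # mean blood dwell 1/2.5 h = 24 min, the printed ~25 min
        assert np.mean(dwells) * 60 == pytest.approx(24.0, rel=0.02)

    def test_single_organ_body(self, rng):
        tiny = BodyConfig(
            spleen_entry_rate=1e-9,
            ln_entry_rates=tuple([2.0 / N_SPHERES] * N_SPHERES),
        )
        organ, _ = step_blood(tiny, 0.0, rng)
        assert organ[0] == "ln"

    def test_thinning_matches_discretization(self, rng):
        """Ogata thinning reproduces the time-varying exit law (dt oracle)."""
        body = BodyConfig().with_dlns(2, ramp=EntryRateRamp(9.0, 0.5, "linear"))
        exits = [step_blood(body, 0.0, rng)[1] for _ in range(30_000)]
        # fine-grained discretization oracle on the hazard
        dt = 1e-3
        tgrid = np.arange(0, 20, dt)
        lam = np.array([body.total_rate(t) for t in tgrid])
        surv = np.exp(-np.cumsum(lam) * dt)
        oracle_mean = float(np.sum(surv) * dt)
        assert np.mean(exits) == pytest.approx(oracle_mean, rel=0.02)


class TestSimulateCell:
    def test_alternation_and_time_conservation(self, body, rng):
        traj = simulate_cell(body, TransitMode.stochastic(), 200.0, rng)
        assert traj.total_time() == pytest.approx(200.0)
        comps = [ep.compartment for ep in traj.episodes]
        for a, b in zip(comps, comps[1:]):
            assert (a == BLOOD) != (b == BLOOD)  # blood alternates with organs

    def test_spleen_only_body(self, rng):
        spleen_only = BodyConfig(
            spleen_entry_rate=2.0, ln_entry_rates=tuple([1e-12] * N_SPHERES)
        )
        with pytest.raises(ValueError):
            BodyConfig(spleen_entry_rate=2.0, ln_entry_rates=tuple([0.0] * N_SPHERES))
        traj = simulate_cell(spleen_only, TransitMode.stochastic(), 100.0, rng)
        organs = {ep.compartment for ep in traj.episodes} - {BLOOD}
        assert organs <= {"spleen"}

    def test_deterministic_mode_fixes_ln_dwell(self, body, rng):
        traj = simulate_cell(body, TransitMode.deterministic(12.0), 400.0, rng)
        ln_eps = [ep for ep in traj.episodes if ep.compartment.startswith("LN")]
        full = [ep for ep in ln_eps if ep.t_exit < 400.0]
        assert full and all(
            ep.t_exit - ep.t_entry == pytest.approx(12.0) for ep in full
        )

    def test_retention_in_dln(self, rng):
        body = BodyConfig().with_dlns(23)  # all single-sphere LNs drain
        fast = PrimingParams.signal_integration(1.0, 100.0)  # near-instant
        traj = simulate_cell(
            body, TransitMode.stochastic(), 2000.0, rng, priming=fast
        )
        assert traj.outcome == "retained"
        assert traj.retained_in.startswith("LN")
        assert traj.episodes[-1].t_exit == pytest.approx(traj.retained_at)


class TestSteadyState:
    def test_burn_in_disabled(self, body, rng):
        assert initialize_steady_state(body, rng, burn_in=False) == (BLOOD, None)

    def test_occupancy_after_burn_in(self, body):
        """Post burn-in compartment distribution matches renewal-reward shares."""
        rng = np.random.default_rng(21)
        counts = {"blood": 0, "spleen": 0, "ln": 0}
        n = 3000
        for _ in range(n):
            state, _ = initialize_steady_state(body, rng)
            key = "blood" if state == BLOOD else state[0] if state[0] == "spleen" else "ln"
            counts[key] += 1
        # renewal-reward: share = rate-weighted mean dwell per cycle
        lam = body.baseline_total_rate
        cyc = 1 / lam + 0.6 * 13.5 + 0.4 * 6.0
        expected = {"blood": (1 / lam) / cyc, "ln": 0.6 * 13.5 / cyc, "spleen": 0.4 * 6.0 / cyc}
        for k in counts:
            assert counts[k] / n == pytest.approx(expected[k], abs=0.025)

    def test_two_seeds_statistically_indistinguishable(self, body):
        def occ(seed):
            rng = np.random.default_rng(seed)
            c = np.zeros(3, dtype=int)
            for _ in range(1500):
                state, _ = initialize_steady_state(body, rng)
                c[0 if state == BLOOD else 1 if state[0] == "spleen" else 2] += 1
            return c
        a, b = occ(1), occ(2)
        stat, p = chisquare(a, b * a.sum() / b.sum())
        assert p > 0.01


@pytest.fixture(scope="module")
def cohort(body):
    return simulate_cohort(body, 4000, horizon=336.0, rng=np.random.default_rng(7))


class TestCohort:
    def test_long_run_occupancy(self, cohort):
        """~74% LN / ~23% spleen / ~4% blood at baseline rates."""
        fr = cohort.occupancy_fractions()
        assert fr["ln"] == pytest.approx(0.74, rel=0.05)
        assert fr["spleen"] == pytest.approx(0.23, rel=0.10)
        assert fr["blood"] == pytest.approx(0.037, rel=0.25)

    def test_occupancy_identity_renewal_reward(self, cohort, body):
        """Occupancy equals (rate x mean dwell) shares from the renewal oracle."""
        lam = body.baseline_total_rate
        cyc = 1 / lam + 0.6 * 13.5 + 0.4 * 6.0
        fr = cohort.occupancy_fractions()
        assert fr["ln"] == pytest.approx(0.6 * 13.5 / cyc, rel=0.03)
        assert fr["spleen"] == pytest.approx(0.4 * 6.0 / cyc, rel=0.05)

    def test_spleen_arrivals_95pct_in_3d(self, cohort):
        assert np.mean(cohort.first_spleen <= 72.0) == pytest.approx(0.95, abs=0.03)

    def test_matches_per_cell_simulator(self, body):
        """Vectorized cohort and the per-cell event loop agree on occupancy."""
        rng = np.random.default_rng(100)
        trajs = []
        for _ in range(400):
            init = initialize_steady_state(body, rng)
            trajs.append(
                simulate_cell(body, TransitMode.stochastic(), 336.0, rng, initial=init)
            )
        fr = occupancy_fractions(trajs, 0.0, 336.0)
        assert fr["ln"] == pytest.approx(0.74, abs=0.03)
        assert fr["spleen"] == pytest.approx(0.225, abs=0.03)


class TestArrivals:
    def test_dln_arrival_fraction(self, body):
        """9 single-sphere dLNs collect >= 2/3 of the cohort within 5 days."""
        res = simulate_cohort(
            body.with_dlns(9), 4000, horizon=168.0, rng=np.random.default_rng(8)
        )
        assert np.mean(res.first_dln <= 120.0) >= 2.0 / 3.0

    def test_arrival_hazard_matches_rates(self, body, rng):
        """Per blood exit, a dLN is hit with probability sum(dln rates)/Lambda."""
        body2 = body.with_dlns(4)
        hits = 0
        total = 20_000
        for _ in range(total):
            organ, _ = step_blood(body2, 0.0, rng)
            if organ[0] == "ln" and body2.is_dln(organ[1]):
                hits += 1
        expect = sum(body2.ln_entry_rates[i] for i in body2.dln_spheres) / body2.baseline_total_rate
        assert hits / total == pytest.approx(expect, abs=0.006)

    def test_empty_target_set_rejected(self, body, rng):
        traj = simulate_cell(body, TransitMode.stochastic(), 50.0, rng)
        with pytest.raises(ValueError):
            arrival_times([traj], [])

    def test_all_compartments_arrival_at_first_blood_exit(self, body, rng):
        traj = simulate_cell(body, TransitMode.stochastic(), 200.0, rng)
        targets = {"spleen"} | {f"LN{i:02d}" for i in range(N_SPHERES)}
        t_arr = arrival_times([traj], targets)[0]
        first_exit = traj.episodes[0].t_exit
        assert t_arr <= first_exit + 1e-9

    def test_initial_occupant_convention(self, body, rng):
        """Cells already inside a target at t=0 count as arrived at 0."""
        init = (("ln", 3), 5.0)
        traj = simulate_cell(body, TransitMode.stochastic(), 50.0, rng, initial=init)
        assert arrival_times([traj], ["LN03"], count_initial=True)[0] == 0.0
        later = arrival_times([traj], ["LN03"], count_initial=False)[0]
        assert np.isnan(later) or later > 0


class TestDepletion:
    def _cohort(self, body, seed, n=400, priming=None, horizon=168.0):
        rng = np.random.default_rng(seed)
        trajs = []
        for _ in range(n):
            init = initialize_steady_state(body, rng)
            trajs.append(
                simulate_cell(
                    body, TransitMode.stochastic(), horizon, rng,
                    priming=priming, initial=init,
                )
            )
        return trajs

    def test_no_dln_curve_is_flat_one(self, body):
        trajs = self._cohort(body, 1, n=100)
        curve = ndln_depletion_curve(trajs, body, np.linspace(0, 100, 11))
        assert np.all(curve == 1.0)

    def test_ramp_accelerates_depletion(self):
        """With a 9-fold entry ramp, 2 dLNs deplete the periphery faster."""
        priming = PrimingParams.signal_integration(8.0, 1.0)
        times = np.linspace(0, 168, 15)
        body_off = BodyConfig().with_dlns(2)
        body_on = BodyConfig().with_dlns(2, ramp=EntryRateRamp(9.0, 4.5))
        off = ndln_depletion_curve(self._cohort(body_off, 31, priming=priming), body_off, times)
        on = ndln_depletion_curve(self._cohort(body_on, 31, priming=priming), body_on, times)
        k96 = int(np.argmin(np.abs(times - 96.0)))
        assert on[k96] < off[k96]
        assert off[0] == pytest.approx(1.0 - 2 / 39 * 0.74, abs=0.05)
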