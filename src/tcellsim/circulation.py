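"""Kinetic Monte Carlo circulation of T cells between blood, spleen and LNs.

Single antigen-specific cells are so rare that they circulate independently,
so the model follows one cell at a time.  A cell in the blood waits an
exponential time with rate Λ(t) = σ_S + Σ_i σ_i(t) (all per hour), then
homes to the spleen with probability σ_S/Λ or to LN sphere ``i`` with
probability σ_i/Λ.  The 30 murine LNs are represented by 39 equal spheres
(axillary, brachial and inguinal pairs by 2 spheres each, the mesenteric LN
by 4, all others by 1), which makes entry rate proportional to LN size while
egress rate is size-independent.  Organ dwell times come from the
first-passage laws of :mod:`tcellsim.geometry`, or from a fixed constant in
deterministic-transit experiments.  Infections designate a subset of spheres
as draining LNs (dLNs), optionally with an entry-rate ramp (9-fold by day
4.5 in the HSV-like scenario), and retention inside dLNs is evaluated by
comparing a pre-drawn Gamma retention time with the dwell time.

Times are hours throughout; t = 0 is the start of observation (infection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from tcellsim import geometry
from tcellsim.priming import PrimingParams, sample_retention_time

__all__ = [
    "EntryRateRamp",
    "BodyConfig",
    "TransitMode",
    "Episode",
    "CellTrajectory",
    "CohortResult",
    "default_sphere_map",
    "step_blood",
    "simulate_cell",
    "initialize_steady_state",
    "simulate_cohort",
    "arrival_times",
    "occupancy_fractions",
    "ndln_depletion_curve",
]

HOURS_PER_WEEK = 168.0

#: Baseline entry rates adopted from classic recirculation estimates: these
#: reproduce the printed 25 min blood residence and the 74:23:3 LN:spleen:
#: blood distribution given 13.5 h / 6 h organ dwell times.
DEFAULT_SPLEEN_ENTRY_RATE = 1.0  # per hour
DEFAULT_TOTAL_LN_ENTRY_RATE = 1.5  # per hour, split evenly over 39 spheres
N_SPHERES = 39


def default_sphere_map() -> dict:
    """Map of the 30 named LNs to the 39 spheres.

    Paired axillary/brachial/inguinal LNs get 2 spheres each, the mesenteric
    LN 4, the remaining 23 LNs 1 each.
    """
    mapping = {}
    idx = 0
    for side in ("left", "right"):
        for name in ("axillary", "brachial", "inguinal"):
            mapping[f"{name}_{side}"] = tuple(range(idx, idx + 2))
            idx += 2
    mapping["mesenteric"] = tuple(range(idx, idx + 4))
    idx += 4
    for k in range(23):
        mapping[f"other_{k:02d}"] = (idx,)
        idx += 1
    assert idx == N_SPHERES
    return mapping


@dataclass(frozen=True)
class EntryRateRamp:
    """Inflammation-driven increase of dLN entry rates after infection.

    ``fold_increase``-fold by ``ramp_end_days`` post infection; ``shape`` is
    ``linear`` (default), ``step`` (full fold immediately at t=0) or
    ``none``.
    """

    fold_increase: float = 9.0
    ramp_end_days: float = 4.5
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.fold_increase < 1:
            raise ValueError("fold_increase must be >= 1")
        if self.shape not in ("linear", "step", "none"):
            raise ValueError(f"unknown ramp shape {self.shape!r}")

    def factor(self, t_hours: float) -> float:
        """Multiplier of the dLN entry rate at ``t_hours`` post infection."""
        if self.shape == "none" or t_hours <= 0:
            return 1.0
        if self.shape == "step":
            return self.fold_increase
        end = self.ramp_end_days * 24.0
        if t_hours >= end:
            return self.fold_increase
        return 1.0 + (self.fold_increase - 1.0) * t_hours / end


@dataclass(frozen=True)
class TransitMode:
    """LN dwell law: first-passage sampling or a fixed dwell ``t_det`` hours."""

    kind: str = "stochastic"
    t_det: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown transit kind {self.kind!r}")
        if self.kind == "deterministic" and not (self.t_det and self.t_det > 0):
            raise ValueError("deterministic transit requires t_det > 0")

    @classmethod
    def stochastic(cls) -> "TransitMode":
        return cls(kind="stochastic")

    @classmethod
    def deterministic(cls, t_det: float) -> "TransitMode":
        return cls(kind="deterministic", t_det=t_det)


@dataclass(frozen=True)
class BodyConfig:
    """Compartment graph: blood, spleen and 39 LN spheres.

    ``ln_entry_rates`` are per-sphere homing rates (per hour); the default
    splits 1.5/h evenly.  ``dln_spheres`` lists the sphere indices draining
    an infection site; ``ramp`` scales their entry rates over time.
    """

    spleen_entry_rate: float = DEFAULT_SPLEEN_ENTRY_RATE
    ln_entry_rates: tuple = tuple([DEFAULT_TOTAL_LN_ENTRY_RATE / N_SPHERES] * N_SPHERES)
    dln_spheres: tuple = ()
    ramp: Optional[EntryRateRamp] = None
    ln_geometry: geometry.LNSphere = field(default_factory=geometry.default_ln_sphere)
    spleen_geometry: geometry.SpleenSection = field(default_factory=geometry.default_spleen_section)

    def __post_init__(self) -> None:
        if len(self.ln_entry_rates) != N_SPHERES:
            raise ValueError(f"need {N_SPHERES} LN sphere rates, got {len(self.ln_entry_rates)}")
        if self.spleen_entry_rate <= 0 or any(r <= 0 for r in self.ln_entry_rates):
            raise ValueError("all entry rates must be > 0")
        if any(i < 0 or i >= N_SPHERES for i in self.dln_spheres):
            raise ValueError("dln_spheres indices out of range")

    # -- rates ---------------------------------------------------------------

    @property
    def total_ln_rate(self) -> float:
        return float(sum(self.ln_entry_rates))

    @property
    def baseline_total_rate(self) -> float:
        return self.spleen_entry_rate + self.total_ln_rate

    def total_rate(self, t: float) -> float:
        """Λ(t): total blood-exit rate at time t (hours post infection)."""
        lam = self.baseline_total_rate
        if self.ramp is not None and self.dln_spheres:
            extra = (self.ramp.factor(t) - 1.0) * sum(
                self.ln_entry_rates[i] for i in self.dln_spheres
            )
            lam += extra
        return lam

    @property
    def max_total_rate(self) -> float:
        """Upper bound Λ_max used for Ogata thinning."""
        if self.ramp is None or not self.dln_spheres:
            return self.baseline_total_rate
        return self.baseline_total_rate + (self.ramp.fold_increase - 1.0) * sum(
            self.ln_entry_rates[i] for i in self.dln_spheres
        )

    def sphere_rates(self, t: float) -> np.ndarray:
        rates = np.asarray(self.ln_entry_rates, dtype=float).copy()
        if self.ramp is not None and self.dln_spheres:
            f = self.ramp.factor(t)
            for i in self.dln_spheres:
                rates[i] *= f
        return rates

    def with_dlns(self, count: int, ramp: Optional[EntryRateRamp] = None) -> "BodyConfig":
        """Designate the first ``count`` single-sphere LNs as draining.

        Single-sphere LNs are the 23 "other" spheres (indices 16..38), so a
        dLN count of 9 matches the influenza-like scenario of 9 draining
        single-sphere LNs.
        """
        single = [i for i in range(16, N_SPHERES)]
        if count > len(single):
            raise ValueError(f"at most {len(single)} single-sphere dLNs available")
        return replace(self, dln_spheres=tuple(single[:count]), ramp=ramp)

    def is_dln(self, sphere: int) -> bool:
        return sphere in self.dln_spheres


# -- trajectories -----------------------------------------------------------

BLOOD = "blood"
SPLEEN = "spleen"


def ln_label(i: int) -> str:
    return f"LN{i:02d}"


@dataclass
class Episode:
    compartment: str
    t_entry: float
    t_exit: float


@dataclass
class CellTrajectory:
    """Ordered compartment episodes of one simulated cell."""

    episodes: list
    outcome: str  # "circulating" | "retained" | "censored"
    retained_at: Optional[float] = None
    retained_in: Optional[str] = None

    def compartment_at(self, t: float) -> Optional[str]:
        for ep in self.episodes:
            if ep.t_entry <= t < ep.t_exit:
                return ep.compartment
        if self.outcome == "retained" and t >= self.retained_at:
            return self.retained_in
        return None

    def total_time(self) -> float:
        return sum(ep.t_exit - ep.t_entry for ep in self.episodes)


def _draw_ln_dwell(body: BodyConfig, mode: TransitMode, rng: np.random.Generator) -> float:
    if mode.kind == "deterministic":
        return mode.t_det
    return float(geometry.sample_ln_transit(body.ln_geometry, rng))


def _draw_spleen_dwell(body: BodyConfig, rng: np.random.Generator) -> float:
    return float(geometry.spleen_transit_table(body.spleen_geometry).sample(rng))


def step_blood(body: BodyConfig, t: float, rng: np.random.Generator):
    """Draw (next organ, blood dwell in hours) for a cell entering blood at t.

    Time-varying rates (entry ramp) are handled by Ogata thinning against
    Λ_max, which is exact without discretization.  The organ is returned as
    ``("spleen", None)`` or ``("ln", sphere_index)``.
    """
    lam_max = body.max_total_rate
    dwell = 0.0
    while True:
        dwell += rng.exponential(1.0 / lam_max)
        lam = body.total_rate(t + dwell)
        if rng.random() * lam_max <= lam:
            break
    u = rng.random() * lam
    if u < body.spleen_entry_rate:
        return (SPLEEN, None), dwell
    u -= body.spleen_entry_rate
    if body.ramp is None or not body.dln_spheres:
        # even split: direct index, avoids a 39-element cumsum per event
        rates = body.ln_entry_rates
        if all(r == rates[0] for r in rates):
            i = min(int(u / rates[0]), N_SPHERES - 1)
            return ("ln", i), dwell
    cum = np.cumsum(body.sphere_rates(t + dwell))
    i = int(np.searchsorted(cum, u, side="right"))
    return ("ln", min(i, N_SPHERES - 1)), dwell


def simulate_cell(
    body: BodyConfig,
    mode: TransitMode,
    duration: float,
    rng: np.random.Generator,
    priming: Optional[PrimingParams] = None,
    initial=None,
    max_hours: Optional[float] = None,
) -> CellTrajectory:
    """Simulate one cell from t=0 to ``duration`` hours.

    ``initial`` is a ``(compartment, residual_dwell)`` pair as produced by
    :func:`initialize_steady_state`; by default the cell starts in the blood
    with a fresh sojourn.  If ``priming`` is given, each dLN visit draws a
    retention time A from the Gamma law and the cell is retained iff A is
    shorter than the dwell, terminating the trajectory at entry + A.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    horizon = duration if max_hours is None else min(duration, max_hours)
    episodes: list = []
    t = 0.0

    def finish(outcome="circulating"):
        return CellTrajectory(episodes=episodes, outcome=outcome)

    # state: either ("blood",) or ("spleen", None) or ("ln", sphere_index)
    if initial is None:
        state, residual = BLOOD, None
    else:
        state, residual = initial

    while t < horizon:
        if state == BLOOD:
            if residual is None:
                organ, dwell = step_blood(body, t, rng)
            else:
                # residual blood sojourn from burn-in; organ chosen at exit
                dwell, residual = residual, None
                organ = _choose_organ(body, t + dwell, rng)
            t_exit = t + dwell
            episodes.append(Episode(BLOOD, t, min(t_exit, horizon)))
            if t_exit >= horizon:
                return finish()
            t = t_exit
            state = organ
        else:
            kind, sphere = state
            if kind == SPLEEN:
                dwell = residual if residual is not None else _draw_spleen_dwell(body, rng)
                label, is_dln = SPLEEN, False
            else:
                dwell = residual if residual is not None else _draw_ln_dwell(body, mode, rng)
                label, is_dln = ln_label(sphere), body.is_dln(sphere)
            residual = None
            if priming is not None and is_dln:
                a = float(sample_retention_time(priming, rng))
                if a < dwell:
                    t_ret = t + a
                    if t_ret >= horizon:
                        episodes.append(Episode(label, t, horizon))
                        return finish()
                    episodes.append(Episode(label, t, t_ret))
                    traj = finish("retained")
                    traj.retained_at = t_ret
                    traj.retained_in = label
                    return traj
            t_exit = t + dwell
            episodes.append(Episode(label, t, min(t_exit, horizon)))
            if t_exit >= horizon:
                return finish()
            t = t_exit
            state = BLOOD
    return finish()


def _choose_organ(body: BodyConfig, t: float, rng: np.random.Generator):
    lam = body.total_rate(t)
    u = rng.random() * lam
    if u < body.spleen_entry_rate:
        return (SPLEEN, None)
    u -= body.spleen_entry_rate
    cum = np.cumsum(body.sphere_rates(t))
    i = int(np.searchsorted(cum, u, side="right"))
    return ("ln", min(i, N_SPHERES - 1))


def initialize_steady_state(
    body: BodyConfig,
    rng: np.random.Generator,
    mode: Optional[TransitMode] = None,
    burn_in: bool = True,
):
    """Desynchronized initial state: (compartment, residual dwell) at t=0.

    Cells start in the blood and circulate for 1 + u weeks (u uniform on
    [0, 1)) before observation starts, which reproduces the stationary
    occupancy and residual-dwell distributions.  With ``burn_in=False`` the
    cell starts in the blood at t=0 (useful for unit tests).

    The burn-in always uses baseline entry rates (the ramp only acts after
    the infection at t=0).
    """
    mode = mode or TransitMode.stochastic()
    if not burn_in:
        return (BLOOD, None)
    baseline = replace(body, ramp=None)
    horizon = (1.0 + rng.random()) * HOURS_PER_WEEK
    t = 0.0
    compartment = BLOOD
    while True:
        if compartment == BLOOD:
            (organ, dwell) = step_blood(baseline, t, rng)
            if t + dwell >= horizon:
                return (BLOOD, t + dwell - horizon)
            t += dwell
            compartment = organ
        elif compartment[0] == SPLEEN:
            dwell = _draw_spleen_dwell(baseline, rng)
            if t + dwell >= horizon:
                return ((SPLEEN, None), t + dwell - horizon)
            t += dwell
            compartment = BLOOD
        else:
            sphere = compartment[1]
            dwell = _draw_ln_dwell(baseline, mode, rng)
            if t + dwell >= horizon:
                return (("ln", sphere), t + dwell - horizon)
            t += dwell
            compartment = BLOOD


# ---------------------------------------------------------------------------
# Vectorized cohort simulation (constant rates, no retention)
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    """Summary statistics of a vectorized cohort run.

    ``occupancy_hours``: per-cell time spent in blood/spleen/LN within
    [0, horizon].  ``first_spleen`` / ``first_dln`` / ``first_ln``: first
    entry times at or after t=0 (NaN if never; 0 for cells already inside at
    t=0 when ``count_initial`` was set).  ``initial_compartment``: 0 blood,
    1 spleen, 2 LN (ndLN), 3 dLN.
    """

    horizon: float
    occupancy_hours: dict
    first_spleen: np.ndarray
    first_ln: np.ndarray
    first_dln: np.ndarray
    initial_compartment: np.ndarray

    def occupancy_fractions(self) -> dict:
        total = sum(float(np.sum(v)) for v in self.occupancy_hours.values())
        return {k: float(np.sum(v)) / total for k, v in self.occupancy_hours.items()}


def simulate_cohort(
    body: BodyConfig,
    n_cells: int,
    horizon: float,
    rng: np.random.Generator,
    mode: Optional[TransitMode] = None,
    burn_in: bool = True,
    count_initial: bool = True,
) -> CohortResult:
    """Vectorized kinetic Monte Carlo for a cohort, baseline rates only.

    All cells alternate blood and organ episodes in lockstep, which allows
    drawing whole rounds of dwell times at once.  Only valid without an
    entry-rate ramp and without retention (use :func:`simulate_cell` for
    those); raises if the body has a ramp.
    """
    if body.ramp is not None:
        raise ValueError("simulate_cohort requires constant rates (no ramp)")
    mode = mode or TransitMode.stochastic()
    lam = body.baseline_total_rate
    p_spleen = body.spleen_entry_rate / lam
    rates = np.asarray(body.ln_entry_rates)
    p_sphere = rates / lam
    dln = np.zeros(N_SPHERES, dtype=bool)
    for i in body.dln_spheres:
        dln[i] = True

    spleen_table = geometry.spleen_transit_table(body.spleen_geometry)
    ln_sampler = geometry._ln_sampler(body.ln_geometry)

    start = -(1.0 + rng.random(n_cells)) * HOURS_PER_WEEK if burn_in else np.zeros(n_cells)
    t = start.copy()
    occ = {k: np.zeros(n_cells) for k in (BLOOD, SPLEEN, "ln")}
    first = {
        SPLEEN: np.full(n_cells, np.nan),
        "ln": np.full(n_cells, np.nan),
        "dln": np.full(n_cells, np.nan),
    }
    initial_comp = np.zeros(n_cells, dtype=int)  # all start in blood (pre burn-in)

    even_rates = bool(np.allclose(rates, rates[0]))
    cum_sphere = np.cumsum(p_sphere / (1.0 - p_spleen))

    # every cell alternates blood -> organ -> blood ..., so whole rounds of
    # blood dwells, organ choices and organ dwells can be drawn at once
    active = np.arange(n_cells)
    while active.size:
        idx = active
        dwell = rng.exponential(1.0 / lam, size=idx.size)
        _accumulate(occ[BLOOD], idx, t[idx], dwell, horizon)
        t[idx] += dwell
        u = rng.random(idx.size)
        to_spleen = u < p_spleen
        sphere = np.zeros(idx.size, dtype=int)
        if np.any(~to_spleen):
            v = (u[~to_spleen] - p_spleen) / (1.0 - p_spleen)
            if even_rates:
                sphere[~to_spleen] = np.minimum((v * N_SPHERES).astype(int), N_SPHERES - 1)
            else:
                sphere[~to_spleen] = np.minimum(
                    np.searchsorted(cum_sphere, v, side="right"), N_SPHERES - 1
                )
        _record_entries(first, idx, t, to_spleen, sphere, dln)
        dwell = np.empty(idx.size)
        ns = int(np.sum(to_spleen))
        if ns:
            dwell[to_spleen] = spleen_table.sample(rng, size=ns)
        if idx.size - ns:
            if mode.kind == "deterministic":
                dwell[~to_spleen] = mode.t_det
            else:
                dwell[~to_spleen] = ln_sampler.sample(rng, size=idx.size - ns)
        _accumulate(occ[SPLEEN], idx[to_spleen], t[idx[to_spleen]], dwell[to_spleen], horizon)
        _accumulate(occ["ln"], idx[~to_spleen], t[idx[~to_spleen]], dwell[~to_spleen], horizon)
        # mark cells inside an organ at t=0 (for the arrival-0 convention)
        inside0 = (t[idx] <= 0) & (t[idx] + dwell > 0)
        comp_code = np.where(to_spleen, 1, np.where(dln[sphere], 3, 2))
        initial_comp[idx[inside0]] = comp_code[inside0]
        t[idx] += dwell
        active = active[t[active] < horizon]
    result = CohortResult(
        horizon=horizon,
        occupancy_hours=occ,
        first_spleen=first[SPLEEN],
        first_ln=first["ln"],
        first_dln=first["dln"],
        initial_compartment=initial_comp,
    )
    if count_initial:
        result.first_spleen[result.initial_compartment == 1] = 0.0
        result.first_ln[result.initial_compartment >= 2] = 0.0
        result.first_dln[result.initial_compartment == 3] = 0.0
    return result


def _accumulate(acc: np.ndarray, idx: np.ndarray, t_entry: np.ndarray, dwell: np.ndarray, horizon: float) -> None:
    if idx.size == 0:
        return
    lo = np.clip(t_entry, 0.0, horizon)
    hi = np.clip(t_entry + dwell, 0.0, horizon)
    acc[idx] += hi - lo


def _record_entries(first, idx, t, to_spleen, sphere, dln) -> None:
    entry = t[idx]
    post = entry >= 0
    sp = to_spleen & post
    first[SPLEEN][idx[sp]] = np.fmin(first[SPLEEN][idx[sp]], entry[sp])
    lnm = (~to_spleen) & post
    first["ln"][idx[lnm]] = np.fmin(first["ln"][idx[lnm]], entry[lnm])
    dm = lnm & dln[sphere]
    first["dln"][idx[dm]] = np.fmin(first["dln"][idx[dm]], entry[dm])


def arrival_times(
    trajectories: Sequence[CellTrajectory],
    targets: Iterable[str],
    count_initial: bool = True,
) -> np.ndarray:
    """First entry time (hours >= 0) of each cell into any target compartment.

    ``targets`` are compartment labels ("spleen", "LN03", ...).  Cells
    already inside a target at t=0 count as arrived at 0 when
    ``count_initial`` (the default); NaN marks cells that never arrive.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("empty target set")
    out = np.full(len(trajectories), np.nan)
    for c, traj in enumerate(trajectories):
        for ep in traj.episodes:
            if ep.compartment in targets:
                if ep.t_entry <= 0 and ep.t_exit > 0:
                    out[c] = 0.0 if count_initial else np.nan
                    if count_initial:
                        break
                    continue
                if ep.t_entry >= 0:
                    out[c] = ep.t_entry
                    break
    return out


def occupancy_fractions(
    trajectories: Sequence[CellTrajectory], t_start: float, t_end: float
) -> dict:
    """Time-averaged fraction of cell-hours in blood / spleen / LN."""
    acc = {BLOOD: 0.0, SPLEEN: 0.0, "ln": 0.0}
    for traj in trajectories:
        for ep in traj.episodes:
            lo, hi = max(ep.t_entry, t_start), min(ep.t_exit, t_end)
            if hi <= lo:
                continue
            key = ep.compartment if ep.compartment in (BLOOD, SPLEEN) else "ln"
            acc[key] += hi - lo
    total = sum(acc.values())
    return {k: v / total for k, v in acc.items()}


def ndln_depletion_curve(
    trajectories: Sequence[CellTrajectory],
    body: BodyConfig,
    times: np.ndarray,
) -> np.ndarray:
    """Fraction of cells outside the dLNs at each time point.

    Retained cells count as inside their dLN from the retention time on;
    with no dLNs the curve is flat at 1.
    """
    times = np.asarray(times, dtype=float)
    if not body.dln_spheres:
        return np.ones_like(times)
    dln_labels = {ln_label(i) for i in body.dln_spheres}
    inside = np.zeros((len(trajectories), times.size), dtype=bool)
    for c, traj in enumerate(trajectories):
        for ep in traj.episodes:
            if ep.compartment in dln_labels:
                inside[c] |= (times >= ep.t_entry) & (times < ep.t_exit)
        if traj.outcome == "retained":
            inside[c] |= times >= traj.retained_at
    return 1.0 - inside.mean(axis=0)
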