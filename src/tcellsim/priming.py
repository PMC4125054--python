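"""Retention-time models for T cell arrest in antigen-bearing lymph nodes.

During phase I of priming a T cell makes serial brief contacts with
antigen-presenting dendritic cells (DCs).  Two hypotheses explain how these
contacts lead to the stable arrest of phase II:

* **Signal integration** — the cell accumulates a cognate signal from every
  contact and arrests once ``n`` successful contacts have been collected.
* **Probabilistic priming** — each new contact independently triggers arrest
  with probability ``p``; unsuccessful contacts are forgotten.

Both are special cases of a general model in which contacts arrive as a
Poisson process with rate ``λ`` (per hour), each succeeds with probability
``p``, and arrest requires ``n`` successes.  Successful contacts then arrive
as a thinned Poisson process with rate ``μ = λ·p``, so the time to retention
is Gamma distributed with shape ``n`` and rate ``μ``.  Only ``μ`` is
identifiable from retention data: a 2 h waiting time with 50% success is
indistinguishable from a 4 h waiting time with 100% success.

All times are in hours and all rates per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import gammainc

__all__ = [
    "PrimingParams",
    "RetentionLaw",
    "ContactEvent",
    "ContactHistory",
    "retention_cdf",
    "sample_retention_time",
    "simulate_contact_history",
    "unique_contact_factor",
    "UNIQUE_CONTACT_FACTOR",
]

#: Fraction of DC contacts that are unique for a persistent random walk in a
#: large 3D tissue (Polya recurrence): converts a "true" contact rate into the
#: effective unique-contact rate relevant for probabilistic priming.
UNIQUE_CONTACT_FACTOR = 2.0 / 3.0


@dataclass(frozen=True)
class PrimingParams:
    """Parameters of the general priming model.

    Parameters
    ----------
    contact_rate : float
        Rate of cognate DC encounters, per hour (``λ > 0``).
    success_prob : float
        Probability that a contact transmits a cognate signal
        (``0 < p <= 1``).
    required_contacts : float
        Successful contacts needed for retention (``n >= 1``).  Integer in
        simulation; real-valued shapes are allowed for fitting.
    unique_contact_corrected : bool
        Marks that :func:`unique_contact_factor` has already been applied to
        ``contact_rate``; guards against applying it twice.
    """

    contact_rate: float
    success_prob: float = 1.0
    required_contacts: float = 1.0
    unique_contact_corrected: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.contact_rate > 0:
            raise ValueError(f"contact_rate must be > 0, got {self.contact_rate}")
        if not 0 < self.success_prob <= 1:
            raise ValueError(f"success_prob must be in (0, 1], got {self.success_prob}")
        if not self.required_contacts >= 1:
            raise ValueError(
                f"required_contacts must be >= 1, got {self.required_contacts}"
            )

    @property
    def success_rate(self) -> float:
        """Effective rate of successful contacts ``μ = λ·p`` (per hour)."""
        return self.contact_rate * self.success_prob

    @property
    def mean_retention(self) -> float:
        """Mean retention time ``n/μ`` in hours."""
        return self.required_contacts / self.success_rate

    @classmethod
    def signal_integration(cls, required_contacts: float, contact_rate: float = 1.0) -> "PrimingParams":
        """Pure signal integration: every contact succeeds (``p = 1``)."""
        return cls(contact_rate=contact_rate, success_prob=1.0, required_contacts=required_contacts)

    @classmethod
    def probabilistic(cls, success_prob: float, contact_rate: float = 1.0) -> "PrimingParams":
        """Pure probabilistic priming: a single success retains (``n = 1``)."""
        return cls(contact_rate=contact_rate, success_prob=success_prob, required_contacts=1.0)

    def to_dict(self) -> dict:
        return {
            "contact_rate_per_h": self.contact_rate,
            "success_prob": self.success_prob,
            "required_contacts": self.required_contacts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrimingParams":
        return cls(
            contact_rate=float(d["contact_rate_per_h"]),
            success_prob=float(d.get("success_prob", 1.0)),
            required_contacts=float(d.get("required_contacts", 1.0)),
        )


class RetentionLaw:
    """Gamma law of the time from lymph-node entry to retention.

    Shape ``n`` (required successful contacts) and rate ``μ = λ·p``; reduces
    to the exponential law of probabilistic priming when ``n = 1``.
    """

    def __init__(self, params: PrimingParams):
        self.params = params
        self._dist = stats.gamma(a=params.required_contacts, scale=1.0 / params.success_rate)

    @property
    def mean(self) -> float:
        return self.params.mean_retention

    @property
    def variance(self) -> float:
        mu = self.params.success_rate
        return self.params.required_contacts / mu**2

    def cdf(self, t):
        return retention_cdf(t, self.params)

    def pdf(self, t):
        return self._dist.pdf(t)

    def sample(self, rng: np.random.Generator, size=None):
        return self._dist.rvs(size=size, random_state=rng)


def retention_cdf(t, params: PrimingParams):
    """P(retention time <= ``t`` hours) under the general priming model.

    This is the regularized lower incomplete gamma function with shape
    ``n`` and rate ``μ = λ·p``.  Accepts scalars or arrays; ``t`` must be
    non-negative.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("retention_cdf requires t >= 0")
    out = gammainc(params.required_contacts, params.success_rate * t)
    return out if out.ndim else float(out)


def sample_retention_time(params: PrimingParams, rng: np.random.Generator, size=None):
    """Draw retention times as sums of ``n`` exponential inter-success waits.

    Equivalent to sampling the Gamma(``n``, rate ``μ``) law directly; for
    integer ``n`` this literally is the sum of independent exponentials.
    """
    return stats.gamma.rvs(
        a=params.required_contacts,
        scale=1.0 / params.success_rate,
        size=size,
        random_state=rng,
    )


@dataclass(frozen=True)
class ContactEvent:
    time: float  # hours since LN entry
    success: bool


@dataclass(frozen=True)
class ContactHistory:
    """Event-level record of one cell's DC contacts within a dLN."""

    events: tuple
    retention_time: Optional[float]  # hours, None if not retained by horizon
    horizon: float

    @property
    def retained(self) -> bool:
        return self.retention_time is not None


def simulate_contact_history(
    params: PrimingParams, horizon: float, rng: np.random.Generator
) -> ContactHistory:
    """Simulate individual DC contacts until retention or ``horizon`` hours.

    Contacts arrive as a Poisson process with rate ``λ``; each succeeds with
    probability ``p``; retention occurs at the ``n``-th success (``n`` is
    rounded to the nearest integer >= 1 here — event-level simulation needs a
    whole number of contacts).  The marginal retention time reproduces
    :func:`retention_cdf` with ``μ = λ·p``.
    """
    if not horizon > 0:
        raise ValueError("horizon must be > 0")
    n_req = max(1, int(round(params.required_contacts)))
    events = []
    t = 0.0
    successes = 0
    retention_time = None
    while True:
        t += rng.exponential(1.0 / params.contact_rate)
        if t > horizon:
            break
        success = bool(rng.random() < params.success_prob)
        events.append(ContactEvent(time=t, success=success))
        if success:
            successes += 1
            if successes >= n_req:
                retention_time = t
                break
    return ContactHistory(events=tuple(events), retention_time=retention_time, horizon=horizon)


def unique_contact_factor() -> float:
    """Return the 2/3 conversion between true and effective contact rates.

    For probabilistic priming only *new* DCs matter; roughly two thirds of
    all contacts of a persistent random walker in a large 3D volume are
    unique, so at the same true contact rate the effective rate of
    probabilistic priming is 2/3 that of signal integration.  Apply via
    :func:`apply_unique_contact_factor`.
    """
    return UNIQUE_CONTACT_FACTOR


def apply_unique_contact_factor(params: PrimingParams) -> PrimingParams:
    """Rescale ``contact_rate`` by 2/3; refuses to apply the factor twice."""
    if params.unique_contact_corrected:
        raise ValueError("unique-contact factor already applied to these parameters")
    return PrimingParams(
        contact_rate=params.contact_rate * UNIQUE_CONTACT_FACTOR,
        success_prob=params.success_prob,
        required_contacts=params.required_contacts,
        unique_contact_corrected=True,
    )
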