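"""Closed-form GP workload model for digital-first access pathways.

The model counts general-practitioner (GP) minutes per consultation request
and compares two arrangements:

* **Conventional care** — most requests receive a face-to-face (f2f)
  consultation, a minority a telephone consultation.  A telephone
  consultation that does not resolve the problem cascades to a f2f
  consultation.

* **Digital-first care** — a fraction of requests (the *access rate*) enter
  a digital pathway first: an asynchronous e-consultation, a telephone
  call, or a video consultation.  A fraction of those (the *completion
  rate*) are resolved without any further contact; the remainder cascade to
  a follow-up consultation.  After an e-consultation the follow-up may be a
  telephone call (which can itself cascade to f2f) or a f2f consultation;
  after a telephone-first or video-first contact the follow-up is f2f.
  The remaining requests take the conventional route unchanged.

Offering an easier access route can change how many requests arrive at all
(*supply-related demand*): a fraction ``d`` of digital consultations are
requests that would not have been made under conventional care.  With
digital share ``a`` of all requests, total requests per baseline request is
``1 / (1 − d·a)``, the self-consistent fixed point of "a fraction d of
digital contacts are new"; ``d`` may be negative if the digital route
suppresses demand.

The headline output is the percent change in GP workload: +10 means the
digital-first arrangement needs 10% more GP hours than conventional care
for the same underlying population.

Every telephone contact in the model — the conventional-arm telephone
consultation, the telephone-first contact itself, and a telephone follow-up
after an e-consultation — carries the same cascade structure
``phone_duration + (1 − phone_completion) · f2f_duration``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "ValidationError",
    "DomainError",
    "PathwayKind",
    "ConventionalMix",
    "PathwayParams",
    "PhoneCascadeParams",
    "Scenario",
    "WorkloadResult",
    "ContactCounts",
    "SimulationResult",
    "conventional_workload",
    "expected_digital_minutes",
    "demand_multiplier",
    "workload_change",
    "estimate_supply_related_demand",
    "simulate_cohort",
    "round_half_up",
]


class ValidationError(ValueError):
    """An input field violates its declared bounds."""


class DomainError(ValueError):
    """Inputs are individually valid but jointly outside the model's domain."""


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be a proportion in [0, 1], got {value!r}")
    return value


def _check_duration(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValidationError(f"{name} must be a finite duration > 0 minutes, got {value!r}")
    return value


class PathwayKind(str, Enum):
    """The three digital-first access pathways."""

    ECONSULT = "econsult"
    TELEPHONE = "telephone"
    VIDEO = "video"


@dataclass(frozen=True)
class ConventionalMix:
    """Baseline consultation mix: fractions must sum to 1, durations in minutes."""

    f2f_fraction: float
    phone_fraction: float
    f2f_duration: float
    phone_duration: float

    def __post_init__(self) -> None:
        _check_fraction("f2f_fraction", self.f2f_fraction)
        _check_fraction("phone_fraction", self.phone_fraction)
        _check_duration("f2f_duration", self.f2f_duration)
        _check_duration("phone_duration", self.phone_duration)
        if abs(self.f2f_fraction + self.phone_fraction - 1.0) > 1e-12:
            raise ValidationError(
                "f2f_fraction + phone_fraction must equal 1, got "
                f"{self.f2f_fraction} + {self.phone_fraction}"
            )


@dataclass(frozen=True)
class PhoneCascadeParams:
    """Completion rate and duration applied to every telephone contact."""

    phone_completion: float
    phone_duration: float

    def __post_init__(self) -> None:
        _check_fraction("phone_completion", self.phone_completion)
        _check_duration("phone_duration", self.phone_duration)


@dataclass(frozen=True)
class PathwayParams:
    """Parameters of one digital-first pathway.

    ``phone_followup_fraction`` is the share of non-completed e-consultations
    whose follow-up is a telephone call rather than f2f; it is structurally
    zero for telephone-first and video-first pathways.  ``demand_fraction``
    is the share of digital consultations that are new supply-related
    demand, in the open interval (−1, 1).
    """

    kind: PathwayKind
    access_rate: float
    completion_rate: float
    digital_duration: float
    demand_fraction: float = 0.0
    phone_followup_fraction: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PathwayKind(self.kind))
        _check_fraction("access_rate", self.access_rate)
        _check_fraction("completion_rate", self.completion_rate)
        _check_fraction("phone_followup_fraction", self.phone_followup_fraction)
        _check_duration("digital_duration", self.digital_duration)
        d = float(self.demand_fraction)
        if not math.isfinite(d) or not -1.0 < d < 1.0:
            raise ValidationError(
                f"demand_fraction must be in the open interval (-1, 1), got {d!r}"
            )
        if self.kind is not PathwayKind.ECONSULT and self.phone_followup_fraction != 0.0:
            raise ValidationError(
                "phone_followup_fraction is only meaningful for the econsult "
                f"pathway and must be 0 for kind={self.kind.value!r}"
            )


@dataclass(frozen=True)
class Scenario:
    """A complete model input: baseline mix, one pathway, shared phone cascade."""

    mix: ConventionalMix
    pathway: PathwayParams
    phone_cascade: PhoneCascadeParams
    label: str = ""


@dataclass(frozen=True)
class ContactCounts:
    """Monthly contact counts around the introduction of a digital route."""

    contacts_before: float
    contacts_after: float
    duplicate_consultations: float
    digital_consultations: float

    def __post_init__(self) -> None:
        for name in ("contacts_before", "contacts_after", "duplicate_consultations"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be a count >= 0, got {v!r}")
        if not math.isfinite(self.digital_consultations) or self.digital_consultations <= 0:
            raise DomainError(
                "digital_consultations must be > 0, got "
                f"{self.digital_consultations!r}"
            )


@dataclass(frozen=True)
class WorkloadResult:
    """Outcome of a workload comparison.

    ``components`` is a labelled breakdown of GP minutes per 100 baseline
    requests under the digital-first arrangement; the entries sum to
    ``workload_ratio * 100 * conventional_minutes_per_request``.
    """

    conventional_minutes_per_request: float
    digital_minutes_per_request: float
    demand_multiplier: float
    workload_ratio: float
    percent_change: float
    rounded_percent_change: int
    components: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Flat record with deterministic key order (components prefixed)."""
        out: dict = {
            "conventional_minutes_per_request": self.conventional_minutes_per_request,
            "digital_minutes_per_request": self.digital_minutes_per_request,
            "demand_multiplier": self.demand_multiplier,
            "workload_ratio": self.workload_ratio,
            "percent_change": self.percent_change,
            "rounded_percent_change": self.rounded_percent_change,
        }
        for key in sorted(self.components):
            out[f"components.{key}"] = self.components[key]
        return out


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves toward +infinity (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


def conventional_workload(mix: ConventionalMix, cascade: PhoneCascadeParams) -> float:
    """Expected GP minutes per request under conventional care.

    The telephone arm cascades: a call that does not complete is followed by
    a f2f consultation.
    """
    phone_minutes = cascade.phone_duration + (1.0 - cascade.phone_completion) * mix.f2f_duration
    return mix.f2f_fraction * mix.f2f_duration + mix.phone_fraction * phone_minutes


def expected_digital_minutes(
    pathway: PathwayParams, cascade: PhoneCascadeParams, f2f_duration: float
) -> float:
    """Expected GP minutes per request that enters the digital pathway.

    Telephone-first and video-first contacts cascade directly to f2f when
    not completed.  A non-completed e-consultation splits between a
    telephone follow-up (which carries the shared phone cascade and can
    itself cascade to f2f) and a direct f2f follow-up.
    """
    _check_duration("f2f_duration", f2f_duration)
    incomplete = 1.0 - pathway.completion_rate
    if pathway.kind is PathwayKind.ECONSULT:
        p = pathway.phone_followup_fraction
        phone_minutes = cascade.phone_duration + (1.0 - cascade.phone_completion) * f2f_duration
        followup = p * phone_minutes + (1.0 - p) * f2f_duration
    else:
        followup = f2f_duration
    return pathway.digital_duration + incomplete * followup


def demand_multiplier(demand_fraction: float, access_rate: float) -> float:
    """Total requests per baseline request when a fraction of digital
    consultations is new demand.

    Fixed point of "fraction ``d`` of the ``a``-share of total requests is
    new": ``N = 1 + d·a·N``, hence ``N = 1 / (1 − d·a)``.  Raises
    :class:`DomainError` when ``d·a >= 1`` (demand grows without bound).
    """
    da = demand_fraction * access_rate
    if da >= 1.0:
        raise DomainError(
            f"unbounded induced demand: demand_fraction*access_rate = {da} >= 1"
        )
    return 1.0 / (1.0 - da)


def workload_change(scenario: Scenario) -> WorkloadResult:
    """Compare GP workload under a digital-first scenario with conventional care.

    Per baseline request the digital arrangement costs
    ``[a·E_digital + (1−a)·W_conv] / (1 − d·a)`` GP minutes, where
    ``W_conv`` is the conventional per-request workload and ``E_digital``
    the per-request workload of the digital pathway.  The workload ratio
    divides by ``W_conv``; the headline percent change is
    ``100·(ratio − 1)``, reported both unrounded and rounded half-up.
    """
    mix, pathway, cascade = scenario.mix, scenario.pathway, scenario.phone_cascade
    w_conv = conventional_workload(mix, cascade)
    e_digital = expected_digital_minutes(pathway, cascade, mix.f2f_duration)
    mult = demand_multiplier(pathway.demand_fraction, pathway.access_rate)

    a = pathway.access_rate
    per_baseline = (a * e_digital + (1.0 - a) * w_conv) * mult
    ratio = per_baseline / w_conv
    pct = 100.0 * (ratio - 1.0)

    # minutes per 100 baseline requests; n_total requests arrive in total
    n_total = 100.0 * mult
    incomplete = 1.0 - pathway.completion_rate
    if pathway.kind is PathwayKind.ECONSULT:
        p = pathway.phone_followup_fraction
        phone_follow = n_total * a * incomplete * p * cascade.phone_duration
        f2f_follow = n_total * a * incomplete * (
            p * (1.0 - cascade.phone_completion) + (1.0 - p)
        ) * mix.f2f_duration
    else:
        phone_follow = 0.0
        f2f_follow = n_total * a * incomplete * mix.f2f_duration
    components = {
        "digital_first_contact": n_total * a * pathway.digital_duration,
        "phone_followup": phone_follow,
        "f2f_followup": f2f_follow,
        "conventional_arm": n_total * (1.0 - a) * w_conv,
    }

    return WorkloadResult(
        conventional_minutes_per_request=w_conv,
        digital_minutes_per_request=per_baseline,
        demand_multiplier=mult,
        workload_ratio=ratio,
        percent_change=pct,
        rounded_percent_change=round_half_up(pct),
        components=components,
    )


def estimate_supply_related_demand(counts: ContactCounts) -> float:
    """Fraction of digital consultations representing new demand.

    Computed from monthly counts as
    ``(contacts_after − contacts_before − duplicates) / digital``:
    the net growth in contacts of all types, net of duplicate consultations
    (f2f consultations directly resulting from a digital one), per digital
    consultation.  Negative when the digital route suppresses demand.
    """
    return (
        counts.contacts_after - counts.contacts_before - counts.duplicate_consultations
    ) / counts.digital_consultations


@dataclass(frozen=True)
class SimulationResult:
    """Empirical counterpart of :class:`WorkloadResult` from a microsimulation."""

    n_baseline: int
    n_total: int
    workload_ratio: float
    percent_change: float
    std_error: float
    n_digital: int
    n_phone_followup: int
    n_f2f_followup: int
    seed: int


def simulate_cohort(scenario: Scenario, n_requests: int, seed: int) -> SimulationResult:
    """Monte Carlo oracle for :func:`workload_change`.

    Simulates ``n_requests`` baseline requests inflated deterministically by
    the demand multiplier; every branch point (access, completion, follow-up
    modality, phone cascade) is an independent Bernoulli draw, so the
    empirical workload ratio isolates branching variance.  ``std_error`` is
    the standard error of ``percent_change``; reproducible for a fixed seed.
    """
    if n_requests < 1:
        raise ValidationError(f"n_requests must be >= 1, got {n_requests!r}")
    mix, pathway, cascade = scenario.mix, scenario.pathway, scenario.phone_cascade
    mult = demand_multiplier(pathway.demand_fraction, pathway.access_rate)
    w_conv = conventional_workload(mix, cascade)
    n_total = int(round(n_requests * mult))

    rng = np.random.default_rng(seed)
    minutes = np.zeros(n_total)

    digital = rng.random(n_total) < pathway.access_rate
    n_dig = int(digital.sum())
    minutes[digital] += pathway.digital_duration

    completed = np.zeros(n_total, dtype=bool)
    completed[digital] = rng.random(n_dig) < pathway.completion_rate
    needs_follow = digital & ~completed
    n_follow = int(needs_follow.sum())

    if pathway.kind is PathwayKind.ECONSULT:
        phone_follow = np.zeros(n_total, dtype=bool)
        phone_follow[needs_follow] = rng.random(n_follow) < pathway.phone_followup_fraction
        f2f_follow = needs_follow & ~phone_follow
        minutes[phone_follow] += cascade.phone_duration
        n_pf = int(phone_follow.sum())
        cascade_f2f = np.zeros(n_total, dtype=bool)
        cascade_f2f[phone_follow] = rng.random(n_pf) >= cascade.phone_completion
        f2f_follow = f2f_follow | cascade_f2f
    else:
        phone_follow = np.zeros(n_total, dtype=bool)
        f2f_follow = needs_follow
    minutes[f2f_follow] += mix.f2f_duration

    conventional = ~digital
    n_conv = int(conventional.sum())
    conv_f2f = np.zeros(n_total, dtype=bool)
    conv_f2f[conventional] = rng.random(n_conv) < mix.f2f_fraction
    conv_phone = conventional & ~conv_f2f
    minutes[conv_f2f] += mix.f2f_duration
    # every telephone contact carries the shared cascade parameters
    minutes[conv_phone] += cascade.phone_duration
    n_cp = int(conv_phone.sum())
    conv_cascade = np.zeros(n_total, dtype=bool)
    conv_cascade[conv_phone] = rng.random(n_cp) >= cascade.phone_completion
    minutes[conv_cascade] += mix.f2f_duration

    baseline_total = n_requests * w_conv
    ratio = float(minutes.sum()) / baseline_total
    sd = float(minutes.std(ddof=1)) if n_total > 1 else 0.0
    se_ratio = math.sqrt(n_total) * sd / baseline_total

    return SimulationResult(
        n_baseline=int(n_requests),
        n_total=n_total,
        workload_ratio=ratio,
        percent_change=100.0 * (ratio - 1.0),
        std_error=100.0 * se_ratio,
        n_digital=n_dig,
        n_phone_followup=int(phone_follow.sum()),
        n_f2f_followup=int(f2f_follow.sum()),
        seed=int(seed),
    )
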