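"""Pairwise decision analysis: incremental cost, effect, ICER and net benefit.

Orientation conventions, used consistently throughout the package:

* ``Comparison.delta_cost`` is the comparator-minus-intervention cost
  difference, ``C_in_person - C_mobile`` — i.e. the saving realised by the
  mobile strategy.  Positive means mobile is cheaper.
* ``Comparison.delta_effect`` is ``E_mobile - E_in_person``.
* Incremental net benefit INB = lambda * delta_effect + delta_cost, so a
  positive INB favours the mobile strategy (this matches the sign convention
  of the two-way sensitivity grid, where negative cells favour in-person).
* The ICER is reported in the standard intervention-minus-comparator frame:
  incremental cost of mobile = ``-delta_cost``, divided by ``delta_effect``.
  When the effect difference is (numerically) zero the ICER is undefined and
  flagged not reportable rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .costs import ArmModel, CostBreakdown, Payer, aggregate_costs

__all__ = [
    "Perspective",
    "Comparison",
    "IcerResult",
    "InbResult",
    "NOT_REPORTABLE",
    "wtp_per_effect",
    "incremental",
    "icer",
    "inb",
    "to_usd",
]

#: Effect differences smaller than this (in absolute value) are treated as
#: exactly zero when deciding whether an ICER is reportable.
DELTA_EFFECT_TOL = 1e-9

NOT_REPORTABLE = "not_reportable"


class Perspective(str, Enum):
    """Which payer strata enter the cost difference."""

    societal = "societal"
    health_system = "health_system"

    @property
    def payers(self) -> tuple[Payer, ...]:
        if self is Perspective.health_system:
            return (Payer.health_system,)
        return (Payer.health_system, Payer.patient, Payer.external)


@dataclass(frozen=True)
class Comparison:
    """An incremental comparison of mobile vs in-person follow-up.

    ``delta_cost`` is oriented comparator-minus-intervention (in-person minus
    mobile): positive = mobile saves money.  ``delta_effect`` is mobile minus
    in-person success probability.
    """

    delta_cost: float
    delta_effect: float
    perspective: Perspective

    @property
    def incremental_cost(self) -> float:
        """Cost of mobile minus cost of in-person (standard ICER numerator)."""
        return -self.delta_cost


@dataclass(frozen=True)
class IcerResult:
    """ICER value (CAD per additional successful outcome) with quadrant label.

    ``value`` is ``None`` and ``reportable`` is False when the effect
    difference is zero to tolerance.
    """

    value: Optional[float]
    reportable: bool
    quadrant: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.reportable:
            return f"{NOT_REPORTABLE} ({self.quadrant})"
        return f"{self.value:.2f} CAD/effect ({self.quadrant})"


@dataclass(frozen=True)
class InbResult:
    wtp_per_effect: float
    inb: float


def wtp_per_effect(wtp_per_qaly: float, qaly_loss: float) -> float:
    """Convert a per-QALY willingness-to-pay threshold to a per-effect one.

    One "effect" is one successful 30-day surgical outcome; its QALY value is
    the decrement attached to the complication it avoids, so the per-effect
    threshold is simply the product of the two inputs.
    """
    if wtp_per_qaly <= 0:
        raise ValueError("wtp_per_qaly must be positive")
    if qaly_loss < 0:
        raise ValueError("qaly_loss must be non-negative")
    return wtp_per_qaly * qaly_loss


def incremental(
    mobile: ArmModel,
    in_person: ArmModel,
    perspective: Perspective = Perspective.societal,
) -> Comparison:
    """Cost and effect differences between the two arms under a perspective.

    Both arms must have been costed with the same economic parameters for the
    comparison to be meaningful.
    """
    cb_m = aggregate_costs(mobile)
    cb_i = aggregate_costs(in_person)
    return incremental_from_breakdowns(
        cb_m, mobile.p_success, cb_i, in_person.p_success, perspective
    )


def incremental_from_breakdowns(
    mobile_costs: CostBreakdown,
    mobile_effect: float,
    in_person_costs: CostBreakdown,
    in_person_effect: float,
    perspective: Perspective = Perspective.societal,
) -> Comparison:
    payers = perspective.payers
    c_m = sum(mobile_costs.by_payer.get(p, 0.0) for p in payers)
    c_i = sum(in_person_costs.by_payer.get(p, 0.0) for p in payers)
    return Comparison(
        delta_cost=c_i - c_m,
        delta_effect=mobile_effect - in_person_effect,
        perspective=perspective,
    )


def _quadrant(incr_cost: float, delta_effect: float) -> str:
    de0 = abs(delta_effect) <= DELTA_EFFECT_TOL
    dc0 = incr_cost == 0.0
    if de0 and dc0:
        return "equivalent"
    if de0:
        return "equal effect, cost saving" if incr_cost < 0 else "equal effect, cost increase"
    if dc0:
        return "dominant (equal cost)" if delta_effect > 0 else "dominated (equal cost)"
    if delta_effect > 0 and incr_cost < 0:
        return "dominant"
    if delta_effect < 0 and incr_cost > 0:
        return "dominated"
    return "trade-off"


def icer(comp: Comparison, tol: float = DELTA_EFFECT_TOL) -> IcerResult:
    """Incremental cost-effectiveness ratio of mobile vs in-person.

    Computed as (C_mobile - C_in_person) / (E_mobile - E_in_person).  When
    the effect difference is zero to ``tol`` the ratio is undefined: the
    result carries ``value=None`` and ``reportable=False`` (a sentinel, not
    an exception), since a pure cost difference carries no ratio information.
    A quadrant label (dominant / dominated / trade-off / equal-effect) is
    always attached.
    """
    ic = comp.incremental_cost
    quadrant = _quadrant(ic, comp.delta_effect)
    if abs(comp.delta_effect) <= tol:
        return IcerResult(value=None, reportable=False, quadrant=quadrant)
    return IcerResult(value=ic / comp.delta_effect, reportable=True, quadrant=quadrant)


def inb(comp: Comparison, lam: float) -> InbResult:
    """Incremental net benefit at willingness-to-pay ``lam`` (CAD/effect).

    INB = lam * delta_effect + delta_cost; positive favours mobile.  When the
    arms are equally effective the INB collapses to the cost difference and
    is invariant in ``lam``.
    """
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return InbResult(wtp_per_effect=lam, inb=lam * comp.delta_effect + comp.delta_cost)


def to_usd(amount_cad: float, rate: float, rounded: bool = True) -> float:
    """Present a CAD amount in USD at ``rate`` USD per CAD.

    Whole-dollar presentation rounding (half-up, via the reporting module's
    shared helper) is applied by default; pass ``rounded=False`` for the raw
    product.
    """
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    value = amount_cad * rate
    if rounded:
        from .reporting import round_half_up

        return round_half_up(value)
    return value
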