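"""Deterministic and probabilistic sensitivity analyses.

Three analyses around the base case:

* **Scenario analysis** — re-cost the in-person arm at an arbitrary visit
  count and optionally let a fraction of mobile-arm patients cross over to
  one in-person visit.
* **Two-way grid** — incremental net benefit over a grid of per-visit
  foregone-leisure cost (columns) by mobile success probability (rows),
  holding the in-person reference effect fixed.
* **Probabilistic sensitivity analysis (PSA)** — Monte Carlo propagation of
  parameter uncertainty: uniform +/-20% on the in-person clinic (health
  system) cost, uniform +/-2 percentage points on each arm's effect
  (truncated to [0, 1]), and a gamma-distributed patient wage feeding the
  foregone-leisure cost.  No mobile-arm parameter is varied.  Summaries
  include the cost-effectiveness acceptability curve (CEAC) and the ICER
  plane with quadrant counts.

Sampling uses a single seeded :class:`numpy.random.Generator` per run with a
fixed draw order (clinic cost, mobile effect, in-person effect, wage) so a
given seed reproduces a run bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .costs import ArmModel, EconParams, Payer, aggregate_costs
from .decision import Comparison, Perspective, wtp_per_effect

__all__ = [
    "IN_PERSON_PATIENT_LABELS",
    "TwoWayGrid",
    "WageDistribution",
    "PsaSpec",
    "PsaResult",
    "scenario_visits",
    "two_way",
    "run_psa",
    "ceac",
    "icer_plane",
]

#: Ledger labels of the in-person arm's patient-side components, in the role
#: order (leisure, caregiver, travel, parking) the analyses need to tell
#: apart.  Override per call if a custom config renames them.
IN_PERSON_PATIENT_LABELS: dict[str, str] = {
    "leisure": "Patient leisure time",
    "caregiver": "Caregiver wage",
    "travel": "Travel (to and from clinic)",
    "parking": "Parking",
}


def _in_person_parts(
    in_person: ArmModel, labels: dict[str, str] | None = None
) -> dict[str, float]:
    """Split the in-person arm into the pieces the sensitivity analyses vary."""
    labels = labels or IN_PERSON_PATIENT_LABELS
    parts = {role: in_person.component(lbl).amount for role, lbl in labels.items()}
    parts["health_system"] = in_person.subtotal(Payer.health_system)
    return parts


def scenario_visits(
    visits: float,
    crossover_fraction: float,
    mobile: ArmModel,
    in_person: ArmModel,
    params: EconParams,
    caregiver_at_crossover: bool = False,
    labels: dict[str, str] | None = None,
) -> Comparison:
    """Societal comparison with the in-person arm re-costed at ``visits``.

    Health-system and per-visit patient costs (leisure, travel, parking)
    scale linearly with the visit count relative to the baseline mean;
    the caregiver attends only the first visit, so that cost is scaled by
    ``min(visits, 1)`` (a fractional mean visit count is read as the fraction
    of patients attending a first visit).

    ``crossover_fraction`` of mobile-arm patients additionally attend one
    in-person visit; its cost is one visit's worth of the baseline in-person
    societal cost.  By default the crossover visit is an unplanned assessment
    without an accompanying caregiver; set ``caregiver_at_crossover`` to
    include one.
    """
    if visits < 0:
        raise ValueError("visits must be non-negative")
    if not 0.0 <= crossover_fraction <= 1.0:
        raise ValueError("crossover_fraction must lie in [0, 1]")

    parts = _in_person_parts(in_person, labels)
    scale = visits / params.visits_per_month
    per_visit_scaled = parts["health_system"] + parts["leisure"] + parts["travel"] + parts["parking"]
    cost_in = per_visit_scaled * scale + parts["caregiver"] * min(visits, 1.0)

    one_visit = per_visit_scaled / params.visits_per_month
    if caregiver_at_crossover:
        one_visit += parts["caregiver"]
    cost_mob = aggregate_costs(mobile).total + crossover_fraction * one_visit

    return Comparison(
        delta_cost=cost_in - cost_mob,
        delta_effect=mobile.p_success - in_person.p_success,
        perspective=Perspective.societal,
    )


@dataclass(frozen=True)
class TwoWayGrid:
    """INB grid over per-visit leisure cost (columns) x mobile effect (rows)."""

    leisure_cost_per_visit_axis: tuple[float, ...]
    mobile_effect_axis: tuple[float, ...]
    inb_matrix: np.ndarray  # shape (len(effect axis), len(leisure axis))
    reference_in_person_effect: float
    wtp_per_effect: float

    def __post_init__(self) -> None:
        m = np.asarray(self.inb_matrix)
        expected = (len(self.mobile_effect_axis), len(self.leisure_cost_per_visit_axis))
        if m.shape != expected:
            raise ValueError(f"inb_matrix shape {m.shape} does not match axes {expected}")
        if not np.all(np.isfinite(m)):
            raise ValueError("inb_matrix contains non-finite cells")

    def cell(self, effect: float, leisure: float) -> float:
        i = self.mobile_effect_axis.index(effect)
        j = self.leisure_cost_per_visit_axis.index(leisure)
        return float(self.inb_matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.inb_matrix,
            index=pd.Index(self.mobile_effect_axis, name="mobile_effect"),
            columns=pd.Index(self.leisure_cost_per_visit_axis, name="leisure_cost_per_visit"),
        )


def two_way(
    leisure_axis: Sequence[float],
    effect_axis: Sequence[float],
    mobile: ArmModel,
    in_person: ArmModel,
    params: EconParams,
    reference_effect: float | None = None,
    labels: dict[str, str] | None = None,
) -> TwoWayGrid:
    """Two-way INB grid over patient leisure cost and mobile effectiveness.

    Cell(e, L) = lambda * (e - reference effect) + [C_in(L) - C_mobile],
    where C_in(L) replaces the in-person patient leisure subtotal with
    ``visits_per_month * L`` (L is a *per-visit* leisure cost, e.g. 3 h times
    an hourly wage) while caregiver, travel and parking stay at baseline, and
    lambda is the per-effect willingness-to-pay derived from the per-QALY
    threshold.
    """
    if len(leisure_axis) == 0 or len(effect_axis) == 0:
        raise ValueError("axes must be non-empty")
    ref = in_person.p_success if reference_effect is None else reference_effect
    if not 0.0 <= ref <= 1.0:
        raise ValueError("reference_effect must lie in [0, 1]")

    lam = wtp_per_effect(params.wtp_per_qaly, params.qaly_loss_per_complication)
    parts = _in_person_parts(in_person, labels)
    cost_mob = aggregate_costs(mobile).total
    fixed_in = parts["health_system"] + parts["caregiver"] + parts["travel"] + parts["parking"]

    L = np.asarray(leisure_axis, dtype=float)
    E = np.asarray(effect_axis, dtype=float)
    delta_cost = fixed_in + params.visits_per_month * L - cost_mob  # per column
    matrix = lam * (E[:, None] - ref) + delta_cost[None, :]

    return TwoWayGrid(
        leisure_cost_per_visit_axis=tuple(float(x) for x in L),
        mobile_effect_axis=tuple(float(x) for x in E),
        inb_matrix=matrix,
        reference_in_person_effect=ref,
        wtp_per_effect=lam,
    )


class WageDistribution(BaseModel):
    """Gamma wage model for the PSA, parameterised by mean and coefficient of
    variation (cv = sd/mean; cv 0 collapses to a point mass at the mean)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    family: Literal["gamma"] = "gamma"
    mean: float = Field(gt=0)
    cv: float = Field(ge=0)


class PsaSpec(BaseModel):
    """Distribution assignments and run size for the probabilistic analysis."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_draws: int = Field(default=10_000, ge=1)
    seed: int = Field(default=0, ge=0)
    clinic_cost_rel_halfwidth: float = Field(default=0.20, ge=0)
    effect_abs_halfwidth: float = Field(default=0.02, ge=0)
    wage_distribution: WageDistribution


@dataclass(frozen=True)
class PsaResult:
    """Paired Monte Carlo draws with arm-cost summaries.

    ``draws`` has one row per draw with columns ``cost_mobile``,
    ``cost_in_person``, ``effect_mobile``, ``effect_in_person``,
    ``delta_cost`` (in-person minus mobile) and ``delta_effect`` (mobile
    minus in-person).
    """

    spec: PsaSpec
    draws: pd.DataFrame
    wtp_per_effect: float
    summaries: dict = field(repr=False)

    @property
    def fraction_mobile_preferred(self) -> float:
        """Share of draws with positive INB at the run's willingness-to-pay."""
        nb = self.wtp_per_effect * self.draws["delta_effect"] + self.draws["delta_cost"]
        return float((nb > 0).mean())


def run_psa(
    spec: PsaSpec,
    mobile: ArmModel,
    in_person: ArmModel,
    params: EconParams,
    labels: dict[str, str] | None = None,
) -> PsaResult:
    """Run the Monte Carlo probabilistic sensitivity analysis.

    Per draw: the in-person clinic (health-system) cost is uniform within
    +/- ``clinic_cost_rel_halfwidth`` of its base value; each arm's effect is
    uniform within +/- ``effect_abs_halfwidth`` of its base value, truncated
    to [0, 1]; the patient wage is gamma with the given mean and cv and feeds
    the leisure cost (wage x leisure hours x visits).  Caregiver, travel and
    parking stay at their deterministic values, as does the entire mobile
    arm.  With all halfwidths and cv zero every draw equals the base case.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_draws
    parts = _in_person_parts(in_person, labels)

    clinic_base = parts["health_system"]
    h = spec.clinic_cost_rel_halfwidth
    clinic = rng.uniform(clinic_base * (1 - h), clinic_base * (1 + h), size=n)

    eh = spec.effect_abs_halfwidth
    effect_mobile = np.clip(
        rng.uniform(mobile.p_success - eh, mobile.p_success + eh, size=n), 0.0, 1.0
    )
    effect_in = np.clip(
        rng.uniform(in_person.p_success - eh, in_person.p_success + eh, size=n), 0.0, 1.0
    )

    wd = spec.wage_distribution
    if wd.cv == 0:
        wage = np.full(n, wd.mean)
    else:
        shape = 1.0 / wd.cv**2
        wage = rng.gamma(shape, wd.mean * wd.cv**2, size=n)
    leisure = wage * params.leisure_hours_per_visit * params.visits_per_month

    cost_in = clinic + leisure + parts["caregiver"] + parts["travel"] + parts["parking"]
    cost_mob = np.full(n, aggregate_costs(mobile).total)

    draws = pd.DataFrame(
        {
            "cost_mobile": cost_mob,
            "cost_in_person": cost_in,
            "effect_mobile": effect_mobile,
            "effect_in_person": effect_in,
        }
    )
    draws["delta_cost"] = draws["cost_in_person"] - draws["cost_mobile"]
    draws["delta_effect"] = draws["effect_mobile"] - draws["effect_in_person"]

    lam = wtp_per_effect(params.wtp_per_qaly, params.qaly_loss_per_complication)
    summaries = {
        arm: {
            "mean": float(draws[f"cost_{arm}"].mean()),
            "sd": float(draws[f"cost_{arm}"].std(ddof=1)) if n > 1 else 0.0,
        }
        for arm in ("mobile", "in_person")
    }
    return PsaResult(spec=spec, draws=draws, wtp_per_effect=lam, summaries=summaries)


def ceac(result: PsaResult, lambda_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    For each lambda, the fraction of draws whose incremental net benefit
    ``lambda * delta_effect + delta_cost`` is strictly positive (a zero INB —
    exact indifference — does not count as preferred).
    """
    if len(result.draws) == 0:
        raise ValueError("PSA result has no draws")
    de = result.draws["delta_effect"].to_numpy()
    dc = result.draws["delta_cost"].to_numpy()
    lams = np.asarray(list(lambda_grid), dtype=float)
    frac = [(lam * de + dc > 0).mean() for lam in lams]
    return pd.DataFrame({"wtp_per_effect": lams, "fraction_mobile_preferred": frac})


def icer_plane(result: PsaResult) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-draw points on the incremental cost-effectiveness plane.

    Points are in the standard intervention-minus-comparator frame:
    x = delta_effect (mobile minus in-person), y = incremental cost (mobile
    minus in-person, the negation of ``delta_cost``).  Quadrant labels use
    the convention that ``delta_effect >= 0`` counts as "more effective" and
    ``incremental cost < 0`` as "cheaper"; the four counts sum to the number
    of draws.
    """
    if len(result.draws) == 0:
        raise ValueError("PSA result has no draws")
    de = result.draws["delta_effect"].to_numpy()
    ic = -result.draws["delta_cost"].to_numpy()
    more_effective = de >= 0
    cheaper = ic < 0
    quadrant = np.where(
        cheaper,
        np.where(more_effective, "cheaper_more_effective", "cheaper_less_effective"),
        np.where(more_effective, "costlier_more_effective", "costlier_less_effective"),
    )
    table = pd.DataFrame(
        {"delta_effect": de, "incremental_cost": ic, "quadrant": quadrant}
    )
    counts = table["quadrant"].value_counts().to_dict()
    for label in (
        "cheaper_more_effective",
        "cheaper_less_effective",
        "costlier_more_effective",
        "costlier_less_effective",
    ):
        counts.setdefault(label, 0)
    return table, counts
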