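"""Micro-costing model for the 30-day postoperative follow-up horizon.

Each follow-up strategy (arm) is a ledger of labeled cost components, each
assigned to a payer stratum (health system, patient/caregiver, external) and
classified as fixed or variable.  Costs are per patient over the first
postoperative month, in CAD.  All amounts are held unrounded internally;
whole-dollar rounding happens only at report time (:mod:`ambucea.reporting`).

The patient-side cost of in-person follow-up is built bottom-up from foregone
leisure time (hourly wage x hours per visit x visits), a caregiver's wage at
the first visit, per-kilometre travel, and parking.  The mobile arm's
patient-side data cost is computed but treated as negligible (excluded from
subtotals) in the default accounting mode.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Payer",
    "CostKind",
    "CostComponent",
    "ArmModel",
    "EconParams",
    "CostBreakdown",
    "aggregate_costs",
    "patient_cost_in_person",
    "patient_cost_mobile",
    "amortize_fixed",
]


class Payer(str, Enum):
    """Who bears a cost under the societal perspective."""

    health_system = "health_system"
    patient = "patient"
    external = "external"


class CostKind(str, Enum):
    fixed = "fixed"
    variable = "variable"


class CostComponent(BaseModel):
    """One labeled dollar amount in an arm's ledger (CAD per patient per 30 days)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    label: str = Field(min_length=1)
    payer: Payer
    kind: CostKind
    amount: float = Field(ge=0, description="CAD per patient per 30-day horizon")


class ArmModel(BaseModel):
    """An intervention arm: its cost components plus its probability of a
    successful 30-day surgical outcome (the effect measure)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    components: tuple[CostComponent, ...] = ()
    p_success: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _unique_labels(self) -> "ArmModel":
        labels = [c.label for c in self.components]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate component labels in arm {self.name!r}: {dupes}")
        return self

    def component(self, label: str) -> CostComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"arm {self.name!r} has no component {label!r}")

    def subtotal(self, payer: Payer) -> float:
        return sum(c.amount for c in self.components if c.payer == payer)


class EconParams(BaseModel):
    """Global economic constants of the model.

    Units: money in CAD, time in hours, distance in km.  ``visits_per_month``
    is the mean number of in-person follow-up visits over the 30-day horizon
    and may be fractional.  ``leisure_hours_per_visit`` is the total foregone
    leisure per visit (clinic time plus round-trip travel time).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    wtp_per_qaly: float = Field(gt=0)
    qaly_loss_per_complication: float = Field(gt=0)
    exchange_rate_usd_per_cad: float = Field(gt=0)
    visits_per_month: float = Field(gt=0)
    clinic_hours_per_visit: float = Field(gt=0)
    leisure_hours_per_visit: float = Field(gt=0)
    caregiver_hourly_wage: float = Field(gt=0)
    parking_per_visit: float = Field(gt=0)
    travel_cost_per_km: float = Field(gt=0)
    amortization_years: float = Field(gt=0)
    patients_per_year: float = Field(gt=0)
    data_mb_per_submission: float = Field(gt=0)
    data_price_per_gb: float = Field(gt=0)


class CostBreakdown(BaseModel):
    """Per-patient cost subtotals by payer stratum, plus the societal total."""

    model_config = ConfigDict(frozen=True)

    by_payer: Mapping[Payer, float]
    total: float

    @model_validator(mode="after")
    def _consistent(self) -> "CostBreakdown":
        if any(v < -1e-12 for v in self.by_payer.values()):
            raise ValueError("negative payer subtotal")
        s = sum(self.by_payer.values())
        if abs(s - self.total) > 1e-9 * max(1.0, abs(s)):
            raise ValueError(f"total {self.total} does not equal payer sum {s}")
        return self


def aggregate_costs(arm: ArmModel) -> CostBreakdown:
    """Sum an arm's component ledger into payer subtotals and a societal total.

    The societal total is the sum over all payer strata (health system +
    patient + external).  Values are unrounded.
    """
    by_payer = {p: 0.0 for p in Payer}
    for c in arm.components:
        by_payer[c.payer] += c.amount
    return CostBreakdown(by_payer=by_payer, total=sum(by_payer.values()))


def patient_cost_in_person(
    wage: float,
    params: EconParams,
    visits: float,
    caregiver_first_visit: bool = True,
    round_trip_km: float = 0.0,
) -> float:
    """Patient/caregiver-borne cost of in-person follow-up.

    Four addends: foregone leisure (wage x leisure hours per visit x visits),
    a caregiver at the first visit only (homemaker wage x leisure hours, not
    scaled by visit count), travel (round-trip km x per-km rate x visits) and
    parking (per-visit rate x visits).

    Parameters
    ----------
    wage : float
        Patient's hourly wage in CAD (labour-force non-participants carry the
        homemaker wage).
    visits : float
        Number of in-person visits over the horizon; may be fractional when
        it represents a cohort mean.
    caregiver_first_visit : bool
        Whether a caregiver accompanies the patient to the first visit.
    round_trip_km : float
        Home-to-hospital-and-back distance driven per visit.
    """
    if wage < 0:
        raise ValueError("wage must be non-negative")
    if visits < 0:
        raise ValueError("visits must be non-negative")
    if round_trip_km < 0:
        raise ValueError("round_trip_km must be non-negative")
    leisure = wage * params.leisure_hours_per_visit * visits
    caregiver = (
        params.caregiver_hourly_wage * params.leisure_hours_per_visit
        if caregiver_first_visit and visits > 0
        else 0.0
    )
    travel = round_trip_km * params.travel_cost_per_km * visits
    parking = params.parking_per_visit * visits
    return leisure + caregiver + travel + parking


def patient_cost_mobile(params: EconParams, n_submissions: float) -> float:
    """Patient-borne data cost of mobile-app follow-up, in CAD.

    Each submission (questionnaire plus photo) uses ``data_mb_per_submission``
    MB at the prevailing price per GB.  Foregone leisure is zero: submissions
    are asynchronous and do not interrupt leisure.  The returned amount is
    reported but excluded from societal subtotals in the default accounting
    mode, where it is classified as negligible.
    """
    if n_submissions < 0:
        raise ValueError("n_submissions must be non-negative")
    return n_submissions * params.data_mb_per_submission * params.data_price_per_gb / 1024.0


def amortize_fixed(total_fixed: float, params: EconParams) -> float:
    """Per-patient share of start-up (fixed) costs.

    Start-up costs are spread over the patients served during the useful
    lifespan of the technology: ``total_fixed / (patients_per_year *
    amortization_years)``.
    """
    if total_fixed < 0:
        raise ValueError("total_fixed must be non-negative")
    denom = params.patients_per_year * params.amortization_years
    if denom <= 0:
        raise ValueError("patients_per_year * amortization_years must be positive")
    return total_fixed / denom
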