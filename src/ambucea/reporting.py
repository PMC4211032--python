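"""Report generation: rounding, tidy tables, plots, provenance.

This is the only module that rounds money or converts currency for
presentation.  Dollar tables are rounded half-up to whole dollars; the
two-way grid keeps two decimals, matching the mixed precision of the source
tables.  Every rendered report carries a provenance block (config hash,
seed, package version) so outputs are traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .config import RunConfig
from .costs import ArmModel, Payer, aggregate_costs, patient_cost_mobile
from .decision import Perspective, icer, inb, incremental, to_usd, wtp_per_effect
from .sensitivity import PsaResult, TwoWayGrid, ceac as ceac_curve, icer_plane

__all__ = [
    "round_half_up",
    "ledger_frame",
    "basecase_report",
    "Report",
    "render_report",
    "plot_ceac",
    "plot_icer_plane",
]

logger = logging.getLogger("ambucea")

_PAYER_TITLES = {
    Payer.health_system: "Health care system costs subtotal",
    Payer.patient: "Patient costs subtotal",
    Payer.external: "External costs subtotal",
}


def round_half_up(amount: float) -> int:
    """Round to the nearest whole dollar, halves away from zero."""
    return int(Decimal(repr(float(amount))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def ledger_frame(arms: dict[str, ArmModel]) -> pd.DataFrame:
    """Tidy component ledger (arm, label, payer, kind, amount) with subtotal
    and societal-total rows appended per arm (kind ``subtotal``/``total``)."""
    rows = []
    for arm_key, arm in arms.items():
        for c in arm.components:
            rows.append(
                {"arm": arm_key, "label": c.label, "payer": c.payer.value,
                 "kind": c.kind.value, "amount": c.amount}
            )
        breakdown = aggregate_costs(arm)
        for payer, title in _PAYER_TITLES.items():
            rows.append(
                {"arm": arm_key, "label": title, "payer": payer.value,
                 "kind": "subtotal", "amount": breakdown.by_payer[payer]}
            )
        rows.append(
            {"arm": arm_key, "label": "Total societal costs", "payer": "all",
             "kind": "total", "amount": breakdown.total}
        )
    return pd.DataFrame(rows, columns=["arm", "label", "payer", "kind", "amount"])


def basecase_report(config: RunConfig) -> dict:
    """Base-case comparison under both perspectives, CAD and USD.

    Whole-dollar amounts are presentation-rounded here; the unrounded cost
    difference is also carried for downstream use.  Under strict accounting
    the mobile arm's computed data cost is added to its patient subtotal
    instead of being treated as negligible.
    """
    mobile, in_person = config.arms.mobile, config.arms.in_person
    params = config.econ_params
    if config.strict_accounting:
        data_cost = patient_cost_mobile(params, n_submissions=18.0)
        comps = list(mobile.components) + [
            {"label": "Data transmission (strict)", "payer": "patient",
             "kind": "variable", "amount": data_cost}
        ]
        mobile = ArmModel(name=mobile.name, components=comps, p_success=mobile.p_success)

    rate = params.exchange_rate_usd_per_cad
    lam = wtp_per_effect(params.wtp_per_qaly, params.qaly_loss_per_complication)
    out: dict = {"wtp_per_effect_cad": lam, "perspectives": {}}
    for perspective in Perspective:
        comp = incremental(mobile, in_person, perspective)
        payers = perspective.payers
        cost_m = sum(aggregate_costs(mobile).by_payer[p] for p in payers)
        cost_i = sum(aggregate_costs(in_person).by_payer[p] for p in payers)
        r = icer(comp)
        out["perspectives"][perspective.value] = {
            "cost_mobile_cad": round_half_up(cost_m),
            "cost_in_person_cad": round_half_up(cost_i),
            "delta_cost_cad": round_half_up(comp.delta_cost),
            "delta_cost_cad_unrounded": comp.delta_cost,
            "delta_cost_usd": to_usd(comp.delta_cost, rate),
            "delta_effect": comp.delta_effect,
            "icer": r.value if r.reportable else "not_reportable",
            "icer_quadrant": r.quadrant,
            "inb_cad_at_wtp": round_half_up(inb(comp, lam).inb),
        }
    return out


@dataclass
class Report:
    """Rendered report: base-case numbers, the tables written, provenance."""

    basecase: dict
    tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)
    files: list[str] = dc_field(default_factory=list)


def _provenance(config: RunConfig) -> dict:
    digest = hashlib.sha256(config.model_dump_json().encode()).hexdigest()
    return {"config_sha256": digest, "seed": config.seed, "version": __version__}


def plot_ceac(curve: pd.DataFrame, path: str | Path) -> None:
    """Cost-effectiveness acceptability curve plot."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp_per_effect"], curve["fraction_mobile_preferred"], lw=2)
    ax.set_xlabel("Willingness-to-pay (CAD per successful outcome)")
    ax.set_ylabel("P(mobile follow-up preferred)")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_icer_plane(table: pd.DataFrame, path: str | Path) -> None:
    """Scatter of PSA draws on the incremental cost-effectiveness plane."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(table["delta_effect"], table["incremental_cost"], s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental effect (mobile − in-person)")
    ax.set_ylabel("Incremental cost, CAD (mobile − in-person)")
    ax.set_title("ICER plane")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_report(
    config: RunConfig,
    outdir: str | Path,
    twoway: TwoWayGrid | None = None,
    psa: PsaResult | None = None,
    ceac_lambdas: list[float] | None = None,
    make_plots: bool = True,
) -> Report:
    """Write the report files for whatever has been computed.

    Always writes the component ledger (``ledger.csv``) and the base-case
    JSON (``basecase.json``).  Given a two-way grid or a PSA result, writes
    their CSV tables (and CEAC/ICER-plane plots for the PSA).  Re-rendering
    with the same config and seed is byte-identical for the CSV/JSON files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    report = Report(basecase=basecase_report(config), provenance=_provenance(config))

    arms = {"mobile": config.arms.mobile, "in_person": config.arms.in_person}
    ledger = ledger_frame(arms)
    ledger.to_csv(outdir / "ledger.csv", index=False)
    report.tables["ledger"] = ledger
    report.files.append("ledger.csv")

    with open(outdir / "basecase.json", "w") as fh:
        json.dump({"provenance": report.provenance, **report.basecase}, fh, indent=2)
    report.files.append("basecase.json")

    if twoway is not None:
        grid = twoway.to_frame().round(2)
        grid.to_csv(outdir / "twoway_inb.csv")
        report.tables["twoway"] = grid
        report.files.append("twoway_inb.csv")

    if psa is not None:
        psa.draws.to_csv(outdir / "psa_draws.csv", index=False)
        report.files.append("psa_draws.csv")
        plane, counts = icer_plane(psa)
        summary = {
            "n_draws": int(len(psa.draws)),
            "wtp_per_effect": psa.wtp_per_effect,
            "cost_summaries": psa.summaries,
            "fraction_mobile_preferred": psa.fraction_mobile_preferred,
            "quadrant_counts": counts,
        }
        with open(outdir / "psa_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        report.files.append("psa_summary.json")

        lam = psa.wtp_per_effect
        lambdas = ceac_lambdas or [lam * f for f in (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0)]
        curve = ceac_curve(psa, lambdas)
        curve.to_csv(outdir / "ceac.csv", index=False)
        report.tables["ceac"] = curve
        report.files.append("ceac.csv")

        if make_plots:
            plot_ceac(curve, outdir / "ceac.png")
            plot_icer_plane(plane, outdir / "icer_plane.png")
            report.files.extend(["ceac.png", "icer_plane.png"])

    logger.info(
        "report rendered: outdir=%s files=%s elapsed=%.3fs",
        outdir, report.files, time.perf_counter() - t0,
    )
    return report
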