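#!/usr/bin/env python
"""Base case: 30-day follow-up cost ledger and incremental comparison.

Writes the tidy component ledger and the base-case JSON (both perspectives,
CAD and USD) to results/basecase/ and prints the headline numbers.
"""

from ambucea import default_config
from ambucea.reporting import render_report

config = default_config()
report = render_report(config, "results/basecase")

soc = report.basecase["perspectives"]["societal"]
hs = report.basecase["perspectives"]["health_system"]
print("Base case (CAD per patient, first postoperative month)")
print(f"  mobile app follow-up:  ${soc['cost_mobile_cad']}")
print(f"  in-person follow-up:   ${soc['cost_in_person_cad']}")
print(f"  societal cost difference:      ${soc['delta_cost_cad']} "
      f"(${soc['delta_cost_usd']} USD)")
print(f"  health-system cost difference: ${hs['delta_cost_cad']} "
      f"(${hs['delta_cost_usd']} USD)")
print(f"  effect difference: {soc['delta_effect']} -> ICER {soc['icer']}")
print(f"  INB at WTP ${report.basecase['wtp_per_effect_cad']:.2f}/effect: "
      f"${soc['inb_cad_at_wtp']} (any WTP, since effects are equal)")
print(f"wrote {', '.join(report.files)} to results/basecase")
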