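#!/usr/bin/env python
"""Probabilistic sensitivity analysis: 10,000 Monte Carlo draws.

Uniform +/-20% on the in-person clinic cost, +/-2 percentage points on each
arm's effect, gamma patient wage; no mobile parameter varied.  Writes the
draw table, CEAC and ICER-plane outputs to results/psa/.
"""

from ambucea import default_config, run_psa
from ambucea.reporting import render_report

config = default_config()
result = run_psa(
    config.psa, config.arms.mobile, config.arms.in_person, config.econ_params
)
report = render_report(config, "results/psa", psa=result)

m, i = result.summaries["mobile"], result.summaries["in_person"]
frac_less_effective = (result.draws["delta_effect"] < 0).mean()
print(f"{config.psa.n_draws} draws (seed {config.psa.seed}):")
print(f"  mean societal cost, mobile:    ${m['mean']:.2f} (SD {m['sd']:.2f} — unvaried)")
print(f"  mean societal cost, in-person: ${i['mean']:.2f} (SD {i['sd']:.2f})")
print(f"  mobile cheaper in {100 * (result.draws['delta_cost'] > 0).mean():.1f}% of draws")
print(f"  mobile less effective in {100 * frac_less_effective:.1f}% of draws")
print(f"  mobile preferred at WTP ${result.wtp_per_effect:.2f}/effect in "
      f"{100 * result.fraction_mobile_preferred:.1f}% of draws")
print(f"wrote {', '.join(report.files)} to results/psa")
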