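# Methods note

## Decision problem and model structure

Two strategies for the first postoperative month after ambulatory breast
reconstruction are compared: conventional in-person follow-up (a mean of
1.64 clinic visits) and asynchronous mobile-app follow-up (daily
questionnaire/photo submissions for two weeks, then weekly). The model is
a deterministic cost comparison with an attached effect probability per
arm — the probability of a successful 30-day surgical outcome (no medical
or surgical re-intervention). Costs are micro-costed per patient in 2013/14
CAD and assigned to payer strata: health system, patient/caregiver,
external. The societal perspective sums all strata; a health-system
perspective restricts to that stratum. The base case models equal effects
in the two arms (0.96 each), reflecting the observational evidence that
follow-up modality does not change the complication risk; the ICER is then
undefined and flagged not reportable, and the incremental net benefit
INB(λ) = λ·ΔE + ΔC collapses to the cost difference at every
willingness-to-pay λ. Positive INB favours the mobile strategy.

λ is derived from a per-QALY threshold: $109,970 CAD/QALY × 0.04 QALY per
superficial skin infection = $4,398.80 per successful outcome.

## Key parameters (defaults, units, provenance)

| Parameter | Default | Notes |
|---|---|---|
| visits_per_month | 1.64 | observed mean in-person attendance |
| leisure_hours_per_visit | 3 h | **calibrated**: 1 h clinic + ~2 h round trip; 3 × $11.28 reproduces the $33.84 caregiver row and the grid's wage columns |
| caregiver_hourly_wage | $11.28/h | homemaker wage; caregiver attends the first visit only, so the cost does not scale with 1.64 |
| implied patient wage | $20.7805/h | **calibrated**: 102.24/(1.64×3); stored at full precision so degenerate runs reproduce the ledger exactly |
| travel_cost_per_km | $0.15288/km | **calibrated** so that 152 km round trip × 1.64 visits = $38.11 (the per-km source rate is not printed) |
| parking_per_visit | $20.00 | 32.80/1.64 |
| amortization | 5 yr × 1000 patients/yr | mobile start-up fixed costs per patient |
| data cost | 0.35 MB/submission at $45/2 GB | ≈$0.14 per patient; computed, classified negligible, excluded from subtotals (a `strict_accounting` flag includes it) |
| wtp_per_qaly, qaly_loss | $109,970, 0.04 | define λ = $4,398.80/effect |
| exchange_rate_usd_per_cad | 0.9102 | back-calculated from the printed 245→223 conversion; a config scalar, never hard-coded |

The payer enum includes `external` with an empty default ledger: the
perspective names externally borne costs but the base-case ledger lists
none.

## Sensitivity analyses

**Scenario.** The in-person arm is re-costed at an arbitrary visit count:
health-system and per-visit patient costs (leisure, travel, parking) scale
linearly with visits relative to the 1.64 baseline; the caregiver cost is
scaled by min(visits, 1), reading a fractional mean as the fraction of
patients attending a first visit. Crossover adds a fraction of one
in-person visit's societal cost to the mobile arm. The crossover visit is
modeled **without** a caregiver by default — it is an unplanned assessment
rather than the scheduled first visit a caregiver accompanies; a
`caregiver_at_crossover` flag reverses this. With the caregiver included,
full crossover overshoots cost-equivalence by $0.22.

**Two-way grid.** INB over per-visit leisure cost L ∈ {33.84, 56.98,
80.12} (3 h at the homemaker, midpoint and age/sex-adjusted wages) by
mobile effect e ∈ {0.96 … 0.90}: cell = λ(e − e_ref) + [C_in(L) − C_mob],
where C_in(L) swaps the leisure subtotal for 1.64·L while caregiver,
travel and parking stay fixed. The reference in-person effect e_ref = 0.96
is itself a calibration: the grid's top row equals the pure cost
difference, implying ΔE = 0 at mobile effect 0.96. The reconstruction
carries a constant ≈ +$0.06 offset against the printed grid (198.69 vs
198.75 etc.), attributable to sub-dollar rounding inside the source's
subtotals; ±$0.15 is the adopted comparison tolerance. Row spacing is
λ × 0.02 = 87.98 and column spacing 1.64 × 23.14 = 37.95 by construction.

**PSA.** 10,000 Monte Carlo draws. Per draw: in-person clinic
(health-system) cost ~ Uniform(±20% of base); each arm's effect ~
Uniform(±2 pp), truncated to [0,1], sampled independently per arm; patient
wage ~ Gamma(mean = implied wage, cv = 0.4) feeding the leisure cost. The
caregiver, travel and parking rows and the entire mobile arm stay at their
deterministic values. The wage-gamma parameters and the published PSA
dispersion are not printed anywhere, so cv = 0.4 is a one-time choice (a
plausible between-patient wage spread); consequently the published
in-person mean/SD and the 99.1% acceptability are treated as soft
calibration checks (mean within ±10%, preferred fraction ≥ 0.95), not
reproduction targets. Our in-person SD (≈$46) is far below the published
$211.80, which evidently reflects a much more dispersed wage/travel input
than the printed parameters imply.

A single seeded `numpy.random.Generator` per run with fixed draw order
(clinic, mobile effect, in-person effect, wage) makes runs bitwise
reproducible; with all halfwidths and cv zero, every draw equals the base
case exactly. CEAC tie rule: a draw counts as "mobile preferred" iff
INB > 0 strictly; exact ties have probability zero under the continuous
distributions.

## Synthetic cohort

The generator emulates the administrative data behind the costing, not any
deposited dataset. One-way distance is lognormal with mean matched to
76 km and σ = 0.8 on the log scale, chosen so P(distance > 540 km) < 0.5%,
then hard-capped at the observed 540 km maximum (cap bias on the mean
< 0.5 km); the true distributional shape beyond mean and maximum is
unknown, so the lognormal is a stand-in. Wages are a mixture: labour-force
participants (default rate 0.70, a plausible rate for this mixed-age
female population) draw a gamma wage whose mean is back-solved so the
mixture mean equals the implied $20.78/h; non-participants carry the
homemaker wage. Visits are a {1,2} mixture with P(2) = 0.64 — every
in-person patient attends at least one visit, so a Poisson would be wrong
at zero — giving the 1.64 mean. Complications are Bernoulli(0.05); they
present to the emergency department outside both arms' ledgers, so **they
do not alter follow-up costs** — they matter only through the effect
probabilities.

What passing cohort tests show: the generator hits its own calibration
targets (distance, visits, wage mixture, ≈$207 mean patient cost) and the
costing is exactly linear in its inputs. They do not validate the real
distance or wage distributions, correlations between wage, distance and
attendance, or visit counts above two.

## Numerical and reporting choices

Money is held unrounded everywhere; rounding happens only in the reporting
module — half-up (away from zero) to whole dollars for dollar tables, two
decimals for the two-way grid. The USD presentation multiplies the
unrounded CAD amount by the configured rate before rounding. The
ICER-reportability tolerance on |ΔE| is 1e-9 (the base case models an
exact zero). Configuration is validated strictly (unknown keys rejected);
partial files deep-merge over the packaged defaults, and an empty file is
an error naming the required sections. Reports carry a provenance block
(config SHA-256, seed, package version); re-rendering with the same config
and seed is byte-identical for CSV/JSON outputs.

Problem sizes: analyses use the study's own sizes throughout — 10,000 PSA
draws and a 10,000-patient cohort — which run in well under a second each.

## Known limitations

- Whether "Compensation" overlaps the clinical-assistant row cannot be
  determined from the ledger; they are treated as distinct.
- The in-person health-system cost is assumed linear in visit count
  (subtotal/1.64 per visit) for the scenario analysis; fixed clinic
  overheads would make one visit slightly dearer than that.
- Only two arms; telephone follow-up is not costed. No EVPI/tornado
  analyses. No geographic realism in the cohort beyond the distance
  distribution.
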