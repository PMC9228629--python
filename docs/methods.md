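# Methods

## Scope and assumptions

`biomoe` implements a screening-level, deterministic reverse-dosimetry
chain. Its core assumptions:

* **Steady-state first-order excretion.** A constant daily external dose
  maps to a constant urinary metabolite concentration through a single
  molar excretion fraction (Fue) and a fixed daily urine output per kg
  body weight. No PBPK kinetics, no within-day variation, no route
  apportionment: the chain covers dietary exposure only.
* **Molar additivity.** Parents sharing the metabolite (chlorpyrifos,
  chlorpyrifos-methyl → TCPy) contribute additively in moles. Direct
  dietary intake of the metabolite itself is not modelled.
* **Aggregated inputs.** The unit of analysis is a published percentile
  set (P50 / P95 / upper 95% CI of P95), not individual samples.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| Fue | 0.7 (0.5–0.93) | – | molar urinary excretion fraction of TCPy; range drives the uncertainty module |
| molar ratio, chlorpyrifos | 0.566 | – | MW(TCPy)/MW(parent) |
| molar ratio, chlorpyrifos-methyl | 0.6153 | – | 198.43/322.53 from standard molecular weights; not tabulated in the source assessments, hence configuration, not constant |
| urine output, adults / children | 0.02 / 0.03 | L/kg bw/day | guidance-value convention |
| urine output, food model | 0.024 | L/kg bw/day | forward-model convention; kept as a separate named constant, never interchanged with the above |
| ADI, chlorpyrifos | 0.01 (2012–2015), 0.001 (2016–2019) | mg/kg bw/day | the regulatory reduction; which ADI underlies a given report-year %ADI figure is not recoverable from the reports, so the table is fully overridable |
| ADI, chlorpyrifos-methyl | 0.01 (all years) | mg/kg bw/day | |
| PoDs | 0.3 (LOAEL, overall), 0.1, 0.1, 1, 5, 10 | mg/kg bw/day | chlorpyrifos endpoint set; methyl variants 3/10/40 for the last three |

Classification cutoffs (strict `<`, boundary to the safer class):

| category | RED below | ORANGE below | YELLOW below |
|---|---|---|---|
| loael_overall | 300 | 1000 | 10,000 |
| st_ache | 100 | 300 | 3,000 |
| noael_generic | 100 | – | 1,000 |
| carcinogenicity | 10,000 | – | 100,000 |

The GREEN boundary is operationalised as 10× the most severe applicable
concern threshold (the orange cutoff where one exists, otherwise red) —
the "additional margin of at least 10" rule stated in prose made into a
table. ORANGE exists only where an extrapolation-range factor applies:
LOAEL→NOAEL (up to 10) for the overall endpoint, subacute→subchronic
(3) for short-term AChE. The short-term AChE endpoint shares the 0.1
mg/kg bw/day PoD with the long-term endpoint but carries its own category.

## Numerical conventions

* Internal unit for concentrations is µg/L; mg/L appears only in
  presentation values, rounded half-to-even at 2 decimals. Reported MoEs
  round half-to-even to integers; classification always uses unrounded
  MoEs.
* Reported MoEs are computed from the *rounded* (2-decimal mg/L) HBM-PoD
  by default, because that is how values derived from published tables
  compose; full precision is available via `use_reported=False`.
* Quantiles everywhere use the linear-interpolation convention between
  order statistics. The convention cannot be validated against the
  source figures (their inputs are external), so it is documented and
  carried consistently rather than argued for.
* Missing values in input tables are the literal token `n.r.` or an empty
  cell; both parse to missing. Records missing some tiers stay usable for
  the tiers they report and are flagged in the validation log; ordering
  violations (P50 > P95) are rejected to the log, never silently fixed.
* Creatinine-adjusted records (µg/g creatinine) require user-supplied
  linear correlation coefficients; the identity default warns, because no
  universal adjusted↔unadjusted correlation exists and the study-specific
  one used in the source analysis is unpublished.

## Uncertainty propagation

Both the HBM-PoD and the MoE are linear in Fue, so the stated 0.5–0.93
range propagates exactly: interval endpoints are the chain recomputed at
the bounds. The Monte-Carlo extension samples Fue from a triangular
distribution (low/mode/high = 0.5/0.7/0.93) — chosen because only those
three points are stated; the family is configurable. Exposure-side
variability is excluded from the Monte Carlo by default since the
percentile tiers already encode it. Seeds are mandatory; identical spec
gives bit-identical output.

## Synthetic data: what it does and does not emulate

Individual urinary concentrations are lognormal — the standard family for
urinary biomarkers and consistent with the multiplicative P95/P50 framing
of the real studies (ratios ≈4 correspond to log-scale SD 0.843, ≈10 to
1.400 via P95/P50 = exp(1.645σ)). Aggregation computes P50/P95 and a
percentile-bootstrap upper 95% confidence bound on P95 (97.5th percentile
of the bootstrap distribution, default 500 resamples, seeded; a minimum of
20 values is required, and the bound is clamped to be ≥ the sample P95 so
the tier-ordering contract always holds). Detection-limit censoring
emulates the studies withheld for LOD reasons: a record whose censored
fraction exceeds 60% reports missing percentiles.

Not emulated: country-specific covariate structure, dietary recall,
creatinine physiology, temporal autocorrelation. Passing tests therefore
demonstrate that the *pipeline arithmetic and its statistical conventions*
behave as specified under the assumed distributional family — not that the
family fits any particular real population.

Problem sizes used in the test suite: quantile-ratio recovery at
n = 10⁵ draws (tolerance 5%); bootstrap coverage over 500 simulated
studies of n = 200 with 500 resamples each (acceptance band 90–98%,
observed ≈92%); Monte-Carlo median versus the closed-form triangular
median at 10⁵ draws (2%).

## Computed-vs-printed divergences

The package computes from its inputs; four published range bounds do not
follow from the published percentile inputs and are asserted in the tests
as documented discrepancies, not targets:

* children carcinogenicity P50 lower bound: printed 47,180; the Israel
  median (2.80 µg/L) gives 47,168 — and the Cyprus median implies 20,256,
  smaller still, so the printed bound is not the minimum of the printed
  inputs under any rounding;
* children overall P50 upper bound: printed 6462; the Slovenia median
  (0.61 µg/L) gives 6492;
* adults overall P50 upper bound: printed 7244 (Germany) although the
  Iceland median implies 9738;
* adults overall upper-CI maximum: printed 1800 (Iceland) although the
  France record's upper CI of 0.06 µg/L implies 99,000 — that record
  appears to have been excluded upstream; here it is retained (flagged
  partially missing) because the ingestion contract keeps partially
  reported records usable for the tiers they report.

## Known limitations

Screening arithmetic only: no dose–response modelling, no benchmark-dose
derivation, no cumulative assessment beyond the TCPy-sharing pair, no
non-dietary routes. Study roll-up labels ("worst colour per tier plus the
endpoints attaining it") depend on which endpoints are included; the
report set is the four carried by the published summary (overall,
long-term, short-term AChE, carcinogenicity).
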