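"""Margins of exposure and colour calls for the packaged biomonitoring table.

Screens every study in the packaged aggregated percentile table against the
four report endpoints and prints the per-study worst colour at each
exposure tier (median population, highly exposed group, most exposed
individuals).
"""

from biomoe.config import default_hbm_fixture_path, load_default_config
from biomoe.dosimetry import Population, hbm_pod
from biomoe.hbm import read_hbm_csv, validate_records
from biomoe.pipeline import REPORT_ENDPOINTS
from biomoe.risk import moe_for_record, summarize_study

cfg = load_default_config()
records, log = validate_records(read_hbm_csv(default_hbm_fixture_path()))
pods = {
    pop: {p.endpoint: hbm_pod(p, cfg.toxicokinetics, pop)
          for p in cfg.pods["chlorpyrifos"]}
    for pop in Population
}

print(f"{'study':<22}{'pop':<10}{'tier':<10}{'worst':<8}endpoints")
for rec in records:
    pop = Population.children if rec.population == "children" else Population.adults
    results = moe_for_record(
        rec, {e: pods[pop][e] for e in REPORT_ENDPOINTS}
    )
    if not results:
        print(f"{rec.study_id:<22}{rec.population:<10}(no usable tiers)")
        continue
    for tier, (color, label) in summarize_study(results).items():
        print(f"{rec.study_id:<22}{rec.population:<10}{tier.value:<10}"
              f"{color.value:<8}{label}")

print("\nRED = margin below the standard uncertainty factors; GREEN = at")
print("least a tenfold margin beyond them.  The listed endpoints are the")
print("ones attaining the worst colour at that tier.")
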