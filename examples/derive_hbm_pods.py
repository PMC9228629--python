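"""Derive biomonitoring-equivalent points of departure for chlorpyrifos.

Converts each animal PoD (mg/kg bw/day) into the urinary TCPy concentration
(mg/L) that corresponds to it at steady state, for adults (urine output
0.02 L/kg bw/day) and children (0.03).  These concentrations are the
reference points that measured biomonitoring percentiles are screened
against.
"""

from biomoe.config import load_default_config
from biomoe.dosimetry import Population, hbm_pod

cfg = load_default_config()

print(f"{'endpoint':<18}{'basis':<8}{'PoD mg/kg/d':>12}{'adults mg/L':>14}{'children mg/L':>15}")
for pod in cfg.pods["chlorpyrifos"]:
    adults = hbm_pod(pod, cfg.toxicokinetics, Population.adults)
    children = hbm_pod(pod, cfg.toxicokinetics, Population.children)
    print(
        f"{pod.endpoint.value:<18}{pod.basis.value:<8}{pod.value:>12}"
        f"{adults.reported_mg_l:>14}{children.reported_mg_l:>15}"
    )

print(
    "\nEach value is PoD x molar_ratio(0.566) x Fue(0.7) / urine output; a\n"
    "measured urinary TCPy level above it would exhaust the margin entirely."
)
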