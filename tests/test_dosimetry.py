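"""Dose <-> urinary-concentration conversions and HBM-PoD derivation."""

import pytest
from hypothesis import given, strategies as st

from biomoe.dosimetry import (
    Basis,
    Endpoint,
    PoDEntry,
    Population,
    ToxicokineticParams,
    dose_to_urine_conc,
    hbm_pod,
    urine_conc_to_dose,
)

# endpoint, PoD (mg/kg bw/day), expected HBM-PoD mg/L (adults, children)
PUBLISHED_POD_TABLE = [
    (Endpoint.overall, 0.3, Basis.LOAEL, 5.94, 3.96),
    (Endpoint.long_term, 0.1, Basis.NOAEL, 1.98, 1.32),
    (Endpoint.short_term_ache, 0.1, Basis.NOAEL, 1.98, 1.32),
    (Endpoint.offspring, 1.0, Basis.NOAEL, 19.81, 13.21),
    (Endpoint.reproductive, 5.0, Basis.NOAEL, 99.05, 66.03),
    (Endpoint.carcinogenicity, 10.0, Basis.NOAEL, 198.10, 132.07),
]


@pytest.mark.parametrize(
    "endpoint,pod_value,basis,adults_mg_l,children_mg_l", PUBLISHED_POD_TABLE
)
def test_hbm_pod_reproduces_published_table(
    tk, endpoint, pod_value, basis, adults_mg_l, children_mg_l
):
    """All six endpoints give the published mg/L values for both populations."""
    pod = PoDEntry(endpoint=endpoint, value=pod_value, basis=basis)
    assert hbm_pod(pod, tk, "adults").reported_mg_l == pytest.approx(
        adults_mg_l, abs=5e-3
    )
    assert hbm_pod(pod, tk, "children").reported_mg_l == pytest.approx(
        children_mg_l, abs=5e-3
    )


def test_children_to_adults_ratio_is_two_thirds(tk, pods):
    """Children/adults HBM-PoD ratio is exactly 0.02/0.03 for every endpoint."""
    for pod in pods.values():
        adults = hbm_pod(pod, tk, Population.adults).value_ugl
        children = hbm_pod(pod, tk, Population.children).value_ugl
        assert children / adults == pytest.approx(2.0 / 3.0, rel=1e-12)


@given(
    pod_value=st.floats(0.01, 100),
    scale=st.floats(0.1, 10),
    fue=st.floats(0.1, 0.99),
)
def test_hbm_pod_linear_in_pod_and_fue(pod_value, scale, fue):
    """Doubling the PoD (or Fue) scales the HBM-PoD by the same factor."""
    tk = ToxicokineticParams(fue=fue, fue_low=fue, fue_high=fue)
    base = PoDEntry(endpoint=Endpoint.overall, value=pod_value, basis=Basis.LOAEL)
    scaled = PoDEntry(
        endpoint=Endpoint.overall, value=pod_value * scale, basis=Basis.LOAEL
    )
    a = hbm_pod(base, tk, "adults").value_ugl
    b = hbm_pod(scaled, tk, "adults").value_ugl
    assert b == pytest.approx(a * scale, rel=1e-9)
    # inverse proportionality to urine output: children = adults * 0.02/0.03
    c = hbm_pod(base, tk, "children").value_ugl
    assert c == pytest.approx(a * 0.02 / 0.03, rel=1e-9)


def test_forward_dose_conversion_matches_hand_calculation(tk):
    """0.001 mg/kg/day of chlorpyrifos at the food-model output -> 16.51 ug/L."""
    conc = dose_to_urine_conc(
        [("chlorpyrifos", 0.001)], {"chlorpyrifos": 0.566}, tk.fue,
        tk.urine_output_food_model,
    )
    assert conc == pytest.approx(0.001 * 0.566 * 0.7 / 0.024 * 1000, rel=1e-12)
    assert round(conc, 2) == 16.51


def test_dose_conversion_additive_and_empty(tk):
    ratios = {"a": 0.566, "b": 0.6153}
    args = (ratios, tk.fue, tk.urine_output_food_model)
    both = dose_to_urine_conc([("a", 0.002), ("b", 0.001)], *args)
    single_a = dose_to_urine_conc([("a", 0.002)], *args)
    single_b = dose_to_urine_conc([("b", 0.001)], *args)
    assert both == pytest.approx(single_a + single_b, rel=1e-12)
    assert dose_to_urine_conc([], *args) == 0.0


@given(dose=st.floats(1e-8, 10), output=st.floats(0.01, 0.05))
def test_round_trip_identity(dose, output):
    """dose -> concentration -> dose is the identity to 1e-12 relative."""
    ratios = {"chlorpyrifos": 0.566}
    conc = dose_to_urine_conc([("chlorpyrifos", dose)], ratios, 0.7, output)
    back = urine_conc_to_dose(conc, "chlorpyrifos", ratios, 0.7, output)
    assert back == pytest.approx(dose, rel=1e-12)


def test_inverse_of_reference_example(tk):
    assert urine_conc_to_dose(
        16.51, "chlorpyrifos", {"chlorpyrifos": 0.566},
        tk.fue, tk.urine_output_food_model,
    ) == pytest.approx(0.001, rel=1e-3)
    assert urine_conc_to_dose(
        0.0, "chlorpyrifos", {"chlorpyrifos": 0.566}, tk.fue, 0.024
    ) == 0.0


def test_rejections(tk, pods):
    with pytest.raises(ValueError, match="population"):
        hbm_pod(pods[Endpoint.overall], tk, "infants")
    with pytest.raises(Exception):
        PoDEntry(endpoint=Endpoint.overall, value=0.0, basis=Basis.LOAEL)
    with pytest.raises(ValueError, match="molar ratio"):
        dose_to_urine_conc([("unknown", 0.001)], {}, 0.7, 0.024)
    with pytest.raises(ValueError):
        dose_to_urine_conc([("chlorpyrifos", -1)], {"chlorpyrifos": 0.566}, 0.7, 0.024)
    with pytest.raises(ValueError):
        urine_conc_to_dose(1.0, "chlorpyrifos", {"chlorpyrifos": 0.566}, 0.7, 0.0)


def test_toxicokinetic_invariants():
    with pytest.raises(Exception):
        ToxicokineticParams(fue=0.4, fue_low=0.5)  # fue below its low bound
    with pytest.raises(Exception):
        ToxicokineticParams(molar_ratio=1.5)
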