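"""Margins of exposure, four-colour classification, ranges and roll-ups."""

import pytest
from hypothesis import given, strategies as st

from biomoe.dosimetry import Endpoint, HBMPoD, Population
from biomoe.hbm import HBMRecord, Tier
from biomoe.risk import (
    Color,
    MoEResult,
    ThresholdCategory,
    classify,
    default_threshold_scheme,
    endpoint_rescale,
    moe,
    moe_for_record,
    moe_range,
    summarize_study,
)


def _pod(endpoint, mg_l, population=Population.children):
    return HBMPoD(endpoint=endpoint, population=population, value_ugl=mg_l * 1000)


class TestMoE:
    def test_published_spot_values(self, hbm_pods_by_pop):
        """Published study-level MoEs reproduce from the rounded PoD table."""
        children = hbm_pods_by_pop[Population.children]
        adults = hbm_pods_by_pop[Population.adults]
        # Cyprus children median 6.52 ug/L against the overall endpoint
        assert round(moe(children[Endpoint.overall], 6.52)) == 607
        # Germany adults median 0.82 ug/L
        assert round(moe(adults[Endpoint.overall], 0.82)) == 7244
        assert round(moe(adults[Endpoint.carcinogenicity], 0.82)) == 241585
        # Israel adults upper CI 55.22; Portugal adults P95 7.35
        assert round(moe(adults[Endpoint.overall], 55.22)) == 108
        assert round(moe(adults[Endpoint.overall], 7.35)) == 808

    def test_pod_equal_to_exposure(self):
        pod = _pod(Endpoint.overall, 3.96)
        assert moe(pod, pod.reported_ugl) == pytest.approx(1.0)

    def test_nonpositive_exposure_rejected(self, hbm_pods_by_pop):
        pod = hbm_pods_by_pop[Population.adults][Endpoint.overall]
        with pytest.raises(ValueError):
            moe(pod, 0.0)
        with pytest.raises(ValueError):
            moe(pod, -1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "value,category,expected",
        [
            # LOAEL-based overall endpoint: 300 / 1000 / 10,000
            (299.99, "loael_overall", Color.RED),
            (300, "loael_overall", Color.ORANGE),
            (607, "loael_overall", Color.ORANGE),
            (1000, "loael_overall", Color.YELLOW),
            (9999.9, "loael_overall", Color.YELLOW),
            (10_000, "loael_overall", Color.GREEN),
            # short-term AChE: 100 / 300 / 3000
            (99, "st_ache", Color.RED),
            (100, "st_ache", Color.ORANGE),
            (299.9, "st_ache", Color.ORANGE),
            (300, "st_ache", Color.YELLOW),
            (3000, "st_ache", Color.GREEN),
            # generic NOAEL categories skip orange: 100 / 1000
            (99.9, "noael_generic", Color.RED),
            (100, "noael_generic", Color.YELLOW),
            (999, "noael_generic", Color.YELLOW),
            (1000, "noael_generic", Color.GREEN),
            # carcinogenicity of a potentially genotoxic substance
            (9999, "carcinogenicity", Color.RED),
            (10_000, "carcinogenicity", Color.YELLOW),
            (99_999, "carcinogenicity", Color.YELLOW),
            (100_000, "carcinogenicity", Color.GREEN),
        ],
    )
    def test_grid_with_boundary_convention(self, value, category, expected):
        """Cutoffs are strict: a boundary MoE lands in the safer class."""
        assert classify(value, category) is expected

    @given(
        m1=st.floats(1, 1e7),
        m2=st.floats(1, 1e7),
        category=st.sampled_from(list(ThresholdCategory)),
    )
    def test_monotone_in_moe(self, m1, m2, category):
        """A larger MoE never gets a more severe colour."""
        lo, hi = sorted((m1, m2))
        assert classify(hi, category).severity <= classify(lo, category).severity

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            classify(500, "acute")
        with pytest.raises(ValueError):
            classify(0, "loael_overall")


class TestRangesAndRescaling:
    def test_children_overall_range_driven_by_highest_median(
        self, aligned_records, hbm_pods_by_pop
    ):
        records, _ = aligned_records
        children = [r for r in records if r.population == "children"]
        lo, hi, contributors = moe_range(
            children, Endpoint.overall, Tier.p50,
            hbm_pods_by_pop[Population.children],
        )
        assert round(lo) == 607  # Cyprus, the most exposed study
        assert "CY Organiko" in contributors and len(contributors) == 5

    def test_single_and_intermediate_records(self, hbm_pods_by_pop):
        pods = hbm_pods_by_pop[Population.adults]
        a = HBMRecord(study_id="a", population="adults", p50=2.0)
        b = HBMRecord(study_id="b", population="adults", p50=4.0)
        mid = HBMRecord(study_id="mid", population="adults", p50=3.0)
        lo1, hi1, _ = moe_range([a], Endpoint.overall, Tier.p50, pods)
        assert lo1 == hi1
        lo2, hi2, _ = moe_range([a, b], Endpoint.overall, Tier.p50, pods)
        lo3, hi3, _ = moe_range([a, b, mid], Endpoint.overall, Tier.p50, pods)
        assert (lo2, hi2) == (lo3, hi3)
        with pytest.raises(ValueError):
            moe_range([], Endpoint.overall, Tier.p50, pods)

    def test_endpoint_rescaling_reproduces_published_value(self, hbm_pods_by_pop):
        """Overall MoE 2970 rescales to the carcinogenicity MoE 99,050."""
        pods = hbm_pods_by_pop[Population.adults]
        rescaled = endpoint_rescale(
            2970, Endpoint.overall, Endpoint.carcinogenicity, pods
        )
        assert round(rescaled) == 99050

    def test_rescaling_identity_and_round_trip(self, hbm_pods_by_pop):
        pods = hbm_pods_by_pop[Population.adults]
        assert endpoint_rescale(123.4, Endpoint.overall, Endpoint.overall, pods) == 123.4
        fwd = endpoint_rescale(607, Endpoint.overall, Endpoint.long_term, pods)
        back = endpoint_rescale(fwd, Endpoint.long_term, Endpoint.overall, pods)
        assert back == pytest.approx(607, rel=1e-12)
        with pytest.raises(ValueError, match="endpoint"):
            endpoint_rescale(1.0, Endpoint.overall, Endpoint.offspring, {})


def _result(endpoint, color, tier=Tier.p50, m=500.0):
    return MoEResult(
        study_id="s", endpoint=endpoint, tier=tier, moe=m, color=color
    )


class TestStudyRollup:
    def test_all_green(self):
        results = [
            _result(e, Color.GREEN)
            for e in (Endpoint.overall, Endpoint.long_term,
                      Endpoint.short_term_ache, Endpoint.carcinogenicity)
        ]
        assert summarize_study(results)[Tier.p50] == (Color.GREEN, "All")

    def test_worst_color_with_labels(self):
        results = [
            _result(Endpoint.overall, Color.ORANGE),
            _result(Endpoint.short_term_ache, Color.ORANGE),
            _result(Endpoint.long_term, Color.YELLOW),
            _result(Endpoint.carcinogenicity, Color.GREEN),
        ]
        assert summarize_study(results)[Tier.p50] == (Color.ORANGE, "OA/ST")

    def test_single_endpoint(self):
        out = summarize_study([_result(Endpoint.carcinogenicity, Color.YELLOW)])
        assert out[Tier.p50] == (Color.YELLOW, "C")
        with pytest.raises(ValueError):
            summarize_study([])


def test_tier_ordering_of_moes(aligned_records, hbm_pods_by_pop):
    """Within a study, MoE at P50 >= at P95 >= at upper CI."""
    records, _ = aligned_records
    for rec in records:
        pop = (
            Population.children if rec.population == "children"
            else Population.adults
        )
        results = moe_for_record(rec, hbm_pods_by_pop[pop])
        by_tier = {
            (r.endpoint, r.tier): r.moe for r in results
        }
        for endpoint in hbm_pods_by_pop[pop]:
            seq = [
                by_tier.get((endpoint, t))
                for t in (Tier.p50, Tier.p95, Tier.upper_ci)
            ]
            present = [v for v in seq if v is not None]
            assert present == sorted(present, reverse=True)
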