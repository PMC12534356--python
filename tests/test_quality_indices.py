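"""HEI, PLI, WQI, CCME WQI: hand oracles, published values, invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pemriver as pr
from pemriver.core_data import Measurement, SampleSet, WaterSample
from pemriver.quality_indices import (
    BackgroundProfile,
    classify_ccme,
    classify_hei,
    classify_pli,
    classify_wqi,
)


def make_sample(site="S", group="main_stem", ph=7.0, **conc):
    return WaterSample(
        site_id=site, group=group, pH=ph,
        concentrations={p: Measurement(value=v) for p, v in conc.items()},
    )


class TestBackground:
    def test_reference_row_reproduced(self, background):
        assert background["Cu"] == pytest.approx(1.07, abs=0.01)
        assert background["Mn"] == pytest.approx(19.8, abs=0.01)
        assert background["Al"] == pytest.approx(47.0, abs=0.01)

    def test_lead_hand_average(self, background):
        assert background["Pb"] == pytest.approx((0.41 + 0.13) / 2)

    def test_single_reference_site(self, fixture_half_dl):
        bg = pr.derive_background(fixture_half_dl, ["NY-01"], "half_dl")
        assert bg["Fe"] == 130.0

    def test_all_censored_reference_under_drop_raises(self, fixture_raw):
        dropped = pr.resolve_censored(fixture_raw, "drop")
        with pytest.raises(ValueError, match="Co"):
            pr.derive_background(dropped, ["NY-01", "NY-13"], "drop")


class TestContaminationFactor:
    def test_identity_at_background(self, background):
        cf = pr.contamination_factor({"Fe": background["Fe"]}, background)
        assert cf.cf["Fe"] == pytest.approx(1.0)

    def test_cobalt_hand_division(self, main_stem, background):
        c = main_stem.get("NY-05").resolved("Co")
        cf = pr.contamination_factor({"Co": c}, background)
        assert cf.cf["Co"] == pytest.approx(493 / 0.0265, rel=1e-12)

    def test_mean_nickel_matches_published_row(self, main_stem, background):
        means = pr.mean_profile(main_stem)
        cf = pr.contamination_factor(means, background)
        assert cf.cf["Ni"] == pytest.approx(1015, abs=1)

    def test_missing_background_entry_raises(self, background):
        with pytest.raises(KeyError, match="Cd"):
            pr.contamination_factor({"Cd": 1.0}, background)


class TestHEI:
    def test_peak_site_value_and_band(self, main_stem):
        rep = pr.hei(main_stem.get("NY-07"))
        assert rep.value == pytest.approx(17.3, abs=0.05)
        assert rep.classification == "low"

    def test_upstream_site(self, main_stem):
        assert pr.hei(main_stem.get("NY-01")).value == pytest.approx(0.852, abs=0.001)

    def test_zero_concentrations_give_zero(self):
        s = make_sample(Co=0.0, Ni=0.0)
        assert pr.hei(s, pems=("Co", "Ni")).value == 0.0

    def test_additivity_and_linearity(self, main_stem):
        rep = pr.hei(main_stem.get("NY-05"))
        assert rep.value == pytest.approx(sum(rep.components.values()))
        doubled = make_sample(**{
            p: 2 * main_stem.get("NY-05").resolved(p) for p in pr.QUANTIFIED_PEMS
        })
        assert pr.hei(doubled).value == pytest.approx(2 * rep.value)

    def test_missing_limit_raises(self):
        s = make_sample(Cd=1.0)
        with pytest.raises(KeyError, match="Cd"):
            pr.hei(s, pems=("Cd",))


class TestPLI:
    def test_peak_site(self, main_stem, background):
        assert pr.pli(main_stem.get("NY-05"), background).value \
            == pytest.approx(14.5, abs=0.5)

    def test_unit_contamination_factors(self, background):
        s = make_sample(**dict(background.cb))
        assert pr.pli(s, background).value == pytest.approx(1.0)

    def test_against_nth_root_product_oracle(self, main_stem, background):
        """Log-space geometric mean equals the direct ⁿ√(ΠCF) oracle."""
        for site in ("NY-01", "NY-07", "NY-15"):
            rep = pr.pli(main_stem.get(site), background)
            product = math.prod(rep.components.values())
            assert rep.value == pytest.approx(
                product ** (1 / len(rep.components)), rel=1e-12)

    @given(k=st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, k, background):
        base = {p: 10.0 for p in pr.QUANTIFIED_PEMS}
        v1 = pr.pli(make_sample(**base), background).value
        vk = pr.pli(make_sample(**{p: k * v for p, v in base.items()}),
                    background).value
        assert vk == pytest.approx(k * v1, rel=1e-9)

    def test_nonpositive_cf_rejected(self, background):
        s = make_sample(**{p: 0.0 for p in pr.QUANTIFIED_PEMS})
        with pytest.raises(ValueError, match="nonpositive"):
            pr.pli(s, background)


class TestWQI:
    def test_upstream_site_value(self, main_stem):
        rep = pr.wqi(main_stem.get("NY-01"))
        assert rep.value == pytest.approx(17.4, abs=0.2)
        assert rep.classification == "excellent"

    def test_calibration_at_standards(self):
        """All parameters at their S_i → WQI = 100 whatever the weights."""
        scheme = pr.WQIScheme()
        s = make_sample(ph=scheme.s_values["pH"], **{
            p: scheme.s_values[p] for p in scheme.weights if p != "pH"
        })
        assert pr.wqi(s, scheme).value == pytest.approx(100.0)
        lopsided = pr.WQIScheme(weights={**scheme.weights, "Mn": 1, "Pb": 1})
        assert pr.wqi(s, lopsided).value == pytest.approx(100.0)

    def test_band_labels_match_published_classes(self, main_stem):
        expected = {
            "NY-01": "excellent", "NY-04": "poor", "NY-05": "poor",
            "NY-07": "poor", "NY-08": "good", "NY-11": "good",
            "NY-12": "good", "NY-14": "good", "NY-15": "good",
        }
        for site, band in expected.items():
            assert pr.wqi(main_stem.get(site)).classification == band

    def test_parameter_missing_from_sample_raises(self):
        with pytest.raises(KeyError):
            pr.wqi(make_sample(Co=1.0))  # scheme needs all ten + pH


class TestCCME:
    def test_river_value_and_breakdown(self, main_stem):
        rep, br = pr.ccme_wqi(main_stem)
        assert rep.value == pytest.approx(72.9, abs=0.3)
        assert rep.classification == "fair"
        assert br.f1 == pytest.approx(27.27, abs=0.01)
        assert br.f2 == pytest.approx(22.22, abs=0.01)
        assert br.f3 == pytest.approx(31.05, abs=0.01)
        assert br.n_failed_parameters == 3 and br.n_failed_tests == 22
        assert br.f3 == pytest.approx(100 * br.nse / (br.nse + 1))

    def test_no_failures_scores_100(self, background):
        samples = SampleSet([
            make_sample(site=f"S{i}", ph=7.0, **{p: 0.5 for p in pr.QUANTIFIED_PEMS})
            for i in range(4)
        ])
        rep, br = pr.ccme_wqi(samples)
        assert (br.f1, br.f2, br.f3) == (0.0, 0.0, 0.0)
        assert rep.value == 100.0

    def test_single_failed_parameter_hand_arithmetic(self):
        """One parameter, value at twice its objective in all four tests."""
        samples = SampleSet([
            make_sample(site=f"S{i}", Mn=200.0, Co=1, Ni=1, Zn=1)
            for i in range(4)
        ])
        rep, br = pr.ccme_wqi(samples, parameters=("Mn", "Co", "Ni", "Zn"))
        assert br.f1 == 25.0 and br.f2 == 25.0
        assert br.nse == pytest.approx(1.0 / 4)
        assert br.f3 == pytest.approx(20.0)

    def test_three_component_formula_and_bounds(self, main_stem):
        rep, br = pr.ccme_wqi(main_stem)
        expected = 100 - math.sqrt(br.f1**2 + br.f2**2 + br.f3**2) / 1.732
        assert rep.value == pytest.approx(expected)
        assert 0.0 <= rep.value <= 100.0 and br.f3 < 100.0

    def test_model_minimum_enforced(self, main_stem):
        with pytest.raises(ValueError, match="minimum"):
            pr.ccme_wqi(main_stem, parameters=("Mn", "Ni", "Co"))
        three = SampleSet(list(main_stem)[:3])
        with pytest.raises(ValueError, match="minimum"):
            pr.ccme_wqi(three)

    def test_removing_failing_test_never_decreases_index(self, main_stem):
        full, _ = pr.ccme_wqi(main_stem)
        without_peak = SampleSet([ws for ws in main_stem
                                  if ws.site_id != "NY-07"])
        reduced, _ = pr.ccme_wqi(without_peak)
        assert reduced.value >= full.value

    def test_ph_checked_against_both_bounds(self):
        acidic = SampleSet([
            make_sample(site=f"S{i}", ph=4.0, **{p: 0.5 for p in pr.QUANTIFIED_PEMS})
            for i in range(4)
        ])
        _, br = pr.ccme_wqi(acidic)
        assert br.n_failed_parameters == 1
        assert all(param == "pH" for _, param, _ in br.excursions)
        # lower-bound excursion: objective/value − 1 = 5.5/4 − 1
        assert br.excursions[0][2] == pytest.approx(5.5 / 4.0 - 1.0)


class TestExceedance:
    @pytest.mark.parametrize("pem,threshold,count,pct", [
        ("Mn", 100, 11, 73.3),
        ("Ni", 20, 9, 60.0),
        ("Ni", 70, 5, 33.3),
        ("Co", 110, 9, 60.0),
    ])
    def test_published_counts_over_non_lake(self, non_lake, pem, threshold,
                                            count, pct):
        c, p = pr.exceedance_summary(non_lake, pem, threshold)
        assert c == count and p == pytest.approx(pct, abs=0.05)

    def test_threshold_above_maximum(self, non_lake):
        assert pr.exceedance_summary(non_lake, "Mn", 1e9) == (0, 0.0)

    def test_tie_at_limit_not_exceeded(self):
        s = SampleSet([make_sample(Mn=100.0)])
        assert pr.exceedance_summary(s, "Mn", 100.0)[0] == 0


class TestBands:
    @given(st.floats(min_value=0, max_value=1e4, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_every_value_gets_exactly_one_band(self, v):
        for fn, labels in [
            (classify_hei, {"low", "medium", "high"}),
            (classify_pli, {"none", "moderate", "severe", "extreme"}),
            (classify_wqi, {"excellent", "good", "poor", "very poor",
                            "unsuitable"}),
        ]:
            assert fn(v) in labels
        if v <= 100:
            assert classify_ccme(v) in {"excellent", "good", "fair",
                                        "marginal", "poor"}

    def test_printed_boundaries(self):
        assert classify_pli(1.0) == "moderate" and classify_pli(0.999) == "none"
        assert classify_wqi(171) == "poor"
        assert classify_hei(40.0) == "low" and classify_hei(40.01) == "medium"
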