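"""Score engine: CTP banding, CTP+L identity, declarative definitions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liverscore.scores import (
    ScoreDefinitionError,
    builtin_definitions,
    compute_ctp,
    compute_ctp_plus_l,
    compute_defined_score,
    compute_panel,
    ctp_component_points,
    organ_failure_count,
)

from conftest import make_cohort, make_record

# representative values landing in band 1 / 2 / 3 of each CTP component
BAND_VALUES = {
    "bilirubin": (20.0, 40.0, 71.0),
    "albumin": (36.0, 30.0, 19.8),
    "inr": (1.2, 1.8, 2.5),
    "ascites": ("none", "mild", "severe"),
    "encephalopathy": (0, 2, 4),
}


class TestCtpComponents:
    @pytest.mark.parametrize("component,value,expected", [
        ("bilirubin", 33.9, 1), ("bilirubin", 34.0, 2), ("bilirubin", 40.0, 2),
        ("bilirubin", 50.0, 2), ("bilirubin", 50.1, 3),
        ("albumin", 36.0, 1), ("albumin", 35.0, 2), ("albumin", 28.0, 2),
        ("albumin", 27.9, 3),
        ("inr", 1.70, 1), ("inr", 1.71, 2), ("inr", 2.30, 2), ("inr", 2.31, 3),
        ("ascites", "none", 1), ("ascites", "mild", 2), ("ascites", "severe", 3),
        ("encephalopathy", 0, 1), ("encephalopathy", 1, 2),
        ("encephalopathy", 2, 2), ("encephalopathy", 3, 3),
        ("encephalopathy", 4, 3),
    ])
    def test_band_assignment(self, component, value, expected):
        assert ctp_component_points(component, value) == expected

    def test_missing_value_propagates_to_missing_score(self):
        assert compute_ctp(make_record(bilirubin=None)) is None
        assert compute_ctp_plus_l(make_record(lactate=None)) is None


class TestComputeCtp:
    def _record_for(self, bands):
        """Record whose components land in the given (1-based) bands."""
        b, a, i, asc, enc = bands
        return make_record(
            bilirubin=BAND_VALUES["bilirubin"][b - 1],
            albumin=BAND_VALUES["albumin"][a - 1],
            pt_ratio=BAND_VALUES["inr"][i - 1],
            ascites=BAND_VALUES["ascites"][asc - 1],
            encephalopathy=BAND_VALUES["encephalopathy"][enc - 1])

    def test_exhaustive_band_combinations(self):
        """Over all 3^5 combinations: CTP equals the component-point sum,
        lies in [5, 15], and mode=excluded drops exactly the
        encephalopathy points."""
        for bands in itertools.product((1, 2, 3), repeat=5):
            rec = self._record_for(bands)
            ctp = compute_ctp(rec, "observed")
            assert ctp == sum(bands)
            assert 5 <= ctp <= 15
            assert compute_ctp(rec, "excluded") == ctp - bands[4]
            assert compute_ctp(rec, "presumed_2") == sum(bands[:4]) + 2

    def test_worked_example_severe_admission(self):
        rec = make_record(bilirubin=71.0, albumin=19.8, pt_ratio=1.8,
                          ascites="severe", encephalopathy=2)
        assert compute_ctp(rec) == 3 + 3 + 2 + 3 + 2 == 13

    def test_presumed_mode_ignores_recorded_grade(self):
        rec = make_record(encephalopathy=4)
        assert compute_ctp(rec, "presumed_2") == compute_ctp(
            make_record(encephalopathy=1), "presumed_2")

    def test_monotone_in_each_component(self):
        base = (1, 2, 2, 1, 2)
        rec0 = self._record_for(base)
        for pos in range(5):
            for worse in range(base[pos], 4):
                bands = list(base)
                bands[pos] = worse
                assert compute_ctp(self._record_for(tuple(bands))) >= \
                    compute_ctp(rec0) - (base[pos] - 1)


class TestCtpPlusL:
    @pytest.mark.parametrize("ctp_bands,lactate,expected", [
        ((1, 1, 1, 1, 1), 0.5, 5.5),
        ((3, 3, 3, 3, 3), 4.1, 19.1),
    ])
    def test_sum_examples(self, ctp_bands, lactate, expected):
        rec = TestComputeCtp()._record_for(ctp_bands)
        rec.lactate = lactate
        assert compute_ctp_plus_l(rec) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(bili=st.floats(1, 500), alb=st.floats(5, 60),
           inr=st.floats(0.9, 6), lactate=st.floats(0.1, 20),
           asc=st.sampled_from(["none", "mild", "severe"]),
           enc=st.sampled_from([0, 1, 2, 3, 4]))
    def test_identity_ctp_plus_l_minus_ctp_is_lactate(self, bili, alb, inr,
                                                      lactate, asc, enc):
        rec = make_record(bilirubin=bili, albumin=alb, pt_ratio=inr,
                          lactate=lactate, ascites=asc, encephalopathy=enc)
        # bit-exact: the score IS the sum of the integer CTP and raw lactate
        assert compute_ctp_plus_l(rec) == compute_ctp(rec) + lactate


def brute_force_band_sum(record, definition):
    """Independent evaluation: linear scan over band edges per component."""
    from liverscore.scores import DERIVED_RULES

    total = definition.constant
    for comp in definition.components:
        if comp.rule is not None:
            v = DERIVED_RULES[comp.rule](record, comp.params)
        else:
            v = getattr(record, comp.field)
        if v is None:
            if comp.normal_if_missing:
                continue
            return None
        if comp.rule is not None:
            total += v
        elif comp.mapping is not None:
            total += comp.mapping[v]
        else:
            band = 0
            for edge in comp.edges:
                past = v >= edge if not comp.right_closed else v > edge
                if past:
                    band += 1
                else:
                    break
            total += comp.points[band]
    return total


class TestDefinedScores:
    def test_builtin_definitions_load_and_validate(self):
        defs = builtin_definitions()
        assert set(defs) == {"MELD", "UKELD", "SOFA", "CLIF-SOFA",
                             "APACHE II", "RFH"}
        assert defs["RFH"].provisional

    def test_sofa_worst_bands_score_24(self):
        rec = make_record(pf_ratio=6.0, pao2=10.0, platelets=10.0,
                          bilirubin=300.0, noradrenaline_dose=0.5, gcs=3,
                          creatinine=500.0)
        sofa = compute_defined_score(rec, builtin_definitions()["SOFA"])
        assert sofa == 24

    def test_band_sum_matches_brute_force_on_random_records(self, rng):
        defs = builtin_definitions()
        band_defs = [defs[n] for n in ("SOFA", "CLIF-SOFA", "APACHE II")]
        for _ in range(300):
            rec = make_record(
                bilirubin=float(rng.lognormal(3.8, 1.2)),
                platelets=float(rng.uniform(5, 500)),
                creatinine=float(rng.lognormal(4.4, 0.8)),
                pf_ratio=float(rng.uniform(4, 55)),
                pao2=float(rng.uniform(12, 60)),
                gcs=int(rng.integers(3, 16)),
                map=float(rng.uniform(40, 130)),
                noradrenaline_dose=float(max(0, rng.normal(0.05, 0.1))),
                pt_ratio=float(rng.lognormal(0.4, 0.4)),
                sodium=float(rng.uniform(115, 155)),
                potassium=float(rng.uniform(2.2, 7.2)),
                wcc=float(rng.uniform(0.6, 44)),
                age=float(rng.uniform(18, 89)),
                encephalopathy=int(rng.integers(0, 5)))
            for d in band_defs:
                assert compute_defined_score(rec, d) == \
                    brute_force_band_sum(rec, d), d.name

    def test_meld_against_hand_formula(self):
        rec = make_record(bilirubin=85.5, creatinine=176.8, pt_ratio=2.0)
        # independent arithmetic: 3.78 ln(5 mg/dL) + 11.2 ln(2) + 9.57 ln(2 mg/dL) + 6.43
        expected = 3.78 * math.log(5.0) + 11.2 * math.log(2.0) \
            + 9.57 * math.log(2.0) + 6.43
        assert compute_defined_score(
            rec, builtin_definitions()["MELD"]) == pytest.approx(expected)

    def test_meld_floors_subnormal_inputs(self):
        rec = make_record(bilirubin=10.0, creatinine=50.0, pt_ratio=0.9)
        # all three inputs floor at 1.0 -> logs vanish, only intercept remains
        assert compute_defined_score(
            rec, builtin_definitions()["MELD"]) == pytest.approx(6.43)

    def test_apache_missing_physiology_scores_zero(self):
        rec = make_record(map=None, sodium=None, pao2=None)
        full = make_record()
        defs = builtin_definitions()
        a_missing = compute_defined_score(rec, defs["APACHE II"])
        a_full = compute_defined_score(full, defs["APACHE II"])
        assert a_missing is not None
        assert a_missing <= a_full + 4  # normal-if-missing never adds points

    def test_missing_component_yields_missing_score(self):
        rec = make_record(creatinine=None)
        assert compute_defined_score(rec, builtin_definitions()["MELD"]) is None

    def test_invalid_definition_rejected(self):
        from liverscore.scores import Component, ScoreDefinition

        with pytest.raises(ScoreDefinitionError, match="increasing"):
            ScoreDefinition("bad", "band_sum", [
                Component("band", field="lactate", edges=[5.0, 2.0],
                          points=[0, 1, 2])])
        with pytest.raises(ScoreDefinitionError, match="unknown field"):
            ScoreDefinition("bad", "band_sum", [
                Component("band", field="nope", edges=[1.0],
                          points=[0, 1])])


class TestOrganFailures:
    def test_counts_fired_systems(self):
        rec = make_record(pf_ratio=10.0, pao2=12.0, map=60.0,
                          creatinine=300.0, gcs=8, platelets=30.0,
                          bilirubin=300.0)
        assert organ_failure_count(rec) == 6

    def test_missing_inputs_count_as_not_failing(self):
        rec = make_record(pf_ratio=None, map=None, creatinine=None, gcs=None,
                          platelets=None, bilirubin=None,
                          noradrenaline_dose=None)
        assert organ_failure_count(rec) == 0


class TestPanel:
    def test_complete_record_has_all_eight_scores(self):
        panel = compute_panel(make_cohort([make_record()]))
        assert panel.shape == (1, 8)
        assert not panel.isna().any().any()

    def test_missing_ascites_kills_ctp_but_not_meld(self):
        panel = compute_panel(make_cohort([make_record(ascites=None)]))
        assert np.isnan(panel["CTP"].iloc[0])
        assert np.isnan(panel["CTP+L"].iloc[0])
        assert not np.isnan(panel["MELD"].iloc[0])

    def test_panel_insensitive_to_record_order(self, glasgow_cohort):
        reversed_cohort = make_cohort(list(glasgow_cohort)[::-1],
                                      label="rev")
        p1 = compute_panel(glasgow_cohort).sort_index()
        p2 = compute_panel(reversed_cohort).sort_index()
        assert p1.equals(p2)

    def test_ctp_plus_l_median_exceeds_ctp_median(self, glasgow_cohort):
        panel = compute_panel(glasgow_cohort)
        both = panel[["CTP", "CTP+L"]].dropna()
        min_lactate = min(r.lactate for r in glasgow_cohort
                          if r.lactate is not None)
        assert both["CTP+L"].median() >= both["CTP"].median() + min_lactate
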