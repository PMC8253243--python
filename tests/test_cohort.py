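"""Cohort statistics: %PPI, test selection, BBB assays, gating, fold change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phenopipe import cohort, synthgen


class TestPercentPpi:
    @pytest.mark.parametrize(
        "pre,pulse,expected", [(50, 100, 50.0), (100, 100, 0.0), (120, 100, -20.0)]
    )
    def test_formula(self, pre, pulse, expected):
        assert cohort.percent_ppi(pre, pulse) == pytest.approx(expected)

    def test_non_positive_pulse_rejected(self):
        with pytest.raises(ValueError):
            cohort.percent_ppi(50.0, 0.0)

    @given(
        st.floats(1.0, 200.0),
        st.floats(1.0, 200.0),
        st.floats(0.01, 100.0),
    )
    def test_invariant_to_common_rescaling(self, pre, pulse, scale):
        a = cohort.percent_ppi(pre, pulse)
        b = cohort.percent_ppi(pre * scale, pulse * scale)
        assert a == pytest.approx(b, abs=1e-8)

    def test_table_processing_averages_then_excludes_negatives(self):
        table = pd.DataFrame(
            {
                "animal": ["m1"] * 8 + ["m2"] * 4,
                "intensity": [70, 70, 75, 75, 80, 80, 120, 120, 70, 75, 80, 120],
                # m1: averaged within intensity first -> (40+60)/2 = 50 etc.
                "amplitude": [40, 60, 30, 50, 20, 40, 90, 110, 150, 50, 50, 100],
            }
        )
        records = cohort.process_startle_table(table)
        m1, m2 = records
        assert m1.ppi[70] == pytest.approx(50.0)
        assert m1.ppi[75] == pytest.approx(60.0)
        assert m1.ppi[80] == pytest.approx(70.0)
        assert not m1.excluded
        assert m2.ppi[70] == pytest.approx(-50.0)
        assert m2.excluded  # non-performer: negative PPI at any intensity

    def test_non_positive_pulse_only_makes_animal_invalid(self):
        table = pd.DataFrame(
            {"animal": [1, 1], "intensity": [70, 120], "amplitude": [10.0, 0.0]}
        )
        (rec,) = cohort.process_startle_table(table)
        assert not rec.valid


class TestTwoSampleSelection:
    def test_normal_samples_take_welch_branch(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 20)
        res = cohort.choose_two_sample_test(a, b)
        assert res.test_name == "welch_t"
        assert all(p >= 0.05 for p in res.shapiro_p)

    def test_heavy_lognormal_takes_mann_whitney_branch(self, rng):
        a = np.exp(rng.normal(0, 1.5, 20))
        b = rng.normal(0, 1, 20)
        res = cohort.choose_two_sample_test(a, b)
        assert res.test_name == "mann_whitney_u"
        assert min(res.shapiro_p) < 0.05

    def test_identical_groups_near_unity_p_and_deterministic(self, rng):
        a = rng.normal(0, 1, 15)
        r1 = cohort.choose_two_sample_test(a, a.copy())
        r2 = cohort.choose_two_sample_test(a, a.copy())
        assert r1 == r2
        assert r1.p > 0.9

    def test_all_tied_data_reports_fallback(self):
        res = cohort.choose_two_sample_test([1.0] * 5, [1.0] * 5)
        assert res.p == 1.0 and "tied" in res.note

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cohort.choose_two_sample_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBbbAssays:
    def test_water_content_examples(self):
        assert cohort.water_content(0.4, 0.1) == pytest.approx(75.0)
        assert cohort.water_content(0.4, 0.4) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cohort.water_content(0.3, 0.4)

    @given(st.floats(0.1, 2.0), st.floats(0.01, 1.0))
    def test_water_content_matches_formula(self, wet, frac):
        dry = wet * frac
        assert cohort.water_content(wet, dry) == pytest.approx(
            100.0 * (wet - dry) / wet
        )

    def test_two_point_standard_curve_is_exact(self):
        res = cohort.tracer_concentration(50.0, [(0.0, 0.0), (100.0, 10.0)])
        assert res.concentration == pytest.approx(5.0)
        assert not res.extrapolated

    def test_controls_normalize_to_unity_mean(self):
        curve = [(0.0, 0.0), (100.0, 10.0)]
        controls = np.array([30.0, 50.0, 70.0])
        conc = cohort.tracer_concentration(controls, curve).concentration
        res = cohort.tracer_concentration(controls, curve, control_mean=conc.mean())
        assert res.normalized.mean() == pytest.approx(1.0)

    def test_triplicates_averaged_before_interpolation(self):
        triplicates = np.array([[40.0, 50.0, 60.0]])
        res = cohort.tracer_concentration(triplicates, [(0.0, 0.0), (100.0, 10.0)])
        assert res.concentration[0] == pytest.approx(5.0)

    def test_out_of_range_reading_flagged(self):
        res = cohort.tracer_concentration(150.0, [(0.0, 0.0), (100.0, 10.0)])
        assert res.extrapolated

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError):
            cohort.tracer_concentration(
                5.0, [(0.0, 0.0), (50.0, 10.0), (100.0, 5.0)]
            )


class TestGating:
    @staticmethod
    def _blood_event(cd4, cd8, b220=0.0, cd11b=0.0):
        return pd.DataFrame(
            [{"CD4": cd4, "CD8": cd8, "B220": b220, "CD11b": cd11b,
              "is_lymphocyte": True}]
        )

    def test_single_t_helper_event(self):
        res = cohort.gate_cells(self._blood_event(4.0, 0.0), "blood")
        assert res.counts["t_helper"] == 1
        assert res.frequencies["t_helper"] == 100.0

    def test_double_positive_lands_ungated(self):
        res = cohort.gate_cells(self._blood_event(4.0, 4.0), "blood")
        assert res.counts["ungated"] == 1
        assert sum(res.counts.values()) == 1

    def test_blood_counts_match_truth_labels(self):
        counts = {"t_helper": 400, "t_cytotoxic": 300, "b_cell": 200,
                  "myeloid": 100, "ungated_double_positive": 50}
        events = synthgen.gen_flow_events("blood", counts, seed=8)
        res = cohort.gate_cells(events, "blood")
        for name in ("t_helper", "t_cytotoxic", "b_cell", "myeloid"):
            assert res.counts[name] == counts[name]
        assert res.counts["ungated"] == 50
        assert sum(res.counts.values()) == res.n_parent  # partition

    def test_brain_subgates_stay_within_parents(self):
        counts = {"microglia": 300, "macrophage": 80, "cd4_t": 120, "cd8_t": 90,
                  "b_cell": 60, "plasma_cell": 40, "leukocyte_other": 70,
                  "ungated_negative": 30}
        events = synthgen.gen_flow_events("brain", counts, seed=9)
        res = cohort.gate_cells(events, "brain")
        assert res.counts["leukocyte"] == 120 + 90 + 60 + 40 + 70
        assert res.subgates["cd4_t"] == 120
        assert res.subgates["b_cell"] == 60
        assert res.subgates["plasma_cell"] == 40
        assert res.subgates["cd4_t"] + res.subgates["cd8_t"] <= res.subgates["leukocyte_parent"]
        assert res.subgates["dn_leukocyte_parent"] <= res.subgates["leukocyte_parent"]

    def test_missing_marker_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            cohort.gate_cells(pd.DataFrame({"CD4": [1.0]}), "blood")

    def test_unknown_panel_rejected(self):
        with pytest.raises(ValueError):
            cohort.gate_cells(self._blood_event(0, 0), "bone_marrow")


class TestCountsAndFolds:
    def test_bead_correction_proportionality(self):
        assert cohort.bead_correct(100, 50, 100) == pytest.approx(200.0)
        assert cohort.bead_correct(123, 100, 100) == pytest.approx(123.0)
        with pytest.raises(ValueError):
            cohort.bead_correct(10, 0, 100)

    @given(st.floats(1, 1e4), st.floats(1, 1e4), st.floats(1, 1e4))
    def test_bead_correction_matches_formula(self, count, rec, added):
        assert cohort.bead_correct(count, rec, added) == pytest.approx(
            count * added / rec
        )

    def test_fold_change_examples(self):
        controls = [2.0, 4.0]  # mean 3
        assert cohort.fold_change_to_control(3.0, controls) == pytest.approx(1.0)
        assert cohort.fold_change_to_control(6.0, controls) == pytest.approx(2.0)
        out = cohort.fold_change_to_control(controls, controls)
        assert out.mean() == pytest.approx(1.0)

    def test_non_positive_control_mean_rejected(self):
        with pytest.raises(ValueError):
            cohort.fold_change_to_control(1.0, [0.0, 0.0])
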