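import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prmquant import prm_quantitation as pq
from prmquant import synthetic_data as sd
from prmquant.formats_io import SampleSpec, TransitionRecord


def rec(label, frag, area, quantitative=True, sample="S1", rep=1, pep="PEPK"):
    return TransitionRecord(sample, rep, pep, 2, frag, 1, label, area, quantitative)


SPEC10 = SampleSpec("S1", 1, 1.0, 20.0, 10.0, 2, False)


class TestCommonTransitions:
    def test_intersection(self):
        records = [
            rec("light", "y5", 1), rec("light", "y7", 1),
            rec("heavy", "y5", 1), rec("heavy", "y7", 1), rec("heavy", "y9", 1),
        ]
        assert pq.common_transitions(records) == {("y5", 1), ("y7", 1)}

    def test_disjoint(self):
        records = [rec("light", "y5", 1), rec("heavy", "y7", 1)]
        assert pq.common_transitions(records) == set()

    def test_non_quantitative_excluded(self):
        records = [
            rec("light", "y7", 1, quantitative=False),
            rec("heavy", "y7", 1),
            rec("light", "y5", 1), rec("heavy", "y5", 1),
        ]
        assert pq.common_transitions(records) == {("y5", 1)}


class TestLightHeavyRatio:
    def test_summed_ratio(self):
        records = [
            rec("light", "y5", 300), rec("light", "y7", 700),
            rec("heavy", "y5", 600), rec("heavy", "y7", 1400),
        ]
        m = pq.light_heavy_ratio(records)
        assert m.ratio_light_over_heavy == pytest.approx(0.5)
        assert m.n_common_transitions == 2
        assert m.sum_light_area == 1000 and m.sum_heavy_area == 2000

    def test_identical_areas_give_one(self):
        records = [rec("light", "y5", 123.4), rec("heavy", "y5", 123.4)]
        assert pq.light_heavy_ratio(records).ratio_light_over_heavy == 1.0

    def test_zero_heavy_discarded(self):
        records = [rec("light", "y5", 10), rec("heavy", "y5", 0)]
        m = pq.light_heavy_ratio(records)
        assert m.qc == pq.DISCARDED and m.reason

    def test_non_common_areas_excluded_from_sums(self):
        records = [
            rec("light", "y5", 100), rec("heavy", "y5", 200),
            rec("light", "y9", 99999),  # light-only: not common
        ]
        m = pq.light_heavy_ratio(records)
        assert m.sum_light_area == 100


class TestToFmol:
    def test_ratio_times_level(self):
        m = pq.PeptideMeasurement("S1", 1, "PEPK", 3, 1, 2, 0.5)
        assert pq.to_fmol(m, SPEC10).light_fmol_raw == pytest.approx(5.0)

    def test_unit_ratio_level_one(self):
        spec = SampleSpec("S1", 1, 1.0, 20.0, 1.0, 2, False)
        m = pq.PeptideMeasurement("S1", 1, "PEPK", 3, 1, 2, 1.0)
        assert pq.to_fmol(m, spec).light_fmol_raw == pytest.approx(1.0)

    def test_level_zero_skipped(self):
        spec = SampleSpec("S1", 1, 1.0, 20.0, 0.0, 2, False)
        m = pq.PeptideMeasurement("S1", 1, "PEPK", 3, 1, 2, 1.0)
        assert pq.to_fmol(m, spec).qc == pq.DISCARDED
        assert "level 0" in pq.to_fmol(m, spec).reason


class TestBleedthrough:
    def test_blank_ratio_is_bleed(self):
        m = pq.PeptideMeasurement("B0-3", 1, "PEPK", 3, 50, 10000, 0.005)
        est = pq.estimate_bleedthrough([m], {"B0-3": 100.0})
        assert est["PEPK"].at_level(100.0) == pytest.approx(0.005)

    def test_no_light_signal_gives_zero(self):
        m = pq.PeptideMeasurement("B0-1", 1, "PEPK", 3, 0, 10000, 0.0)
        est = pq.estimate_bleedthrough([m], {"B0-1": 1.0})
        assert est["PEPK"].at_level(1.0) == 0.0

    def test_level_matched_vs_mean(self):
        ms = [
            pq.PeptideMeasurement("B0-1", 1, "PEPK", 3, 1, 100, 0.002),
            pq.PeptideMeasurement("B0-2", 1, "PEPK", 3, 1, 100, 0.006),
        ]
        est = pq.estimate_bleedthrough(ms, {"B0-1": 1.0, "B0-2": 10.0})
        assert est["PEPK"].at_level(10.0) == pytest.approx(0.006)
        assert est["PEPK"].at_level(100.0) == pytest.approx(0.004)  # mean fallback
        assert est["PEPK"].at_level(10.0, level_matched=False) == pytest.approx(0.004)

    def test_synthetic_round_trip_exact(self):
        truth = sd.generate_truth(
            2, seed=8, tech_cv=0, bio_cv=0, bleed_range=(0.01, 0.01),
            include_control=False,
        )
        design = sd.generate_design()
        records = sd.simulate_transitions(truth, design)
        table = pq.quantify(records, design)
        blanks = table[table["role"] == "blank"]
        assert np.allclose(blanks["ratio_light_over_heavy"], 0.01)
        samples = table[(table["role"] == "sample") & (table["level"] > 0)]
        assert np.allclose(samples["bleed_fraction"], 0.01)

    def test_correction_kept(self):
        m = pq.PeptideMeasurement(
            "S1", 1, "PEPK", 3, 1e6, 1e6, 1.0, heavy_fmol=10.0, light_fmol_raw=10.0
        )
        out = pq.correct_bleedthrough(m, 0.05)  # contribution 0.5 = 5% of 10
        assert out.qc != pq.DISCARDED
        assert out.light_fmol_corrected == pytest.approx(9.5)

    def test_correction_discarded_above_20_percent(self):
        m = pq.PeptideMeasurement(
            "S1", 1, "PEPK", 3, 1e6, 1e6, 0.2, heavy_fmol=10.0, light_fmol_raw=2.0
        )
        out = pq.correct_bleedthrough(m, 0.05)  # contribution 0.5 = 25% of 2
        assert out.qc == pq.DISCARDED and "bleed" in out.reason

    def test_zero_bleed_unchanged(self):
        m = pq.PeptideMeasurement(
            "S1", 1, "PEPK", 3, 1e6, 1e6, 0.7, heavy_fmol=10.0, light_fmol_raw=7.0
        )
        out = pq.correct_bleedthrough(m, 0.0)
        assert out.light_fmol_corrected == pytest.approx(7.0)


def oracle_qc(n_common, sum_light, sum_heavy, level, light_fmol):
    """Literal transcription of the published quality rules, kept independent
    of the implementation under test."""
    maybe_poor = False
    if n_common <= 2:
        maybe_poor = True
    if sum_light < 10000:
        maybe_poor = True
    if sum_heavy < 10000:
        maybe_poor = True
    if level == 1 and light_fmol > 10:
        maybe_poor = True
    if level == 10 and light_fmol > 500:
        maybe_poor = True
    if level == 100 and light_fmol < 2:
        maybe_poor = True
    return "Maybe Poor" if maybe_poor else "Good"


class TestClassifyQc:
    def _measurement(self, n_common, sum_light, sum_heavy, ratio, level):
        m = pq.PeptideMeasurement(
            "S1", 1, "PEPK", n_common, sum_light, sum_heavy, ratio
        )
        spec = SampleSpec("S1", 1, 1.0, 20.0, level, 2, False)
        return pq.to_fmol(m, spec), spec

    def test_two_common_transitions_maybe_poor(self):
        m, spec = self._measurement(2, 1e6, 1e6, 1.0, 10.0)
        assert pq.classify_qc(m, spec) == pq.MAYBE_POOR

    def test_extreme_ratio_level1(self):
        m, spec = self._measurement(5, 1e6, 1e6, 12.0, 1.0)  # 12 fmol > 10
        assert pq.classify_qc(m, spec) == pq.MAYBE_POOR

    def test_good_case(self):
        m, spec = self._measurement(5, 5e5, 5e5, 4.0, 10.0)  # 40 fmol
        assert pq.classify_qc(m, spec) == pq.GOOD

    def test_low_area_either_label(self):
        m, spec = self._measurement(5, 9999, 1e6, 4.0, 10.0)
        assert pq.classify_qc(m, spec) == pq.MAYBE_POOR
        m, spec = self._measurement(5, 1e6, 9999, 4.0, 10.0)
        assert pq.classify_qc(m, spec) == pq.MAYBE_POOR

    def test_level100_low_light(self):
        m, spec = self._measurement(5, 1e6, 1e6, 0.01, 100.0)  # 1 fmol < 2
        assert pq.classify_qc(m, spec) == pq.MAYBE_POOR

    def test_oracle_equivalence_randomized(self, rng):
        levels = np.array([1.0, 10.0, 100.0])
        for _ in range(10_000):
            n_common = int(rng.integers(1, 8))
            sum_heavy = float(rng.choice([5e3, 9999.0, 10000.0, 1e5, 1e7]))
            level = float(rng.choice(levels))
            ratio = float(10 ** rng.uniform(-4, 2))
            sum_light = ratio * sum_heavy
            m = pq.PeptideMeasurement(
                "S1", 1, "PEPK", n_common, sum_light, sum_heavy, ratio
            )
            spec = SampleSpec("S1", 1, 1.0, 20.0, level, 2, False)
            m = pq.to_fmol(m, spec)
            assert pq.classify_qc(m, spec) == oracle_qc(
                n_common, sum_light, sum_heavy, level, m.light_fmol_raw
            )

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        n_common=st.integers(min_value=1, max_value=8),
        base_light=st.floats(min_value=1.0, max_value=1e6),
        base_heavy=st.floats(min_value=1.0, max_value=1e6),
        level=st.sampled_from([1.0, 10.0, 100.0]),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance_with_floor_disabled(
        self, scale, n_common, base_light, base_heavy, level
    ):
        spec = SampleSpec("S1", 1, 1.0, 20.0, level, 2, False)

        def classify(light, heavy):
            m = pq.PeptideMeasurement(
                "S1", 1, "PEPK", n_common, light, heavy, light / heavy
            )
            m = pq.to_fmol(m, spec)
            return pq.classify_qc(m, spec, area_floor=0.0), m

        qc_a, m_a = classify(base_light, base_heavy)
        qc_b, m_b = classify(base_light * scale, base_heavy * scale)
        assert qc_a == qc_b
        assert m_a.light_fmol_raw == pytest.approx(m_b.light_fmol_raw, rel=1e-9)


class TestQuantifyPipeline:
    def _toy_inputs(self, rng, n_proteins=4):
        truth = sd.generate_truth(n_proteins, seed=int(rng.integers(1e6)))
        design = sd.generate_design()
        records = sd.simulate_transitions(truth, design)
        return truth, design, records

    def test_pipeline_matches_op_composition(self, rng):
        # dual route: the vectorized pipeline vs the per-group operations
        truth, design, records = self._toy_inputs(rng)
        table = pq.quantify(records, design, control_peptides=truth.control_peptides)
        specs = {s.sample_id: s for s in design}
        groups = {}
        for record in records:
            groups.setdefault(
                (record.sample_id, record.tech_rep, record.peptide_key), []
            ).append(record)
        for (sample, rep, pep), group in groups.items():
            m = pq.light_heavy_ratio(group)
            row = table[
                (table.sample_id == sample)
                & (table.tech_rep == rep)
                & (table.peptide_key == pep)
            ].iloc[0]
            assert row["n_common_transitions"] == m.n_common_transitions
            assert row["sum_light_area"] == pytest.approx(m.sum_light_area)
            assert row["sum_heavy_area"] == pytest.approx(m.sum_heavy_area)
            if m.qc != pq.DISCARDED and not specs[sample].is_blank:
                m = pq.to_fmol(m, specs[sample])
                if m.qc != pq.DISCARDED:
                    assert row["light_fmol_raw"] == pytest.approx(m.light_fmol_raw)

    def test_unknown_sample_rejected(self):
        records = [rec("light", "y5", 1, sample="MYSTERY")]
        with pytest.raises(ValueError, match="MYSTERY"):
            pq.quantify(records, [SPEC10])

    def test_control_peptides_get_zero_bleed(self):
        truth = sd.generate_truth(2, seed=12, tech_cv=0, bio_cv=0,
                                  bleed_range=(0.01, 0.01))
        design = sd.generate_design()
        records = sd.simulate_transitions(truth, design)
        table = pq.quantify(records, design, control_peptides=truth.control_peptides)
        controls = table[
            table.peptide_key.isin(truth.control_peptides)
            & (table.role == "sample") & (table.level > 0)
        ]
        assert (controls["bleed_fraction"] == 0).all()
        # recovered spike equals the configured control amount exactly
        assert np.allclose(controls["light_fmol_corrected"], truth.control_fmol)

    def test_level_zero_rows_discarded_with_reason(self, table1_design):
        truth = sd.generate_truth(2, seed=13)
        records = sd.simulate_transitions(truth, table1_design)
        table = pq.quantify(records, table1_design,
                            control_peptides=truth.control_peptides)
        zero = table[(table.role == "sample") & (table.level == 0)]
        assert (zero["qc"] == pq.DISCARDED).all()
        assert zero["reason"].str.len().gt(0).all()
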