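import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lyschase.preprocess import (
    aggregate_technical,
    classify_label_state,
    compute_R,
    flag_rapid_degraders,
    heavy_fraction_summary,
)
from tests.conftest import BIRTH, WEANING, quant_frame


def tech_rows(pid, values, channel="H", design=BIRTH, age=7.0, bio=1):
    return [(pid, design, age, bio, i + 1, channel, v) for i, v in enumerate(values)]


class TestAggregateTechnical:
    def test_median_needs_two_of_four(self):
        rows = tech_rows("P1", [10, 12, np.nan, np.nan]) + tech_rows("P2", [10, np.nan, np.nan, np.nan])
        agg = aggregate_technical(quant_frame(rows), n_tech=4)
        a = agg.set_index("protein_id")
        assert a.loc["P1", "H"] == 11.0  # median of the detected pair
        assert np.isnan(a.loc["P2", "H"])  # one detection: set as n.a.

    def test_zero_is_not_a_detection(self):
        rows = tech_rows("P1", [10, 0, 0, np.nan])
        agg = aggregate_technical(quant_frame(rows), n_tech=4)
        assert np.isnan(agg["H"].iloc[0])

    def test_single_tech_passthrough(self):
        agg = aggregate_technical(quant_frame(tech_rows("P1", [5.0])), n_tech=1)
        assert agg["H"].iloc[0] == 5.0

    def test_permutation_invariance(self):
        vals = [3.0, 9.0, np.nan, 5.0]
        a = aggregate_technical(quant_frame(tech_rows("P1", vals)), n_tech=4)
        b = aggregate_technical(quant_frame(tech_rows("P1", vals[::-1])), n_tech=4)
        assert a["H"].iloc[0] == b["H"].iloc[0]

    def test_r_and_f_consistency(self):
        rows = tech_rows("P1", [100, 100]) + tech_rows("P1", [50, 50], channel="L")
        agg = aggregate_technical(quant_frame(rows), n_tech=4)
        r, f = agg["R"].iloc[0], agg["F"].iloc[0]
        assert r == pytest.approx(math.log(1.5))
        assert f == pytest.approx(math.exp(-r))

    def test_censored_high_flag(self):
        rows = tech_rows("P1", [np.nan, np.nan, np.nan, np.nan]) + \
            tech_rows("P1", [40, 44], channel="L")
        agg = aggregate_technical(quant_frame(rows), n_tech=4)
        assert agg["censored_high"].iloc[0]
        assert np.isnan(agg["R"].iloc[0])


class TestComputeR:
    @pytest.mark.parametrize("L,H,expected", [
        (0.0, 5.0, 0.0),
        (5.0, 5.0, math.log(2)),
        (15.0, 5.0, math.log(4)),
    ])
    def test_examples(self, L, H, expected):
        assert compute_R(L, H) == pytest.approx(expected, abs=1e-12)

    def test_f_from_r(self):
        # L = 3H: a quarter of the protein is still heavy
        assert math.exp(-compute_R(15.0, 5.0)) == pytest.approx(0.25)

    def test_h_zero_censored_high(self):
        assert compute_R(3.0, 0.0) == math.inf

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_R(-1.0, 2.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.0, 1e6), st.floats(1e-6, 1e6))
    def test_identity_f_exp_minus_r(self, L, H):
        assert math.exp(-compute_R(L, H)) == pytest.approx(H / (H + L), rel=1e-9)


class TestLabelState:
    def test_heavy_only_definition(self):
        rows = tech_rows("P1", [5, 6, 7, np.nan], bio=1) + \
            tech_rows("P1", [np.nan] * 4, channel="L", bio=1) + \
            tech_rows("P1", [np.nan] * 4, bio=2) + \
            tech_rows("P1", [np.nan] * 4, channel="L", bio=2)
        states = classify_label_state(quant_frame(rows), n_tech=4)
        assert states.state.iloc[0] == "heavy_only"

    def test_both_channels(self):
        rows = tech_rows("P1", [5, 6, np.nan, np.nan]) + \
            tech_rows("P1", [2, 3, np.nan, np.nan], channel="L")
        states = classify_label_state(quant_frame(rows), n_tech=4)
        assert states.state.iloc[0] == "both"

    def test_single_heavy_detection_is_undetected(self):
        rows = tech_rows("P1", [5, np.nan, np.nan, np.nan]) + \
            tech_rows("P1", [np.nan] * 4, channel="L")
        states = classify_label_state(quant_frame(rows), n_tech=4)
        assert states.state.iloc[0] == "undetected"


class TestHeavyFractionSummary:
    def test_mean_and_sd_over_bio_reps(self):
        rows = []
        for bio, f in ((1, 0.95), (2, 0.93)):
            rows += tech_rows("P1", [f * 100] * 2, bio=bio)
            rows += tech_rows("P1", [(1 - f) * 100] * 2, channel="L", bio=bio)
        agg = aggregate_technical(quant_frame(rows), n_tech=4)
        s = heavy_fraction_summary(agg)
        assert s.f_mean.iloc[0] == pytest.approx(0.94)
        assert s.f_sd.iloc[0] == pytest.approx(0.0141, abs=2e-4)

    def test_single_rep_reported_without_sd(self):
        rows = tech_rows("P1", [50, 50], bio=1) + tech_rows("P1", [50, 50], channel="L", bio=1)
        agg = aggregate_technical(quant_frame(rows), n_tech=4)
        s = heavy_fraction_summary(agg)
        assert s.f_mean.iloc[0] == pytest.approx(0.5)
        assert np.isnan(s.f_sd.iloc[0])
        assert s.n_reps.iloc[0] == 1

    def test_no_f_no_row(self):
        rows = tech_rows("P1", [np.nan] * 4)
        agg = aggregate_technical(quant_frame(rows), n_tech=4)
        assert heavy_fraction_summary(agg).empty


class TestRapidDegraders:
    def series(self, design, heavy_late, light_late):
        rows = []
        for age in (7.0, 42.0, 84.0):
            h = [5, 6, 7, 8] if (age < 42 or heavy_late) else [np.nan] * 4
            l = [5, 6, 7, 8] if light_late or age < 42 else [np.nan] * 4
            rows += tech_rows("P1", h, design=design, age=age)
            rows += tech_rows("P1", l, channel="L", design=design, age=age)
        return quant_frame(rows)

    def test_flagged_when_heavy_vanishes_in_both_designs(self):
        recs = {BIRTH: self.series(BIRTH, heavy_late=False, light_late=True),
                WEANING: self.series(WEANING, heavy_late=False, light_late=True)}
        assert flag_rapid_degraders(recs, cutoff_age=42.0, n_tech=4) == {"P1"}

    def test_not_flagged_if_heavy_persists(self):
        recs = {BIRTH: self.series(BIRTH, heavy_late=True, light_late=True),
                WEANING: self.series(WEANING, heavy_late=False, light_late=True)}
        assert flag_rapid_degraders(recs, cutoff_age=42.0, n_tech=4) == set()

    def test_not_expressed_not_flagged(self):
        recs = {BIRTH: self.series(BIRTH, heavy_late=False, light_late=False),
                WEANING: self.series(WEANING, heavy_late=False, light_late=False)}
        assert flag_rapid_degraders(recs, cutoff_age=42.0, n_tech=4) == set()
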