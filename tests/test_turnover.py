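import math

import numpy as np
import pytest

from lyschase.free_pool import FreePoolModel
from lyschase.growth import GrowthModel, fit_growth_curve
from lyschase.turnover import (
    TurnoverModelSpec,
    fit_2lys_peptide,
    half_life,
    model_R,
    simulate_fraction,
)
import pandas as pd

NO_GROWTH = GrowthModel.constant()
NO_POOL = FreePoolModel.zero("chase_from_birth", 0.0)


def growth_from(pairs):
    return fit_growth_curve(pd.DataFrame(
        [{"age_days": a, "volume": v, "method": "lwh"} for a, v in pairs]))


class TestSimulateFraction:
    def test_pure_decay_limit(self):
        t = np.linspace(0.5, 300, 50)
        for k in (1e-3, 0.05, 1.0):
            F = simulate_fraction(k, 1.0, NO_POOL, NO_GROWTH, t).F
            np.testing.assert_allclose(F, np.exp(-k * t), atol=1e-12)

    def test_growth_only_dilution(self):
        g = growth_from([(1e-9, 1.0), (56.0, 8.0)])
        F = simulate_fraction(0.0, 1.0, NO_POOL, g, [56.0]).F
        assert F[0] == pytest.approx(1 / 8, abs=1e-9)

    def test_steady_state_at_constant_pool(self):
        pool = FreePoolModel("x", p0=0.5, lambda_free=0.0, chase_start=0.0, p_label=0.5)
        F = simulate_fraction(0.1, 1.0, pool, NO_GROWTH, [2000.0]).F
        assert F[0] == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_k(self):
        pool = FreePoolModel("x", p0=0.9, lambda_free=0.1, chase_start=0.0)
        g = growth_from([(1.0, 1.0), (100.0, 20.0)])
        t = np.linspace(1, 400, 60)
        ks = np.array([0.01, 0.05, 0.2])
        F = simulate_fraction(ks, 0.987, pool, g, t).F
        assert np.all(np.diff(F, axis=0) <= 1e-12)

    def test_zero_pool_object_equals_p0_zero(self):
        charged_shape = FreePoolModel("x", p0=0.0, lambda_free=0.3, chase_start=0.0,
                                      p_label=0.0)
        t = np.linspace(0, 100, 30)
        F1 = simulate_fraction(0.05, 1.0, NO_POOL, NO_GROWTH, t).F
        F2 = simulate_fraction(0.05, 1.0, charged_shape, NO_GROWTH, t).F
        np.testing.assert_array_equal(F1, F2)

    def test_plateau_before_chase_start(self):
        pool = FreePoolModel("chase_from_weaning", p0=0.987, lambda_free=0.15,
                             chase_start=21.0)
        traj = simulate_fraction(0.1, 0.987, pool, NO_GROWTH, [5.0, 21.0, 42.0])
        assert traj.F[0] == 0.987
        assert traj.F[1] == 0.987
        assert traj.F[2] < 0.987

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_fraction(-0.1, 1.0, NO_POOL, NO_GROWTH, [1.0])
        with pytest.raises(ValueError):
            simulate_fraction(0.1, 1.5, NO_POOL, NO_GROWTH, [1.0])


class TestModelR:
    @pytest.mark.parametrize("F,expected", [(1.0, 0.0), (0.5, math.log(2)), (0.25, 1.3863)])
    def test_examples(self, F, expected):
        assert model_R(np.array([F]))[0] == pytest.approx(expected, abs=1e-4)

    def test_zero_fraction_censored(self):
        assert model_R(np.array([0.0]))[0] == math.inf


class TestHalfLife:
    def test_closed_form_across_rates(self):
        for k in np.logspace(-3, 0, 10):
            assert half_life(k, 1.0, NO_POOL, NO_GROWTH) == pytest.approx(
                math.log(2) / k, rel=1e-12)

    def test_tiny_rate_censored(self):
        assert half_life(1e-5, 1.0, NO_POOL, NO_GROWTH, cap=10000.0) == math.inf

    def test_zero_rate_censored(self):
        g = growth_from([(1e-9, 1.0), (70.0, 2.0)])
        assert half_life(0.0, 1.0, NO_POOL, g) == math.inf

    def test_growth_and_recycling_do_not_shift_the_cohort_clock(self):
        # dilution removes no heavy molecules and recycling only adds new
        # ones, so the labelled-cohort half-life depends on k alone
        pool = FreePoolModel("x", p0=0.9, lambda_free=0.1, chase_start=0.0)
        g = growth_from([(1.0, 1.0), (100.0, 50.0)])
        assert half_life(0.02, 0.987, pool, g) == pytest.approx(math.log(2) / 0.02)


class TestPeptide2Lys:
    def test_halving_every_ten_days(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        k = fit_2lys_peptide(t, 100.0 * 0.5 ** (t / 10.0))
        assert k == pytest.approx(math.log(2) / 10, rel=1e-9)

    def test_constant_intensity_zero_rate(self):
        k = fit_2lys_peptide([0.0, 7.0, 21.0], [50.0, 50.0, 50.0])
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_recovery_with_growth_dilution(self):
        g = growth_from([(1.0, 1.0), (50.0, 10.0), (100.0, 12.0)])
        k_true = 0.05
        t = np.array([1.0, 10.0, 30.0, 60.0, 90.0])
        # measured HH concentration = amount / total protein
        hh = np.exp(-k_true * (t - t[0])) * np.exp(
            g.log_total(t[0]) - g.log_total(t))
        k = fit_2lys_peptide(t, hh, growth=g)
        assert k == pytest.approx(k_true, rel=0.01)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_2lys_peptide([0.0, 10.0], [1.0, 0.5])


class TestModelSpec:
    def test_variant_filters(self):
        assert TurnoverModelSpec(variant="late_only_3w").min_age == 21.0
        assert TurnoverModelSpec(variant="late_only_6w").min_age == 42.0
        assert not TurnoverModelSpec(variant="no_recycling").recycling

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            TurnoverModelSpec(variant="bogus")
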