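import numpy as np
import pytest
from scipy.stats import kstest

from lyschase.preprocess import aggregate_technical
from lyschase.synthetic import (
    CohortConfig,
    generate_aging_abundance,
    generate_cohort,
    generate_longevity_profiles,
)
from lyschase.turnover import simulate_fraction


class TestReproducibility:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = CohortConfig(n_proteins=8)
        p1 = generate_cohort(cfg, seed=5).write(tmp_path / "a")
        p2 = generate_cohort(cfg, seed=5).write(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        cfg = CohortConfig(n_proteins=8)
        a = generate_cohort(cfg, seed=5)
        b = generate_cohort(cfg, seed=6)
        assert not a.quant.equals(b.quant)


class TestForwardModel:
    def test_noiseless_round_trip_matches_model_R(self):
        cfg = CohortConfig(n_proteins=5, k_values=(0.001, 0.01, 0.05, 0.2, 0.5),
                           noise_cv=0.0, detection_limit=0.0, volume_cv=0.0)
        sim = generate_cohort(cfg, seed=1)
        agg = aggregate_technical(sim.quant, n_tech=1)
        for design in ("chase_from_birth", "chase_from_weaning"):
            sub = agg[agg["design"] == design]
            for pid, k in zip(sim.truth.protein_id, sim.truth.true_k):
                rows = sub[sub.protein_id == pid].sort_values(["age_days", "bio_rep"])
                F = simulate_fraction(k, cfg.p_label, sim.pools[design],
                                      sim.growth_model, rows.age_days.to_numpy()).F
                np.testing.assert_allclose(rows.R.to_numpy(), -np.log(F), rtol=1e-9)

    def test_zero_rate_constant_growth_stays_at_label(self):
        cfg = CohortConfig(n_proteins=1, k_values=(0.0,), noise_cv=0.0,
                           detection_limit=0.0, volume_cv=0.0,
                           volume_max=0.1000001, volume_floor=0.1)
        sim = generate_cohort(cfg, seed=1)
        agg = aggregate_technical(sim.quant, n_tech=1)
        np.testing.assert_allclose(agg["F"].dropna(), cfg.p_label, atol=1e-6)

    def test_truth_traceability(self):
        cfg = CohortConfig(n_proteins=12)
        sim = generate_cohort(cfg, seed=2)
        assert set(sim.quant.protein_id) == set(sim.truth.protein_id)
        assert sim.truth.protein_id.is_unique


class TestMissingness:
    def test_monotone_in_detection_limit(self):
        base = dict(n_proteins=30)
        fracs = []
        for dl in (0.0, 1e4, 1e5):
            sim = generate_cohort(CohortConfig(**base, detection_limit=dl), seed=3)
            fracs.append(sim.quant.intensity.isna().mean())
        assert fracs[0] == 0.0
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > fracs[1]

    def test_intensities_nonnegative(self):
        sim = generate_cohort(CohortConfig(n_proteins=10), seed=4)
        assert (sim.quant.intensity.dropna() >= 0).all()
        assert (sim.two_lys[["hh", "hl", "ll"]] >= 0).all().all()


class TestRateMixture:
    def test_component_proportions_and_ranges(self):
        cfg = CohortConfig(n_proteins=600)
        sim = generate_cohort(cfg, seed=6)
        counts = sim.truth.true_cluster.value_counts(normalize=True)
        assert counts["low"] == pytest.approx(0.60, abs=0.07)
        assert counts["intermediate"] == pytest.approx(0.27, abs=0.07)
        assert counts["high"] == pytest.approx(0.13, abs=0.05)
        for name, (_, (lo, hi)) in zip(("high", "intermediate", "low"), cfg.k_mixture):
            ks = sim.truth.loc[sim.truth.true_cluster == name, "true_k"]
            assert ks.between(lo, hi).all()

    def test_log_uniform_within_component(self):
        cfg = CohortConfig(n_proteins=800)
        sim = generate_cohort(cfg, seed=7)
        _, (lo, hi) = cfg.k_mixture[2]
        ks = sim.truth.loc[sim.truth.true_cluster == "low", "true_k"]
        stat = kstest(np.log(ks), "uniform", args=(np.log(lo), np.log(hi) - np.log(lo)))
        assert stat.pvalue > 0.01


class TestArchetypeGenerators:
    def test_longevity_profiles_shapes_and_truth(self):
        mat, truth = generate_longevity_profiles(n_per_archetype=7, seed=1)
        assert mat.shape == (21, 6)
        assert truth.archetype.value_counts().eq(7).all()
        assert ((mat.values >= 0) & (mat.values <= 100)).all()

    def test_zero_noise_aging_profiles_hit_archetypes(self):
        tab, truth = generate_aging_abundance(n_per_archetype=2, noise_cv=0.0, seed=1)
        wide = tab.groupby(["protein_id", "age_days"])["rel_abundance"].mean().unstack()
        ups = truth.loc[truth.archetype == "up", "protein_id"]
        profile = wide.loc[ups.iloc[0]].to_numpy()
        assert profile[0] < profile[1] < profile[2]

    def test_per_archetype_counts(self):
        tab, truth = generate_aging_abundance(n_per_archetype=4, seed=1)
        assert truth.archetype.value_counts().eq(4).all()
        assert len(tab) == len(truth) * 3 * 3
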