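"""Synthetic pulse-chase cohorts with known ground truth.

Emulates the deposited study design: a chase-from-birth arm sampled at 11
timepoints (24 h to 65 weeks) and a chase-from-weaning arm sampled at 6
timepoints (6 to 65 weeks), three biological replicates each, optional
technical quadruplicates, ~98.7% initial labelling, lognormal intensity
noise and a hard detection limit that produces intensity-dependent
missingness.  Degradation rates are drawn from a three-component
log-uniform mixture whose weights follow the observed longevity cluster
proportions; organ volume rises ~200-fold from birth and plateaus.  Every
emitted record traces back to a ground-truth row, and all outputs are
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lyschase.free_pool import FreePoolModel
from lyschase.growth import GrowthModel
from lyschase.turnover import half_life, simulate_fraction

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_aging_abundance",
    "generate_longevity_profiles",
]

BIRTH, WEANING = "chase_from_birth", "chase_from_weaning"

#: chase sampling ages in days (24 h, 48 h, 1, 2, 3, 6, 9, 12, 30, 50, 65 wk)
TIMEPOINTS_BIRTH = (1.0, 2.0, 7.0, 14.0, 21.0, 42.0, 63.0, 84.0, 210.0, 350.0, 455.0)
#: weaning-arm sampling ages (6, 9, 12, 30, 50, 65 wk)
TIMEPOINTS_WEANING = (42.0, 63.0, 84.0, 210.0, 350.0, 455.0)

CLUSTER_NAMES = ("high", "intermediate", "low")


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    The defaults are the deposited experiment's design: timepoint grids,
    three biological replicates, 98.7% labelling.  The rate mixture
    weights (0.13/0.27/0.60 slow/medium/fast) follow the observed
    longevity cluster proportions, with log-uniform rate ranges chosen to
    give half-lives of hundreds of days, ~1-3 weeks and ~2-10 days
    respectively.  The free pool decays with a ~4.6-day half-life (gone
    within 3-6 weeks) and the organ grows ~200-fold before plateauing.
    """

    n_proteins: int = 200
    k_mixture: tuple = (
        (0.13, (7e-4, 3e-3)),    # slow: extremely long-lived
        (0.27, (0.03, 0.09)),    # medium
        (0.60, (0.07, 0.35)),    # fast
    )
    k_values: tuple | None = None  # explicit rates override the mixture
    p_label: float = 0.987
    pool_lambda: float = 0.15          # per day, both designs
    weaning_day: float = 21.0
    timepoints_birth: tuple = TIMEPOINTS_BIRTH
    timepoints_weaning: tuple = TIMEPOINTS_WEANING
    n_bio: int = 3
    n_tech: int = 1
    noise_cv: float = 0.10             # lognormal CV of intensities
    detection_limit: float = 1e4
    log10_intensity_mean: float = 6.0  # per-protein MS1 scale
    log10_intensity_sd: float = 0.5
    two_lys_scale: float = 1e8         # summed proteome-wide 2Lys signal
    volume_floor: float = 0.1          # mm^3 at birth
    volume_max: float = 20.0           # plateau (~200-fold rise)
    volume_t50: float = 70.0           # days to half-plateau
    volume_hill: float = 2.0
    volume_cv: float = 0.05

    def volume_at(self, t):
        t = np.asarray(t, dtype=float)
        rise = (self.volume_max - self.volume_floor) * t**self.volume_hill / (
            t**self.volume_hill + self.volume_t50**self.volume_hill)
        return self.volume_floor + rise

    def pool(self, design: str) -> FreePoolModel:
        start = 0.0 if design == BIRTH else self.weaning_day
        return FreePoolModel(design=design, p0=self.p_label,
                             lambda_free=self.pool_lambda, chase_start=start,
                             p_label=self.p_label)

    def growth(self) -> GrowthModel:
        knots = np.unique(np.concatenate([
            [0.5], self.timepoints_birth, self.timepoints_weaning]))
        return GrowthModel(knots=knots, log_volume=np.log(self.volume_at(knots)))


@dataclass
class SyntheticCohort:
    quant: pd.DataFrame
    two_lys: pd.DataFrame
    abundance: pd.DataFrame
    volume: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig
    pools: dict = field(default_factory=dict)
    growth_model: GrowthModel | None = None

    def write(self, outdir) -> dict[str, Path]:
        """Write the TSV dialects the readers consume (plus the truth table)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for design in (BIRTH, WEANING):
            sub = self.quant[self.quant["design"] == design].drop(columns=["design"])
            p = outdir / f"quant_{design}.tsv"
            sub.to_csv(p, sep="\t", index=False, na_rep="")
            paths[f"quant_{design}"] = p
        for name, df in [("two_lys", self.two_lys), ("abundance", self.abundance),
                         ("volume", self.volume), ("truth", self.truth)]:
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False, na_rep="")
            paths[name] = p
        return paths


def _draw_rates(config: CohortConfig, rng: np.random.Generator):
    if config.k_values is not None:
        k = np.asarray(config.k_values, dtype=float)
        comp = np.full(k.size, -1)
        return k, comp
    weights = np.array([w for w, _ in config.k_mixture], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    comp = rng.choice(len(weights), size=config.n_proteins, p=weights)
    k = np.empty(config.n_proteins)
    for c, (_, (klo, khi)) in enumerate(config.k_mixture):
        if klo <= 0 or khi <= klo:
            raise ValueError("rate ranges must be positive and increasing")
        sel = comp == c
        k[sel] = np.exp(rng.uniform(np.log(klo), np.log(khi), size=sel.sum()))
    return k, comp


def _lognoise(rng, cv, size):
    sd = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sd**2, sd, size=size))


def generate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> SyntheticCohort:
    """Forward-simulate a full two-design pulse-chase cohort.

    Per protein and design the heavy fraction F(t) follows the turnover
    model with the configured pool and growth; emitted intensities are
    H = F * scale * noise and L = (1-F) * scale * noise per replicate,
    with values below the detection limit left missing.  2Lys species
    follow binomial proportions at the instantaneous pool heavy fraction.
    """
    rng = np.random.default_rng(seed)
    k, comp = _draw_rates(config, rng)
    P = len(k)
    ids = [f"P{i + 1:04d}" for i in range(P)]
    growth = config.growth()
    pools = {BIRTH: config.pool(BIRTH), WEANING: config.pool(WEANING)}
    scale = 10.0 ** rng.normal(config.log10_intensity_mean,
                               config.log10_intensity_sd, size=P)

    frames = []
    for design, times in ((BIRTH, config.timepoints_birth),
                          (WEANING, config.timepoints_weaning)):
        times = np.asarray(times, dtype=float)
        F = simulate_fraction(k, config.p_label, pools[design], growth, times).F  # (P, T)
        for channel, frac in (("H", F), ("L", 1.0 - F)):
            base = frac * scale[:, None]  # (P, T)
            for bio in range(1, config.n_bio + 1):
                for tech in range(1, config.n_tech + 1):
                    noise = _lognoise(rng, config.noise_cv, base.shape)
                    inten = base * noise
                    inten = np.where(inten >= config.detection_limit, inten, np.nan)
                    frames.append(pd.DataFrame({
                        "protein_id": np.repeat(ids, times.size),
                        "gene_symbol": np.repeat(ids, times.size),
                        "design": design,
                        "age_days": np.tile(times, P),
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "channel": channel,
                        "intensity": inten.ravel(),
                    }))
    quant = pd.concat(frames, ignore_index=True).sort_values(
        ["design", "protein_id", "age_days", "bio_rep", "tech_rep", "channel"],
        kind="mergesort", ignore_index=True)

    # 2Lys species (pooled over the proteome) at each sampling age
    rows = []
    for design, times in ((BIRTH, config.timepoints_birth),
                          (WEANING, config.timepoints_weaning)):
        pool = pools[design]
        for t in times:
            p = float(pool(t))
            for rep in range(1, config.n_bio + 1):
                eps = _lognoise(rng, config.noise_cv, 3)
                vals = config.two_lys_scale * np.array(
                    [p**2, 2 * p * (1 - p), (1 - p) ** 2]) * eps
                vals = np.where(vals >= config.detection_limit, vals, 0.0)
                rows.append({"design": design, "age_days": t, "rep": rep,
                             "hh": vals[0], "hl": vals[1], "ll": vals[2]})
    two_lys = pd.DataFrame(rows)

    # DIA relative abundance (constant concentration by default)
    rows = []
    for t in config.timepoints_birth:
        for rep in range(1, config.n_bio + 1):
            rows.append(pd.DataFrame({
                "protein_id": ids,
                "age_days": t,
                "rep": rep,
                "rel_abundance": _lognoise(rng, config.noise_cv, P),
            }))
    abundance = pd.concat(rows, ignore_index=True)

    # volume measurements (l*w*h boxes around the true curve)
    rows = []
    ages = np.unique(np.concatenate([[0.5], config.timepoints_birth]))
    for t in ages:
        v_true = float(config.volume_at(t))
        for _rep in range(3):
            v = v_true * float(_lognoise(rng, config.volume_cv, 1)[0])
            edge = v ** (1.0 / 3.0)
            rows.append({"age_days": t, "method": "lwh",
                         "l": edge, "w": edge, "h": edge, "volume": edge**3})
    volume = pd.DataFrame(rows)

    cap = 10000.0
    hl_true = np.array([
        half_life(ki, config.p_label, pools[BIRTH], growth, cap=cap) for ki in k])
    truth = pd.DataFrame({
        "protein_id": ids,
        "true_k": k,
        "true_halflife": np.where(np.isfinite(hl_true), hl_true, np.inf),
        "true_cluster": [CLUSTER_NAMES[c] if c >= 0 else "" for c in comp],
        "expressed_from": 0.0,
        "intensity_scale": scale,
    })
    return SyntheticCohort(quant=quant, two_lys=two_lys, abundance=abundance,
                           volume=volume, truth=truth, config=config,
                           pools=pools, growth_model=growth)


# --- planted-archetype generators for clustering recovery -----------------

AGING_AGES = (63.0, 84.0, 350.0)  # 9, 12, 50 weeks

#: mean log-abundance profiles over (9, 12, 50) weeks
AGING_ARCHETYPES = {
    "up": (0.0, 0.6, 1.4),
    "down": (1.4, 0.8, 0.0),
    "late_drop": (1.0, 1.0, -0.4),
    "late_rise": (-0.2, -0.2, 1.2),
    "mid_peak": (0.0, 1.2, 0.0),
    "mid_dip": (1.0, -0.2, 1.0),
}


def generate_aging_abundance(n_per_archetype: int = 50, noise_cv: float = 0.10,
                             n_reps: int = 3, seed: int = 0):
    """DIA abundance table at 9/12/50 weeks with six planted trend archetypes.

    Returns ``(table, truth)`` where truth maps protein_id to its
    archetype.  Archetypes are separable after per-protein z-scoring; a
    strictly flat profile would be annihilated by that very z-scoring, so
    all six planted trends are non-degenerate.
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    i = 0
    for name, profile in AGING_ARCHETYPES.items():
        base = np.exp(np.asarray(profile))
        for _ in range(n_per_archetype):
            i += 1
            pid = f"A{i:04d}"
            truth_rows.append({"protein_id": pid, "archetype": name})
            for age, mu in zip(AGING_AGES, base):
                for rep in range(1, n_reps + 1):
                    rows.append({
                        "protein_id": pid, "age_days": age, "rep": rep,
                        "rel_abundance": mu * float(_lognoise(rng, noise_cv, 1)[0]),
                    })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


#: %heavy retention archetypes on the >=6-week grid: high ~90%, mid ~40%, low ~5%
LONGEVITY_ARCHETYPES = {
    "high": (95.0, 93.0, 91.0, 88.0, 86.0, 85.0),
    "intermediate": (55.0, 50.0, 43.0, 35.0, 30.0, 26.0),
    "low": (12.0, 9.0, 7.0, 4.0, 2.0, 1.0),
}


def generate_longevity_profiles(n_per_archetype: int = 50, noise_sd: float = 3.0,
                                seed: int = 0):
    """Modelled %heavy trajectory matrix with three planted longevity archetypes."""
    rng = np.random.default_rng(seed)
    ages = np.asarray(TIMEPOINTS_WEANING)
    rows, labels, index = [], [], []
    i = 0
    for name, profile in LONGEVITY_ARCHETYPES.items():
        for _ in range(n_per_archetype):
            i += 1
            rows.append(np.clip(np.asarray(profile) +
                                rng.normal(0, noise_sd, size=len(profile)), 0, 100))
            labels.append(name)
            index.append(f"L{i:04d}")
    matrix = pd.DataFrame(np.asarray(rows), index=index, columns=[float(a) for a in ages])
    truth = pd.DataFrame({"protein_id": index, "archetype": labels})
    return matrix, truth
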