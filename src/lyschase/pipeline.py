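"""End-to-end orchestration: tables in, fits/clusters/atlas out.

Thin glue over the library modules, shared by the command-line interface
and by reproducibility checks.  All randomness flows from one root seed,
split per stage, so a rerun with the same inputs and seed is
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lyschase import io as lio
from lyschase.clustering import longevity_cluster
from lyschase.free_pool import P_LABEL_DEFAULT, FreePoolModel, fit_pool_decay
from lyschase.growth import GrowthModel, fit_growth_curve
from lyschase.inference import (
    BIRTH,
    WEANING,
    FitConfig,
    fit_cohort,
    fits_to_frame,
    percent_heavy_matrix,
)
from lyschase.preprocess import aggregate_technical, flag_rapid_degraders
from lyschase.turnover import TurnoverModelSpec

log = logging.getLogger("lyschase")

__all__ = ["RunConfig", "run_pipeline", "fit_pools"]

CHASE_STARTS = {BIRTH: 0.0, WEANING: 21.0}


@dataclass
class RunConfig:
    """Validated run settings, echoed into the output directory."""

    outdir: str = "lyschase_out"
    seed: int = 0
    # simulate stage (used when no input paths are given)
    simulate: bool = True
    n_proteins: int = 200
    n_tech: int = 1
    # input paths (used when simulate is False)
    quant_birth: str | None = None
    quant_weaning: str | None = None
    two_lys: str | None = None
    abundance: str | None = None
    volume: str | None = None
    # model / inference
    variant: str = "full"
    halflife_cap_days: float = 10000.0
    n_chains: int = 4
    n_warmup: int = 400
    n_draws: int = 500
    p_label: float = P_LABEL_DEFAULT
    detection_limit: float | None = None
    include_censored: bool = True
    n_tech_rule: int = 4
    rapid_cutoff_age: float = 42.0
    # clustering
    k_longevity: int = 3

    def validate(self) -> None:
        if not self.simulate:
            if self.quant_birth is None and self.quant_weaning is None:
                raise ValueError("need at least one quantification table")
            for name in ("quant_birth", "quant_weaning", "two_lys", "abundance", "volume"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
        if self.variant not in ("full", "no_recycling", "late_only_3w", "late_only_6w"):
            raise ValueError(f"variant {self.variant!r} not runnable end-to-end")
        if self.n_chains < 2 or self.n_draws < 10:
            raise ValueError("need >=2 chains and >=10 draws")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def fit_pools(two_lys: pd.DataFrame | None, p_label: float = P_LABEL_DEFAULT,
              pool_lambda_fallback: float = 0.15) -> dict[str, FreePoolModel]:
    """Fit one free-pool model per design from pooled 2Lys species.

    The pool decay is a property of the animal's lysine metabolism, not of
    the pulse design, so both designs are fitted jointly on time since
    their own chase start (the weaning arm starts sampling after the pool
    has largely emptied and rarely supports a fit on its own).  With no
    usable 2Lys data, a default decay is used and logged.
    """
    donor = None
    if two_lys is not None and len(two_lys):
        frames = []
        for design, start in CHASE_STARTS.items():
            sub = (two_lys[two_lys["design"] == design]
                   if "design" in two_lys.columns else two_lys)
            sub = sub[sub["age_days"] >= start]
            if len(sub):
                frames.append(sub.assign(age_days=sub["age_days"] - start))
            if "design" not in two_lys.columns:
                break
        joint = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        usable = joint[(joint.get("hh", pd.Series(dtype=float)) > 0)] if len(joint) else joint
        if len(usable) and usable["age_days"].nunique() >= 2:
            donor = fit_pool_decay(joint, chase_start=0.0, p_label=p_label)
    out = {}
    for design, start in CHASE_STARTS.items():
        if donor is not None:
            out[design] = FreePoolModel(design=design, p0=donor.p0,
                                        lambda_free=donor.lambda_free,
                                        chase_start=start, p_label=p_label,
                                        lambda_se=donor.lambda_se,
                                        logp0_se=donor.logp0_se,
                                        lam_logp0_corr=donor.lam_logp0_corr)
        else:
            log.warning("no usable 2Lys data; using default pool decay")
            out[design] = FreePoolModel(design=design, p0=p_label,
                                        lambda_free=pool_lambda_fallback,
                                        chase_start=start, p_label=p_label)
    return out


def _load_or_simulate(cfg: RunConfig):
    if cfg.simulate:
        from lyschase.synthetic import CohortConfig, generate_cohort

        sim = generate_cohort(
            CohortConfig(n_proteins=cfg.n_proteins, n_tech=cfg.n_tech), seed=cfg.seed)
        if cfg.detection_limit is None:
            cfg.detection_limit = sim.config.detection_limit
        return sim.quant, sim.two_lys, sim.abundance, sim.volume, sim.truth
    frames = []
    if cfg.quant_birth:
        frames.append(lio.read_quant_table(cfg.quant_birth, design=BIRTH))
    if cfg.quant_weaning:
        frames.append(lio.read_quant_table(cfg.quant_weaning, design=WEANING))
    quant = pd.concat(frames, ignore_index=True)
    two_lys = lio.read_2lys_table(cfg.two_lys) if cfg.two_lys else None
    abundance = lio.read_abundance_table(cfg.abundance) if cfg.abundance else None
    volume = lio.read_volume_table(cfg.volume) if cfg.volume else None
    return quant, two_lys, abundance, volume, None


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Simulate-or-load, preprocess, fit, cluster and write the atlas."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    quant, two_lys, abundance, volume, truth = _load_or_simulate(cfg)
    cfg.to_yaml(outdir / "config.yaml")

    n_tech_present = int(quant.groupby(
        ["protein_id", "design", "age_days", "bio_rep", "channel"])["tech_rep"]
        .count().max())
    rule_n = min(cfg.n_tech_rule, n_tech_present)
    agg = aggregate_technical(quant, n_tech=rule_n)
    records_by_design = {d: quant[quant["design"] == d] for d in quant["design"].unique()}
    rapid = flag_rapid_degraders(records_by_design, cutoff_age=cfg.rapid_cutoff_age,
                                 n_tech=rule_n)
    log.info("loaded %d proteins; %d flagged as rapid degraders",
             quant["protein_id"].nunique(), len(rapid))

    pools = fit_pools(two_lys, p_label=cfg.p_label)
    if volume is not None:
        growth = fit_growth_curve(volume, abundance)
    else:
        growth = GrowthModel.constant()

    spec = TurnoverModelSpec(variant=cfg.variant, halflife_cap_days=cfg.halflife_cap_days)
    fit_cfg = FitConfig(model=spec, n_chains=cfg.n_chains, n_warmup=cfg.n_warmup,
                        n_draws=cfg.n_draws, p_label=cfg.p_label,
                        include_censored=cfg.include_censored,
                        detection_limit=cfg.detection_limit)
    fits = fit_cohort(agg, pools, growth, config=fit_cfg, seed=cfg.seed, exclude=rapid)
    frame = fits_to_frame(fits)
    n_ok = int((frame["status"] == "ok").sum())
    log.info("fitted %d proteins (%d ok, %d skipped, %d censored)",
             len(fits), n_ok, int((frame["status"] == "skipped_too_few_points").sum()),
             int(frame["censored"].sum()))
    frame.to_csv(outdir / "fits.tsv", sep="\t", index=False)

    grid = np.asarray(sorted(a for a in agg["age_days"].unique() if a >= 42.0))
    if grid.size == 0:
        grid = np.array([42.0])
    ph = percent_heavy_matrix(fits, pools, growth, grid, config=fit_cfg)
    ph.to_csv(outdir / "percent_heavy.tsv", sep="\t", index_label="protein_id")
    clusters = {}
    if len(ph) >= cfg.k_longevity:
        cl = longevity_cluster(ph, k=cfg.k_longevity)
        cl.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        clusters = dict(zip(cl["protein_id"], cl["label"]))

    with open(outdir / "pools.yaml", "w") as fh:
        yaml.safe_dump({d: p.to_dict() for d, p in pools.items()}, fh, sort_keys=True)
    with open(outdir / "growth.yaml", "w") as fh:
        yaml.safe_dump(growth.to_dict(), fh, sort_keys=True)
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    usable = {f.protein_id: f for f in fits if f.status in ("ok", "low_ess")}
    f_model_rows = []
    for design, sub in agg.groupby("design"):
        ages = np.sort(sub["age_days"].unique())
        pool = pools[design]
        from lyschase.turnover import simulate_fraction
        from lyschase.free_pool import FreePoolModel as _FP

        pool_eff = pool if spec.recycling else _FP.zero(design, pool.chase_start)
        for pid, fit in usable.items():
            F = simulate_fraction(fit.k_median, cfg.p_label, pool_eff, growth, ages,
                                  protein_id=pid).F
            f_model_rows.append(pd.DataFrame({
                "protein_id": pid, "design": design, "age_days": ages, "F_model": F}))
    f_model = (pd.concat(f_model_rows, ignore_index=True)
               if f_model_rows else None)
    atlas_path = outdir / "atlas.tsv"
    lio.write_atlas(usable, clusters, agg, atlas_path, f_model=f_model,
                    cap=cfg.halflife_cap_days)
    log.info("atlas written to %s", atlas_path)
    return {"outdir": outdir, "atlas": atlas_path, "fits": outdir / "fits.tsv"}
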