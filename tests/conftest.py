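"""Shared fixtures: small crafted tables and one session-scoped recovery cohort."""

import numpy as np
import pandas as pd
import pytest

from lyschase.growth import fit_growth_curve
from lyschase.inference import FitConfig, fit_cohort, fits_to_frame
from lyschase.pipeline import fit_pools
from lyschase.preprocess import aggregate_technical
from lyschase.synthetic import CohortConfig, generate_cohort
from lyschase.turnover import TurnoverModelSpec

BIRTH, WEANING = "chase_from_birth", "chase_from_weaning"


def quant_frame(rows):
    """Build a quant records frame from (pid, design, age, bio, tech, channel, val)."""
    df = pd.DataFrame(rows, columns=["protein_id", "design", "age_days", "bio_rep",
                                     "tech_rep", "channel", "intensity"])
    df["gene_symbol"] = df["protein_id"]
    return df


@pytest.fixture(scope="session")
def recovery_cohort():
    """The parameter-recovery study: 200 proteins, log-spaced rates
    0.002-0.7/day, both pulse designs, 3 biological replicates, 10% CV
    lognormal noise, recycling and growth on."""
    cfg = CohortConfig(
        n_proteins=200,
        k_values=tuple(np.logspace(np.log10(0.002), np.log10(0.7), 200)),
    )
    sim = generate_cohort(cfg, seed=2024)
    agg = aggregate_technical(sim.quant, n_tech=1)
    pools = fit_pools(sim.two_lys)
    growth = fit_growth_curve(sim.volume, sim.abundance)
    return {"sim": sim, "agg": agg, "pools": pools, "growth": growth, "config": cfg}


@pytest.fixture(scope="session")
def recovery_fits(recovery_cohort):
    rc = recovery_cohort
    fits = fit_cohort(rc["agg"], rc["pools"], rc["growth"],
                      FitConfig(detection_limit=rc["config"].detection_limit), seed=7)
    return fits


@pytest.fixture(scope="session")
def recovery_fits_no_recycling(recovery_cohort):
    rc = recovery_cohort
    cfg = FitConfig(model=TurnoverModelSpec(variant="no_recycling"),
                    detection_limit=rc["config"].detection_limit)
    return fit_cohort(rc["agg"], rc["pools"], rc["growth"], cfg, seed=7)


@pytest.fixture(scope="session")
def recovery_frame(recovery_fits, recovery_cohort):
    fr = fits_to_frame(recovery_fits)
    fr = fr[fr["status"].isin(["ok", "low_ess"])].set_index("protein_id")
    truth = recovery_cohort["sim"].truth.set_index("protein_id")
    return fr.join(truth)
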