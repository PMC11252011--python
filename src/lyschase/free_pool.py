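"""Free heavy-lysine pool estimation from 2Lys missed-cleavage peptides.

A tryptic peptide with one missed cleavage carries two lysines.  If the
free lysine pool has heavy fraction p at synthesis time, newly made 2Lys
peptides are HH, HL and LL in binomial proportions (p^2, 2p(1-p), (1-p)^2).
The estimator ``p = 2*HH / (2*HH + HL)`` inverts these proportions using
only the heavy-containing species: pre-pulse (old) peptides are almost
exclusively LL, so including LL would mix old protein into the pool
estimate, while pure-HH peptides are very unlikely to arise except from a
heavy pool.  The pool itself is modelled as a single exponential decay
after the chase starts and as the labelling plateau before it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "P_LABEL_DEFAULT",
    "FreePoolModel",
    "species_proportions",
    "estimate_p_from_species",
    "fit_pool_decay",
]

#: Heavy fraction of the labelled proteome at the end of the pulse
#: (measured parental labelling efficiency).
P_LABEL_DEFAULT = 0.987


@dataclass(frozen=True)
class FreePoolModel:
    """Free heavy-lysine fraction p(t) for one pulse design.

    p(t) = p_label for t < chase_start, and
    p(t) = p0 * exp(-lambda_free * (t - chase_start)) afterwards.
    A ``lambda_free`` of +inf marks an exhausted pool (p = 0 in the chase).
    """

    design: str
    p0: float
    lambda_free: float
    chase_start: float
    p_label: float = P_LABEL_DEFAULT
    # regression uncertainty of the fit (0 = treat as exactly known);
    # downstream inference marginalizes over these
    lambda_se: float = 0.0
    logp0_se: float = 0.0
    lam_logp0_corr: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if self.lambda_free < 0:
            raise ValueError("lambda_free must be >= 0")

    @classmethod
    def zero(cls, design: str = "", chase_start: float = 0.0) -> "FreePoolModel":
        """A pool that is always empty (the no-recycling limit, k_on = 0)."""
        return cls(design=design, p0=0.0, lambda_free=0.0, chase_start=chase_start, p_label=0.0)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if math.isinf(self.lambda_free):
            chase = np.zeros_like(t)
        else:
            chase = self.p0 * np.exp(-self.lambda_free * np.maximum(t - self.chase_start, 0.0))
        out = np.where(t < self.chase_start, self.p_label, chase)
        return float(out) if out.ndim == 0 else out

    def to_dict(self):
        return {
            "design": self.design,
            "p0": float(self.p0),
            "lambda_free": float(self.lambda_free),
            "chase_start": float(self.chase_start),
            "p_label": float(self.p_label),
        }


def species_proportions(p):
    """Expected (HH, HL, LL) fractions of newly synthesized 2Lys peptides."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must be in [0, 1]")
    hh = p**2
    hl = 2 * p * (1 - p)
    ll = (1 - p) ** 2
    if hh.ndim == 0:
        return float(hh), float(hl), float(ll)
    return hh, hl, ll


def estimate_p_from_species(hh, hl):
    """Invert the binomial species proportions: p = 2HH / (2HH + HL).

    Uses only heavy-containing species so that pre-existing (pre-pulse) LL
    peptide signal does not bias the estimate.
    """
    hh = np.asarray(hh, dtype=float)
    hl = np.asarray(hl, dtype=float)
    if np.any(hh < 0) or np.any(hl < 0):
        raise ValueError("species intensities must be nonnegative")
    denom = 2 * hh + hl
    if np.any(denom == 0):
        raise ValueError("p is undefined when HH and HL are both zero")
    out = 2 * hh / denom
    return float(out) if out.ndim == 0 else out


def fit_pool_decay(
    two_lys_records: pd.DataFrame,
    chase_start: float,
    p_label: float = P_LABEL_DEFAULT,
    design: str = "",
) -> FreePoolModel:
    """Fit the single-exponential pool decay to 2Lys species intensities.

    Ordinary least squares of log p-hat against time since chase start,
    with the decay rate constrained to be >= 0 and p0 <= 1.  Records at or
    before the chase start and records with p-hat = 0 are excluded from the
    regression; if every usable record has p-hat = 0 the pool is declared
    exhausted (``lambda_free = inf``).
    """
    rec = two_lys_records
    if design:
        if "design" in rec.columns:
            rec = rec[rec["design"] == design]
    rec = rec[(rec["hh"] + rec["hl"]) > 0]
    rec = rec[rec["age_days"].to_numpy(dtype=float) >= chase_start]
    if len(rec) == 0:
        raise ValueError("no usable 2Lys records in the chase period")
    p_hat = estimate_p_from_species(rec["hh"].to_numpy(float), rec["hl"].to_numpy(float))
    p_hat = np.atleast_1d(p_hat)
    t = rec["age_days"].to_numpy(dtype=float) - chase_start
    pos = p_hat > 0
    if not np.any(pos):
        return FreePoolModel(
            design=design, p0=0.0, lambda_free=math.inf, chase_start=chase_start, p_label=p_label
        )
    t, logp = t[pos], np.log(p_hat[pos])
    if t.size < 2 or np.allclose(t, t[0]):
        raise ValueError("need 2Lys records at >=2 distinct chase timepoints")
    lam_se = p0_se = corr = 0.0
    if t.size >= 3:
        coef, cov = np.polyfit(t, logp, 1, cov=True)
        slope, intercept = coef
        lam_se = float(np.sqrt(cov[0, 0]))
        p0_se = float(np.sqrt(cov[1, 1]))
        denom = lam_se * p0_se
        # slope enters as -lambda, flipping the correlation sign
        corr = float(-cov[0, 1] / denom) if denom > 0 else 0.0
    else:
        slope, intercept = np.polyfit(t, logp, 1)
    if slope > 0:  # pool cannot refill with heavy lysine during the chase
        lam, p0 = 0.0, float(np.exp(np.mean(logp)))
    else:
        lam, p0 = float(-slope), float(np.exp(intercept))
    return FreePoolModel(
        design=design,
        p0=min(p0, 1.0),
        lambda_free=lam,
        chase_start=chase_start,
        p_label=p_label,
        lambda_se=lam_se,
        logp0_se=p0_se,
        lam_logp0_corr=corr,
    )
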