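"""Organ growth and protein abundance trajectories.

Total protein amount for protein *i* is modelled as
``P_i(t) = V(t) * c_i(t)`` where ``V`` is organ volume and ``c_i`` the
relative protein concentration (from DIA-MS).  Both are interpolated
log-linearly between measured timepoints, so the relative growth rate
``g_i(t) = d/dt [log V(t) + log c_i(t)]`` is piecewise constant and the
turnover ODE integrates exactly on each segment.  Beyond the measured age
range the trajectory is held constant (g = 0) by default; growth has
plateaued at late ages and half-life extrapolation needs an evaluable
model out to the censoring cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthModel",
    "sphere_volume",
    "box_volume",
    "fit_growth_curve",
    "dilution_factor",
]


def sphere_volume(r):
    """Volume of a sphere of radius ``r``: 4/3 * pi * r**3 (used for oocytes)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    out = 4.0 / 3.0 * math.pi * r**3
    return float(out) if out.ndim == 0 else out


def box_volume(length, width, height):
    """Volume of a box l*w*h (used for whole ovaries)."""
    dims = np.broadcast_arrays(
        np.asarray(length, float), np.asarray(width, float), np.asarray(height, float)
    )
    if any(np.any(d <= 0) for d in dims):
        raise ValueError("all dimensions must be positive")
    out = dims[0] * dims[1] * dims[2]
    return float(out) if out.ndim == 0 else out


@dataclass
class GrowthModel:
    """Piecewise log-linear total-protein trajectory.

    Parameters
    ----------
    knots : ndarray
        Strictly increasing ages (days) with volume measurements.
    log_volume : ndarray
        Mean log volume at each knot.
    log_conc : dict
        Optional per-protein ``protein_id -> (ages, log c_i)`` concentration
        profiles, interpolated like the volume.  Proteins absent from the
        dict have ``log c_i = 0`` (constant concentration).
    extrapolation : str
        ``"hold"`` (default) keeps V and c constant outside the knot range;
        ``"error"`` raises instead.
    """

    knots: np.ndarray
    log_volume: np.ndarray
    log_conc: dict = field(default_factory=dict)
    extrapolation: str = "hold"
    borrowed: dict = field(default_factory=dict)
    #: standard error of the fitted total log growth amplitude
    #: (0 = treat the growth curve as exactly known)
    amplitude_se: float = 0.0

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        self.log_volume = np.asarray(self.log_volume, dtype=float)
        if self.knots.size != self.log_volume.size:
            raise ValueError("knots and log_volume must have equal length")
        if self.knots.size < 1:
            raise ValueError("at least one knot required")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.extrapolation not in ("hold", "error"):
            raise ValueError(f"unknown extrapolation policy {self.extrapolation!r}")

    @classmethod
    def constant(cls):
        """A degenerate model with V == 1 everywhere (no growth, g = 0)."""
        return cls(knots=np.array([0.0, 1.0]), log_volume=np.array([0.0, 0.0]))

    def _check_range(self, t):
        if self.extrapolation == "error":
            t = np.asarray(t, float)
            if np.any(t < self.knots[0]) or np.any(t > self.knots[-1]):
                raise ValueError(
                    f"age outside measured range [{self.knots[0]}, {self.knots[-1]}] "
                    "and extrapolation policy is 'error'"
                )

    def log_volume_at(self, t):
        self._check_range(t)
        return np.interp(np.asarray(t, float), self.knots, self.log_volume)

    def volume(self, t):
        out = np.exp(self.log_volume_at(t))
        return float(out) if out.ndim == 0 else out

    def log_conc_at(self, t, protein_id=None):
        t = np.asarray(t, float)
        if protein_id is None or protein_id not in self.log_conc:
            return np.zeros_like(t)
        ages, logc = self.log_conc[protein_id]
        return np.interp(t, ages, logc)

    def log_total(self, t, protein_id=None):
        """log P_i(t) = log V(t) + log c_i(t)."""
        return self.log_volume_at(t) + self.log_conc_at(t, protein_id)

    def all_knots(self, protein_id=None):
        """Union of volume and concentration knots (segment boundaries)."""
        pts = [self.knots]
        if protein_id is not None and protein_id in self.log_conc:
            pts.append(np.asarray(self.log_conc[protein_id][0], float))
        return np.unique(np.concatenate(pts))

    def growth_rate(self, t, protein_id=None, eps=1e-7):
        """Relative growth rate g_i(t) (per day), right-sided at knots."""
        t = np.asarray(t, float)
        lo = self.log_total(t, protein_id)
        hi = self.log_total(t + eps, protein_id)
        out = (hi - lo) / eps
        return float(out) if out.ndim == 0 else out

    def dilution_factor(self, t0, t1, protein_id=None):
        """P(t0)/P(t1): the fraction of old protein remaining per unit made at t0."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        return float(np.exp(self.log_total(t0, protein_id) - self.log_total(t1, protein_id)))

    def to_dict(self):
        return {
            "knots": [float(x) for x in self.knots],
            "log_volume": [float(x) for x in self.log_volume],
            "extrapolation": self.extrapolation,
            "n_proteins_with_conc": len(self.log_conc),
        }


def dilution_factor(model: GrowthModel, t0, t1, protein_id=None):
    """Module-level convenience wrapper around :meth:`GrowthModel.dilution_factor`."""
    return model.dilution_factor(t0, t1, protein_id=protein_id)


def fit_growth_curve(
    volume_records: pd.DataFrame,
    abundance_records: pd.DataFrame | None = None,
    extrapolation: str = "hold",
) -> GrowthModel:
    """Build a :class:`GrowthModel` from volume (and optional DIA abundance) tables.

    Replicate volumes at the same age are averaged in log space, giving a
    model that reproduces the geometric knot means exactly.  Per-protein
    concentrations are interpolated the same way on their own age grid;
    a protein with a zero/missing abundance at a knot borrows the nearest
    observed knot (recorded in ``model.borrowed``).
    """
    vol = volume_records
    if np.any(vol["volume"].to_numpy(dtype=float) <= 0):
        raise ValueError("volumes must be positive")
    by_age = vol.groupby("age_days")["volume"].apply(lambda v: np.mean(np.log(v)))
    if len(by_age) < 2:
        raise ValueError("need volume measurements at >=2 distinct ages")
    knots = by_age.index.to_numpy(dtype=float)
    order = np.argsort(knots)
    # uncertainty of the first->last log-amplitude, from replicate scatter
    se_by_age = vol.groupby("age_days")["volume"].apply(
        lambda v: np.std(np.log(v), ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
    se = se_by_age.to_numpy(dtype=float)[order]
    amp_se = float(np.sqrt(se[0] ** 2 + se[-1] ** 2))
    model = GrowthModel(
        knots=knots[order],
        log_volume=by_age.to_numpy(dtype=float)[order],
        extrapolation=extrapolation,
        amplitude_se=amp_se,
    )
    if abundance_records is not None and len(abundance_records):
        _attach_concentrations(model, abundance_records)
    return model


def _attach_concentrations(model: GrowthModel, abundance: pd.DataFrame) -> None:
    ages_all = np.sort(abundance["age_days"].unique()).astype(float)
    for pid, sub in abundance.groupby("protein_id", sort=True):
        pos = sub[sub["rel_abundance"] > 0]
        if pos.empty:
            continue
        by_age = pos.groupby("age_days")["rel_abundance"].apply(lambda v: np.mean(np.log(v)))
        obs_ages = by_age.index.to_numpy(dtype=float)
        logc = np.empty_like(ages_all)
        missing = []
        for i, a in enumerate(ages_all):
            j = int(np.argmin(np.abs(obs_ages - a)))
            if obs_ages[j] != a:
                missing.append(float(a))
            logc[i] = by_age.iloc[j]
        model.log_conc[str(pid)] = (ages_all.copy(), logc)
        if missing:
            model.borrowed[str(pid)] = missing
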