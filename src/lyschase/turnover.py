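"""Forward model of heavy-fraction dynamics during the chase.

Amount dynamics for one protein: total amount P(t) = V(t) c(t) follows the
growth model, heavy amount H obeys dH/dt = s(t) p(t) - k H, where k is the
degradation rate, p(t) the free heavy-lysine pool and s(t) = P'(t) + k P(t)
the synthesis flux required to realize P(t) under degradation k.  The
heavy *fraction* F = H/P therefore obeys

    dF/dt = (g(t) + k) (p(t) - F),        g(t) = d log P / dt,

which is the fitted observable through R = -ln F = ln(L/H + 1).  The
heavy synthesis flux s(t) p(t) is the recycling ("k_on") term: the higher
the remaining free heavy lysine, the more heavy protein is still being
made during the chase.  When the total amount shrinks faster than
degradation alone would allow (g + k < 0) the implied synthesis flux would
be negative, which is unphysical; the flux is clamped at zero there and
dF/dt = -(k + g) F.

Because g is piecewise constant (log-linear growth interpolation) and p is
piecewise exponential, the ODE has a closed-form solution on every
segment, so trajectories are exact up to floating point -- no numerical
integrator is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from lyschase.free_pool import FreePoolModel
from lyschase.growth import GrowthModel

__all__ = [
    "VARIANTS",
    "TurnoverModelSpec",
    "Trajectory",
    "simulate_fraction",
    "model_R",
    "half_life",
    "fit_2lys_peptide",
    "propagate_segments",
    "build_segments",
]

VARIANTS = ("full", "no_recycling", "late_only_3w", "late_only_6w", "peptide_2lys")

#: Minimum chase age (days) retained by the late-timepoint variants.
LATE_CUTOFF = {"late_only_3w": 21.0, "late_only_6w": 42.0}


@dataclass(frozen=True)
class TurnoverModelSpec:
    """Which model variant to fit and how half-lives are extracted.

    variant:
        "full" -- recycling + growth + abundance change;
        "no_recycling" -- free pool forced to zero (k_on = 0);
        "late_only_3w"/"late_only_6w" -- pool forced to zero and data
        restricted to chase ages >= 3 or 6 weeks, where the pool is
        depleted and growth has slowed;
        "peptide_2lys" -- decay of pure-HH 2Lys peptide intensities.
    f0_policy:
        "fixed_to_label" fixes the heavy fraction at chase start to the
        labelling plateau; "free_parameter" samples it (used for the
        chase-from-weaning design whose pulse phase is not modelled).
    """

    variant: str = "full"
    f0_policy: str = "fixed_to_label"
    halflife_cap_days: float = 10000.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.f0_policy not in ("fixed_to_label", "free_parameter"):
            raise ValueError(f"unknown F0 policy {self.f0_policy!r}")

    @property
    def recycling(self) -> bool:
        return self.variant == "full"

    @property
    def min_age(self) -> float:
        return LATE_CUTOFF.get(self.variant, 0.0)


@dataclass
class Trajectory:
    """Model heavy fraction evaluated on a time grid (days)."""

    times: np.ndarray
    F: np.ndarray

    @property
    def R(self) -> np.ndarray:
        return model_R(self)


def model_R(trajectory):
    """R(t) = -ln F(t); F = 0 maps to +inf (censored-high)."""
    F = trajectory.F if isinstance(trajectory, Trajectory) else np.asarray(trajectory, float)
    with np.errstate(divide="ignore"):
        return -np.log(F)


def build_segments(pool: FreePoolModel, growth: GrowthModel, t_end, extra_times=(), protein_id=None):
    """Segment boundaries and per-segment coefficients on [chase_start, t_end].

    Returns (grid, dt, g, p_start, lam) where ``grid`` has length n_seg+1
    and the remaining arrays length n_seg.  Within segment j, g is the
    constant relative growth rate, and the pool is
    p(tau) = p_start[j] * exp(-lam[j] * tau) with tau the time since the
    segment start.
    """
    t0 = pool.chase_start
    pts = np.concatenate(
        [
            np.asarray([t0, t_end], float),
            np.asarray(extra_times, float).ravel(),
            growth.all_knots(protein_id),
        ]
    )
    pts = np.unique(pts)
    grid = pts[(pts >= t0) & (pts <= t_end)]
    if grid.size < 2:
        grid = np.array([t0, max(t_end, t0)])
    dt = np.diff(grid)
    logP = growth.log_total(grid, protein_id)
    with np.errstate(invalid="ignore"):
        g = np.where(dt > 0, np.diff(logP) / np.where(dt > 0, dt, 1.0), 0.0)
    if np.isinf(pool.lambda_free):
        p_start = np.zeros_like(dt)
        lam = np.zeros_like(dt)
    else:
        p_start = pool(grid[:-1])
        p_start = np.atleast_1d(np.asarray(p_start, float))
        lam = np.full_like(dt, pool.lambda_free)
    return grid, dt, g, p_start, lam


def propagate_segments(k, F0, dt, g, p_start, lam):
    """Exact per-segment propagation of the heavy fraction.

    k, F0 : arrays of parameter values (any common shape S).
    dt : (n_seg,) segment lengths.
    g, p_start, lam : (n_seg,) or (..., n_seg) broadcastable against S
        (per-protein growth rates, per-chain pool parameters).

    Returns F with shape S + (n_seg + 1,), including the starting value.
    """
    k = np.asarray(k, dtype=float)
    F = np.broadcast_arrays(k, np.asarray(F0, dtype=float))[1].astype(float).copy()
    n_seg = len(dt)
    g = np.asarray(g, dtype=float)
    p_start = np.asarray(p_start, dtype=float)
    lam = np.asarray(lam, dtype=float)
    out = np.empty(F.shape + (n_seg + 1,))
    out[..., 0] = F
    for j in range(n_seg):
        gj = g[..., j] if g.ndim > 1 else g[j]
        a = k + gj
        E = np.exp(-a * dt[j])
        psj = p_start[..., j] if p_start.ndim > 1 else p_start[j]
        lamj = lam[..., j] if lam.ndim > 1 else lam[j]
        if np.ndim(psj) == 0 and psj <= 0:
            F = F * E
        else:
            denom = a - lamj
            small = np.abs(denom) < 1e-10
            safe = np.where(small, 1.0, denom)
            Elam = np.exp(-lamj * dt[j])
            rec = a * psj * np.where(small, dt[j] * E, (Elam - E) / safe)
            # synthesis clamp: no recycling inflow where the implied flux is negative
            rec = np.where(a > 0, rec, 0.0)
            F = F * E + rec
        F = np.clip(F, 0.0, 1.0)
        out[..., j + 1] = F
    return out


def simulate_fraction(k, F0, pool: FreePoolModel, growth: GrowthModel, times, protein_id=None):
    """Heavy-fraction trajectory F(t) at the requested times.

    ``k`` and ``F0`` may be scalars or arrays (broadcast together); the
    returned ``Trajectory.F`` then has shape ``k.shape + (n_times,)``.
    Times before the chase start sit on the labelling plateau F0.
    """
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("degradation rate k must be >= 0")
    F0_arr = np.asarray(F0, dtype=float)
    if np.any((F0_arr < 0) | (F0_arr > 1)):
        raise ValueError("F0 must be in [0, 1]")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    t_end = max(times.max(), pool.chase_start)
    grid, dt, g, p_start, lam = build_segments(
        pool, growth, t_end, extra_times=times, protein_id=protein_id
    )
    F_grid = propagate_segments(k_arr, F0_arr, dt, g, p_start, lam)
    idx = np.searchsorted(grid, times)
    idx = np.clip(idx, 0, len(grid) - 1)
    F = F_grid[..., idx]
    pre = times < pool.chase_start
    if np.any(pre):
        F = np.where(pre, np.broadcast_to(F0_arr[..., None], F.shape), F)
    return Trajectory(times=times, F=F)


def half_life(k, F0, pool: FreePoolModel, growth: GrowthModel, cap: float = 10000.0,
              protein_id=None) -> float:
    """Days for the heavy-labelled protein cohort to decay to half, or inf.

    The half-life tracks the molecules that exist at the chase start:
    organ growth dilutes the heavy *fraction* but destroys no heavy
    protein (it cancels from the amount), and lysine recycling only
    creates *new* molecules, so the labelled cohort decays as exp(-k t)
    and H1/2 = ln2/k.  Recycling and growth matter because they must be
    modelled to estimate k from the measured fractions in the first
    place -- ignoring recycling biases k down and hence H1/2 up.  The
    ``F0``/``pool``/``growth`` arguments keep the trajectory-model
    interface (and document that the result is conditional on them only
    through k); returns ``float('inf')`` when the cohort has not halved
    within ``cap`` days (reported downstream as ">cap").
    """
    k = float(k)
    if k < 0 or not 0 <= float(F0) <= 1:
        raise ValueError("invalid k or F0")
    if k == 0:
        return float("inf")
    h = math.log(2.0) / k
    return h if h < cap else float("inf")


def fit_2lys_peptide(times, hh_intensities, growth: GrowthModel | None = None,
                     protein_id=None) -> float:
    """Degradation rate from the decay of pure-HH 2Lys peptide intensities.

    HH peptides are essentially never re-made during the chase (the free
    pool would have to supply two heavy lysines), so the HH fraction of an
    abundant protein decays as exp(-(k+g) t): a least-squares fit of
    log HH(t), after adding back the known dilution log P(t) - log P(t0),
    has slope -k.  Equivalent to the full model with p = 0 restricted to
    the HH species.
    """
    times = np.asarray(times, dtype=float)
    hh = np.asarray(hh_intensities, dtype=float)
    ok = np.isfinite(hh) & (hh > 0)
    times, hh = times[ok], hh[ok]
    if times.size < 3:
        raise ValueError("need >=3 positive HH intensity timepoints")
    y = np.log(hh)
    if growth is not None:
        y = y + growth.log_total(times, protein_id) - growth.log_total(times[0], protein_id)
    slope, _ = np.polyfit(times, y, 1)
    return float(-slope)
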