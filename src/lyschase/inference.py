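"""Per-protein Bayesian estimation of degradation rates and half-lives.

The observable is R = ln(L/H + 1) per (timepoint, biological replicate),
modelled as Normal(R_model(t; theta), sigma) with the degradation rate k
shared across both pulse designs, a flat prior on log10 k in [-4, 1], a
free heavy fraction at weaning for the chase-from-weaning design (its
pulse phase is not modelled) and a per-protein noise scale.  Timepoints
where the heavy channel fell below detection while light persisted enter
as one-sided censored observations R >= R_bound, which guards against
survivor bias toward long half-lives.

The free-pool decay parameters and the growth amplitude are themselves
estimates from 2Lys and volume regressions; treating them as exact would
make every protein's interval too narrow.  They are therefore included
as nuisance parameters with Gaussian priors at the regression estimates
(scaled by their standard errors) and marginalized per protein.

Sampling is adaptive random-walk Metropolis with reflection at the prior
bounds, four chains per protein, proposal scales tuned only during warmup
(so the post-warmup chain is a valid fixed-kernel MCMC), and every chain
of every protein advanced in one vectorized pass -- a whole cohort fits
in seconds.  Half-life summaries exploit that H1/2 is a decreasing
function of k for fixed pool/growth, so posterior quantiles of H1/2 are
the mapped reversed quantiles of k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from lyschase.free_pool import P_LABEL_DEFAULT, FreePoolModel
from lyschase.growth import GrowthModel
from lyschase.stats import SpearmanResult, spearman_as89
from lyschase.turnover import TurnoverModelSpec, build_segments, half_life, propagate_segments

__all__ = [
    "FitConfig",
    "TurnoverFit",
    "fit_cohort",
    "fit_protein",
    "fits_to_frame",
    "summarize_percent_heavy",
    "percent_heavy_matrix",
    "compare_halflives",
]

BIRTH, WEANING = "chase_from_birth", "chase_from_weaning"

# parameter vector layout
_LOGK, _F0W, _LOGSIG, _LAM, _LOGP0, _GAMMA = range(6)


@dataclass(frozen=True)
class FitConfig:
    """Sampler and model settings for turnover inference."""

    model: TurnoverModelSpec = field(default_factory=TurnoverModelSpec)
    n_chains: int = 4
    n_warmup: int = 400
    n_draws: int = 500  # post-warmup draws per chain
    p_label: float = P_LABEL_DEFAULT
    log10k_bounds: tuple = (-4.0, 1.0)
    f0_weaning_bounds: tuple = (0.5, 1.0)
    log_sigma_bounds: tuple = (math.log(1e-3), math.log(3.0))
    include_censored: bool = True
    detection_limit: float | None = None
    min_obs: int = 3
    min_ess: float = 50.0
    target_accept: float = 0.30
    marginalize_inputs: bool = True  # sample pool/growth nuisances
    # "scaled": sd of R is sigma * (1 - F + floor), the first-order
    # propagation of multiplicative intensity noise; "constant": sigma
    noise_model: str = "scaled"
    noise_floor: float = 0.05


@dataclass
class TurnoverFit:
    """Posterior summary for one protein."""

    protein_id: str
    status: str = "ok"
    k_median: float = np.nan
    k_q5: float = np.nan
    k_q95: float = np.nan
    halflife_median: float = np.nan
    halflife_q5: float = np.nan
    halflife_q95: float = np.nan
    censored: bool = False
    f0_weaning_median: float = np.nan
    sigma_median: float = np.nan
    n_data: int = 0
    accept_rate: float = np.nan
    ess_k: float = np.nan
    converged: bool = False
    k_samples: np.ndarray | None = None


class _DesignData:
    """Precomputed observation matrices and ODE segments for one design."""

    def __init__(self, agg: pd.DataFrame, design: str, proteins: list[str],
                 pool: FreePoolModel, growth: GrowthModel, config: FitConfig):
        sub = agg[agg["design"] == design]
        spec = config.model
        if spec.min_age > 0:
            sub = sub[sub["age_days"] >= spec.min_age]
        self.design = design
        self.pool = pool if spec.recycling else FreePoolModel.zero(design, pool.chase_start)
        self.f0_free = design == WEANING
        P = len(proteins)
        pidx = {p: i for i, p in enumerate(proteins)}
        ages = np.sort(sub["age_days"].unique().astype(float))
        ages = ages[ages >= self.pool.chase_start]
        self.ages = ages
        obs_keys = (
            sub[["age_days", "bio_rep"]].drop_duplicates().sort_values(
                ["age_days", "bio_rep"]).to_numpy()
        )
        obs_keys = obs_keys[np.isin(obs_keys[:, 0], ages)]
        self.obs_age_idx = (np.searchsorted(ages, obs_keys[:, 0])
                            if len(obs_keys) else np.array([], int))
        okey = {(a, int(r)): j for j, (a, r) in enumerate(obs_keys)}
        O = len(obs_keys)
        self.R_obs = np.full((P, O), np.nan)
        self.cens = np.zeros((P, O), dtype=bool)
        self.R_bound = np.full((P, O), np.nan)
        dl = config.detection_limit
        for row in sub.itertuples(index=False):
            i = pidx.get(row.protein_id)
            j = okey.get((row.age_days, int(row.bio_rep)))
            if i is None or j is None:
                continue
            if np.isfinite(row.R):
                self.R_obs[i, j] = row.R
            elif getattr(row, "censored_high", False) and config.include_censored and dl:
                if np.isfinite(row.L) and row.L > 0:
                    self.cens[i, j] = True
                    self.R_bound[i, j] = math.log1p(row.L / dl)
        self.finite = np.isfinite(self.R_obs)
        self.n_per_protein = self.finite.sum(axis=1) + self.cens.sum(axis=1)
        self.has_cens = bool(self.cens.any())
        self.noise_scaled = config.noise_model == "scaled"
        self.noise_floor = config.noise_floor
        # segment machinery (shared grid; per-protein growth rates)
        t_end = max(ages.max(initial=self.pool.chase_start), self.pool.chase_start)
        grid, dt, g, p_start, lam = build_segments(self.pool, growth, t_end, extra_times=ages)
        self.grid, self.dt, self.p_start, self.lam = grid, dt, p_start, lam
        self.pool_offsets = grid[:-1] - self.pool.chase_start  # for sampled pools
        if growth.log_conc:
            logP = np.stack([growth.log_total(grid, p) for p in proteins])
            with np.errstate(invalid="ignore"):
                self.g = np.where(dt > 0, np.diff(logP, axis=1) / np.where(dt > 0, dt, 1.0), 0.0)
            self.g = self.g[:, None, :]  # (P, 1, S) broadcasts over chains
        else:
            self.g = g
        self.age_pos = np.searchsorted(grid, ages)

    def log_likelihood(self, k, f0w, sigma, p_label, lam=None, logp0=None, gamma=None):
        """Summed log likelihood per (protein, chain).

        ``lam``/``logp0``/``gamma`` are optional sampled nuisance values
        (shape like ``k``); None keeps the precomputed point estimates.
        """
        if self.R_obs.size == 0 and not self.has_cens:
            return 0.0
        F0 = f0w if self.f0_free else p_label
        S = len(self.dt)
        g = self.g
        if gamma is not None:
            g = g * (1.0 + gamma[..., None])
        p_start, lam_seg = self.p_start, self.lam
        if lam is not None and self.pool.p0 > 0:
            p_start = np.minimum(
                np.exp(logp0[..., None] - lam[..., None] * self.pool_offsets), 1.0)
            lam_seg = np.broadcast_to(lam[..., None], lam.shape + (S,))
        F = propagate_segments(k, F0, self.dt, g, p_start, lam_seg)
        F = F[..., self.age_pos]
        with np.errstate(divide="ignore"):
            Rm = -np.log(np.maximum(F, 1e-300))
        Rm = Rm[..., self.obs_age_idx]  # (P, C, O)
        if self.noise_scaled:
            w = (1.0 - F[..., self.obs_age_idx]) + self.noise_floor
            sig = sigma[..., None] * w
        else:
            sig = sigma[..., None] * np.ones_like(Rm)
        resid = np.where(self.finite[:, None, :],
                         (np.nan_to_num(self.R_obs[:, None, :]) - Rm) / sig, 0.0)
        ll = -0.5 * np.sum(resid * resid, axis=-1)
        ll -= np.sum(np.where(self.finite[:, None, :], np.log(sig), 0.0), axis=-1)
        if self.has_cens:
            z = (Rm - np.nan_to_num(self.R_bound[:, None, :])) / sig
            ll += np.sum(np.where(self.cens[:, None, :], log_ndtr(z), 0.0), axis=-1)
        return ll


def _reflect(x, lo, hi):
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.minimum(y, 2.0 * span - y)


def _ess_chains(samples: np.ndarray) -> float:
    """Effective sample size, Geyer initial-positive-sequence, summed over chains."""
    total = 0.0
    for chain in samples:
        n = chain.size
        c = chain - chain.mean()
        var = np.dot(c, c) / n
        if var == 0:
            total += n
            continue
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(c, nfft)
        acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real / (var * n)
        tau = 1.0
        for t in range(1, n - 1, 2):
            pair = acf[t] + acf[t + 1]
            if pair < 0:
                break
            tau += 2.0 * pair
        total += n / max(tau, 1.0)
    return float(total)


def fit_cohort(agg: pd.DataFrame, pools: dict[str, FreePoolModel], growth: GrowthModel,
               config: FitConfig = FitConfig(), seed: int = 0,
               exclude=(), keep_samples: bool = False) -> list[TurnoverFit]:
    """Fit every protein in an aggregated replicate table.

    ``agg`` is the output of :func:`lyschase.preprocess.aggregate_technical`
    (both designs concatenated); ``pools`` maps design name to its
    :class:`FreePoolModel`.  Proteins in ``exclude`` (e.g. flagged rapid
    degraders) are dropped.  All chains of all proteins are advanced
    together, so the cost is nearly independent of cohort size up to the
    vectorization width.
    """
    rng = np.random.default_rng(seed)
    exclude = set(exclude)
    proteins = sorted(p for p in agg["protein_id"].unique() if p not in exclude)
    designs = [d for d in (BIRTH, WEANING) if (agg["design"] == d).any()]
    if not designs:
        raise ValueError("no recognised pulse designs in the data")
    data = [_DesignData(agg, d, proteins, pools[d], growth, config) for d in designs]

    P, C = len(proteins), config.n_chains
    n_data = sum(d.n_per_protein for d in data)
    ok = n_data >= config.min_obs

    pool_prior = pools.get(BIRTH, next(iter(pools.values())))
    sample_pool = (config.marginalize_inputs and config.model.recycling
                   and pool_prior.p0 > 0
                   and (pool_prior.lambda_se > 0 or pool_prior.logp0_se > 0))
    # Input-model nuisances belong to the full model only: a reduced
    # variant (k_on = 0, late-only) must not be free to re-attribute the
    # mechanism it dropped to a growth/pool adjustment, or the variant
    # comparison would no longer isolate that mechanism.
    sample_growth = (config.marginalize_inputs and config.model.recycling
                     and growth.amplitude_se > 0)
    lam0 = pool_prior.lambda_free if np.isfinite(pool_prior.lambda_free) else 0.0
    logp00 = math.log(pool_prior.p0) if pool_prior.p0 > 0 else 0.0
    lam_se = pool_prior.lambda_se if sample_pool else 0.0
    p0_se = pool_prior.logp0_se if sample_pool else 0.0
    corr = np.clip(pool_prior.lam_logp0_corr, -0.99, 0.99) if sample_pool else 0.0
    gam_se = growth.amplitude_se if sample_growth else 0.0

    lo = np.array([config.log10k_bounds[0], config.f0_weaning_bounds[0],
                   config.log_sigma_bounds[0],
                   max(0.0, lam0 - 8 * lam_se) if sample_pool else lam0 - 1.0,
                   max(logp00 - 8 * p0_se, math.log(0.05)) if sample_pool else logp00 - 1.0,
                   -0.5 if sample_growth else -1.0])
    hi = np.array([config.log10k_bounds[1], config.f0_weaning_bounds[1],
                   config.log_sigma_bounds[1],
                   lam0 + 8 * lam_se if sample_pool else lam0 + 1.0,
                   min(logp00 + 8 * p0_se, 0.0) if sample_pool else logp00 + 1.0,
                   0.5 if sample_growth else 1.0])
    hi = np.maximum(hi, lo + 1e-9)
    widths = np.array([0.10, 0.015, 0.25,
                       lam_se if sample_pool else 0.0,
                       p0_se if sample_pool else 0.0,
                       gam_se if sample_growth else 0.0])

    def logpost(theta):
        k = 10.0 ** theta[..., _LOGK]
        f0w = theta[..., _F0W]
        sigma = np.exp(theta[..., _LOGSIG])
        lam = theta[..., _LAM] if sample_pool else None
        logp0 = theta[..., _LOGP0] if sample_pool else None
        gamma = theta[..., _GAMMA] if sample_growth else None
        out = 0.0
        for d in data:
            out = out + d.log_likelihood(k, f0w, sigma, config.p_label,
                                         lam=lam, logp0=logp0, gamma=gamma)
        if sample_pool:
            dl = (lam - lam0) / (lam_se if lam_se > 0 else 1.0)
            dp = (logp0 - logp00) / (p0_se if p0_se > 0 else 1.0)
            out = out - 0.5 * (dl * dl - 2 * corr * dl * dp + dp * dp) / (1 - corr**2)
        if sample_growth:
            out = out - 0.5 * (theta[..., _GAMMA] / gam_se) ** 2
        return out

    # --- initialization: coarse scan over k, other dims at their centres --
    centre = np.array([0.0, min(config.p_label, hi[_F0W]), math.log(0.1),
                       lam0, logp00, 0.0])
    k_grid = np.linspace(lo[_LOGK], hi[_LOGK], 61)
    theta_grid = np.tile(centre, (P, k_grid.size, 1))
    theta_grid[..., _LOGK] = k_grid[None, :]
    best = np.argmax(logpost(theta_grid), axis=1)  # (P,)

    theta = np.tile(centre, (P, C, 1))
    theta[..., _LOGK] = k_grid[best][:, None] + 0.05 * rng.standard_normal((P, C))
    theta[..., _F0W] -= np.abs(0.01 * rng.standard_normal((P, C)))
    theta[..., _LOGSIG] += 0.3 * rng.standard_normal((P, C))
    if sample_pool:
        theta[..., _LAM] += 0.3 * lam_se * rng.standard_normal((P, C))
        theta[..., _LOGP0] += 0.3 * p0_se * rng.standard_normal((P, C))
    if sample_growth:
        theta[..., _GAMMA] += 0.3 * gam_se * rng.standard_normal((P, C))
    theta = _reflect(theta, lo, hi)

    log_scale = np.zeros((P, C))
    ll = logpost(theta)
    n_iter = config.n_warmup + config.n_draws
    k_samples = np.empty((P, C, config.n_draws))
    f0_samples = np.empty((P, C, config.n_draws))
    sig_samples = np.empty((P, C, config.n_draws))
    n_accept = np.zeros((P, C))

    for it in range(n_iter):
        step = np.exp(log_scale)[..., None] * widths * rng.standard_normal((P, C, 6))
        prop = _reflect(theta + step, lo, hi)
        ll_prop = logpost(prop)
        accept = np.log(rng.random((P, C))) < (ll_prop - ll)
        theta = np.where(accept[..., None], prop, theta)
        ll = np.where(accept, ll_prop, ll)
        if it < config.n_warmup:
            gamma_t = 2.0 / (1.0 + it) ** 0.6
            log_scale += gamma_t * (accept.astype(float) - config.target_accept)
            log_scale = np.clip(log_scale, -4.0, 2.0)
        else:
            j = it - config.n_warmup
            k_samples[..., j] = theta[..., _LOGK]
            f0_samples[..., j] = theta[..., _F0W]
            sig_samples[..., j] = theta[..., _LOGSIG]
            n_accept += accept

    accept_rate = n_accept / config.n_draws
    cap = config.model.halflife_cap_days
    birth_pool = pools.get(BIRTH, next(iter(pools.values())))
    hl_pool = birth_pool if config.model.recycling else FreePoolModel.zero(
        BIRTH, birth_pool.chase_start)

    fits = []
    for i, pid in enumerate(proteins):
        if not ok[i]:
            fits.append(TurnoverFit(protein_id=pid, status="skipped_too_few_points",
                                    n_data=int(n_data[i])))
            continue
        ks = 10.0 ** k_samples[i].ravel()
        kq5, kmed, kq95 = np.quantile(ks, [0.05, 0.5, 0.95])
        hl = [half_life(k, config.p_label, hl_pool, growth, cap=cap, protein_id=pid)
              for k in (kmed, kq95, kq5)]  # H1/2 decreasing in k
        hmed, hq5, hq95 = hl
        # a posterior piling on the prior's lower rate bound means the data
        # never saw the label leave: the half-life is only bounded below
        at_floor = kq5 <= 10.0 ** (config.log10k_bounds[0] + 0.05)
        censored = not np.isfinite(hmed) or hmed >= cap or at_floor
        if at_floor:
            hmed = hq95 = float("inf")
        ess = _ess_chains(k_samples[i])
        fits.append(TurnoverFit(
            protein_id=pid,
            k_median=float(kmed), k_q5=float(kq5), k_q95=float(kq95),
            halflife_median=float(min(hmed, cap)),
            halflife_q5=float(min(hq5, cap)),
            halflife_q95=float(min(hq95, cap)),
            censored=bool(censored),
            f0_weaning_median=float(np.median(f0_samples[i])),
            sigma_median=float(np.exp(np.median(sig_samples[i]))),
            n_data=int(n_data[i]),
            accept_rate=float(accept_rate[i].mean()),
            ess_k=ess,
            converged=bool(ess >= config.min_ess),
            k_samples=ks if keep_samples else None,
            status="ok" if ess >= config.min_ess else "low_ess",
        ))
    return fits


def fit_protein(series_birth, series_weaning, pools, growth,
                config: FitConfig = FitConfig(), seed: int = 0,
                keep_samples: bool = True) -> TurnoverFit:
    """Fit a single protein from its per-design series (either may be None)."""
    frames = []
    for s in (series_birth, series_weaning):
        if s is None:
            continue
        tab = s.table.copy()
        tab["protein_id"] = s.protein_id
        tab["design"] = s.design
        frames.append(tab)
    if not frames:
        raise ValueError("at least one series required")
    agg = pd.concat(frames, ignore_index=True)
    fits = fit_cohort(agg, pools, growth, config=config, seed=seed,
                      keep_samples=keep_samples)
    return fits[0]


def fits_to_frame(fits: list[TurnoverFit]) -> pd.DataFrame:
    cols = ["protein_id", "status", "k_median", "k_q5", "k_q95", "halflife_median",
            "halflife_q5", "halflife_q95", "censored", "f0_weaning_median",
            "sigma_median", "n_data", "accept_rate", "ess_k", "converged"]
    return pd.DataFrame([{c: getattr(f, c) for c in cols} for f in fits])


def summarize_percent_heavy(fit: TurnoverFit, pools, growth, times,
                            config: FitConfig = FitConfig()) -> np.ndarray:
    """Modelled %13C6-Lys retention at the posterior-median rate.

    The retention of the chase-start labelled cohort, 100 * exp(-k t):
    growth dilution cancels from the labelled amount and recycling only
    adds unlabelled-cohort molecules, so this is the survival curve the
    longevity clustering operates on.  Computed through the trajectory
    model (zero pool, unit growth) for internal consistency with
    :func:`lyschase.turnover.simulate_fraction`.
    """
    from lyschase.growth import GrowthModel as _GM
    from lyschase.turnover import simulate_fraction

    birth_pool = pools.get(BIRTH, next(iter(pools.values())))
    traj = simulate_fraction(fit.k_median, 1.0,
                             FreePoolModel.zero(BIRTH, birth_pool.chase_start),
                             _GM.constant(), times)
    return 100.0 * traj.F


def percent_heavy_matrix(fits, pools, growth, times,
                         config: FitConfig = FitConfig()) -> pd.DataFrame:
    """Rows = proteins with successful fits, columns = ages (days), values = %H."""
    rows, index = [], []
    for f in fits:
        if f.status not in ("ok", "low_ess"):
            continue
        rows.append(summarize_percent_heavy(f, pools, growth, times, config))
        index.append(f.protein_id)
    return pd.DataFrame(np.asarray(rows), index=index,
                        columns=[float(t) for t in np.atleast_1d(times)])


def compare_halflives(fits_a, fits_b, censored: str = "exclude",
                      cap: float = 10000.0) -> SpearmanResult:
    """Spearman correlation (AS 89 p-value) between two half-life sets.

    ``fits_a``/``fits_b`` are lists of :class:`TurnoverFit` or mappings
    protein_id -> half-life.  Censored fits are excluded by default, or
    tie-ranked at the cap with ``censored="cap"``.
    """
    def as_map(fits):
        if isinstance(fits, dict):
            return {str(k): (float(v), False) for k, v in fits.items()}
        return {f.protein_id: (f.halflife_median, f.censored) for f in fits
                if f.status in ("ok", "low_ess")}

    a, b = as_map(fits_a), as_map(fits_b)
    shared = sorted(set(a) & set(b))
    xs, ys = [], []
    for pid in shared:
        va, ca = a[pid]
        vb, cb = b[pid]
        if censored == "exclude" and (ca or cb):
            continue
        xs.append(min(va, cap))
        ys.append(min(vb, cap))
    if len(xs) < 4:
        raise ValueError("need >=4 shared uncensored proteins")
    return spearman_as89(np.array(xs), np.array(ys))
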