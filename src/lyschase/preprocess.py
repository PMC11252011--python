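"""Replicate aggregation, detection rules and ratio computation.

The detection rules mirror the study's data-exclusion conventions:

* a channel's median over technical replicates is only computed if the
  channel was detected (present and > 0) in at least two of the technical
  replicates (with a single technical replicate the value passes through);
* a protein is "heavy only" if the heavy channel passes that rule in at
  least one biological replicate while the light channel has no signal in
  any technical replicate of any biological replicate ("light only"
  symmetric);
* the fitted observable is R = ln(L/H + 1), so the heavy fraction is
  F = H/(H+L) = exp(-R);
* proteins whose heavy channel vanishes from every late chase timepoint in
  both pulse designs while the light channel persists degrade too fast to
  model and are excluded from inference (rapid degraders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProteinSeries",
    "aggregate_technical",
    "classify_label_state",
    "heavy_fraction_summary",
    "compute_R",
    "flag_rapid_degraders",
    "series_from_aggregate",
]

LABEL_STATES = ("heavy_only", "light_only", "both", "undetected")


@dataclass
class ProteinSeries:
    """Aggregated heavy/light series for one protein in one pulse design.

    ``table`` has one row per (age_days, bio_rep) with columns H, L
    (medians over technical replicates, NaN when the detection rule
    failed), R, F and ``censored_high`` (heavy undetected while light
    detected: R is only known to be large).
    """

    protein_id: str
    design: str
    table: pd.DataFrame

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.table["age_days"].unique())

    @property
    def n_observed(self) -> int:
        return int(self.table["R"].notna().sum())


def compute_R(L, H):
    """R = ln(L/H + 1); H = 0 gives +inf (censored-high, fully chased)."""
    L = np.asarray(L, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(L < 0) or np.any(H < 0):
        raise ValueError("intensities must be nonnegative")
    with np.errstate(divide="ignore"):
        out = np.log1p(L / H)
    return float(out) if out.ndim == 0 else out


def _min_detections(n_tech: int) -> int:
    return 2 if n_tech >= 2 else 1


def _detected(x: pd.Series) -> pd.Series:
    return x.notna() & (x > 0)


def aggregate_technical(records: pd.DataFrame, n_tech: int = 4,
                        light_missing: str = "zero") -> pd.DataFrame:
    """Collapse technical replicates to channel medians and compute R and F.

    A channel median is reported iff the channel was detected in at least
    two of ``n_tech`` technical replicates (pass-through when
    ``n_tech == 1``); the median is taken over the detected values.

    ``light_missing`` controls points where heavy passes but light does
    not: ``"zero"`` (default) treats the light signal as below detection,
    giving R = 0-ish, F = H/(H+0) = 1 (the heavy-only convention);
    ``"drop"`` leaves R/F missing there.
    """
    if light_missing not in ("zero", "drop"):
        raise ValueError("light_missing must be 'zero' or 'drop'")
    min_det = _min_detections(n_tech)
    df = records.copy()
    df["_det"] = _detected(df["intensity"])
    df["_val"] = df["intensity"].where(df["_det"])  # median over detected values only
    key = ["protein_id", "design", "age_days", "bio_rep", "channel"]
    grp = df.groupby(key, sort=True)
    agg = grp.agg(n_det=("_det", "sum"), med=("_val", "median")).reset_index()
    agg["med"] = agg["med"].where(agg["n_det"] >= min_det)
    wide = (agg.set_index(["protein_id", "design", "age_days", "bio_rep", "channel"])
            ["med"].unstack("channel").reset_index())
    for ch in ("H", "L"):
        if ch not in wide.columns:
            wide[ch] = np.nan
    H = wide["H"].to_numpy(dtype=float)
    L = wide["L"].to_numpy(dtype=float)
    have_h = np.isfinite(H)
    have_l = np.isfinite(L)
    censored = ~have_h & have_l
    L_eff = np.where(have_l, L, 0.0 if light_missing == "zero" else np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(have_h, np.log1p(L_eff / H), np.nan)
        F = np.where(have_h, H / (H + L_eff), np.nan)
    out = wide[["protein_id", "design", "age_days", "bio_rep"]].copy()
    out["H"] = H
    out["L"] = L
    out["R"] = R
    out["F"] = F
    out["censored_high"] = censored
    return out.sort_values(["protein_id", "design", "age_days", "bio_rep"],
                           kind="mergesort", ignore_index=True)


def series_from_aggregate(agg: pd.DataFrame) -> dict[tuple[str, str], ProteinSeries]:
    """Split an aggregated table into per-(protein, design) series objects."""
    out = {}
    for (pid, design), sub in agg.groupby(["protein_id", "design"], sort=True):
        out[(pid, design)] = ProteinSeries(
            protein_id=pid, design=design,
            table=sub.drop(columns=["protein_id", "design"]).reset_index(drop=True),
        )
    return out


def classify_label_state(records: pd.DataFrame, n_tech: int = 4) -> pd.DataFrame:
    """Assign heavy_only/light_only/both/undetected per (protein, design)."""
    min_det = _min_detections(n_tech)
    df = records.copy()
    df["_det"] = _detected(df["intensity"])
    per_rep = (
        df.groupby(["protein_id", "design", "age_days", "bio_rep", "channel"])["_det"]
        .sum().reset_index(name="n_det")
    )
    per_rep["passes"] = per_rep["n_det"] >= min_det
    summary = per_rep.groupby(["protein_id", "design", "channel"]).agg(
        any_pass=("passes", "any"), total_det=("n_det", "sum")
    ).unstack("channel")
    def col(frame, metric, ch, default):
        try:
            return frame[(metric, ch)].fillna(default)
        except KeyError:
            return pd.Series(default, index=frame.index)
    h_pass = col(summary, "any_pass", "H", False).astype(bool)
    l_pass = col(summary, "any_pass", "L", False).astype(bool)
    h_det = col(summary, "total_det", "H", 0)
    l_det = col(summary, "total_det", "L", 0)
    state = np.select(
        [h_pass & (l_det == 0), l_pass & (h_det == 0), h_pass & l_pass],
        ["heavy_only", "light_only", "both"],
        default="undetected",
    )
    out = summary.index.to_frame(index=False)
    out["state"] = state
    return out


def heavy_fraction_summary(agg: pd.DataFrame) -> pd.DataFrame:
    """Mean and s.d. of the heavy fraction F over biological replicates.

    Reported per (protein, design, age) whenever F is available in at
    least one biological replicate; replicates where the heavy channel
    passed but light never did contribute F = 1 (fully heavy).  The s.d.
    (ddof=1) is missing when only one replicate has F.
    """
    df = agg.copy()
    f_eff = df["F"].where(~(df["H"].notna() & df["L"].isna()), 1.0)
    df["_f"] = f_eff
    rows = []
    for (pid, design, age), sub in df.groupby(["protein_id", "design", "age_days"], sort=True):
        f = sub["_f"].dropna()
        if f.empty:
            continue
        rows.append({
            "protein_id": pid, "design": design, "age_days": age,
            "f_mean": float(f.mean()),
            "f_sd": float(f.std(ddof=1)) if len(f) > 1 else np.nan,
            "n_reps": int(len(f)),
        })
    return pd.DataFrame(rows, columns=["protein_id", "design", "age_days",
                                       "f_mean", "f_sd", "n_reps"])


def flag_rapid_degraders(records_by_design: dict[str, pd.DataFrame],
                         cutoff_age: float = 42.0, n_tech: int = 4,
                         require_all_designs: bool = True) -> set[str]:
    """Proteins degrading too fast to model.

    A protein is flagged when, in every pulse design it appears in (all
    designs must agree when ``require_all_designs``), the heavy channel
    never passes the detection rule at any chase timepoint at or beyond
    ``cutoff_age`` while the light channel does.  Proteins absent from the
    late timepoints altogether (not expressed) are not flagged.
    """
    min_det = _min_detections(n_tech)
    flagged_per_design = []
    all_proteins = set()
    for design, records in records_by_design.items():
        df = records[records["age_days"] >= cutoff_age].copy()
        all_proteins.update(records["protein_id"].unique())
        if df.empty:
            flagged_per_design.append(set())
            continue
        df["_det"] = _detected(df["intensity"])
        per = (
            df.groupby(["protein_id", "age_days", "bio_rep", "channel"])["_det"]
            .sum().reset_index(name="n_det")
        )
        per["passes"] = per["n_det"] >= min_det
        by_ch = per.groupby(["protein_id", "channel"])["passes"].any().unstack("channel")
        h = by_ch["H"] if "H" in by_ch.columns else pd.Series(False, index=by_ch.index)
        l = by_ch["L"] if "L" in by_ch.columns else pd.Series(False, index=by_ch.index)
        flagged_per_design.append(set(by_ch.index[~h.fillna(False) & l.fillna(False)]))
    if not flagged_per_design:
        return set()
    if require_all_designs:
        out = set.intersection(*flagged_per_design) if flagged_per_design else set()
    else:
        out = set.union(*flagged_per_design)
    return out & all_proteins
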