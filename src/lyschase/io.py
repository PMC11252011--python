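"""Readers and writers for the pipeline's tabular formats.

All tables are plain tab-separated files in long format with named header
columns (column order free): search-engine exports are wide and
dialect-varied, so the pipeline consumes a normalized long layout instead
of raw MaxQuant/Spectronaut reports.  Ages are stored internally in days;
an optional ``age_unit`` column (``days``/``weeks``) converts on read.
Missing intensities are empty cells or ``NA`` and stay missing -- zero is
a measured value, distinct from not-detected.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "DESIGNS",
    "TableFormatError",
    "TableValidationError",
    "read_quant_table",
    "read_volume_table",
    "read_abundance_table",
    "read_2lys_table",
    "read_gmt",
    "write_gmt",
    "write_atlas",
    "read_atlas",
]

DESIGNS = ("chase_from_birth", "chase_from_weaning")

NA_VALUES = ["", "NA", "NaN", "nan", "n.a.", "na"]


class TableFormatError(ValueError):
    """The file does not have the expected header/structure."""


class TableValidationError(ValueError):
    """The file parsed but violates a content invariant."""


def _read_tsv(path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    except Exception as exc:  # malformed beyond pandas' tolerance
        raise TableFormatError(f"could not parse {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _convert_ages(df: pd.DataFrame) -> pd.DataFrame:
    if "age_unit" in df.columns:
        unit = df["age_unit"].astype(str).str.lower()
        bad = ~unit.isin(["days", "day", "d", "weeks", "week", "wk", "w"])
        if bad.any():
            raise TableValidationError(f"unknown age units: {sorted(unit[bad].unique())}")
        factor = np.where(unit.str.startswith("w"), 7.0, 1.0)
        df = df.drop(columns=["age_unit"])
        df["age_days"] = df["age_days"].astype(float) * factor
    else:
        df["age_days"] = df["age_days"].astype(float)
    if (df["age_days"] <= 0).any():
        raise TableValidationError("age_days must be > 0")
    return df


def read_quant_table(path, design: str | None = None) -> pd.DataFrame:
    """Read a long-format protein quantification table.

    Columns: protein_id, age_days, bio_rep, tech_rep, channel (H/L),
    intensity; optional gene_symbol, design, age_unit.  Missing
    intensities are preserved as NaN, never coerced to 0.
    """
    df = _read_tsv(path, {"protein_id", "age_days", "bio_rep", "tech_rep", "channel", "intensity"})
    if design is not None:
        if design not in DESIGNS:
            raise TableValidationError(f"unknown design {design!r}")
        df["design"] = design
    elif "design" not in df.columns:
        raise TableFormatError("design must be given as an argument or a column")
    bad_design = ~df["design"].isin(DESIGNS)
    if bad_design.any():
        raise TableValidationError(f"unknown designs: {sorted(df['design'][bad_design].unique())}")
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = df["protein_id"]
    df = _convert_ages(df)
    df["channel"] = df["channel"].astype(str).str.upper()
    if not df["channel"].isin(["H", "L"]).all():
        raise TableValidationError("channel must be H or L")
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    if (df["intensity"].dropna() < 0).any():
        raise TableValidationError("intensities must be >= 0 (or missing)")
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    if (df["bio_rep"] < 1).any() or (df["tech_rep"] < 1).any():
        raise TableValidationError("replicate indices start at 1")
    key = ["protein_id", "design", "age_days", "bio_rep", "tech_rep", "channel"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise TableValidationError(
            f"duplicate record for {tuple(dup[k] for k in key)}"
        )
    cols = ["protein_id", "gene_symbol", "design", "age_days", "bio_rep", "tech_rep",
            "channel", "intensity"]
    return df[cols]


def read_volume_table(path) -> pd.DataFrame:
    """Read organ/oocyte volume measurements.

    Accepts either a ``volume`` column or raw dimensions: ``l, w, h`` for
    method ``lwh`` (v = l*w*h) or ``r`` for method ``sphere``
    (v = 4/3 pi r^3).  One volume unit per table (optional ``unit`` column
    is carried through unchanged).
    """
    from lyschase.growth import box_volume, sphere_volume

    df = _read_tsv(path, {"age_days", "method"})
    df = _convert_ages(df)
    method = df["method"].astype(str).str.lower()
    if not method.isin(["lwh", "sphere"]).all():
        raise TableValidationError("method must be 'lwh' or 'sphere'")
    if "unit" in df.columns and df["unit"].nunique() > 1:
        raise TableValidationError("one volume unit per table")
    if "volume" in df.columns:
        vol = df["volume"].astype(float).to_numpy()
    else:
        vol = np.empty(len(df))
        is_box = (method == "lwh").to_numpy()
        if is_box.any():
            for c in ("l", "w", "h"):
                if c not in df.columns:
                    raise TableFormatError(f"method lwh requires column {c!r}")
            sub = df.loc[is_box]
            vol[is_box] = box_volume(sub["l"].astype(float), sub["w"].astype(float),
                                     sub["h"].astype(float))
        if (~is_box).any():
            if "r" not in df.columns:
                raise TableFormatError("method sphere requires column 'r'")
            vol[~is_box] = sphere_volume(df.loc[~is_box, "r"].astype(float))
    if np.any(~np.isfinite(vol)) or np.any(vol <= 0):
        raise TableValidationError("volumes must be positive")
    out = pd.DataFrame({"age_days": df["age_days"], "volume": vol, "method": method})
    return out


def read_abundance_table(path) -> pd.DataFrame:
    """Read normalized DIA relative-abundance profiles (long format)."""
    df = _read_tsv(path, {"protein_id", "age_days", "rep", "rel_abundance"})
    df = _convert_ages(df)
    df["rel_abundance"] = pd.to_numeric(df["rel_abundance"], errors="raise")
    if (df["rel_abundance"].dropna() < 0).any():
        raise TableValidationError("rel_abundance must be >= 0")
    df["rep"] = df["rep"].astype(int)
    return df[["protein_id", "age_days", "rep", "rel_abundance"]]


def read_2lys_table(path) -> pd.DataFrame:
    """Read summed 2Lys missed-cleavage peptide species intensities (HH/HL/LL)."""
    df = _read_tsv(path, {"age_days", "rep", "hh", "hl", "ll"})
    if "design" in df.columns:
        bad = ~df["design"].isin(DESIGNS)
        if bad.any():
            raise TableValidationError(
                f"unknown designs: {sorted(df['design'][bad].unique())}")
    df = _convert_ages(df)
    for c in ("hh", "hl", "ll"):
        df[c] = pd.to_numeric(df[c], errors="raise").fillna(0.0)
        if (df[c] < 0).any():
            raise TableValidationError(f"{c} intensities must be >= 0")
    cols = [c for c in ("design", "age_days", "rep", "hh", "hl", "ll") if c in df.columns]
    return df[cols]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name TAB description TAB members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}:{lineno}: GMT lines need name, description and >=1 member")
            name, _desc, *members = fields
            members = {m for m in members if m}
            if not members:
                raise TableFormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


# --- atlas ----------------------------------------------------------------

ATLAS_COLUMNS = [
    "protein_id", "design", "age_days", "bio_rep", "H", "L", "R", "F_model",
    "halflife_days", "halflife_q5", "halflife_q95", "cluster",
]


def _fmt_halflife(value: float, censored: bool, cap: float) -> str:
    if censored or (isinstance(value, float) and math.isinf(value)):
        return f">{cap:g}"
    return f"{value:.6g}"


def _parse_halflife(text) -> tuple[float, bool]:
    s = str(text)
    if s.startswith(">"):
        return float(s[1:]), True
    return float(s), False


def write_atlas(fits, clusters, series_table: pd.DataFrame, path,
                f_model: pd.DataFrame | None = None, cap: float = 10000.0) -> None:
    """Write the per-protein atlas: measured H/L/R plus model summaries.

    Parameters
    ----------
    fits : mapping protein_id -> TurnoverFit (or object with halflife
        median/q5/q95 and ``censored`` attributes).
    clusters : mapping protein_id -> longevity cluster label (may be empty).
    series_table : aggregated replicate-level table with columns
        protein_id, design, age_days, bio_rep, H, L, R.
    f_model : optional table protein_id, design, age_days, F_model with the
        posterior-median modelled heavy fraction.
    Censored half-lives are written as a ``>cap`` sentinel and re-read as
    censored by :func:`read_atlas`.
    """
    have = set(series_table["protein_id"])
    missing = [pid for pid in fits if pid not in have]
    if missing:
        raise TableValidationError(
            f"proteins in fits but absent from series: {sorted(missing)[:5]}")
    rows = series_table.copy()
    rows = rows[rows["protein_id"].isin(fits.keys())]
    if f_model is not None:
        rows = rows.merge(f_model, on=["protein_id", "design", "age_days"], how="left")
    else:
        rows["F_model"] = np.nan
    med, q5, q95 = {}, {}, {}
    for pid, fit in fits.items():
        cen = bool(getattr(fit, "censored", False))
        med[pid] = _fmt_halflife(fit.halflife_median, cen, cap)
        q5[pid] = _fmt_halflife(fit.halflife_q5, False, cap)
        q95[pid] = _fmt_halflife(fit.halflife_q95, cen or math.isinf(fit.halflife_q95), cap)
    rows["halflife_days"] = rows["protein_id"].map(med)
    rows["halflife_q5"] = rows["protein_id"].map(q5)
    rows["halflife_q95"] = rows["protein_id"].map(q95)
    rows["cluster"] = rows["protein_id"].map(dict(clusters)).fillna("")
    rows = rows[ATLAS_COLUMNS].sort_values(
        ["protein_id", "design", "age_days", "bio_rep"], kind="mergesort")
    rows.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_atlas(path) -> pd.DataFrame:
    """Read an atlas table back; adds boolean ``censored`` from the sentinel."""
    df = _read_tsv(path, set(ATLAS_COLUMNS))
    parsed = df["halflife_days"].map(_parse_halflife)
    df["censored"] = [c for _, c in parsed]
    df["halflife_days"] = [v for v, _ in parsed]
    for col in ("halflife_q5", "halflife_q95"):
        df[col] = [v for v, _ in df[col].map(_parse_halflife)]
    df["cluster"] = df["cluster"].fillna("")
    return df
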