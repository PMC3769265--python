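"""From raw weighings to analysis-ready adjusted weights.

Beef-cattle breeding programs evaluate standardized weights rather than raw
weighings taken at whatever age the animal happened to be handled.  A raw
record carries birth weight (BW), weaning weight (WW) with its age, and the
last adult weight (AW) with its age; from these, weights adjusted to 120,
240, 365 and 450 days of age are obtained by linear interpolation on the
average daily gains:

    pre-WWG  = (WW - BW) / weaning_age
    W120     = BW + 120 * pre-WWG
    W240     = BW + 240 * pre-WWG
    post-WWG = (AW - W240) / (age at last weighing - 240)
    W365     = W240 + 125 * post-WWG
    W450     = W240 + 210 * post-WWG

Consistency filtering then removes trait values outside three standard
deviations of the trait mean, codes contemporary groups (herd x birth-year x
birth-season quarter), and drops trait values in contemporary groups with
fewer than three records or from progeny of sires with fewer than three
recorded offspring.  The full stage order is: adjusted weights -> outlier
filter -> contemporary-group coding -> group-size rule -> sire-count rule,
with per-stage record counts logged so the pipeline can be audited.

All functions operate on pandas DataFrames with the documented column names;
``TRAITS = ["w120", "w240", "w365", "w450"]`` throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("willham.preprocess")

TRAITS = ["w120", "w240", "w365", "w450"]

RAW_COLUMNS = [
    "animal", "sire", "dam", "herd", "birth_date", "sex", "dam_age",
    "bw", "ww", "weaning_age", "aw", "last_age",
]

__all__ = [
    "TRAITS",
    "RAW_COLUMNS",
    "FilterReport",
    "adjusted_weights",
    "contemporary_groups",
    "filter_outliers",
    "filter_structure",
    "screen_fixed_effects",
    "preprocess_records",
    "read_records",
    "write_records",
]


@dataclass
class FilterReport:
    """Per-stage record and trait-value counts, for auditing the pipeline."""

    stages: list[dict] = field(default_factory=list)

    def log_stage(self, name: str, df: pd.DataFrame) -> None:
        counts = {t: int(df[t].notna().sum()) for t in TRAITS if t in df}
        self.stages.append({"stage": name, "n_records": len(df), **counts})
        logger.info("stage %-18s records=%d traits=%s", name, len(df), counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def adjusted_weights(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute W120..W450; returns (kept records with traits, excluded rows).

    Missing raw inputs propagate to missing adjusted weights without error.
    Structurally impossible rows (non-positive weaning age, last weighing at
    or before 240 d, weaning weight below birth weight) are excluded whole,
    with a reason column on the returned exclusions frame.
    """
    df = records.copy()
    for c in ("bw", "ww", "weaning_age", "aw", "last_age", "dam_age"):
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce")

    reason = pd.Series("", index=df.index, dtype=object)
    bad_wa = df["weaning_age"].notna() & (df["weaning_age"] <= 0)
    bad_ia = df["last_age"].notna() & (df["last_age"] <= 240)
    bad_ww = df["ww"].notna() & df["bw"].notna() & (df["ww"] < df["bw"])
    reason[bad_wa] = "weaning_age <= 0"
    reason[bad_ia] = "last_age <= 240 d"
    reason[bad_ww] = "ww < bw"
    invalid = reason != ""
    excluded = df[invalid].assign(reason=reason[invalid])
    for _, row in excluded.iterrows():
        logger.warning("record %s excluded: %s", row.get("animal"), row["reason"])
    df = df[~invalid].copy()

    pre = (df["ww"] - df["bw"]) / df["weaning_age"]
    df["w120"] = df["bw"] + 120.0 * pre
    df["w240"] = df["bw"] + 240.0 * pre
    post = (df["aw"] - df["w240"]) / (df["last_age"] - 240.0)
    df["w365"] = df["w240"] + 125.0 * post
    df["w450"] = df["w240"] + 210.0 * post
    return df, excluded


_QUARTER = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2, 7: 3, 8: 3, 9: 3, 10: 4, 11: 4, 12: 4}


def contemporary_groups(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign contemporary-group codes ``herd-year-season``.

    Season of birth is the calendar quarter (Jan-Mar = 1 ... Oct-Dec = 4).
    Rows lacking herd or a parseable birth date are excluded with a reason.
    """
    df = records.copy()
    dates = pd.to_datetime(df["birth_date"], errors="coerce")
    herd = df["herd"].astype(str).str.strip().replace({"": None, "nan": None})
    bad = dates.isna() | herd.isna()
    excluded = df[bad].assign(reason="missing herd or birth date")
    if bad.any():
        logger.warning("%d records lack herd/birth date; excluded", int(bad.sum()))
    df = df[~bad].copy()
    dates = dates[~bad]
    season = dates.dt.month.map(_QUARTER)
    df["cg"] = (
        herd[~bad].astype(str) + "-" + dates.dt.year.astype(str) + "-" + season.astype(str)
    )
    return df, excluded


def filter_outliers(records: pd.DataFrame, trait: str, k: float = 3.0) -> pd.DataFrame:
    """Blank trait values more than ``k`` sample SDs from the trait mean.

    One pass: mean and SD are computed over all non-missing values including
    any outliers.  A zero SD (all values identical) removes nothing.
    """
    df = records.copy()
    x = df[trait]
    n = int(x.notna().sum())
    if n == 0:
        logger.warning("trait %s empty; outlier filter skipped", trait)
        return df
    if n < 2:
        return df
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return df
    out = x.notna() & ((x - mu).abs() > k * sd)
    if out.any():
        logger.info("trait %s: %d values beyond %.1f SD removed", trait, int(out.sum()), k)
    df.loc[out, trait] = np.nan
    return df


def filter_structure(
    records: pd.DataFrame,
    min_cg: int = 3,
    min_sire_offspring: int = 3,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Apply the group-size and sire-progeny rules, once each, in that order.

    Per trait: blank values in contemporary groups holding fewer than
    ``min_cg`` non-missing records for that trait; then blank values of
    progeny of sires with fewer than ``min_sire_offspring`` offspring
    carrying the trait.  No iteration — a group reduced below the threshold
    by the sire rule is kept.
    """
    df = records.copy()
    for t in traits or TRAITS:
        if t not in df:
            continue
        has = df[t].notna()
        small = df["cg"].map(df.loc[has].groupby("cg")[t].count()).fillna(0) < min_cg
        df.loc[has & small, t] = np.nan

        has = df[t].notna()
        sire = df["sire"].astype(str)
        known = sire.notna() & (sire != "0") & (sire != "nan")
        sire_n = df.loc[has & known].groupby("sire")[t].count()
        few = known & (df["sire"].map(sire_n).fillna(0) < min_sire_offspring)
        df.loc[has & few, t] = np.nan
    return df


def _dummies(col: pd.Series) -> np.ndarray:
    lv = pd.unique(col.astype(str))
    return (col.astype(str).to_numpy()[:, None] == lv[1:][None, :]).astype(float)


def screen_fixed_effects(
    records: pd.DataFrame,
    trait: str,
    effects: tuple[str, ...] = ("sex", "herd", "year_season", "dam_age"),
) -> pd.DataFrame:
    """Partial F-tests of each fixed effect on one trait.

    Fits the trait on all effects jointly by least squares, then drops one
    effect at a time: F = (dSSE/ddf) / MSE_full, with degrees of freedom from
    matrix ranks so aliased (rank-deficient) columns are handled.  ``sex``,
    ``herd`` and ``year_season`` enter as factors, ``dam_age`` as a linear
    covariate.  Factors with a single observed level are excluded with a
    warning.  Returns a frame with columns effect, df, F, p.
    """
    df = records[records[trait].notna()].copy()
    if "year_season" not in df and "birth_date" in df:
        dates = pd.to_datetime(df["birth_date"], errors="coerce")
        df["year_season"] = dates.dt.year.astype(str) + "-" + dates.dt.month.map(_QUARTER).astype(str)
    y = df[trait].to_numpy(float)
    n = len(y)

    blocks: dict[str, np.ndarray] = {}
    for eff in effects:
        if eff not in df:
            continue
        if eff == "dam_age":
            x = pd.to_numeric(df[eff], errors="coerce").to_numpy(float)
            if np.isnan(x).any() or np.ptp(x) == 0:
                logger.warning("covariate %s constant or missing; excluded", eff)
                continue
            blocks[eff] = (x - x.mean())[:, None]
        else:
            if df[eff].astype(str).nunique() < 2:
                logger.warning("factor %s has a single level; excluded", eff)
                continue
            blocks[eff] = _dummies(df[eff])

    def fit(cols: list[str]) -> tuple[float, int]:
        X = np.hstack([np.ones((n, 1))] + [blocks[c] for c in cols])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), int(rank)

    names = list(blocks)
    sse_full, rank_full = fit(names)
    dfe = n - rank_full
    if dfe <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    mse = sse_full / dfe

    rows = []
    for eff in names:
        sse_red, rank_red = fit([c for c in names if c != eff])
        ddf = rank_full - rank_red
        if ddf == 0:
            logger.warning("effect %s aliased with others; dropped from table", eff)
            continue
        num = max(sse_red - sse_full, 0.0) / ddf
        # perfect fits: an effect explaining nothing on top of an exact model
        if num <= 1e-12 * max(sse_red, 1.0):
            F = 0.0
        elif mse == 0.0:
            F = np.inf
        else:
            F = num / mse
        rows.append({"effect": eff, "df": ddf, "F": F, "p": float(stats.f.sf(F, ddf, dfe))})
    return pd.DataFrame(rows)


def preprocess_records(
    records: pd.DataFrame,
    k_sd: float = 3.0,
    min_cg: int = 3,
    min_sire_offspring: int = 3,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the whole preprocessing pipeline on raw records.

    Stage order: adjusted weights -> per-trait 3-SD outlier filter ->
    contemporary-group coding -> group-size rule -> sire-count rule.
    Records left with no trait values are dropped at the end.
    """
    report = FilterReport()
    report.log_stage("raw", records)
    df, _ = adjusted_weights(records)
    report.log_stage("adjusted", df)
    for t in TRAITS:
        df = filter_outliers(df, t, k=k_sd)
    report.log_stage("outliers", df)
    df, _ = contemporary_groups(df)
    report.log_stage("cg_coded", df)
    cg_only = filter_structure(df, min_cg=min_cg, min_sire_offspring=0)
    report.log_stage("cg_size", cg_only)
    df = filter_structure(df, min_cg=min_cg, min_sire_offspring=min_sire_offspring)
    report.log_stage("sire_count", df)
    df = df[df[TRAITS].notna().any(axis=1)].copy()
    report.log_stage("final", df)
    keep = ["animal", "sire", "dam", "sex", "dam_age", "cg"] + TRAITS
    return df[[c for c in keep if c in df]], report


def read_records(path) -> pd.DataFrame:
    """Read a raw phenotype file (comma or tab delimited, empty = missing)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.replace("", np.nan)
    for c in ("dam_age", "bw", "ww", "weaning_age", "aw", "last_age") + tuple(TRAITS):
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
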