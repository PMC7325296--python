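"""Data ingestion, sample preparation, descriptive tables and orchestration.

The analysis sample is the subset of surveyed households with positive
tobacco expenditure in the reference month; the outcome TEHB is tobacco
expenditure as a percentage of total monthly household expenditure.
``run_pipeline`` chains ingestion, the positive-expenditure filter, the PCA
wealth index, fractional ranks, descriptives, national and subgroup
concentration indices, concentration-curve coordinates and the Wagstaff
decomposition, writing every table as delimited text plus a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import HDI_CATEGORIES, RunConfig
from .decompose import decompose, expand_covariates
from .inequality import concentration_curve, subgroup_concentration
from .wealth import fit_wealth_index, fractional_rank, score_and_classify

__all__ = [
    "ValidationError",
    "load_households",
    "prepare_analysis_sample",
    "descriptive_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "household_id", "head_age", "head_female", "head_illiterate", "hh_size",
    "prop_male", "urban", "province_id", "total_expenditure",
    "tobacco_expenditure",
)


class ValidationError(ValueError):
    """Schema violation in input microdata; message cites row numbers."""


def _bad_rows(mask: pd.Series, limit: int = 10) -> str:
    rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:limit]]
    return f"rows {rows}" + ("..." if mask.sum() > limit else "")


def load_households(path: str | Path,
                    hdi_lookup_path: str | Path | None = None
                    ) -> pd.DataFrame:
    """Read and validate a household microdata CSV.

    The optional lookup file must have columns ``province_id`` and
    ``hdi_category`` and is joined onto the table; a table that already
    carries ``hdi_category`` can be loaded without one.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")

    numeric = ["head_age", "hh_size", "prop_male", "total_expenditure",
               "tobacco_expenditure"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric values in {col!r}: {_bad_rows(bad)}")
        df[col] = coerced

    na = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    if na.any():
        raise ValidationError(f"missing values: {_bad_rows(na)}")

    checks = [
        (df["total_expenditure"] <= 0, "total_expenditure must be > 0"),
        (df["tobacco_expenditure"] < 0, "tobacco_expenditure must be >= 0"),
        (df["tobacco_expenditure"] > df["total_expenditure"],
         "tobacco_expenditure exceeds total_expenditure"),
        (df["hh_size"] < 1, "hh_size must be >= 1"),
        (~df["prop_male"].between(0, 100), "prop_male must lie in [0, 100]"),
    ]
    for mask, msg in checks:
        if mask.any():
            raise ValidationError(f"{msg}: {_bad_rows(mask)}")

    if hdi_lookup_path is not None:
        lookup = pd.read_csv(hdi_lookup_path)
        for col in ("province_id", "hdi_category"):
            if col not in lookup.columns:
                raise ValidationError(f"HDI lookup lacks column {col!r}")
        unknown_cat = ~lookup["hdi_category"].isin(HDI_CATEGORIES)
        if unknown_cat.any():
            raise ValidationError(
                f"HDI lookup has categories outside {HDI_CATEGORIES}")
        df = df.drop(columns=["hdi_category"], errors="ignore")
        merged = df.merge(lookup[["province_id", "hdi_category"]],
                          on="province_id", how="left", validate="m:1")
        bad = merged["hdi_category"].isna()
        if bad.any():
            provs = sorted(merged.loc[bad, "province_id"].unique().tolist())
            raise ValidationError(
                f"province id(s) absent from HDI lookup: {provs}")
        df = merged
    elif "hdi_category" not in df.columns:
        raise ValidationError(
            "no hdi_category column and no HDI lookup provided")
    return df


def prepare_analysis_sample(table: pd.DataFrame
                            ) -> tuple[pd.DataFrame, int]:
    """Derive TEHB (%) and keep households with positive tobacco expenditure.

    Returns the analysis subsample and the number of rows dropped by the
    positive-expenditure filter (also logged).
    """
    df = table.copy()
    df["tehb"] = 100.0 * df["tobacco_expenditure"] / df["total_expenditure"]
    keep = df["tobacco_expenditure"] > 0
    dropped = int((~keep).sum())
    out = df[keep].reset_index(drop=True)
    if out.empty:
        raise ValidationError("no households with positive tobacco "
                              "expenditure; analysis sample is empty")
    assert len(out) + dropped == len(table)  # row-count conservation
    log.info("analysis sample: retained %d of %d households (%d dropped)",
             len(out), len(table), dropped)
    return out, dropped


_STRATA_BUILDERS = {
    "head_sex": lambda d: np.where(d["head_female"] == 1, "Female", "Male"),
    "education": lambda d: np.where(d["head_illiterate"] == 1,
                                    "Illiterate", "Literate"),
    "hh_size_class": lambda d: np.where(d["hh_size"] >= 4,
                                        "4 and above", "Less than 4"),
    "area": lambda d: np.where(d["urban"] == 1, "Urban", "Rural"),
}


def descriptive_table(table: pd.DataFrame,
                      strata: list[str]) -> pd.DataFrame:
    """Stratified descriptives of TEHB: n, %, mean and SD per level.

    Derived strata (``head_sex``, ``education``, ``hh_size_class``,
    ``area``) are built on the fly; any existing column (e.g.
    ``wealth_quintile``, ``hdi_category``) can be used directly.  The
    p-value column is left empty by design.  The SD of a single-household
    level is reported as 0 and flagged in the log.
    """
    df = table.copy()
    records = [{
        "variable": "Overall", "level": "", "n": len(df), "pct": 100.0,
        "tehb_mean": float(df["tehb"].mean()),
        "tehb_sd": float(df["tehb"].std(ddof=1)) if len(df) > 1 else 0.0,
        "p_value": "",
    }]
    for stratum in strata:
        if stratum in _STRATA_BUILDERS:
            df[stratum] = _STRATA_BUILDERS[stratum](df)
        elif stratum not in df.columns:
            raise KeyError(f"unknown stratum column: {stratum!r}")
        for level, sub in df.groupby(stratum, sort=True, observed=True):
            if len(sub) == 1:
                log.warning("stratum %s=%r holds a single household; "
                            "SD reported as 0", stratum, level)
                sd = 0.0
            else:
                sd = float(sub["tehb"].std(ddof=1))
            records.append({
                "variable": stratum, "level": str(level), "n": len(sub),
                "pct": 100.0 * len(sub) / len(df),
                "tehb_mean": float(sub["tehb"].mean()),
                "tehb_sd": sd, "p_value": "",
            })
    return pd.DataFrame.from_records(records)


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "subgroup": r.subgroup_label, "n": r.n, "c_hat": r.c_hat,
        "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high, "mu": r.mu,
    } for r in results])


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write all output tables.

    Stages: load -> positive-expenditure filter -> PCA wealth index ->
    scores/quintiles/ranks -> descriptive table -> national + subgroup
    concentration indices -> concentration curves -> decomposition.
    Outputs (CSV unless noted): scored_households, descriptives,
    concentration_indices, concentration_curves, decomposition, run_log
    (JSON).  Any stage failure aborts with the stage name in the message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        raw = load_households(config.households_path, config.hdi_lookup_path)

        stage = "prepare"
        sample, dropped = prepare_analysis_sample(raw)

        stage = "wealth_index"
        indicators = (list(config.indicators) if config.indicators
                      else sorted((c for c in sample.columns
                                   if c.startswith("asset_")),
                                  key=lambda c: int(c.split("_")[1])))
        model = fit_wealth_index(sample, indicators)
        scored = score_and_classify(sample, model)
        scored["frac_rank"] = fractional_rank(
            scored["wealth_score"].to_numpy())

        stage = "descriptives"
        desc = descriptive_table(
            scored, ["head_sex", "education", "hh_size_class",
                     "wealth_quintile", "area", "hdi_category"])

        stage = "concentration"
        frames, curves = [], []
        national = subgroup_concentration(scored, "urban",
                                          outcome=config.outcome)
        frames.append(_results_frame(national))
        for col in config.subgroup_columns:
            if col == "urban":
                continue
            frames.append(_results_frame(
                subgroup_concentration(scored, col,
                                       outcome=config.outcome)[1:]))
        cindex = pd.concat(frames, ignore_index=True)

        curve_nat = concentration_curve(scored[config.outcome],
                                        scored["frac_rank"])
        curves.append(pd.DataFrame({"subgroup": "national",
                                    "p": curve_nat.p, "L": curve_nat.L}))
        for col in config.subgroup_columns:
            for level, sub in scored.groupby(col, sort=True, observed=True):
                rs = fractional_rank(sub["wealth_score"].to_numpy())
                cur = concentration_curve(sub[config.outcome], rs)
                curves.append(pd.DataFrame(
                    {"subgroup": f"{col}={level}", "p": cur.p, "L": cur.L}))
        curve_df = pd.concat(curves, ignore_index=True)

        stage = "decomposition"
        expanded, covariates, groups = expand_covariates(scored)
        table = decompose(expanded, covariates,
                          expanded["frac_rank"].to_numpy(),
                          outcome=config.outcome, groups=groups)
        decomp_df = table.to_frame()
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    paths = {
        "scored_households": out_dir / "scored_households.csv",
        "descriptives": out_dir / "descriptives.csv",
        "concentration_indices": out_dir / "concentration_indices.csv",
        "concentration_curves": out_dir / "concentration_curves.csv",
        "decomposition": out_dir / "decomposition.csv",
        "run_log": out_dir / "run_log.json",
    }
    scored.to_csv(paths["scored_households"], index=False)
    desc.to_csv(paths["descriptives"], index=False)
    cindex.to_csv(paths["concentration_indices"], index=False)
    curve_df.to_csv(paths["concentration_curves"], index=False)
    decomp_df.to_csv(paths["decomposition"], index=False)

    run_log = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "rows_in": int(len(raw)),
        "rows_retained": int(len(sample)),
        "rows_dropped": dropped,
        "indicators": indicators,
        "variance_explained": model.variance_explained,
        "national_c": float(national[0].c_hat),
    }
    paths["run_log"].write_text(json.dumps(run_log, indent=2, default=str))
    log.info("pipeline complete; outputs in %s", out_dir)
    return paths
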