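"""Wagstaff decomposition of the concentration index into covariate shares.

Given a linear outcome model y = alpha + sum_k beta_k x_k + eps, the
concentration index of y decomposes exactly as

    C = sum_k (beta_k * xbar_k / mu) * C_k  +  GC_eps / mu

where C_k is the covariate's own concentration index against the common
wealth rank, beta_k*xbar_k/mu its elasticity, and GC_eps = 2*cov(eps, r)
the generalized concentration index of the residual.  Because OLS residuals
make y - eps an exact linear combination of the x_k, the identity holds to
machine precision when every term uses the same ranks and the covariance
form of the index.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DecompositionRow",
    "DecompositionTable",
    "fit_outcome_model",
    "covariate_concentration_indices",
    "decompose",
    "table3_check",
    "expand_covariates",
    "significance_stars",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class DecompositionRow:
    variable: str
    group: str
    beta: float
    p_value: float
    xbar: float
    elasticity: float
    c_k: float
    abs_contribution: float
    rel_contribution_pct: float


@dataclasses.dataclass
class DecompositionTable:
    rows: list[DecompositionRow]
    residual: float          # GC_eps / mu
    total_c: float           # covariance-form index of the outcome
    sum_contributions: float
    sum_rel_pct: float
    residual_rel_pct: float

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with Sum / Residual / Total footer rows."""
        recs = [dataclasses.asdict(r) for r in self.rows]
        body = pd.DataFrame.from_records(recs)
        footer = pd.DataFrame([
            {"variable": "Sum", "abs_contribution": self.sum_contributions,
             "rel_contribution_pct": self.sum_rel_pct},
            {"variable": "Residual", "abs_contribution": self.residual,
             "rel_contribution_pct": self.residual_rel_pct},
            {"variable": "Total", "abs_contribution": self.total_c,
             "rel_contribution_pct": 100.0},
        ])
        return pd.concat([body, footer], ignore_index=True)


def significance_stars(p: float) -> str:
    """Three-level star convention: ***1%, **5%, *10%."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def _pop_cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a * b) - a.mean() * b.mean())


def _find_collinear(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns (beyond the constant) that do not add rank, in order."""
    bad, cols = [], [np.ones(x.shape[0])]
    rank = 1
    for j, name in enumerate(names):
        cand = np.column_stack(cols + [x[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r == rank:
            bad.append(name)
        else:
            cols.append(x[:, j])
            rank = r
    return bad


def fit_outcome_model(table: pd.DataFrame, covariates: list[str],
                      outcome: str = "tehb", cov_type: str = "HC1"):
    """OLS of the outcome on pre-coded numeric covariates (with intercept).

    Categorical covariates must be pre-expanded to reference-coded
    indicators (see :func:`expand_covariates`).  Robust (HC1) standard
    errors drive the significance stars by default.
    """
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise KeyError(f"missing covariate column(s): {missing}")
    if outcome not in table.columns:
        raise KeyError(f"missing outcome column: {outcome!r}")
    x = table[covariates].to_numpy(dtype=float)
    X = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _find_collinear(x, list(covariates))
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    y = table[outcome].to_numpy(dtype=float)
    return sm.OLS(y, X).fit(cov_type=cov_type)


def covariate_concentration_indices(table: pd.DataFrame,
                                    covariates: list[str],
                                    rank) -> dict[str, float]:
    """Covariance-form concentration index of each covariate vs the common rank.

    C_k = 2*cov(x_k, r)/xbar_k.  A covariate with zero mean has no defined
    index; it is reported as NaN with a warning.
    """
    r = np.asarray(rank, dtype=float)
    if len(r) != len(table):
        raise ValueError("rank must be aligned to the table")
    out: dict[str, float] = {}
    for c in covariates:
        x = table[c].to_numpy(dtype=float)
        xbar = x.mean()
        if xbar == 0.0:
            log.warning("covariate %r has zero mean; its C_k is undefined", c)
            out[c] = float("nan")
        else:
            out[c] = 2.0 * _pop_cov(x, r) / xbar
    return out


def decompose(table: pd.DataFrame, covariates: list[str], rank,
              outcome: str = "tehb",
              groups: dict[str, str] | None = None,
              cov_type: str = "HC1") -> DecompositionTable:
    """Full Wagstaff decomposition of the outcome's concentration index.

    The residual term is computed from the OLS residuals as 2*cov(eps, r)/mu
    (not by subtraction), which makes the adding-up identity exact; the
    identity is still verified and a violation beyond 1e-8 raises.
    """
    groups = groups or {}
    fit = fit_outcome_model(table, covariates, outcome=outcome,
                            cov_type=cov_type)
    r = np.asarray(rank, dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    mu = float(y.mean())
    if mu == 0.0:
        raise ValueError("outcome mean is zero; decomposition undefined")
    total_c = 2.0 * _pop_cov(y, r) / mu
    c_ks = covariate_concentration_indices(table, covariates, r)

    rows: list[DecompositionRow] = []
    for j, name in enumerate(covariates):
        beta = float(fit.params[j + 1])
        x = table[name].to_numpy(dtype=float)
        xbar = float(x.mean())
        c_k = c_ks[name]
        if np.isfinite(c_k):
            elasticity = beta * xbar / mu
            abs_contribution = elasticity * c_k
        else:
            # zero-mean covariate: contribution still defined via covariance
            elasticity = float("nan")
            abs_contribution = 2.0 * beta * _pop_cov(x, r) / mu
        rel = (100.0 * abs_contribution / total_c if total_c != 0.0
               else float("nan"))
        rows.append(DecompositionRow(
            variable=name,
            group=groups.get(name, ""),
            beta=beta,
            p_value=float(fit.pvalues[j + 1]),
            xbar=xbar,
            elasticity=elasticity,
            c_k=c_k,
            abs_contribution=abs_contribution,
            rel_contribution_pct=rel,
        ))

    eps = y - np.asarray(fit.fittedvalues, dtype=float)
    residual = 2.0 * _pop_cov(eps, r) / mu
    total_contrib = float(sum(row.abs_contribution for row in rows))
    gap = abs(total_contrib + residual - total_c)
    if gap > 1e-8:
        raise AssertionError(
            f"adding-up identity violated by {gap:.3e}; "
            "check rank alignment and covariate coding")
    if total_c != 0.0:
        sum_rel = 100.0 * total_contrib / total_c
        res_rel = 100.0 * residual / total_c
    else:
        sum_rel = res_rel = float("nan")
    return DecompositionTable(
        rows=rows,
        residual=residual,
        total_c=total_c,
        sum_contributions=total_contrib,
        sum_rel_pct=sum_rel,
        residual_rel_pct=res_rel,
    )


def table3_check(elasticity: float, c_k: float,
                 total_c: float) -> tuple[float, float]:
    """Audit helper: (absolute, relative %) contribution from printed inputs.

    Pure arithmetic on already-estimated elasticity and covariate index;
    used to verify the internal consistency of published decomposition
    tables cell by cell.
    """
    if total_c == 0.0:
        raise ValueError("total concentration index must be nonzero")
    abs_contribution = elasticity * c_k
    return abs_contribution, 100.0 * abs_contribution / total_c


# reference coding used throughout: male head, literate head, household size
# < 4, poorest quintile, urban area, low-HDI province are the baselines
_GROUPS = {
    "head_age": "demographic",
    "head_female": "demographic",
    "prop_male": "demographic",
    "hh_size_4plus": "socioeconomic",
    "head_illiterate": "socioeconomic",
    "quintile_2": "socioeconomic",
    "quintile_3": "socioeconomic",
    "quintile_4": "socioeconomic",
    "quintile_5": "socioeconomic",
    "rural": "ecological",
    "hdi_middle": "ecological",
    "hdi_high": "ecological",
}


def expand_covariates(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str],
                                                    dict[str, str]]:
    """Standard covariate coding for the decomposition.

    Returns (table-with-indicator-columns, covariate order, group labels).
    Requires a scored table (``wealth_quintile`` present).
    """
    need = ["head_age", "head_female", "head_illiterate", "hh_size",
            "prop_male", "urban", "hdi_category", "wealth_quintile"]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise KeyError(f"cannot build covariates; missing: {missing}")
    out = table.copy()
    out["hh_size_4plus"] = (out["hh_size"] >= 4).astype(int)
    for q in (2, 3, 4, 5):
        out[f"quintile_{q}"] = (out["wealth_quintile"] == q).astype(int)
    out["rural"] = 1 - out["urban"].astype(int)
    out["hdi_middle"] = (out["hdi_category"] == "middle").astype(int)
    out["hdi_high"] = (out["hdi_category"] == "high").astype(int)
    order = ["head_age", "head_female", "prop_male", "hh_size_4plus",
             "head_illiterate", "quintile_2", "quintile_3", "quintile_4",
             "quintile_5", "rural", "hdi_middle", "hdi_high"]
    return out, order, dict(_GROUPS)
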