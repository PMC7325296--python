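"""Asset-based wealth index, SES quintiles, and fractional ranks.

The socioeconomic ranking behind all inequality measures in this package is
the classic asset-index construction: standardize a set of household asset
and housing indicators, take the first principal component as the wealth
score, orient it so that higher means richer, and classify households into
population-share quintiles.  Fractional ranks of the score feed the
convenient-regression concentration index.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "WealthModel",
    "fit_wealth_index",
    "score_and_classify",
    "fractional_rank",
]


@dataclasses.dataclass
class WealthModel:
    """Fitted first-principal-component wealth index.

    ``loadings`` has unit Euclidean norm; ``orientation`` (+1/-1) is chosen
    so the oriented score correlates positively with the plain sum of the
    indicators, i.e. higher score = richer.  ``quintile_cuts`` are the
    20/40/60/80 percentiles of the oriented training scores, kept as
    model metadata for scoring new data against the training distribution.
    """

    indicator_names: list[str]
    indicator_means: np.ndarray
    indicator_scales: np.ndarray
    loadings: np.ndarray
    orientation: int
    variance_explained: float
    quintile_cuts: np.ndarray

    def score(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.indicator_names if c not in table.columns]
        if missing:
            raise KeyError(f"missing indicator column(s): {missing}")
        x = table[self.indicator_names].to_numpy(dtype=float)
        z = (x - self.indicator_means) / self.indicator_scales
        # column-wise accumulation instead of BLAS matmul: identical rows
        # then give bit-identical scores, so exact ties stay exact ties
        s = np.zeros(len(z))
        for k in range(z.shape[1]):
            s += self.loadings[k] * z[:, k]
        return self.orientation * s

    # flat text serialisation: one key per line, vectors comma-separated
    def to_file(self, path: str | Path) -> None:
        def vec(v) -> str:
            return ",".join(repr(float(x)) for x in np.asarray(v, float))

        lines = [
            "indicator_names=" + ",".join(self.indicator_names),
            "indicator_means=" + vec(self.indicator_means),
            "indicator_scales=" + vec(self.indicator_scales),
            "loadings=" + vec(self.loadings),
            f"orientation={self.orientation}",
            f"variance_explained={self.variance_explained!r}",
            "quintile_cuts=" + vec(self.quintile_cuts),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "WealthModel":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                k, _, v = line.partition("=")
                kv[k] = v
        arr = lambda s: np.array([float(x) for x in kv[s].split(",")])
        return cls(
            indicator_names=kv["indicator_names"].split(","),
            indicator_means=arr("indicator_means"),
            indicator_scales=arr("indicator_scales"),
            loadings=arr("loadings"),
            orientation=int(kv["orientation"]),
            variance_explained=float(kv["variance_explained"]),
            quintile_cuts=arr("quintile_cuts"),
        )


def fit_wealth_index(table: pd.DataFrame,
                     indicators: list[str]) -> WealthModel:
    """Fit the PCA wealth index on standardized indicators.

    Standardization to zero mean / unit variance makes this a correlation-
    matrix PCA, appropriate when indicators mix counts, areas and binaries.
    """
    if len(indicators) < 2:
        raise ValueError("need at least 2 indicator columns")
    missing = [c for c in indicators if c not in table.columns]
    if missing:
        raise KeyError(f"missing indicator column(s): {missing}")
    x = table[indicators].to_numpy(dtype=float)
    n, k = x.shape
    if n <= k:
        raise ValueError(
            f"need more households ({n}) than indicators ({k}) to fit a PCA")
    means = x.mean(axis=0)
    scales = x.std(axis=0)  # population SD; affine-invariance, not inference
    zero = [name for name, s in zip(indicators, scales) if s == 0.0]
    if zero:
        raise ValueError(f"zero-variance indicator(s): {zero}")
    z = (x - means) / scales

    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(z)[:, 0]
    loadings = pca.components_[0]
    loadings = loadings / np.linalg.norm(loadings)

    # PCA sign is arbitrary; orient so score rises with total ownership
    asset_sum = x.sum(axis=1)
    corr = np.corrcoef(scores, asset_sum)[0, 1] if asset_sum.std() > 0 else 0.0
    orientation = -1 if corr < 0 else 1

    model = WealthModel(
        indicator_names=list(indicators),
        indicator_means=means,
        indicator_scales=scales,
        loadings=loadings,
        orientation=orientation,
        variance_explained=float(pca.explained_variance_ratio_[0]),
        quintile_cuts=np.zeros(4),
    )
    # cut points from the model's own scoring path so that re-scoring the
    # training data reproduces them exactly
    model.quintile_cuts = np.quantile(model.score(table), [0.2, 0.4, 0.6, 0.8])
    return model


def score_and_classify(table: pd.DataFrame,
                       model: WealthModel) -> pd.DataFrame:
    """Append ``wealth_score`` and ``wealth_quintile`` (1=poorest..5=richest).

    Quintiles are population-share quintiles of the score: with distinct
    scores each class holds ~n/5 households.  Tied scores share the quintile
    of their mean sorted position, so identical households always land in
    the same class (all-identical input collapses to a single quintile) and
    class sizes differ only by boundary-tie counts.
    """
    out = table.copy()
    scores = model.score(table)
    n = len(scores)
    if n == 0:
        raise ValueError("empty table")
    mean_pos = stats.rankdata(scores, method="average")
    quintile = np.ceil(5.0 * mean_pos / n).astype(int)
    out["wealth_score"] = scores
    out["wealth_quintile"] = np.clip(quintile, 1, 5)
    return out


def fractional_rank(scores, n: int | None = None,
                    convention: str = "i_over_n") -> np.ndarray:
    """Fractional SES rank r_i in (0, 1], aligned to input order.

    ``i_over_n`` (default): the household at ascending sorted position i
    gets i/n; ties get the mean of their positions over n.  ``midpoint``:
    the common alternative (2i-1)/(2n) = (i - 0.5)/n, a constant shift of
    1/(2n) that leaves any covariance-based index unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if n is None:
        n = scores.size
    if n != scores.size:
        raise ValueError(f"n={n} does not match {scores.size} scores")
    pos = stats.rankdata(scores, method="average")
    if convention == "i_over_n":
        return pos / n
    if convention == "midpoint":
        return (pos - 0.5) / n
    raise ValueError(f"unknown rank convention: {convention!r}")
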