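"""Residual analysis of differential promoter binding.

The procedure: promoter activity scores in a reference stage (G1) and a
stressed stage (HU) are compared across all genes by ordinary least squares
of HU on G1.  The fit absorbs global, sample-wide differences in binding
level (protein abundance, batch effects); per-gene deviation from the fitted
trend — the residual — ranks dynamic binding.  The top-K genes by absolute
residual, after excluding genes whose unit-max-scaled score falls below a
minimal-signal floor in either stage, are the differential-binding (DB)
calls.  Two independent experiments are intersected to obtain a
high-confidence DB set.

The analysis is exposed as a statsmodels-style model:

>>> model = PromoterBindingShift(g1_scores, hu_scores)
>>> res = model.fit(top_k=1000)
>>> res.selection.genes  # ordered top-DB gene ids
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError

DEFAULT_TOP_K = 1000
DEFAULT_MIN_SIGNAL = -0.075


def scale_to_unit_max(scores: pd.Series) -> pd.Series:
    """Divide scores by the sample maximum (must be > 0); negatives preserved."""
    m = float(scores.max())
    if not np.isfinite(m) or m <= 0:
        raise DegenerateInputError(f"cannot scale: maximal score {m} is not positive")
    return scores / m


def fit_db_regression(x: pd.Series, y: pd.Series) -> Tuple[float, float, pd.DataFrame]:
    """OLS of y (HU) on x (G1) over the shared genes.

    Returns (slope, intercept, residual table) with columns
    x, y, fitted, residual, direction, abs_rank.
    """
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise DegenerateInputError("need at least 3 shared genes for the regression")
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    if np.allclose(xv, xv[0]):
        raise DegenerateInputError("constant predictor: singular fit")
    sxx = np.sum((xv - xv.mean()) ** 2)
    sxy = np.sum((xv - xv.mean()) * (yv - yv.mean()))
    slope = sxy / sxx
    intercept = yv.mean() - slope * xv.mean()
    fitted = intercept + slope * xv
    resid = yv - fitted
    table = pd.DataFrame(
        {"x": xv, "y": yv, "fitted": fitted, "residual": resid,
         "direction": np.where(resid >= 0, "up", "down")},
        index=pd.Index(common, name="gene_id"),
    )
    order = _residual_order(table)
    table["abs_rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    return float(slope), float(intercept), table


def _residual_order(table: pd.DataFrame) -> pd.Index:
    """Gene ids by descending |residual|, ties broken lexicographically."""
    idx = sorted(table.index, key=lambda g: (-abs(table.at[g, "residual"]), str(g)))
    return pd.Index(idx)


@dataclass(frozen=True)
class DBSelection:
    """Ordered top-K differential-binding call."""
    genes: tuple
    k: int
    min_signal: float

    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene):
        return gene in set(self.genes)


def select_top_db(table: pd.DataFrame, scaled_x: pd.Series, scaled_y: pd.Series,
                  k: int = DEFAULT_TOP_K,
                  min_signal: float = DEFAULT_MIN_SIGNAL) -> DBSelection:
    """Top-K genes by |residual| among genes passing the minimal-signal filter.

    A gene is excluded when its unit-max-scaled score is below ``min_signal``
    in either compared sample.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    passes = (scaled_x.reindex(table.index) >= min_signal) & \
             (scaled_y.reindex(table.index) >= min_signal)
    passing = table.loc[passes.fillna(False)]
    order = _residual_order(passing)
    return DBSelection(genes=tuple(order[:k]), k=k, min_signal=min_signal)


def intersect_top_db(sel_a: DBSelection, sel_b: DBSelection) -> list:
    """Genes in both selections, ordered by the worse (max) of their ranks."""
    rank_a = {g: i for i, g in enumerate(sel_a.genes)}
    rank_b = {g: i for i, g in enumerate(sel_b.genes)}
    common = set(rank_a) & set(rank_b)
    return sorted(common, key=lambda g: (max(rank_a[g], rank_b[g]), str(g)))


def db_group_test(residuals: pd.Series, group: Iterable) -> Tuple[pd.Series, float]:
    """Z-scores of residuals and a group-vs-rest Wilcoxon rank-sum test.

    z = (r - mean(r)) / sd(r) over all genes; the two-sided rank-sum p is
    exact for combined n <= 30 and a continuity-corrected normal
    approximation otherwise.
    """
    group = set(group)
    if not group or not group < set(residuals.index):
        raise ValueError("group must be a non-empty proper subset of the genes")
    sd = residuals.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError("residual standard deviation is zero")
    z = (residuals - residuals.mean()) / sd
    in_group = residuals.index.isin(group)
    a = residuals[in_group].to_numpy()
    b = residuals[~in_group].to_numpy()
    method = "exact" if (a.size + b.size) <= 30 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return z.rename("z"), float(res.pvalue)


class PromoterBindingShift:
    """Model of the promoter-binding shift between two cell-cycle stages.

    Parameters
    ----------
    g1_scores, hu_scores : Series of promoter activity scores indexed by
        gene id (reference and stressed stage respectively).
    """

    def __init__(self, g1_scores: pd.Series, hu_scores: pd.Series):
        self.g1_scores = g1_scores.astype(float)
        self.hu_scores = hu_scores.astype(float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x_col: str = "g1", y_col: str = "hu",
                       gene_col: Optional[str] = "gene_id") -> "PromoterBindingShift":
        if gene_col is not None and gene_col in df.columns:
            df = df.set_index(gene_col)
        return cls(df[x_col], df[y_col])

    def fit(self, top_k: int = DEFAULT_TOP_K,
            min_signal: float = DEFAULT_MIN_SIGNAL) -> "PromoterBindingShiftResults":
        slope, intercept, table = fit_db_regression(self.g1_scores, self.hu_scores)
        scaled_x = scale_to_unit_max(self.g1_scores)
        scaled_y = scale_to_unit_max(self.hu_scores)
        table = table.assign(
            scaled_x=scaled_x.reindex(table.index),
            scaled_y=scaled_y.reindex(table.index),
        )
        table["passes_filter"] = (table["scaled_x"] >= min_signal) & \
                                 (table["scaled_y"] >= min_signal)
        selection = select_top_db(table, scaled_x, scaled_y, k=top_k,
                                  min_signal=min_signal)
        return PromoterBindingShiftResults(self, slope, intercept, table, selection)


class PromoterBindingShiftResults:
    """Fit results: trend line, per-gene residual table, top-K DB selection."""

    def __init__(self, model: PromoterBindingShift, slope: float, intercept: float,
                 residual_table: pd.DataFrame, selection: DBSelection):
        self.model = model
        self.slope = slope
        self.intercept = intercept
        self.residual_table = residual_table
        self.selection = selection

    @property
    def residuals(self) -> pd.Series:
        return self.residual_table["residual"]

    @property
    def n_genes(self) -> int:
        return len(self.residual_table)

    def group_test(self, group: Iterable) -> Tuple[pd.Series, float]:
        return db_group_test(self.residuals, group)

    def summary(self) -> str:
        t = self.residual_table
        n_up = int((t.loc[list(self.selection.genes), "direction"] == "up").sum())
        n_down = len(self.selection) - n_up
        lines = [
            "Promoter binding shift (residual analysis)",
            "=" * 46,
            f"genes                 {self.n_genes}",
            f"slope                 {self.slope:.4f}",
            f"intercept             {self.intercept:.4f}",
            f"residual sd           {t['residual'].std(ddof=1):.4f}",
            f"min-signal filter     {self.selection.min_signal}",
            f"genes passing filter  {int(t['passes_filter'].sum())}",
            f"top-K requested       {self.selection.k}",
            f"top-DB selected       {len(self.selection)} ({n_up} up / {n_down} down)",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        out = self.residual_table.copy()
        ranks = {g: i + 1 for i, g in enumerate(self.selection.genes)}
        out["selected_rank"] = [ranks.get(g, np.nan) for g in out.index]
        return out
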