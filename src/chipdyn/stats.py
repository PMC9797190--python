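"""Cross-analysis statistics: Fisher exact tests, TF-target enrichment,
binding-vs-expression correlation/association, and a naive differential
expression surrogate.

The DE surrogate is deliberately simple (median-of-ratios size factors and a
fold-change threshold) and clearly labelled as such; externally computed DE
tables are accepted everywhere a DE result is consumed, so a full NB-GLM
engine can be slotted in.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     sided: str = "two") -> Tuple[float, float]:
    """Fisher's exact test for the 2x2 table [[a, b], [c, d]].

    ``sided='two'`` sums hypergeometric tables with probability <= the
    observed table's (the classical convention); ``sided='greater'`` is the
    upper tail on ``a``.  Returns (p, sample odds ratio ad/bc, inf allowed).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise DegenerateInputError("degenerate margins in 2x2 table")
    alternative = {"two": "two-sided", "greater": "greater"}[sided]
    res = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return float(res.pvalue), odds


@dataclass(frozen=True)
class EnrichmentResult:
    table: Tuple[int, int, int, int]  # a, b, c, d with a = targets ∩ selection
    in_selection_pct: float
    background_pct: float
    p: float
    odds_ratio: float


def tf_enrichment(universe: int, targets: Set[str], selection: Set[str]) -> EnrichmentResult:
    """Enrichment of a TF-target gene set within a selection (one-sided Fisher).

    ``universe`` is the total gene count and must be supplied explicitly;
    frequencies are percentages: overlap/|selection| and |targets|/universe.
    """
    targets, selection = set(targets), set(selection)
    if not selection:
        raise DegenerateInputError("empty selection")
    if universe < len(targets | selection):
        raise ValueError("universe smaller than targets ∪ selection")
    a = len(targets & selection)
    b = len(selection) - a
    c = len(targets) - a
    d = universe - a - b - c
    p, odds = fisher_exact_2x2(a, b, c, d, sided="greater")
    return EnrichmentResult(
        table=(a, b, c, d),
        in_selection_pct=100.0 * a / len(selection),
        background_pct=100.0 * len(targets) / universe,
        p=p, odds_ratio=odds,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman r (tie-free, n <= 10)."""
    n = x.size
    rx = tuple(sps.rankdata(x))
    ry = tuple(sps.rankdata(y))
    count = 0
    total = 0
    denom = n * (n * n - 1) / 6.0
    thresh = abs(r_obs) - 1e-12
    for perm in itertools.permutations(ry):
        d2 = sum((u - v) ** 2 for u, v in zip(rx, perm))
        if abs(1.0 - d2 / denom) >= thresh:
            count += 1
        total += 1
    return count / total


def db_de_correlation(residuals: Mapping[str, float],
                      log2fc: Mapping[str, float]) -> Tuple[float, float, int]:
    """Spearman correlation between binding change and expression change.

    Computed on the shared gene set (average ranks for ties); the p-value is
    an exact permutation p for n <= 10 without ties, otherwise the
    t-approximation.  Returns (r, p, n).
    """
    rs = pd.Series(residuals, dtype=float)
    fc = pd.Series(log2fc, dtype=float)
    common = rs.index.intersection(fc.index)
    if len(common) < 3:
        raise DegenerateInputError("need at least 3 shared genes")
    x = rs.loc[common].to_numpy()
    y = fc.loc[common].to_numpy()
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    n = len(common)
    tie_free = (np.unique(x).size == n) and (np.unique(y).size == n)
    if n <= 10 and tie_free:
        p = _spearman_exact_p(x, y, r)
    else:
        p = float(res.pvalue)
    return r, p, n


def db_de_association(db_direction: Mapping[str, str],
                      de_direction: Mapping[str, str]) -> Tuple[Tuple[int, int, int, int], float]:
    """2x2 association between DB direction and DE direction (two-sided Fisher).

    Table rows are DB up/down, columns DE up/down.  A zero margin raises
    with the margin named.
    """
    db = pd.Series(db_direction)
    de = pd.Series(de_direction)
    common = db.index.intersection(de.index)
    dbv, dev = db.loc[common], de.loc[common]
    a = int(((dbv == "up") & (dev == "up")).sum())
    b = int(((dbv == "up") & (dev == "down")).sum())
    c = int(((dbv == "down") & (dev == "up")).sum())
    d = int(((dbv == "down") & (dev == "down")).sum())
    for name, margin in (("DB up", a + b), ("DB down", c + d),
                         ("DE up", a + c), ("DE down", b + d)):
        if margin == 0:
            raise DegenerateInputError(f"zero margin: {name}")
    p, _ = fisher_exact_2x2(a, b, c, d, sided="two")
    return (a, b, c, d), p


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Genes with a zero count in any sample are excluded from the reference.
    """
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise DegenerateInputError(f"samples with zero total counts: {bad}")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise DegenerateInputError("no gene has positive counts in all samples")
    log_ref = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_ref, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def naive_de(counts: pd.DataFrame, condition: Mapping[str, str],
             cond_a: str, cond_b: str, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Naive differential-expression surrogate (NOT an NB-GLM engine).

    After median-of-ratios normalization, log2FC = log2((mean_b + 1) /
    (mean_a + 1)) over normalized counts; a gene is flagged significant when
    |log2FC| >= threshold.  All-zero genes are dropped (recorded in
    ``frame.attrs['dropped']``); ``frame.attrs['engine'] = 'surrogate'``.
    """
    cond = pd.Series(condition)
    samples_a = cond.index[cond == cond_a]
    samples_b = cond.index[cond == cond_b]
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError("each condition needs at least one replicate")
    used = counts[list(samples_a) + list(samples_b)]
    if (used.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    nonzero = used.sum(axis=1) > 0
    dropped = used.index[~nonzero].tolist()
    used = used.loc[nonzero]
    sf = size_factors(used)
    norm = used.div(sf, axis=1)
    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    significant = log2fc.abs() >= lfc_threshold
    direction = np.where(~significant, "ns", np.where(log2fc >= 0, "up", "down"))
    out = pd.DataFrame({"log2fc": log2fc, "significant": significant,
                        "direction": direction})
    out.index.name = "gene_id"
    out.attrs["engine"] = "surrogate"
    out.attrs["dropped"] = dropped
    out.attrs["size_factors"] = sf.to_dict()
    return out
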