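"""Promoter-window scoring, empirical promoter-binding significance,
binding-specificity (Lorenz/Gini) and peak-to-promoter annotation.

The scoring promoter is the 500-bp window upstream of the TSS; for peak
annotation the promoter is extended to 50 bp downstream.  The score of a
window is the overlap-weighted mean of the log2-enrichment bins it covers,
i.e. the bin-sum scaled by the window width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError
from .genome import BinnedTrack, GenomeLayout


@dataclass(frozen=True)
class PromoterWindow:
    chrom: str
    start: int
    end: int
    clipped: bool


def promoter_window(chrom: str, tss: int, strand: str, layout: GenomeLayout,
                    upstream: int = 500, downstream: int = 0) -> PromoterWindow:
    """Strand-aware promoter interval around a TSS, clipped to the chromosome.

    + strand -> [tss - upstream, tss + downstream);
    - strand -> [tss - downstream, tss + upstream).
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise ValueError(f"bad strand {strand!r}")
    length = layout.length(chrom)
    cstart, cend = max(start, 0), min(end, length)
    return PromoterWindow(chrom, cstart, cend, clipped=(cstart != start or cend != end))


def promoter_scores(track: BinnedTrack, genes: pd.DataFrame,
                    upstream: int = 500, downstream: int = 0) -> pd.Series:
    """Per-gene promoter score: width-normalized mean signal over the window.

    Zero-width windows after clipping score NaN (reported, not fatal).
    Returns a Series indexed by gene_id.
    """
    genes = genes.reset_index(drop=True)
    scores = np.full(len(genes), np.nan)
    for chrom, sub in genes.groupby("chrom", sort=False):
        tss = sub["tss"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        starts = np.where(plus, tss - upstream, tss - downstream)
        ends = np.where(plus, tss + downstream, tss + upstream)
        scores[sub.index.to_numpy()] = track.interval_means(chrom, starts, ends, oob="clip")
    return pd.Series(scores, index=genes["gene_id"].to_numpy(), name="score")


def empirical_promoter_p(track: BinnedTrack, genes: pd.DataFrame,
                         n_null: int = 10000, seed: int = 0,
                         upstream: int = 500, alpha: float = 0.05) -> Tuple[pd.Series, int]:
    """One-sided empirical p-values for promoter scores.

    The null is the score distribution of ``n_null`` uniformly placed
    windows of the same width on the same track (in-bounds placements only);
    p = (1 + #{null >= obs}) / (1 + n_null).  Returns (p Series indexed by
    gene_id, count of genes with p <= alpha).
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    layout = track.layout
    usable = {c: layout.length(c) - upstream for c in layout.chroms}
    if all(u <= 0 for u in usable.values()):
        raise ValueError("genome shorter than the promoter window")
    chroms = [c for c, u in usable.items() if u > 0]
    weights = np.array([usable[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    chrom_idx = rng.choice(len(chroms), size=n_null, p=weights)
    null_scores = np.empty(n_null)
    for i, chrom in enumerate(chroms):
        mask = chrom_idx == i
        if not mask.any():
            continue
        starts = rng.integers(0, usable[chrom], size=int(mask.sum()))
        null_scores[mask] = track.interval_means(chrom, starts, starts + upstream)
    null_sorted = np.sort(null_scores)

    obs = promoter_scores(track, genes, upstream=upstream)
    # #{null >= obs} via searchsorted on the ascending null
    n_ge = n_null - np.searchsorted(null_sorted, obs.to_numpy(), side="left")
    pvals = (1.0 + n_ge) / (1.0 + n_null)
    p = pd.Series(pvals, index=obs.index, name="p")
    return p, int((p <= alpha).sum())


@dataclass(frozen=True)
class LorenzResult:
    """Lorenz curve points (population share, signal share) and Gini index."""
    curve: np.ndarray  # shape (n+1, 2), from (0,0) to (1,1)
    gini: float


def lorenz_gini(values) -> LorenzResult:
    """Lorenz curve and Gini index of nonnegative per-gene signal.

    gini = 1 - 2 * trapezoidal area under the Lorenz curve, which equals
    half the relative mean absolute difference of the data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values")
    if np.any(x < 0):
        raise DegenerateInputError("values must be nonnegative")
    total = x.sum()
    if total == 0:
        raise DegenerateInputError("Gini undefined for all-zero input")
    xs = np.sort(x)
    cum = np.concatenate([[0.0], np.cumsum(xs)]) / total
    pop = np.linspace(0.0, 1.0, x.size + 1)
    area = np.trapezoid(cum, pop)
    gini = 1.0 - 2.0 * area
    return LorenzResult(curve=np.column_stack([pop, cum]), gini=float(gini))


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame, layout: GenomeLayout,
                   upstream: int = 500, downstream: int = 50) -> Tuple[pd.DataFrame, float]:
    """Categorize peaks as promoter / gene body / other.

    A peak is *promoter* if it intersects any strand-aware [-upstream, +downstream)
    window around a TSS; failing that, *gene body* if it intersects a gene's
    extent (requires a gene_end column); otherwise *other*.  Returns the
    annotated frame and the promoter-overlap fraction.
    """
    if len(peaks) == 0:
        raise DegenerateInputError("empty peak set: promoter fraction undefined")
    windows: Dict[str, list] = {c: [] for c in layout.chroms}
    bodies: Dict[str, list] = {c: [] for c in layout.chroms}
    has_body = "gene_end" in genes.columns
    for _, g in genes.iterrows():
        wdw = promoter_window(g["chrom"], int(g["tss"]), g["strand"], layout,
                              upstream=upstream, downstream=downstream)
        windows[g["chrom"]].append((wdw.start, wdw.end))
        if has_body and pd.notna(g.get("gene_end")):
            lo, hi = sorted((int(g["tss"]), int(g["gene_end"])))
            bodies[g["chrom"]].append((lo, hi))

    def hits(ivs, s, e):
        return any(s < b and e > a for a, b in ivs)

    cats = []
    for _, pk in peaks.iterrows():
        chrom, s, e = pk["chrom"], int(pk["start"]), int(pk["end"])
        if chrom in windows and hits(windows[chrom], s, e):
            cats.append("promoter")
        elif chrom in bodies and hits(bodies[chrom], s, e):
            cats.append("gene body")
        else:
            cats.append("other")
    out = peaks.copy()
    out["category"] = cats
    frac = float(np.mean(out["category"] == "promoter"))
    return out, frac
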