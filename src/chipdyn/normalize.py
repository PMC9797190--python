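"""IP/input count normalization to log2 enrichment tracks.

Two flavours are provided.  *Simple* normalization computes, per 25-bp bin,
the log2 ratio of IP to input counts with each side reciprocally scaled by
the other sample's genome-wide total (so library size cancels):

    value_i = log2( ((ip_i + c*T_ip/B) * T_input) / ((input_i + c*T_in/B) * T_ip) )
            = log2( (ip_i*B/T_ip + c) / (input_i*B/T_in + c) )

i.e. the pseudocount ``c`` lives on the mean-coverage-normalized scale (B =
number of genome bins), the convention used when log2 ratios are taken of
1x-normalized coverage tracks.  This keeps log ratios bounded at empty bins
and makes the output *exactly* invariant to rescaling either library; c = 0
recovers the bare reciprocal-total formula.

*Origin-aware* normalization applies the same computation independently to
origin-proximal bins (within a configurable radius of any origin center,
default 5 kb) and to the rest of the genome, each partition acting as its
own mini-genome (partition-restricted totals and bin counts); this absorbs
the elevated replication background around fired origins at the cost of
absolute comparability between the two partitions.

Replicates are normalized each against their own input and then averaged
bin-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegeneratePartitionError, LayoutError
from .genome import BinnedTrack, GenomeLayout


@dataclass(frozen=True)
class NormalizationConfig:
    pseudocount: float = 1.0
    origin_radius: int = 5000

    def __post_init__(self):
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.origin_radius < 0:
            raise ValueError("origin_radius must be >= 0")


def _check_layouts(ip: BinnedTrack, input_: BinnedTrack) -> None:
    if ip.layout.chrom_lengths != input_.layout.chrom_lengths or \
            ip.layout.bin_width != input_.layout.bin_width:
        raise LayoutError("IP and input tracks have mismatched layouts")


def log2_enrichment(ip: BinnedTrack, input_: BinnedTrack,
                    cfg: NormalizationConfig = NormalizationConfig()) -> BinnedTrack:
    """Simple normalization over the whole genome."""
    _check_layouts(ip, input_)
    t_ip, t_in = ip.total(), input_.total()
    if t_ip <= 0 or t_in <= 0:
        raise DegeneratePartitionError("zero total counts in IP or input")
    c = cfg.pseudocount
    n_bins = sum(ip.layout.n_bins(ch) for ch in ip.layout.chroms)
    data = {
        chrom: np.log2((ip.data[chrom] * n_bins / t_ip + c) /
                       (input_.data[chrom] * n_bins / t_in + c))
        for chrom in ip.layout.chroms
    }
    return BinnedTrack(ip.layout, data, "log2fc")


def average_replicates(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Bin-wise arithmetic mean of replicate log2fc tracks."""
    if not tracks:
        raise ValueError("need at least one track to average")
    first = tracks[0]
    for t in tracks[1:]:
        _check_layouts(first, t)
    data = {
        chrom: np.mean([t.data[chrom] for t in tracks], axis=0)
        for chrom in first.layout.chroms
    }
    return BinnedTrack(first.layout, data, "log2fc")


def origin_proximal_mask(layout: GenomeLayout, origins: pd.DataFrame,
                         radius: int) -> Dict[str, np.ndarray]:
    """Boolean mask per chromosome: bin intersects [center-radius, center+radius].

    The closed right endpoint means radius 0 still marks the bin containing
    the center.
    """
    w = layout.bin_width
    masks = {c: np.zeros(layout.n_bins(c), dtype=bool) for c in layout.chroms}
    for _, row in origins.iterrows():
        chrom, center = row["chrom"], int(row["center"])
        lo, hi = center - radius, center + radius  # closed interval in bp
        b0 = max(lo // w, 0)
        b1 = min(hi // w, layout.n_bins(chrom) - 1)
        if b1 >= b0:
            masks[chrom][b0 : b1 + 1] = True
    return masks


def origin_aware_normalize(ip: BinnedTrack, input_: BinnedTrack,
                           origins: pd.DataFrame,
                           cfg: NormalizationConfig = NormalizationConfig()) -> BinnedTrack:
    """Partitioned normalization: origin-proximal bins and the complement
    are normalized independently with partition-restricted totals."""
    _check_layouts(ip, input_)
    masks = origin_proximal_mask(ip.layout, origins, cfg.origin_radius)
    c = cfg.pseudocount
    out = {chrom: np.empty(ip.layout.n_bins(chrom)) for chrom in ip.layout.chroms}
    for part_name, invert in (("origin-proximal", False), ("origin-distal", True)):
        sel = {ch: (~m if invert else m) for ch, m in masks.items()}
        n_sel = sum(int(m.sum()) for m in sel.values())
        if n_sel == 0:
            continue
        t_ip = sum(float(ip.data[ch][m].sum()) for ch, m in sel.items())
        t_in = sum(float(input_.data[ch][m].sum()) for ch, m in sel.items())
        if t_ip <= 0 or t_in <= 0:
            raise DegeneratePartitionError(
                f"partition {part_name!r} has zero total counts in IP or input"
            )
        for chrom, m in sel.items():
            if not m.any():
                continue
            out[chrom][m] = np.log2(
                (ip.data[chrom][m] * n_sel / t_ip + c) /
                (input_.data[chrom][m] * n_sel / t_in + c)
            )
    return BinnedTrack(ip.layout, out, "log2fc")
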