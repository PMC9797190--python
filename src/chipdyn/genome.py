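"""Genome data model: layout, binned tracks, gene/origin annotation frames.

All coordinates in this package are 0-based, half-open.  Signal is carried on a
fixed-width bin grid (default 25 bp) per chromosome; a :class:`BinnedTrack`
tags its values as raw ``counts``, ``log2fc`` enrichment, or normalized
replication-incorporation (``edu``) signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import LayoutError, ValidationError

DEFAULT_BIN_WIDTH = 25

#: Allowed value-semantics tags for a BinnedTrack.
TRACK_KINDS = ("counts", "log2fc", "edu")

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]
ORIGIN_COLUMNS = ["origin_id", "chrom", "center"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths plus the shared bin width."""

    chrom_lengths: Mapping[str, int]
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        if self.bin_width <= 0:
            raise LayoutError(f"bin width must be positive, got {self.bin_width}")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise LayoutError(f"chromosome {chrom!r} has non-positive length {length}")
        object.__setattr__(self, "chrom_lengths", dict(self.chrom_lengths))

    @property
    def chroms(self) -> tuple:
        return tuple(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise LayoutError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length(chrom) / self.bin_width)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        length = self.length(chrom)
        if not (0 <= start < end <= length):
            raise LayoutError(
                f"interval {chrom}:{start}-{end} outside chromosome of length {length}"
            )


class BinnedTrack:
    """Per-chromosome value vectors on a fixed bin grid.

    Parameters
    ----------
    layout : GenomeLayout
    data : mapping of chromosome -> 1-D float array of length ``n_bins(chrom)``
    kind : one of :data:`TRACK_KINDS`
    """

    __slots__ = ("layout", "data", "kind")

    def __init__(self, layout: GenomeLayout, data: Mapping[str, np.ndarray], kind: str):
        if kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {kind!r}; expected one of {TRACK_KINDS}")
        if set(data) != set(layout.chroms):
            raise LayoutError(
                f"track chromosomes {sorted(data)} do not match layout {sorted(layout.chroms)}"
            )
        clean: Dict[str, np.ndarray] = {}
        for chrom in layout.chroms:
            arr = np.asarray(data[chrom], dtype=float)
            if arr.ndim != 1 or arr.size != layout.n_bins(chrom):
                raise LayoutError(
                    f"{chrom}: expected {layout.n_bins(chrom)} bins, got shape {arr.shape}"
                )
            clean[chrom] = arr
        if kind == "counts":
            for chrom, arr in clean.items():
                if np.any(arr < 0):
                    raise ValidationError(f"negative counts on {chrom}")
        else:
            for chrom, arr in clean.items():
                if not np.all(np.isfinite(arr)):
                    raise ValidationError(f"non-finite {kind} values on {chrom}")
        self.layout = layout
        self.data = clean
        self.kind = kind

    @classmethod
    def zeros(cls, layout: GenomeLayout, kind: str = "counts") -> "BinnedTrack":
        return cls(layout, {c: np.zeros(layout.n_bins(c)) for c in layout.chroms}, kind)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.layout, {c: v.copy() for c, v in self.data.items()}, self.kind)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    # -- interval statistics ------------------------------------------------

    def _integral(self, chrom: str) -> np.ndarray:
        # cumulative bp-weighted integral F with F[k] = sum(values[:k]) * w
        w = self.layout.bin_width
        return np.concatenate([[0.0], np.cumsum(self.data[chrom]) * w])

    def interval_sums(self, chrom: str, starts, ends) -> np.ndarray:
        """bp-weighted signal sums over clipped intervals ``[start, end)``.

        A full bin of value v contributes ``v * bin_width``; partial overlap
        contributes proportionally.  Out-of-chromosome portions contribute 0.
        """
        w = self.layout.bin_width
        length = self.layout.length(chrom)
        starts = np.clip(np.asarray(starts, dtype=float), 0, length)
        ends = np.clip(np.asarray(ends, dtype=float), 0, length)
        ends = np.maximum(ends, starts)
        F = self._integral(chrom)
        values = self.data[chrom]

        def eval_at(t):
            k = np.minimum((t // w).astype(int), values.size - 1)
            return F[k] + (t - k * w) * values[k]

        return eval_at(ends) - eval_at(starts)

    def interval_means(self, chrom: str, starts, ends, oob: str = "clip") -> np.ndarray:
        """Overlap-weighted means over intervals ``[start, end)``.

        oob='clip'  : normalize by the covered (in-chromosome) width; empty
                      coverage yields NaN.
        oob='zero'  : w0 convention — out-of-range bp contribute 0 with full
                      weight, normalize by the requested width.
        """
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        sums = self.interval_sums(chrom, starts, ends)
        if oob == "zero":
            widths = ends - starts
        elif oob == "clip":
            length = self.layout.length(chrom)
            widths = np.clip(ends, 0, length) - np.clip(starts, 0, length)
            widths = np.maximum(widths, 0.0)
        else:
            raise ValueError(f"unknown oob mode {oob!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(widths > 0, sums / np.where(widths > 0, widths, 1.0), np.nan)
        return out

    def interval_mean(self, chrom: str, start: float, end: float, oob: str = "clip") -> float:
        return float(self.interval_means(chrom, [start], [end], oob=oob)[0])


# -- annotation tables ------------------------------------------------------


def validate_genes(genes: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Validate a gene annotation frame against a layout.

    Required columns: gene_id, chrom, tss, strand.  Optional: gene_end,
    tf_labels (comma-separated), cluster.  Raises ValidationError listing
    offending row indices.
    """
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValidationError(f"gene table missing columns {missing}")
    offenders = []
    for idx, row in genes.iterrows():
        if row["chrom"] not in layout.chroms:
            offenders.append((idx, f"unknown chromosome {row['chrom']!r}"))
        elif not (0 <= int(row["tss"]) < layout.length(row["chrom"])):
            offenders.append((idx, f"tss {row['tss']} out of bounds"))
        if row["strand"] not in ("+", "-"):
            offenders.append((idx, f"bad strand {row['strand']!r}"))
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        offenders.append(("*", f"duplicate gene ids {dups}"))
    if offenders:
        raise ValidationError(f"{len(offenders)} invalid gene records", offenders)
    out = genes.copy()
    out["tss"] = out["tss"].astype(int)
    return out.reset_index(drop=True)


def validate_origins(origins: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    missing = [c for c in ORIGIN_COLUMNS if c not in origins.columns]
    if missing:
        raise ValidationError(f"origin table missing columns {missing}")
    offenders = []
    for idx, row in origins.iterrows():
        if row["chrom"] not in layout.chroms:
            offenders.append((idx, f"unknown chromosome {row['chrom']!r}"))
        elif not (0 <= int(row["center"]) < layout.length(row["chrom"])):
            offenders.append((idx, f"center {row['center']} out of bounds"))
    if origins["origin_id"].duplicated().any():
        dups = origins.loc[origins["origin_id"].duplicated(), "origin_id"].tolist()
        offenders.append(("*", f"duplicate origin ids {dups}"))
    if offenders:
        raise ValidationError(f"{len(offenders)} invalid origin records", offenders)
    out = origins.copy()
    out["center"] = out["center"].astype(int)
    return out.reset_index(drop=True)
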