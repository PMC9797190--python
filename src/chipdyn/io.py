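"""Readers and writers for the plain-text formats the pipeline touches.

bedGraph intervals are resampled onto the layout's bin grid by
coverage-weighted mean with absent regions counted as 0, so a write→read
round trip of bin-aligned data is value-identical.  All writers emit a fixed
column order and LF line endings.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .genome import BinnedTrack, GenomeLayout, validate_genes, validate_origins


def read_bedgraph(path, layout: GenomeLayout, kind: str = "counts") -> BinnedTrack:
    """Read a bedGraph file onto the layout's bin grid.

    Values are distributed by bp overlap; each bin's value is the
    coverage-weighted mean with uncovered bp contributing 0.  Overlapping
    records or unknown chromosomes raise :class:`FormatError`.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": int, "end": int, "value": float},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse bedGraph {path}: {exc}") from exc

    w = layout.bin_width
    sums = {c: np.zeros(layout.n_bins(c)) for c in layout.chroms}
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in layout.chroms:
            raise FormatError(f"{path}: chromosome {chrom!r} absent from layout")
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(ends <= starts):
            raise FormatError(f"{path}: interval with end <= start on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"{path}: overlapping intervals on {chrom}")
        length = layout.length(chrom)
        if starts[0] < 0 or ends[-1] > length:
            raise FormatError(f"{path}: interval outside chromosome {chrom}")
        vec = sums[chrom]
        for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
            b0, b1 = s // w, (e - 1) // w
            if b0 == b1:
                vec[b0] += v * (e - s)
                continue
            vec[b0] += v * ((b0 + 1) * w - s)
            vec[b1] += v * (e - b1 * w)
            if b1 > b0 + 1:
                vec[b0 + 1 : b1] += v * w
        # weighted mean over full bin width (absent bp are 0)
    data = {}
    for chrom in layout.chroms:
        length = layout.length(chrom)
        widths = np.full(layout.n_bins(chrom), float(w))
        if length % w:
            widths[-1] = length % w
        data[chrom] = sums[chrom] / widths
    return BinnedTrack(layout, data, kind)


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a track as run-length-compressed bedGraph (zero bins included)."""
    w = track.layout.bin_width
    with open(path, "w", newline="\n") as fh:
        for chrom in track.layout.chroms:
            values = track.data[chrom]
            length = track.layout.length(chrom)
            if values.size == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [values.size]])
            for rs, re_ in zip(run_starts, run_ends):
                start = rs * w
                end = min(re_ * w, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{values[rs]:g}\n")


def read_bed(path, layout: GenomeLayout) -> pd.DataFrame:
    """Read BED3+ intervals; returns a frame with chrom/start/end (+name)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if chrom not in layout.chroms:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > layout.length(chrom):
                raise FormatError(f"{path}:{lineno}: interval out of bounds")
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in intervals.columns]
    intervals.to_csv(path, sep="\t", header=False, index=False, columns=cols,
                     lineterminator="\n")


def read_gene_table(path, layout: GenomeLayout) -> pd.DataFrame:
    """Read the 4+-column gene TSV (gene_id chrom tss strand [gene_end tf_labels cluster])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_genes(df, layout)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    cols = [c for c in ["gene_id", "chrom", "tss", "strand", "gene_end", "tf_labels", "cluster"]
            if c in genes.columns]
    genes.to_csv(path, sep="\t", index=False, columns=cols, lineterminator="\n")


def read_origin_table(path, layout: GenomeLayout) -> pd.DataFrame:
    """Read origin TSV (origin_id chrom center [timing class/true_type])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_origins(df, layout)


def write_origin_table(origins: pd.DataFrame, path) -> None:
    cols = [c for c in ["origin_id", "chrom", "center", "timing", "true_type", "origin_class"]
            if c in origins.columns]
    origins.to_csv(path, sep="\t", index=False, columns=cols, lineterminator="\n")


def read_gff3_lite(path, layout: GenomeLayout) -> pd.DataFrame:
    """Convenience GFF3 reader extracting gene records only (ID, TSS, strand).

    The TSS is the strand-appropriate end of the feature (GFF is 1-based
    closed; converted to 0-based).  Attributes other than ID are ignored.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            gid = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gid = item[3:]
            if gid is None:
                raise FormatError(f"{path}:{lineno}: gene without ID attribute")
            start0, end0 = int(start) - 1, int(end)
            tss = start0 if strand == "+" else end0 - 1
            rows.append((gid, chrom, tss, strand, end0 if strand == "+" else start0))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "gene_end"])
    return validate_genes(df, layout)


def read_de_table(path) -> pd.DataFrame:
    """Read an externally computed differential-expression table.

    Expected columns: gene_id, log2fc, significant (bool-like).  A direction
    column is derived if absent.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc"):
        if col not in df.columns:
            raise FormatError(f"DE table missing column {col!r}")
    if "significant" not in df.columns:
        df["significant"] = True
    df["significant"] = df["significant"].astype(bool)
    if "direction" not in df.columns:
        df["direction"] = np.where(
            ~df["significant"], "ns", np.where(df["log2fc"] >= 0, "up", "down")
        )
    return df


def read_gene_list(path) -> list:
    """One-gene-per-line TF target list."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
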