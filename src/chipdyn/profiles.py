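"""Metagene signal matrices and average profiles around anchors.

A signal matrix has one row per anchor (TSS or origin center) and one column
per flank bin of the window [anchor - flank, anchor + flank).  Averaging
follows the w0 convention: bp outside the chromosome contribute zero with
full weight, so edge anchors are not inflated.  Rows of minus-strand genes
are reversed when strand-aware, putting upstream signal on the left for
every gene; origin matrices are never strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import BinnedTrack


@dataclass(frozen=True)
class SignalMatrix:
    values: np.ndarray            # (n_anchors, 2*flank/bin)
    anchors: tuple                # anchor ids, row order
    flank: int
    bin_width: int

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        offsets = np.arange(-self.flank, self.flank, self.bin_width)
        return pd.DataFrame(self.values, index=pd.Index(self.anchors, name="anchor"),
                            columns=offsets)


def signal_matrix(track: BinnedTrack, anchors: pd.DataFrame, flank: int,
                  bin_width: int = 25, strand_aware: bool = False,
                  id_col: Optional[str] = None,
                  pos_col: Optional[str] = None) -> SignalMatrix:
    """Build an anchor x flank-bin matrix of w0-averaged signal.

    ``anchors`` needs an id column (gene_id or origin_id), a position column
    (tss or center), plus strand when ``strand_aware``.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of the bin width")
    if id_col is None:
        id_col = "gene_id" if "gene_id" in anchors.columns else "origin_id"
    if pos_col is None:
        pos_col = "tss" if "tss" in anchors.columns else "center"
    anchors = anchors.reset_index(drop=True)
    n_cols = 2 * flank // bin_width
    mat = np.zeros((len(anchors), n_cols))
    offsets = np.arange(n_cols) * bin_width
    for chrom, sub in anchors.groupby("chrom", sort=False):
        pos = sub[pos_col].to_numpy()
        for j in range(n_cols):
            starts = pos - flank + offsets[j]
            mat[sub.index.to_numpy(), j] = track.interval_means(
                chrom, starts, starts + bin_width, oob="zero")
    if strand_aware:
        minus = (anchors["strand"] == "-").to_numpy()
        mat[minus] = mat[minus, ::-1]
    return SignalMatrix(values=mat, anchors=tuple(anchors[id_col]),
                        flank=flank, bin_width=bin_width)


def average_profile(matrix: SignalMatrix) -> np.ndarray:
    """Column-wise mean signal across anchors."""
    if matrix.n_rows == 0:
        raise ValueError("empty matrix")
    return matrix.values.mean(axis=0)


def order_rows(matrix: SignalMatrix, keys: pd.Series, ascending: bool = True,
               cluster: Optional[pd.Series] = None) -> SignalMatrix:
    """Stable row reorder by a per-anchor key; missing keys sort last.

    With ``cluster`` given, rows are grouped into contiguous cluster blocks
    (clusters in sorted label order) and sorted by key within each block —
    the layout used for expression-ordered heatmaps per coexpression
    cluster (descending fold change within cluster: ``ascending=False``).
    """
    ids = list(matrix.anchors)
    k = keys.reindex(ids)
    sort_key = k.to_numpy(dtype=float)
    missing = ~np.isfinite(sort_key)
    primary = np.where(missing, np.inf if ascending else -np.inf, sort_key)
    if cluster is not None:
        cl = cluster.reindex(ids).astype(str).to_numpy()
        order = np.lexsort((np.arange(len(ids)),
                            -primary if not ascending else primary,
                            np.where(missing, 1, 0), cl))
    else:
        order = np.lexsort((np.arange(len(ids)),
                            -primary if not ascending else primary,
                            np.where(missing, 1, 0)))
    return SignalMatrix(values=matrix.values[order],
                        anchors=tuple(ids[i] for i in order),
                        flank=matrix.flank, bin_width=matrix.bin_width)
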