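"""Replication-origin typing from replication-incorporation (EdU) signal.

Under hydroxyurea the checkpoint blocks late origins, so in wild-type cells
only early origins incorporate EdU at the first timepoint; in
checkpoint-deficient mutants late origins fire promiscuously and show signal
at the later timepoint.  Origins are classified:

* early    — wild-type signal at the first HU timepoint > threshold (default 2)
* late     — otherwise, mean mutant signal at the later timepoint > threshold
* inactive — the rest

The per-origin statistic is the mean track value over a window centered on
the origin (default ±2.5 kb, well inside the ~10-kb fork extent).
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .exceptions import ChipdynError
from .genome import BinnedTrack

EDU_THRESHOLD = 2.0
ORIGIN_WINDOW = 2500


def origin_edu_score(track: BinnedTrack, chrom: str, center: int,
                     window: int = ORIGIN_WINDOW) -> float:
    """Mean signal over [center - window, center + window), edge-clipped."""
    return track.interval_mean(chrom, center - window, center + window, oob="clip")


def origin_edu_scores(track: BinnedTrack, origins: pd.DataFrame,
                      window: int = ORIGIN_WINDOW) -> pd.Series:
    origins = origins.reset_index(drop=True)
    out = np.empty(len(origins))
    for chrom, sub in origins.groupby("chrom", sort=False):
        centers = sub["center"].to_numpy()
        out[sub.index.to_numpy()] = track.interval_means(
            chrom, centers - window, centers + window, oob="clip")
    return pd.Series(out, index=origins["origin_id"].to_numpy(), name="edu_score")


def classify_origins(wt_first: pd.Series, mutant_later: Mapping[str, pd.Series],
                     threshold: float = EDU_THRESHOLD,
                     late_rule: str = "mean") -> pd.DataFrame:
    """Classify origins as early/late/inactive.

    Parameters
    ----------
    wt_first : per-origin score in wild type at the first HU timepoint.
    mutant_later : per-genotype per-origin scores at the later timepoint.
    late_rule : 'mean' (threshold on the across-mutant mean, default) or
        'all' (threshold required in every mutant separately).

    Returns a frame indexed by origin id with the per-sample scores and an
    ``origin_class`` column; classes partition the origin universe.
    """
    if not mutant_later:
        raise ValueError("need at least one mutant genotype")
    universe = wt_first.index
    for name, s in mutant_later.items():
        if not universe.equals(s.index):
            missing = universe.symmetric_difference(s.index).tolist()
            raise ChipdynError(f"origin universe mismatch for {name!r}: {missing[:5]}")
    frame = pd.DataFrame({"wt_first": wt_first})
    for name, s in mutant_later.items():
        frame[f"later_{name}"] = s
    later = frame.drop(columns="wt_first")
    early = frame["wt_first"] > threshold
    if late_rule == "mean":
        late_signal = later.mean(axis=1) > threshold
    elif late_rule == "all":
        late_signal = (later > threshold).all(axis=1)
    else:
        raise ValueError(f"unknown late_rule {late_rule!r}")
    frame["origin_class"] = np.where(early, "early",
                                     np.where(late_signal, "late", "inactive"))
    frame.index.name = "origin_id"
    return frame


def assign_timing(origins: pd.DataFrame, timing: pd.DataFrame,
                  max_dist: int = 5000) -> pd.Series:
    """Representative replication timing for each origin.

    ``timing`` has columns chrom, center, timing (one value per fixed-width
    profiling window).  Each origin receives the timing of the nearest window
    center on its chromosome if within ``max_dist`` bp, else NaN.  Equidistant
    windows resolve to the lower coordinate.
    """
    out = pd.Series(np.nan, index=pd.Index(origins["origin_id"], name="origin_id"),
                    name="timing", dtype=float)
    for chrom, sub in origins.groupby("chrom", sort=False):
        tw = timing[timing["chrom"] == chrom].sort_values("center")
        if tw.empty:
            continue
        centers = tw["center"].to_numpy()
        values = tw["timing"].to_numpy()
        pos = sub["center"].to_numpy()
        right = np.searchsorted(centers, pos)
        left = np.clip(right - 1, 0, centers.size - 1)
        right = np.clip(right, 0, centers.size - 1)
        dl = np.abs(pos - centers[left])
        dr = np.abs(centers[right] - pos)
        pick = np.where(dl <= dr, left, right)  # tie -> lower coordinate
        dist = np.minimum(dl, dr)
        assigned = np.where(dist <= max_dist, values[pick], np.nan)
        out.loc[sub["origin_id"].to_numpy()] = assigned
    return out


def filter_blacklist(origins: pd.DataFrame, blacklist: pd.DataFrame,
                     pad: int = 0) -> pd.DataFrame:
    """Drop origins whose (padded) center point hits a blacklist interval.

    The origin is treated as the point interval [center, center+1); with
    half-open semantics a center exactly at an interval end is retained.
    """
    if blacklist is None or len(blacklist) == 0:
        return origins.reset_index(drop=True)
    keep = []
    by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in blacklist.groupby("chrom")}
    for _, row in origins.iterrows():
        ivs = by_chrom.get(row["chrom"])
        c = int(row["center"])
        lo, hi = c - pad, c + 1 + pad
        hit = ivs is not None and bool(np.any((ivs[:, 0] < hi) & (ivs[:, 1] > lo)))
        keep.append(not hit)
    return origins.loc[keep].reset_index(drop=True)
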