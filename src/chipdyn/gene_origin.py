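"""Gene–origin relations and replication–transcription conflict statistics.

Each gene is related to its nearest replication-origin center on the same
chromosome: distance (TSS to center), relative orientation, and origin
class.  Orientation is defined by the replication fork that reaches the
gene: the fork travels away from the origin center, so a gene whose
transcription points *toward* the center meets that fork head-on (HO), and a
gene transcribed *away* from the center is co-directional (CD).  Genes whose
nearest active origin is close (<5 kb) can then be tested for a
downregulation bias by origin class and by orientation with Fisher's exact
test.
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .stats import fisher_exact_2x2

DISTANCE_EDGES = (1000, 2000, 5000)
CATEGORY_LABELS = ("<1kb", "1-2kb", "2-5kb", "none")


def distance_category(distance: float, edges=DISTANCE_EDGES) -> str:
    if not np.isfinite(distance) or distance >= edges[2]:
        return "none"
    if distance < edges[0]:
        return "<1kb"
    if distance < edges[1]:
        return "1-2kb"
    return "2-5kb"


def orientation(tss: int, strand: str, center: int) -> str:
    """HO / CD / NA for a gene and an origin on the same chromosome.

    The fork arriving at the gene moves away from the center:
    rightward if TSS > center, leftward if TSS < center.  Transcription
    opposing that fork (pointing toward the center) is head-on.
    """
    if tss == center:
        return "NA"
    fork_rightward = tss > center
    transcribes_rightward = strand == "+"
    return "CD" if fork_rightward == transcribes_rightward else "HO"


def nearest_origin(genes: pd.DataFrame, origins: pd.DataFrame,
                   active_only: bool = False) -> pd.DataFrame:
    """Relate each gene to its nearest origin center on the same chromosome.

    Ties resolve to the lower-coordinate origin.  ``active_only`` restricts
    the search universe to early/late origins (requires an origin_class or
    true_type column).  Genes on chromosomes without origins get category
    'none' and no origin id.

    Returns a frame indexed by gene_id with columns origin_id, distance,
    orientation, origin_class, category.
    """
    origins = origins.reset_index(drop=True)
    class_col = "origin_class" if "origin_class" in origins.columns else (
        "true_type" if "true_type" in origins.columns else None)
    if active_only:
        if class_col is None:
            raise ValueError("active_only requires an origin class column")
        origins = origins[origins[class_col].isin(["early", "late"])].reset_index(drop=True)

    rows = []
    by_chrom = {c: g.sort_values("center").reset_index(drop=True)
                for c, g in origins.groupby("chrom")}
    for _, g in genes.iterrows():
        sub = by_chrom.get(g["chrom"])
        if sub is None or sub.empty:
            rows.append((g["gene_id"], None, np.nan, "NA", None, "none"))
            continue
        centers = sub["center"].to_numpy()
        tss = int(g["tss"])
        right = np.searchsorted(centers, tss)
        left = min(max(right - 1, 0), centers.size - 1)
        right = min(right, centers.size - 1)
        dl, dr = abs(tss - centers[left]), abs(centers[right] - tss)
        pick = left if dl <= dr else right  # tie -> lower coordinate
        center = int(centers[pick])
        dist = abs(tss - center)
        oclass = sub.iloc[pick][class_col] if class_col else None
        rows.append((g["gene_id"], sub.iloc[pick]["origin_id"], float(dist),
                     orientation(tss, g["strand"], center), oclass,
                     distance_category(dist)))
    out = pd.DataFrame(rows, columns=["gene_id", "origin_id", "distance",
                                      "orientation", "origin_class", "category"])
    return out.set_index("gene_id")


def deg_origin_bias(relations: pd.DataFrame, de_direction: Mapping[str, str],
                    max_dist: int = 5000) -> Dict[str, object]:
    """Down/up-regulation counts stratified by gene–origin relation.

    ``de_direction`` maps gene id -> 'up' | 'down' for the differentially
    expressed genes of interest.  Returns per-stratum counts/proportions for
    distance category, origin class, and orientation (the latter two among
    genes with distance < ``max_dist``), plus two-sided Fisher tests for the
    late-vs-early and HO-vs-CD contrasts.  Contrasts with an empty stratum
    are skipped with a warning.
    """
    de = pd.Series(de_direction)
    missing = de.index.difference(relations.index)
    if len(missing):
        raise ValueError(f"DE genes absent from relations: {list(missing[:5])}")
    rel = relations.loc[de.index].assign(de=de)

    def stack(frame, column):
        tab = (frame.groupby([column, "de"], dropna=False).size()
               .unstack("de", fill_value=0))
        for col in ("down", "up"):
            if col not in tab.columns:
                tab[col] = 0
        tab = tab[["down", "up"]]
        tab["down_frac"] = tab["down"] / (tab["down"] + tab["up"]).replace(0, np.nan)
        return tab

    near = rel[rel["distance"] < max_dist]
    result: Dict[str, object] = {
        "by_distance": stack(rel, "category"),
        "by_origin_class": stack(near, "origin_class"),
        "by_orientation": stack(near, "orientation"),
    }

    def contrast(tab, a, b, label):
        if a not in tab.index or b not in tab.index:
            warnings.warn(f"{label}: stratum missing, contrast skipped")
            return None
        table = (int(tab.loc[a, "down"]), int(tab.loc[a, "up"]),
                 int(tab.loc[b, "down"]), int(tab.loc[b, "up"]))
        if min(table[0] + table[1], table[2] + table[3]) == 0:
            warnings.warn(f"{label}: empty stratum, contrast skipped")
            return None
        p, odds = fisher_exact_2x2(*table, sided="two")
        return {"table": table, "p": p, "odds_ratio": odds}

    result["late_vs_early"] = contrast(result["by_origin_class"], "late", "early",
                                       "late-vs-early")
    result["ho_vs_cd"] = contrast(result["by_orientation"], "HO", "CD", "HO-vs-CD")
    return result
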