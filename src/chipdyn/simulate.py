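"""Synthetic genomes, annotations and signal tracks with known ground truth.

The generator emulates the study design the pipeline analyses: cells
arrested in G1 and released into hydroxyurea (timepoints G1, HU45, HU90),
assayed by ChIP (IP + input), replication incorporation (EdU) and RNA
counting, across a wild-type and two checkpoint-deficient genotypes.

Signal model (negative binomial counts throughout, dispersion ``alpha`` with
var = mu + alpha * mu^2):

* IP tracks: flat background at ``depth`` reads/bin, a rectangular promoter
  component over the 500-bp scoring window upstream of each TSS whose height
  realises a per-gene log2 enrichment (planted DB genes shift that
  enrichment by ``db_effect`` between G1 and HU), and a flat fork component
  within the fork extent of each origin fired for that genotype/timepoint.
* input tracks: background only.
* EdU tracks: plateau over the fork extent of fired origins on a near-zero
  background, reported on a normalized scale (counts / depth).  Firing
  program: G1 none; wild type fires early origins only; checkpoint-deficient
  genotypes fire early and late; inactive origins never fire.  The extent
  grows with time in HU (half extent at the first timepoint).
* RNA counts: per-gene NB means; planted DEGs shift by ``deg_log2fc``
  between G1 and HU conditions; in checkpoint-deficient genotypes genes near
  late origins (<5 kb) receive an extra negative shift with probability
  ``ho_down_bias`` (head-on genes) or ``cd_down_bias`` (co-directional),
  emulating replication–transcription conflicts.

A single integer seed drives one root SeedSequence; per-sample child streams
are spawned deterministically, so identical configs give byte-identical
outputs regardless of generation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import DesignError, PlacementError
from .genome import BinnedTrack, GenomeLayout

GENOTYPES = ("WT", "rad53-kd", "mrc1-d", "other")
CHECKPOINT_DEFICIENT = ("rad53-kd", "mrc1-d")
TIMEPOINTS = ("G1", "HU45", "HU90")
ASSAYS = ("IP", "input", "EdU", "RNA")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults emulate a scaled yeast genome: 4 chromosomes x 750 kb holding
    2000 genes and 120 origins with the early/late/inactive mix observed in
    origin databases, NB read noise at 50 reads/bin, a 10-kb fork extent,
    and conflict-bias probabilities 0.8 (head-on) vs 0.4 (co-directional).
    """

    n_chromosomes: int = 4
    chrom_length: int = 750_000
    bin_width: int = 25
    n_genes: int = 2000
    n_origins: int = 120
    fraction_early: float = 0.31
    fraction_late: float = 0.32
    fraction_inactive: float = 0.37
    n_db_genes: int = 150
    db_effect: float = 1.0            # log2 shift of promoter enrichment G1 -> HU
    promoter_log2: float = 2.0        # mean baseline promoter enrichment (log2 IP/input)
    promoter_log2_sd: float = 0.5     # between-gene spread of baseline enrichment
    fork_extent: int = 10_000         # bp of synthesis around a fired origin
    fork_amplitude: float = 1.0       # fork component, in multiples of depth
    nb_dispersion: float = 0.05       # NB alpha; 0 -> Poisson
    depth: float = 50.0               # mean background reads per bin
    edu_plateau: float = 4.0          # EdU plateau on the normalized scale
    edu_background: float = 0.2
    rna_mean: float = 200.0           # mean RNA counts per gene
    n_deg: int = 200
    deg_log2fc: float = 2.0
    conflict_log2fc: float = -1.5     # extra shift for conflict-suppressed genes
    ho_down_bias: float = 0.8
    cd_down_bias: float = 0.4
    hu_global_log2: float = 0.3       # global promoter amplitude drift G1 -> HU
    seed: int = 0

    def __post_init__(self):
        fr = (self.fraction_early, self.fraction_late, self.fraction_inactive)
        if any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("origin-type fractions must lie in [0,1] and sum to 1")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_origins",
                     "n_db_genes", "n_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.chrom_length % self.bin_width:
            raise ValueError("chrom_length must be divisible by bin_width")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)},
            bin_width=self.bin_width,
        )


@dataclass(frozen=True)
class SampleDesign:
    genotype: str
    timepoint: str
    assay: str
    replicate: int = 1

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise DesignError(f"unknown genotype {self.genotype!r}")
        if self.timepoint not in TIMEPOINTS:
            raise DesignError(f"unknown timepoint {self.timepoint!r}")
        if self.assay not in ASSAYS:
            raise DesignError(f"unknown assay {self.assay!r}")

    @property
    def name(self) -> str:
        return f"{self.genotype}_{self.timepoint}_{self.assay}_rep{self.replicate}"


@dataclass
class GroundTruth:
    """Planted effects: what a correct caller should recover."""
    db_genes: Dict[str, float]          # gene -> signed log2 promoter shift
    origin_types: Dict[str, str]        # origin -> early|late|inactive
    deg: Dict[str, float]               # gene -> planted log2FC
    orientation_bias: Dict[str, bool]   # gene -> conflict-suppressed flag
    promoter_levels: Dict[str, float] = field(default_factory=dict)
    # gene -> baseline log2 promoter enrichment, fixed across samples

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


# -- RNG plumbing -----------------------------------------------------------

_STREAMS = {"annotation": 0, "truth": 1, "chip": 2, "edu": 3, "rna": 4, "null": 5}


def _rng(config: SimConfig, stream: str, *key: int) -> np.random.Generator:
    """Deterministic child stream for (config.seed, stream, key...)."""
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(_STREAMS[stream], *key))
    return np.random.default_rng(ss)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, alpha) with var = mu + alpha mu^2; Poisson when alpha == 0."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    if alpha <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / alpha
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


# -- annotation -------------------------------------------------------------

def generate_annotation(config: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place genes, origins and a small blacklist on the toy genome.

    Genes sit on a jittered grid (balanced strands, promoter windows never
    overlap); origin centers sit on an offset grid so fork extents rarely
    reach promoters of unrelated chrom" regions.  Raises PlacementError when
    the requested density cannot be placed without overlap.
    """
    layout = config.layout()
    rng = _rng(config, "annotation")
    chroms = list(layout.chroms)

    # genes: round-robin over chromosomes on an even grid with jitter
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1
    margin = 1000
    gene_rows = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        usable = config.chrom_length - 2 * margin
        spacing = usable / n
        # adjacent promoter windows must be disjoint (divergent pairs need a
        # 1000-bp TSS gap) so planted effects stay attributable to one gene
        if spacing * 0.75 < 1050:
            raise PlacementError(
                f"{n} genes on {chrom}: spacing {spacing:.0f} bp cannot keep "
                "500-bp promoter windows disjoint")
        jitter = rng.integers(-int(spacing // 8), int(spacing // 8) + 1, size=n)
        tss = (margin + (np.arange(n) + 0.5) * spacing + jitter).astype(int)
        strands = np.where(np.arange(n) % 2 == 0, "+", "-")
        strands = rng.permutation(strands)
        lengths = rng.integers(800, 2000, size=n)
        for t, s, ln in zip(tss, strands, lengths):
            end = t + ln if s == "+" else t - ln
            end = int(np.clip(end, 0, config.chrom_length))
            gene_rows.append((f"g{gid:05d}", chrom, int(t), s, end))
            gid += 1
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "tss", "strand", "gene_end"])

    # origins: offset grid, non-overlapping centers
    per_chrom_o = [config.n_origins // len(chroms)] * len(chroms)
    for i in range(config.n_origins % len(chroms)):
        per_chrom_o[i] += 1
    origin_rows = []
    oid = 0
    for chrom, n in zip(chroms, per_chrom_o):
        if n == 0:
            continue
        spacing = config.chrom_length / n
        if spacing < 2 * config.bin_width:
            raise PlacementError(f"{n} origins on {chrom}: centers would collide")
        jitter = rng.integers(-int(spacing // 5), int(spacing // 5) + 1, size=n)
        centers = ((np.arange(n) + 0.5) * spacing + jitter).astype(int)
        centers = np.clip(centers, 0, config.chrom_length - 1)
        if np.unique(centers).size != n:
            raise PlacementError(f"origin centers collide on {chrom}")
        for c in centers:
            origin_rows.append((f"ori{oid:04d}", chrom, int(c)))
            oid += 1
    origins = pd.DataFrame(origin_rows, columns=["origin_id", "chrom", "center"])

    # true origin types per configured fractions
    n_o = len(origins)
    n_early = int(round(config.fraction_early * n_o))
    n_late = int(round(config.fraction_late * n_o))
    n_late = min(n_late, n_o - n_early)
    types = np.array(["early"] * n_early + ["late"] * n_late +
                     ["inactive"] * (n_o - n_early - n_late))
    origins["true_type"] = rng.permutation(types)

    # a couple of hyper-ChIPable blacklist regions per chromosome
    bl_rows = []
    for k, chrom in enumerate(chroms):
        for j in range(2):
            start = int(rng.integers(0, config.chrom_length - 3000))
            bl_rows.append((chrom, start, start + int(rng.integers(500, 3000)),
                            f"hc{k}_{j}"))
    blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end", "name"])
    return genes, origins, blacklist


def generate_truth(config: SimConfig, genes: pd.DataFrame,
                   origins: pd.DataFrame) -> GroundTruth:
    """Draw the planted effects: DB genes, DEGs, conflict-suppressed genes."""
    rng = _rng(config, "truth")
    gene_ids = genes["gene_id"].to_numpy()
    levels = rng.normal(config.promoter_log2, config.promoter_log2_sd,
                        size=gene_ids.size)
    db_pick = rng.choice(gene_ids, size=min(config.n_db_genes, gene_ids.size),
                         replace=False)
    signs = rng.choice([1.0, -1.0], size=db_pick.size, p=[0.7, 0.3])
    db_genes = {g: float(s * config.db_effect) for g, s in zip(db_pick, signs)}

    deg_pick = rng.choice(gene_ids, size=min(config.n_deg, gene_ids.size),
                          replace=False)
    deg_signs = rng.choice([1.0, -1.0], size=deg_pick.size)
    deg = {g: float(s * config.deg_log2fc) for g, s in zip(deg_pick, deg_signs)}

    # conflict suppression near late origins, orientation-biased
    from .gene_origin import nearest_origin
    rel = nearest_origin(genes, origins)
    near_late = rel[(rel["origin_class"] == "late") & (rel["distance"] < 5000)]
    bias: Dict[str, bool] = {}
    for g, row in near_late.iterrows():
        p = config.ho_down_bias if row["orientation"] == "HO" else config.cd_down_bias
        bias[g] = bool(rng.random() < p)
    truth = GroundTruth(
        db_genes=db_genes,
        origin_types=dict(zip(origins["origin_id"], origins["true_type"])),
        deg=deg,
        orientation_bias=bias,
        promoter_levels=dict(zip(gene_ids, map(float, levels))),
    )
    return truth


# -- firing program ---------------------------------------------------------

def fired_origins(origins: pd.DataFrame, truth: GroundTruth, genotype: str,
                  timepoint: str) -> pd.DataFrame:
    """Origins that have fired for a genotype/timepoint.

    G1: none.  WT: early only.  Checkpoint-deficient: early and late.
    Inactive origins never fire.
    """
    if genotype not in GENOTYPES:
        raise DesignError(f"unknown genotype {genotype!r}")
    if timepoint == "G1":
        return origins.iloc[0:0]
    types = origins["origin_id"].map(truth.origin_types)
    if genotype in CHECKPOINT_DEFICIENT:
        mask = types.isin(["early", "late"])
    else:
        mask = types == "early"
    return origins[mask.to_numpy()]


def _fork_extent_at(config: SimConfig, timepoint: str) -> int:
    return config.fork_extent // 2 if timepoint == "HU45" else config.fork_extent


def _add_plateau(vec: np.ndarray, bin_width: int, center: int, extent: int,
                 height: float, chrom_length: int) -> None:
    lo = max(center - extent, 0)
    hi = min(center + extent, chrom_length)
    b0, b1 = lo // bin_width, -(-hi // bin_width)
    vec[b0:b1] += height


def _chip_mean_track(config: SimConfig, layout: GenomeLayout, genes: pd.DataFrame,
                     origins: pd.DataFrame, truth: GroundTruth,
                     sample: SampleDesign) -> Dict[str, np.ndarray]:
    """Expected IP counts per bin for one ChIP sample."""
    depth = config.depth
    means = {c: np.full(layout.n_bins(c), depth) for c in layout.chroms}
    in_hu = sample.timepoint != "G1"
    global_shift = config.hu_global_log2 if in_hu else 0.0
    w = config.bin_width
    for chrom, sub in genes.groupby("chrom", sort=False):
        base = sub["gene_id"].map(truth.promoter_levels)
        levels = base.fillna(config.promoter_log2).to_numpy() + global_shift
        if in_hu:
            levels += sub["gene_id"].map(truth.db_genes).fillna(0.0).to_numpy()
        heights = depth * (2.0 ** levels - 1.0)
        tss = sub["tss"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        starts = np.clip(np.where(plus, tss - 500, tss), 0, config.chrom_length)
        ends = np.clip(np.where(plus, tss, tss + 500), 0, config.chrom_length)
        b0 = starts // w
        b1 = -(-ends // w)
        vec = means[chrom]
        delta = np.zeros(vec.size + 1)
        np.add.at(delta, b0, heights)
        np.add.at(delta, b1, -heights)
        vec += np.cumsum(delta[:-1])
    if config.fork_amplitude > 0:
        fired = fired_origins(origins, truth, sample.genotype, sample.timepoint)
        extent = _fork_extent_at(config, sample.timepoint)
        for _, o in fired.iterrows():
            _add_plateau(means[o["chrom"]], config.bin_width, int(o["center"]),
                         extent, config.fork_amplitude * depth, config.chrom_length)
    return means


def simulate_chip_tracks(genes: pd.DataFrame, origins: pd.DataFrame,
                         truth: GroundTruth, design: Sequence[SampleDesign],
                         config: SimConfig) -> Dict[str, BinnedTrack]:
    """Simulate NB count tracks for every IP/input sample in the design.

    Every IP sample must have a matching input (same genotype, timepoint,
    replicate); violations raise DesignError.
    """
    names = [d.name for d in design]
    if len(set(names)) != len(names):
        raise DesignError("duplicate (genotype, timepoint, assay, replicate) in design")
    inputs = {(d.genotype, d.timepoint, d.replicate) for d in design if d.assay == "input"}
    for d in design:
        if d.assay == "IP" and (d.genotype, d.timepoint, d.replicate) not in inputs:
            raise DesignError(f"IP sample {d.name} has no matched input")
    layout = config.layout()
    tracks: Dict[str, BinnedTrack] = {}
    for i, d in enumerate(sorted((d for d in design if d.assay in ("IP", "input")),
                                 key=lambda s: s.name)):
        rng = _rng(config, "chip", i)
        if d.assay == "IP":
            means = _chip_mean_track(config, layout, genes, origins, truth, d)
        else:
            means = {c: np.full(layout.n_bins(c), config.depth) for c in layout.chroms}
        data = {c: _nb_draw(rng, m, config.nb_dispersion) for c, m in means.items()}
        tracks[d.name] = BinnedTrack(layout, data, "counts")
    return tracks


def simulate_edu_track(origins: pd.DataFrame, truth: GroundTruth, genotype: str,
                       timepoint: str, config: SimConfig,
                       noise: bool = True, replicate: int = 1) -> BinnedTrack:
    """Replication-incorporation track on the normalized (plateau ~4) scale."""
    layout = config.layout()
    levels = {c: np.full(layout.n_bins(c), config.edu_background)
              for c in layout.chroms}
    fired = fired_origins(origins, truth, genotype, timepoint)
    extent = _fork_extent_at(config, timepoint)
    for _, o in fired.iterrows():
        _add_plateau(levels[o["chrom"]], config.bin_width, int(o["center"]),
                     extent, config.edu_plateau - config.edu_background,
                     config.chrom_length)
    if not noise:
        return BinnedTrack(layout, levels, "edu")
    rng = _rng(config, "edu", GENOTYPES.index(genotype), TIMEPOINTS.index(timepoint),
               replicate)
    depth = max(config.depth, 1.0)
    data = {c: _nb_draw(rng, lv * depth, config.nb_dispersion) / depth
            for c, lv in levels.items()}
    return BinnedTrack(layout, data, "edu")


def simulate_rna_counts(genes: pd.DataFrame, truth: GroundTruth,
                        design: Sequence[SampleDesign],
                        config: SimConfig) -> pd.DataFrame:
    """Gene x sample NB count table for the RNA samples of a design.

    G1 is the reference condition; planted DEGs shift by their signed
    log2FC in HU samples, and conflict-suppressed genes (near fired late
    origins in checkpoint-deficient genotypes) get ``conflict_log2fc`` on
    top.
    """
    rna = [d for d in design if d.assay == "RNA"]
    if not rna:
        raise DesignError("design contains no RNA samples")
    rng_base = _rng(config, "rna", 0)
    gene_ids = genes["gene_id"].to_numpy()
    baseline = rng_base.lognormal(mean=np.log(config.rna_mean), sigma=0.6,
                                  size=gene_ids.size)
    cols = {}
    for i, d in enumerate(sorted(rna, key=lambda s: s.name)):
        mu = baseline.copy()
        if d.timepoint != "G1":
            for j, g in enumerate(gene_ids):
                lfc = truth.deg.get(g, 0.0)
                if d.genotype in CHECKPOINT_DEFICIENT and truth.orientation_bias.get(g):
                    lfc += config.conflict_log2fc
                if lfc:
                    mu[j] *= 2.0 ** lfc
        rng = _rng(config, "rna", 1 + i)
        cols[d.name] = _nb_draw(rng, mu, config.nb_dispersion)
    out = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id")).astype(int)
    return out


def standard_design(n_reps: int = 2, genotypes: Sequence[str] = ("WT",) + CHECKPOINT_DEFICIENT,
                    timepoints: Sequence[str] = TIMEPOINTS,
                    assays: Sequence[str] = ("IP", "input")) -> List[SampleDesign]:
    """Fully crossed genotype x timepoint x assay x replicate design."""
    return [SampleDesign(g, t, a, r)
            for g in genotypes for t in timepoints for a in assays
            for r in range(1, n_reps + 1)]
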