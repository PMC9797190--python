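"""Self-contained benchmark simulations used by the test suite and the
results-reproduction script.

Each function simulates data with the generator's study conditions, runs the
relevant pipeline stage, and returns the measured performance.  Problem
sizes are the package's documented benchmark conditions (see
docs/methods.md): they are deliberately desk-scale.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import simulate as sim
from .diffbind import PromoterBindingShift, intersect_top_db
from .gene_origin import deg_origin_bias, nearest_origin
from .normalize import NormalizationConfig, average_replicates, log2_enrichment
from .origins import classify_origins, origin_edu_scores
from .promoter import empirical_promoter_p, promoter_scores
from .simulate import SampleDesign, SimConfig


def _db_experiment_scores(config: SimConfig, genes, origins, truth,
                          timepoints=("G1", "HU45"), n_reps: int = 2):
    """Simulate one ChIP experiment and return per-timepoint promoter scores."""
    design = [SampleDesign("WT", t, a, r)
              for t in timepoints for a in ("IP", "input")
              for r in range(1, n_reps + 1)]
    tracks = sim.simulate_chip_tracks(genes, origins, truth, design, config)
    scores = {}
    for t in timepoints:
        reps = []
        for r in range(1, n_reps + 1):
            ip = tracks[SampleDesign("WT", t, "IP", r).name]
            inp = tracks[SampleDesign("WT", t, "input", r).name]
            reps.append(log2_enrichment(ip, inp))
        fc = average_replicates(reps)
        scores[t] = promoter_scores(fc, genes)
    return scores


def db_recovery(seed: int, n_genes: int = 2000, n_db: int = 150,
                effect: float = 1.0, top_k: int = 300) -> Dict[str, float]:
    """Planted differential-binding recovery for one seed.

    Two independently simulated experiments; top-K selection per experiment,
    then intersection.  The fork component is off: this benchmark isolates
    promoter dynamics (the fork signal is exercised by the origin-typing
    benchmark).
    """
    base = dict(n_genes=n_genes, n_db_genes=n_db, db_effect=effect,
                fork_amplitude=0.0)
    cfg_a = SimConfig(seed=seed * 2 + 1, **base)
    cfg_b = SimConfig(seed=seed * 2 + 2, **base)
    genes, origins, _ = sim.generate_annotation(cfg_a)
    truth = sim.generate_truth(cfg_a, genes, origins)
    selections = []
    results = []
    for cfg in (cfg_a, cfg_b):
        scores = _db_experiment_scores(cfg, genes, origins, truth)
        res = PromoterBindingShift(scores["G1"], scores["HU45"]).fit(top_k=top_k)
        selections.append(res.selection)
        results.append(res)
    overlap = intersect_top_db(*selections)
    planted = set(truth.db_genes)
    recovered = [g for g in overlap if g in planted]
    false_members = [g for g in overlap if g not in planted]
    directions = results[0].residual_table.loc[recovered, "direction"]
    expected = ["up" if truth.db_genes[g] > 0 else "down" for g in recovered]
    sign_ok = int((directions.to_numpy() == np.array(expected)).sum())
    return {
        "recovery": len(recovered) / len(planted),
        "false_member_rate": len(false_members) / max(len(overlap), 1),
        "sign_fidelity": sign_ok / max(len(recovered), 1),
        "n_overlap": len(overlap),
    }


def db_recovery_median(seeds=range(10), **kw) -> Dict[str, float]:
    runs = [db_recovery(s, **kw) for s in seeds]
    return {k: float(np.median([r[k] for r in runs]))
            for k in ("recovery", "false_member_rate", "sign_fidelity")}


def origin_typing_accuracy(seed: int, noise: bool = True) -> float:
    """Agreement between classified and planted origin types for one seed."""
    cfg = SimConfig(seed=seed)
    genes, origins, _ = sim.generate_annotation(cfg)
    truth = sim.generate_truth(cfg, genes, origins)
    wt45 = sim.simulate_edu_track(origins, truth, "WT", "HU45", cfg, noise=noise)
    wt_scores = origin_edu_scores(wt45, origins)
    mutant_later = {}
    for g in sim.CHECKPOINT_DEFICIENT:
        tr = sim.simulate_edu_track(origins, truth, g, "HU90", cfg, noise=noise)
        mutant_later[g] = origin_edu_scores(tr, origins)
    classes = classify_origins(wt_scores, mutant_later)
    predicted = classes["origin_class"]
    true = pd.Series(truth.origin_types).reindex(predicted.index)
    return float((predicted == true).mean())


def origin_typing_accuracy_median(seeds=range(10), noise: bool = True) -> float:
    return float(np.median([origin_typing_accuracy(s, noise=noise) for s in seeds]))


def orientation_bias_run(seed: int, ho_p: float, cd_p: float,
                         n_near: int = 60, alpha: float = 0.05) -> bool:
    """One orientation-bias simulation; True when the HO-vs-CD Fisher test
    rejects at ``alpha``.

    Down/up labels are drawn per gene with orientation-dependent
    probabilities among the first ``n_near`` genes within 5 kb of an origin.
    """
    cfg = SimConfig(seed=seed, n_genes=400, n_origins=120,
                    ho_down_bias=ho_p, cd_down_bias=cd_p)
    genes, origins, _ = sim.generate_annotation(cfg)
    origins = origins.rename(columns={"true_type": "origin_class"})
    rel = nearest_origin(genes, origins)
    near = rel[rel["distance"] < 5000]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(97,)))
    chosen = near.index.to_numpy()[:n_near]
    directions = {}
    for g in chosen:
        p_down = ho_p if rel.loc[g, "orientation"] == "HO" else cd_p
        directions[g] = "down" if rng.random() < p_down else "up"
    report = deg_origin_bias(rel, directions)
    contrast = report["ho_vs_cd"]
    return contrast is not None and contrast["p"] < alpha


def orientation_bias_power(seeds=range(100), ho_p: float = 0.8,
                           cd_p: float = 0.4) -> float:
    return float(np.mean([orientation_bias_run(s, ho_p, cd_p) for s in seeds]))


def promoter_p_uniformity(seed: int, n_genes: int = 500,
                          n_null: int = 10000) -> Tuple[float, float]:
    """KS distance and p of empirical promoter p-values against U(0,1) on a
    signal-free (background-only) track."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_chromosomes=2,
                    chrom_length=400_000)
    genes, _, _ = sim.generate_annotation(cfg)
    layout = cfg.layout()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    data = {c: rng.normal(0.0, 1.0, layout.n_bins(c)) for c in layout.chroms}
    from .genome import BinnedTrack
    track = BinnedTrack(layout, data, "log2fc")
    p, _ = empirical_promoter_p(track, genes, n_null=n_null, seed=seed + 1)
    ks = sps.kstest(p.to_numpy(), "uniform")
    return float(ks.statistic), float(ks.pvalue)


def group_test_size(seed: int, n_sims: int = 1000, n_genes: int = 200,
                    group_size: int = 20, alpha: float = 0.05) -> float:
    """Rejection rate of the group-vs-rest rank-sum test on random groups."""
    from .diffbind import db_group_test
    rng = np.random.default_rng(seed)
    residuals = pd.Series(rng.normal(size=n_genes),
                          index=[f"g{i}" for i in range(n_genes)])
    reject = 0
    for _ in range(n_sims):
        group = rng.choice(residuals.index, size=group_size, replace=False)
        _, p = db_group_test(residuals, group)
        if p < alpha:
            reject += 1
    return reject / n_sims
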