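"""Self-validation experiments: the simulation studies that quantify the
pipeline's operating characteristics (null calibration, parameter recovery,
allele-signature recovery, linkage-filter completeness) on screens with
known ground truth.

Each function generates data with :mod:`sgafit.synthetic_screen`, runs the
ordinary analysis path, and scores the result against the planted truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import QuerySpec, SimConfig
from .differential_fitness import estimate_block_correlation, run_differential
from .interaction_calls import classify_trifecta
from .normalization import apply_linkage_filter, normalize_screen
from .synthetic_screen import (
    TRIFECTA_KINDS,
    make_genome,
    make_layout,
    plant_trifecta_category,
    plant_truth,
    simulate_full,
    simulate_screen,
)


def _queries(names=("mutA", "mutB", "mutC"), fp=0.0, fn=0.0, effect_sd=0.25):
    out = [QuerySpec(name="ctrl", control=True, fraction_positive=0, fraction_negative=0)]
    out += [
        QuerySpec(name=n, fraction_positive=fp, fraction_negative=fn, effect_sd=effect_sd)
        for n in names
    ]
    return out


def null_screen_calibration(
    n_screens: int = 20, n_genes: int = 1000, base_seed: int = 0, alpha: float = 0.05
) -> dict:
    """False calls on screens with no planted interactions.

    Every gene is null, so any padj < alpha in a mutant-control contrast is
    a false discovery.  Reports the fraction of tested genes falsely called
    (averaged over screens) and, for reference, the mean per-screen
    false-discovery proportion V/max(R, 1).
    """
    rates, fdps = [], []
    for i in range(n_screens):
        cfg = SimConfig(n_genes=n_genes, queries=_queries(), seed=base_seed + i)
        genome, layout, truth, plates = simulate_full(cfg)
        matrix, _ = normalize_screen(plates, layout, genome, truth.query_loci, "ctrl")
        fits = run_differential(matrix, control="ctrl")
        mc = fits[fits["contrast"].str.endswith("-ctrl")]
        called = mc[mc["padj"] < alpha]
        n_called_genes = called["gene_id"].nunique()
        rates.append(n_called_genes / mc["gene_id"].nunique())
        R = len(called)
        fdps.append(R / max(R, 1) if R > 0 else 0.0)
    return {
        "false_call_rate": float(np.mean(rates)),
        "mean_fdp": float(np.mean(fdps)),
        "n_screens": n_screens,
    }


def parameter_recovery(
    seed: int = 0,
    n_genes: int = 1000,
    fraction: float = 0.05,
    effect: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Recovery of planted interactions of fixed magnitude.

    ``fraction`` of genes receive +/-``effect`` for one mutant; reports the
    sensitivity (padj < alpha among planted genes surviving the filters),
    the mean absolute error of the effect estimates, and the consensus
    intra-quadruplicate correlation versus the generator value.
    """
    queries = _queries(names=("mutA",), fp=fraction / 2, fn=fraction / 2, effect_sd=0.0)
    queries[1].effect_mean = effect
    cfg = SimConfig(n_genes=n_genes, queries=queries, seed=seed)
    genome, layout, truth, plates = simulate_full(cfg)
    matrix, _ = normalize_screen(plates, layout, genome, truth.query_loci, "ctrl")
    consensus = estimate_block_correlation(matrix, "ctrl").consensus
    fits = run_differential(matrix, control="ctrl")
    fa = fits[fits["contrast"] == "mutA-ctrl"].set_index("gene_id")
    planted = truth.effects.query("query == 'mutA' and delta != 0").set_index("gene_id")[
        "delta"
    ]
    common = planted.index.intersection(fa.index)
    sens = float((fa.loc[common, "padj"] < alpha).mean())
    mae = float((fa.loc[common, "effect"] - planted.loc[common]).abs().mean())
    return {
        "sensitivity": sens,
        "effect_mae": mae,
        "rho_consensus": float(consensus),
        "rho_true": cfg.rho,
        "rho_error": float(abs(consensus - cfg.rho)),
        "n_planted": int(len(common)),
    }


def trifecta_category_screen(
    kind: str, seed: int, n_genes: int = 500, n_planted: int = 25, alpha: float = 0.05
) -> tuple[int, int]:
    """One screen planted with a single allele-signature category.

    Returns (correctly classified, total) over planted genes with magnitude
    >= 1.0 that survive the exclusion filters.
    """
    cfg = SimConfig(n_genes=n_genes, queries=_queries(names=("ref", "alt")), seed=seed)
    genome = make_genome(cfg.n_genes, cfg.n_chromosomes, cfg.spacing, cfg.seed)
    layout = make_layout(
        genome,
        plate_rows=cfg.plate_rows,
        plate_cols=cfg.plate_cols,
        quad=cfg.quad,
        control_empty_quadrants=cfg.control_empty_quadrants,
        seed=cfg.seed,
    )
    truth = plant_truth(genome, cfg)
    planted = plant_trifecta_category(truth, genome, kind, "ref", "alt", n_planted, seed)
    plates = simulate_screen(layout, truth, cfg, genome=genome)
    matrix, _ = normalize_screen(plates, layout, genome, truth.query_loci, "ctrl")
    fits = run_differential(matrix, control="ctrl", reference="ref")
    by = {c: t for c, t in fits.groupby("contrast")}
    tri = classify_trifecta(
        by["alt-ctrl"], by["ref-ctrl"], by["alt-ref"], alpha=alpha
    ).set_index("gene_id")
    big = [g for g, m in planted.items() if g in tri.index and m >= 1.0]
    correct = int(sum(tri.loc[g, "category"] == kind for g in big))
    return correct, len(big)


def trifecta_recovery(seeds=(0, 1, 2), **kwargs) -> dict:
    """Recovery rate over all six categories and several replicate screens."""
    correct = total = 0
    per_kind = {}
    for kind in TRIFECTA_KINDS:
        kc = kn = 0
        for seed in seeds:
            c, n = trifecta_category_screen(kind, seed, **kwargs)
            kc += c
            kn += n
        per_kind[kind] = (kc, kn)
        correct += kc
        total += kn
    return {
        "recovery_rate": correct / total if total else float("nan"),
        "n_genes_scored": total,
        "per_category": per_kind,
    }


def linkage_filter_check(seed: int = 0, n_genes: int = 400) -> dict:
    """The 500-kb filter must remove every artifact-penalized gene.

    The simulator penalizes genes inside the window around each query
    locus; this checks that the filter excludes all of them, that the
    boundary is inclusive at exactly the window, and that the first gene
    beyond it is retained.
    """
    cfg = SimConfig(n_genes=n_genes, queries=_queries(), seed=seed)
    genome, layout, truth, plates = simulate_full(cfg)
    matrix, report = normalize_screen(plates, layout, genome, truth.query_loci, "ctrl")
    penalized_total = excluded_count = 0
    for q, locus in truth.query_loci.items():
        penalized = set(
            truth.effects.query("query == @q and linked")["gene_id"]
        )
        present = set(matrix.loc[matrix["query"] == q, "gene_id"])
        penalized_total += len(penalized)
        excluded_count += len(penalized - present)
    # boundary behaviour on a synthetic map with a gene at exactly 500 kb
    bmap = pd.DataFrame(
        {
            "gene_id": ["q", "at", "beyond"],
            "chromosome": ["c", "c", "c"],
            "start": [0, 500_000, 500_001],
            "end": [100, 500_100, 500_101],
            "strand": ["+", "+", "+"],
        }
    )
    rep = apply_linkage_filter(bmap, "q", window=500_000)
    boundary_ok = set(rep["gene_id"]) == {"q", "at"}
    return {
        "excluded_fraction": excluded_count / penalized_total if penalized_total else 1.0,
        "n_penalized": penalized_total,
        "boundary_inclusive": bool(boundary_ok),
    }
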