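"""Exploratory summaries and end-to-end orchestration.

Tables here (PCA biplot coordinates, hierarchical clustering with the
+/-0.5 display colour classes, linkage profiles, volcano tables) are
plot-ready TSVs for any plotting layer; the ``run_pipeline`` entry point
chains simulate -> normalize -> fit -> call -> classify -> report and
writes a provenance manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import __version__
from .config import Config
from .errors import ProcessingError, UnknownLocusError
from .interaction_calls import call_interactions, classify_trifecta, overlap_counts
from .differential_fitness import run_differential
from .normalization import normalize_screen, remove_batch_effect
from .screen_io import (
    save_config,
    write_genome_bed,
    write_layout,
    write_plate_table,
    write_truth,
)
from .synthetic_screen import simulate_full

logger = logging.getLogger(__name__)

#: Display-only colour thresholds for cluster heatmaps (never used for calling).
DISPLAY_NEGATIVE = -0.5
DISPLAY_POSITIVE = 0.5


@dataclass
class PcaResult:
    """Sample scores, gene loadings and percent variance explained."""

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # genes x components
    variance_explained: np.ndarray  # %, sums to 100 over all components


@dataclass
class ClusterResult:
    """Agglomerative clustering of gene profiles."""

    gene_order: list[str]
    merges: np.ndarray          # scipy linkage matrix (pairs + heights)
    display: pd.DataFrame       # per-gene values with colour class


def pca_scores(matrix: pd.DataFrame) -> PcaResult:
    """Centered PCA of a gene x sample matrix (samples as observations).

    Missing values are imputed by the gene mean; each component's sign is
    fixed by making its largest-magnitude gene loading positive, so scores
    are reproducible.
    """
    if matrix.shape[1] < 2:
        raise ProcessingError("PCA needs at least 2 samples")
    X = matrix.T.values.astype(float)          # samples x genes
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_means, inds[1])
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * S
    total = np.sum(S**2)
    var_exp = (S**2 / total * 100.0) if total > 0 else np.zeros_like(S)
    comp = [f"PC{j + 1}" for j in range(len(S))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=matrix.index, columns=comp),
        variance_explained=var_exp,
    )


def uncentered_correlation_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - uncentered correlation; constant-zero profiles get the
    maximal distance (2.0)."""
    norms = np.sqrt(np.sum(X**2, axis=1))
    bad = norms == 0
    if bad.any():
        logger.warning("%d constant-zero profiles assigned maximal distance", bad.sum())
    safe = np.where(bad, 1.0, norms)
    G = (X / safe[:, None]) @ (X / safe[:, None]).T
    D = 1.0 - G
    D[bad, :] = 2.0
    D[:, bad] = 2.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def hcluster(
    matrix: pd.DataFrame, metric: str = "uncentered", linkage: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of genes over their per-strain profiles.

    Default distance is 1 - uncentered correlation with average linkage
    (the classic colony-cluster defaults); leaves are ordered by standard
    dendrogram traversal with ties broken by input order.  The display
    table carries the +/-0.5 colour classes used for heatmap rendering.
    """
    if len(matrix) < 2:
        raise ProcessingError("clustering needs at least 2 genes")
    X = matrix.values.astype(float)
    X = np.where(np.isnan(X), 0.0, X)
    if metric == "uncentered":
        D = uncentered_correlation_distance(X)
        Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    else:
        Z = hierarchy.linkage(X, method=linkage, metric=metric)
    order = hierarchy.leaves_list(Z)
    display = matrix.copy()
    classes = np.select(
        [matrix.values < DISPLAY_NEGATIVE, matrix.values > DISPLAY_POSITIVE],
        ["negative", "positive"],
        default="neutral",
    )
    for j, col in enumerate(matrix.columns):
        display[f"{col}_class"] = classes[:, j]
    return ClusterResult(
        gene_order=[matrix.index[i] for i in order],
        merges=Z,
        display=display,
    )


def linkage_profile(
    fits: pd.DataFrame,
    genome: pd.DataFrame,
    query_locus: str,
    contrast: str | None = None,
    window: int = 500_000,
) -> pd.DataFrame:
    """Signed genomic distance to the query locus vs interaction effect.

    Diagnostic table behind linkage plots: genes on the query chromosome
    with their distance (midpoint - query midpoint), effect, and an
    ``excluded`` flag for |distance| <= window.  ``empty_window`` attribute
    is set when no fitted gene lies on the query chromosome.
    """
    row = genome.loc[genome["gene_id"] == query_locus]
    if row.empty:
        raise UnknownLocusError(f"query locus '{query_locus}' not in genome")
    sub = fits if contrast is None else fits[fits["contrast"] == contrast]
    eff = sub.groupby("gene_id")["effect"].mean()
    g = genome[genome["chromosome"] == row["chromosome"].iloc[0]].copy()
    qmid = float((row["start"].iloc[0] + row["end"].iloc[0]) / 2.0)
    g["distance_bp"] = (g["start"] + g["end"]) / 2.0 - qmid
    g["effect"] = g["gene_id"].map(eff)
    out = g.dropna(subset=["effect"])[["gene_id", "distance_bp", "effect"]].copy()
    out["excluded"] = np.abs(out["distance_bp"]) <= window
    out.attrs["empty_window"] = out.empty
    return out.reset_index(drop=True)


def condition_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene x (query, batch) mean normalized values from the screen matrix."""
    piv = matrix.pivot_table(
        index="gene_id", columns=["query", "batch"], values="value", aggfunc="mean"
    )
    piv.columns = pd.MultiIndex.from_tuples(piv.columns, names=["query", "batch"])
    return piv


def strain_effects(fits: pd.DataFrame, control: str) -> pd.DataFrame:
    """Gene x strain effect matrix from the mutant-control contrasts."""
    sub = fits[fits["contrast"].str.endswith(f"-{control}")]
    return sub.pivot_table(index="gene_id", columns="contrast", values="effect")


def run_pipeline(config: Config, out_dir, simulate: bool = True) -> dict:
    """End-to-end run: simulate -> normalize -> fit -> call -> classify ->
    report, writing every table plus a provenance manifest to ``out_dir``.

    Returns a dict of the in-memory results.  Idempotent: identical config
    and seed give byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not simulate:
        raise NotImplementedError(
            "external plate tables are consumed via the normalize/fit subcommands"
        )
    sim = config.simulation
    genome, layout, truth, plates = simulate_full(sim)
    control = sim.control_query
    matrix, exclusions = normalize_screen(
        plates, layout, genome, truth.query_loci, control,
        min_fraction=config.min_fraction, window=config.linkage_window,
    )
    non_control = [q.name for q in sim.queries if not q.control]
    reference = config.reference or non_control[0]
    fits = run_differential(matrix, control=control, reference=reference)
    calls = call_interactions(fits, alpha=config.alpha, control=control)
    per_strain, shared = overlap_counts(calls) if calls["strain"].nunique() >= 2 else (
        pd.DataFrame(), pd.DataFrame()
    )

    trifecta = {}
    by_contrast = {c: t for c, t in fits.groupby("contrast")}
    for allele in non_control:
        if allele == reference:
            continue
        key_a, key_b, key_d = (
            f"{allele}-{control}", f"{reference}-{control}", f"{allele}-{reference}",
        )
        if key_d in by_contrast:
            trifecta[allele] = classify_trifecta(
                by_contrast[key_a], by_contrast[key_b], by_contrast[key_d],
                alpha=config.alpha,
            )

    means = condition_means(matrix)
    adjusted = remove_batch_effect(means)
    pca = pca_scores(adjusted)
    effects = strain_effects(fits, control)
    clusters = hcluster(effects.dropna()) if len(effects.dropna()) >= 2 else None
    profiles = {
        q: linkage_profile(
            fits[fits["contrast"] == f"{q}-{control}"] if q != control else fits,
            genome, truth.query_loci[q], window=config.linkage_window,
        )
        for q in truth.query_loci
        if q != control
    }

    # --- write the bundle
    write_genome_bed(genome, out / "genome.bed")
    write_layout(layout, out / "layout.tsv")
    write_truth(truth.effects, out / "truth.tsv")
    write_plate_table(plates, out / "plates.tsv")
    matrix.to_csv(out / "screen_matrix.tsv", sep="\t", index=False)
    exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)
    calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    if not per_strain.empty:
        per_strain.to_csv(out / "overlap_strains.tsv", sep="\t", index=False)
        shared.to_csv(out / "overlap_shared.tsv", sep="\t", index=False)
    for allele, table in trifecta.items():
        table.to_csv(out / f"trifecta_{allele}.tsv", sep="\t", index=False)
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pd.DataFrame(
        {"component": pca.scores.columns, "variance_explained_pct": pca.variance_explained}
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
    if clusters is not None:
        pd.DataFrame({"gene_id": clusters.gene_order}).to_csv(
            out / "cluster_order.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            clusters.merges, columns=["left", "right", "height", "size"]
        ).to_csv(out / "cluster_merges.tsv", sep="\t", index=False)
    for q, prof in profiles.items():
        prof.to_csv(out / f"linkage_profile_{q}.tsv", sep="\t", index=False)
    save_config(config, out / "config.resolved.yaml")

    manifest = {
        "tool": "sgafit",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_genes": int(genome.shape[0]),
        "n_observations": int(matrix.shape[0]),
        "n_calls": int(calls.shape[0]),
        "contrasts": sorted(fits["contrast"].unique()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "genome": genome,
        "layout": layout,
        "truth": truth,
        "plates": plates,
        "matrix": matrix,
        "exclusions": exclusions,
        "fits": fits,
        "calls": calls,
        "trifecta": trifecta,
        "pca": pca,
        "clusters": clusters,
        "profiles": profiles,
    }
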