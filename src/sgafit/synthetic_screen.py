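"""Synthetic SGA screens with known ground truth.

Emulates a deletion-library screen crossed with several query alleles plus a
neutral control query: quadruplicate pinning on 1536-format plates, three
independent batches, plate/row/column and smooth spatial artifacts,
intra-quadruplicate correlation, a decreasing variance-vs-colony-size trend,
colony dropout, empty control quadrants, and a linkage-induced fitness dip
around each query locus.  Every nuisance and every planted interaction is
recorded so downstream stages can be scored against truth.

Colony sizes are generated as ``2**(base + delta + batch + row + col +
spatial + block + eps)``; a dropped-out colony is emitted with size 0 and is
treated as missing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import QuerySpec, SimConfig
from .errors import CapacityError, StructuralError, UnknownLocusError
from .screen_io import GENOME_COLUMNS, LAYOUT_COLUMNS, PLATE_COLUMNS


@dataclass
class SimTruth:
    """Planted ground truth of one simulated screen.

    ``effects`` has one row per (gene, query) with the true log2 interaction
    effect ``delta`` and a ``linked`` flag for genes inside the linkage
    window of that query's locus.  ``nuisance`` is filled by
    :func:`simulate_screen` with the realized batch/row/column/spatial
    fields.
    """

    effects: pd.DataFrame           # gene_id, query, delta, linked
    query_loci: dict[str, str]      # query name -> locus gene_id
    seed: int
    linkage_window: int
    nuisance: dict[str, Any] = field(default_factory=dict)

    def delta_lookup(self) -> dict[tuple[str, str], float]:
        return {
            (g, q): d
            for g, q, d in self.effects[["gene_id", "query", "delta"]].itertuples(index=False)
        }


def make_genome(n_genes: int, n_chromosomes: int, spacing: int, seed: int) -> pd.DataFrame:
    """Lay out ``n_genes`` at regular ``spacing`` round-robin over chromosomes.

    Returns a genome map with BED-convention 0-based half-open coordinates.
    Deterministic given ``seed`` (used only for strand assignment).
    """
    if n_genes < 1 or n_chromosomes < 1 or n_genes < n_chromosomes:
        raise ValueError("need n_genes >= n_chromosomes >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    rng = np.random.default_rng([seed, 101])
    width = len(str(n_genes))
    gene_len = max(1, min(1500, spacing - 1))
    chrom = np.arange(n_genes) % n_chromosomes
    idx_on_chrom = np.arange(n_genes) // n_chromosomes
    starts = idx_on_chrom * spacing
    strands = rng.choice(["+", "-"], size=n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(n_genes)],
            "chromosome": [f"chr{c + 1}" for c in chrom],
            "start": starts,
            "end": starts + gene_len,
            "strand": strands,
        },
        columns=GENOME_COLUMNS,
    )


def make_layout(
    genome: pd.DataFrame,
    plate_rows: int = 32,
    plate_cols: int = 48,
    quad: int = 4,
    control_empty_quadrants: int = 0,
    seed: int = 0,
    n_plates: int | None = None,
) -> pd.DataFrame:
    """Assign each library gene to one 2x2 pinning block.

    Genes are shuffled across blocks (so genomic neighbours are not plate
    neighbours); a stated number of blocks is reserved as empty control
    quadrants; unused blocks are empty.  Libraries larger than one plate
    spill onto further plates in block order.
    """
    if quad != 4 or plate_rows % 2 or plate_cols % 2:
        raise ValueError("layout requires quad=4 and even plate dimensions (2x2 blocks)")
    rng = np.random.default_rng([seed, 102])
    genes = list(genome["gene_id"])
    blocks_per_plate = (plate_rows // 2) * (plate_cols // 2)
    needed = len(genes) + control_empty_quadrants
    auto_plates = max(1, -(-needed // blocks_per_plate))
    if n_plates is None:
        n_plates = auto_plates
    elif n_plates * blocks_per_plate < needed:
        raise CapacityError(
            f"library of {len(genes)} genes (+{control_empty_quadrants} control-empty "
            f"blocks) does not fit {n_plates} plate(s) of {blocks_per_plate} blocks"
        )
    total_blocks = n_plates * blocks_per_plate
    # Reserve control-empty quadrants, then scatter genes over the rest.
    reserved = rng.choice(total_blocks, size=control_empty_quadrants, replace=False)
    free = np.setdiff1d(np.arange(total_blocks), reserved)
    slots = rng.permutation(free)[: len(genes)]
    gene_of_block = {int(s): g for s, g in zip(slots, genes)}
    reserved_set = set(int(r) for r in reserved)

    records = []
    bc_per_plate = plate_cols // 2
    for b in range(total_blocks):
        plate = b // blocks_per_plate + 1
        within = b % blocks_per_plate
        br, bcol = divmod(within, bc_per_plate)
        gene = gene_of_block.get(b)
        kind = "library" if gene is not None else "empty"
        block_id = f"p{plate}_b{within + 1:03d}"
        for dr in (0, 1):
            for dc in (0, 1):
                records.append(
                    (plate, 2 * br + dr + 1, 2 * bcol + dc + 1, block_id, kind,
                     gene, b in reserved_set)
                )
    return pd.DataFrame(records, columns=LAYOUT_COLUMNS)


def _resolve_loci(genome: pd.DataFrame, queries: list[QuerySpec]) -> dict[str, str]:
    """Map each query to its locus gene; ``locus=None`` is placed at an
    evenly spaced quantile of the genome order (deterministic)."""
    gene_ids = list(genome["gene_id"])
    known = set(gene_ids)
    loci = {}
    auto = [q for q in queries if q.locus is None]
    for i, q in enumerate(queries):
        if q.locus is not None:
            if q.locus not in known:
                raise UnknownLocusError(f"query '{q.name}' locus '{q.locus}' not in genome")
            loci[q.name] = q.locus
    for j, q in enumerate(auto):
        pos = int(round((j + 1) / (len(auto) + 1) * (len(gene_ids) - 1)))
        loci[q.name] = gene_ids[pos]
    return loci


def _linked_mask(genome: pd.DataFrame, locus: str, window: int) -> np.ndarray:
    row = genome.loc[genome["gene_id"] == locus]
    if row.empty:
        raise UnknownLocusError(f"locus '{locus}' not in genome")
    mid = (genome["start"].values + genome["end"].values) / 2.0
    qmid = float((row["start"].iloc[0] + row["end"].iloc[0]) / 2.0)
    same = (genome["chromosome"] == row["chromosome"].iloc[0]).values
    return same & (np.abs(mid - qmid) <= window)


def plant_truth(genome: pd.DataFrame, config: SimConfig) -> SimTruth:
    """Draw planted interaction effects for every (gene, query).

    For each non-control query, ``round(fraction * n_genes)`` genes receive a
    positive / negative effect with magnitude ``|N(effect_mean, effect_sd)|``;
    the control query has delta = 0 everywhere.  Genes inside the linkage
    window of the query locus are flagged ``linked`` (they receive no special
    delta; the linkage artifact is an additive penalty applied at simulation
    time).
    """
    rng = np.random.default_rng([config.seed, 103])
    loci = _resolve_loci(genome, config.queries)
    genes = genome["gene_id"].values
    n = len(genes)
    frames = []
    for q in config.queries:
        delta = np.zeros(n)
        if not q.control:
            n_pos = int(round(q.fraction_positive * n))
            n_neg = int(round(q.fraction_negative * n))
            picked = rng.choice(n, size=n_pos + n_neg, replace=False)
            mags = np.abs(rng.normal(q.effect_mean, q.effect_sd, size=n_pos + n_neg))
            delta[picked[:n_pos]] = mags[:n_pos]
            delta[picked[n_pos:]] = -mags[n_pos:]
        linked = _linked_mask(genome, loci[q.name], config.linkage_window)
        frames.append(
            pd.DataFrame(
                {"gene_id": genes, "query": q.name, "delta": delta, "linked": linked}
            )
        )
    effects = pd.concat(frames, ignore_index=True)
    return SimTruth(
        effects=effects,
        query_loci=loci,
        seed=config.seed,
        linkage_window=config.linkage_window,
    )


def _spatial_field(rng: np.random.Generator, rows: int, cols: int, amplitude: float) -> np.ndarray:
    """A smooth random surface of roughly the requested log2 amplitude:
    a superposition of two low-frequency sinusoidal modes."""
    if amplitude == 0:
        return np.zeros((rows, cols))
    r = np.arange(rows)[:, None] / rows
    c = np.arange(cols)[None, :] / cols
    field = np.zeros((rows, cols))
    for _ in range(2):
        kr, kc = rng.uniform(0.5, 1.5, size=2)
        pr, pc = rng.uniform(0, 2 * np.pi, size=2)
        field = field + np.sin(2 * np.pi * kr * r + pr) * np.sin(2 * np.pi * kc * c + pc)
    peak = np.max(np.abs(field))
    return field * (amplitude / peak if peak > 0 else 0.0)


def simulate_screen(
    layout: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    genome: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate the raw colony-size table for every (query, batch) plate.

    The residual SD follows ``sigma0 * (1 + trend_strength * max(0, base -
    m))`` where ``m`` is the expected log2 size, so small colonies are
    noisier; a fraction ``rho`` of the residual variance is a block effect
    shared by the four colonies of a quadruplicate.  Linked genes receive an
    additive ``-linkage_penalty * (1 - d/W)`` log2 penalty inside the window,
    mimicking meiotic linkage to the query marker.
    """
    layout_genes = set(layout.loc[layout["gene_id"].notna(), "gene_id"])
    truth_genes = set(truth.effects["gene_id"])
    if not layout_genes <= truth_genes:
        raise StructuralError("layout and truth refer to different gene universes")
    rng = np.random.default_rng([config.seed, 104])
    delta = truth.delta_lookup()

    # Linkage penalty per (query, gene): -penalty * (1 - d/W) inside the window.
    penalty: dict[tuple[str, str], float] = {}
    if genome is not None and config.linkage_penalty > 0:
        mid = dict(zip(genome["gene_id"], (genome["start"] + genome["end"]) / 2.0))
        chrom = dict(zip(genome["gene_id"], genome["chromosome"]))
        for qname, locus in truth.query_loci.items():
            for g in layout_genes:
                if chrom[g] != chrom[locus]:
                    continue
                d = abs(mid[g] - mid[locus])
                if d <= config.linkage_window:
                    penalty[(qname, g)] = -config.linkage_penalty * (
                        1.0 - d / config.linkage_window
                    )

    batch_offsets = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    truth.nuisance["batch_offsets"] = {
        f"b{i + 1}": float(v) for i, v in enumerate(batch_offsets)
    }
    truth.nuisance["plates"] = {}

    queries = [q.name for q in config.queries]
    m_maps = {
        qname: {
            g: config.base + delta.get((g, qname), 0.0) + penalty.get((qname, g), 0.0)
            for g in layout_genes
        }
        for qname in queries
    }
    plates = sorted(layout["plate"].unique())
    records = []
    for bi in range(config.n_batches):
        batch = f"b{bi + 1}"
        for qname in queries:
            for plate in plates:
                sub = layout[layout["plate"] == plate]
                rows_idx = sub["row"].values - 1
                cols_idx = sub["col"].values - 1
                row_off = rng.normal(0.0, config.rowcol_sd, size=config.plate_rows)
                col_off = rng.normal(0.0, config.rowcol_sd, size=config.plate_cols)
                spatial = _spatial_field(
                    rng, config.plate_rows, config.plate_cols, config.spatial_amplitude
                )
                truth.nuisance["plates"][(batch, qname, f"p{plate}")] = {
                    "row": row_off, "col": col_off, "spatial": spatial,
                }
                genes = sub["gene_id"].values
                is_lib = sub["position_kind"].values == "library"
                m = sub["gene_id"].map(m_maps[qname]).values.astype(float)
                sd_tot = config.sigma0 * (
                    1.0 + config.trend_strength * np.maximum(0.0, config.base - m)
                )
                # Block effects: one draw per quadruplicate, shared by its 4 colonies.
                block_codes, block_uniques = pd.factorize(sub["block_id"].values)
                block_draw = rng.standard_normal(len(block_uniques))
                eps = rng.standard_normal(len(sub))
                logsize = (
                    m
                    + batch_offsets[bi]
                    + row_off[rows_idx]
                    + col_off[cols_idx]
                    + spatial[rows_idx, cols_idx]
                    + np.sqrt(config.rho) * sd_tot * block_draw[block_codes]
                    + np.sqrt(1.0 - config.rho) * sd_tot * eps
                )
                size = np.where(is_lib, np.power(2.0, logsize), 0.0)
                dropped = rng.random(len(sub)) < config.dropout_p
                size = np.where(is_lib & dropped, 0.0, size)
                records.append(
                    pd.DataFrame(
                        {
                            "batch": batch,
                            "query": qname,
                            "plate": f"p{plate}",
                            "row": rows_idx + 1,
                            "col": cols_idx + 1,
                            "size": size,
                            "position_kind": np.where(is_lib, "library", "empty"),
                            "gene_id": np.where(is_lib, genes, None),
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)[PLATE_COLUMNS]


TRIFECTA_KINDS = [
    "shared_positive",
    "shared_negative",
    "residual_restored",
    "increased_sensitivity",
    "unique_gain_positive",
    "unique_gain_negative",
]


def plant_trifecta_category(
    truth: SimTruth,
    genome: pd.DataFrame,
    kind: str,
    reference: str,
    allele: str,
    n_planted: int,
    seed: int,
    effect_mean: float = 1.0,
    effect_sd: float = 0.25,
) -> dict[str, float]:
    """Plant one allele-signature category into an otherwise-null truth.

    Per planted gene a magnitude m = |N(effect_mean, effect_sd)| is drawn
    and, with a random sign s for the sign-symmetric categories, the
    reference (B = reference-control) and allele (A = allele-control)
    effects are set so that the comparison D = allele-reference carries the
    category's pattern:

    * shared_{sign}: ref = allele = s m (D = 0);
    * residual_restored: ref = s m, allele = 0 (D = -s m, opposite B);
    * increased_sensitivity: ref = s m, allele = 2 s m (D = s m, same sign);
    * unique_gain_{sign}: ref = 0, allele = s m (D = s m, B null).

    Returns gene -> planted magnitude; mutates ``truth.effects``.
    """
    if kind not in TRIFECTA_KINDS:
        raise ValueError(f"unknown category '{kind}'")
    rng = np.random.default_rng([seed, 105])
    genes = genome["gene_id"].values
    picks = rng.choice(len(genes), size=n_planted, replace=False)
    mags = np.abs(rng.normal(effect_mean, effect_sd, size=n_planted))
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    eff = truth.effects.set_index(["gene_id", "query"])
    planted = {}
    for gi, m, s in zip(picks, mags, signs):
        gid = genes[gi]
        if kind == "shared_positive":
            d_ref, d_alt = m, m
        elif kind == "shared_negative":
            d_ref, d_alt = -m, -m
        elif kind == "residual_restored":
            d_ref, d_alt = s * m, 0.0
        elif kind == "increased_sensitivity":
            d_ref, d_alt = s * m, 2 * s * m
        elif kind == "unique_gain_positive":
            d_ref, d_alt = 0.0, m
        else:  # unique_gain_negative
            d_ref, d_alt = 0.0, -m
        eff.loc[(gid, reference), "delta"] = d_ref
        eff.loc[(gid, allele), "delta"] = d_alt
        planted[gid] = float(m)
    truth.effects = eff.reset_index()
    return planted


def simulate_full(config: SimConfig):
    """Convenience wrapper: genome -> layout -> truth -> plates.

    Returns ``(genome, layout, truth, plates)``; byte-identical output for
    identical configuration (including seed).
    """
    genome = make_genome(config.n_genes, config.n_chromosomes, config.spacing, config.seed)
    layout = make_layout(
        genome,
        plate_rows=config.plate_rows,
        plate_cols=config.plate_cols,
        quad=config.quad,
        control_empty_quadrants=config.control_empty_quadrants,
        seed=config.seed,
    )
    truth = plant_truth(genome, config)
    plates = simulate_screen(layout, truth, config, genome=genome)
    return genome, layout, truth, plates
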