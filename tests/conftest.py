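"""Shared fixtures: small synthetic screens and clean correlated matrices."""

import numpy as np
import pandas as pd
import pytest

import sgafit
from sgafit.config import QuerySpec, SimConfig


def null_queries():
    return [
        QuerySpec(name="ctrl", control=True, fraction_positive=0, fraction_negative=0),
        QuerySpec(name="mutA", fraction_positive=0, fraction_negative=0),
        QuerySpec(name="mutB", fraction_positive=0, fraction_negative=0),
        QuerySpec(name="mutC", fraction_positive=0, fraction_negative=0),
    ]


def cs_matrix(
    n_genes,
    rho,
    seed,
    queries=("ctrl", "mutA", "mutB", "mutC"),
    batches=("b1", "b2", "b3"),
    k=4,
    sd=1.0,
    effects=None,
):
    """Screen matrix with exact compound-symmetric quadruplicate blocks.

    ``effects`` maps (gene_id, query) -> mean shift, for planting signal.
    """
    rng = np.random.default_rng(seed)
    nb = len(queries) * len(batches)
    blk = np.sqrt(rho) * rng.standard_normal((n_genes, nb, 1))
    eps = np.sqrt(1 - rho) * rng.standard_normal((n_genes, nb, k))
    v = (blk + eps).reshape(n_genes, -1) * sd
    q = np.repeat(list(queries), len(batches) * k)
    b = np.tile(np.repeat(list(batches), k), len(queries))
    r = np.tile(np.arange(1, k + 1), len(queries) * len(batches))
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    df = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, nb * k),
            "query": np.tile(q, n_genes),
            "batch": np.tile(b, n_genes),
            "replicate": np.tile(r, n_genes),
            "value": v.ravel(),
            "weight": 1.0,
        }
    )
    if effects:
        shift = df.set_index(["gene_id", "query"]).index.map(
            lambda key: effects.get(key, 0.0)
        )
        df["value"] = df["value"] + np.asarray(shift, dtype=float)
    df["block_id"] = df["gene_id"] + "|" + df["query"] + "|" + df["batch"]
    return df


@pytest.fixture(scope="session")
def small_screen():
    """A modest 4-query screen with planted interactions, run end to end
    through simulation and normalization (shared across tests)."""
    cfg = SimConfig(n_genes=300, seed=11)
    genome, layout, truth, plates = sgafit.simulate_full(cfg)
    matrix, exclusions = sgafit.normalize_screen(
        plates, layout, genome, truth.query_loci, cfg.control_query
    )
    return {
        "config": cfg,
        "genome": genome,
        "layout": layout,
        "truth": truth,
        "plates": plates,
        "matrix": matrix,
        "exclusions": exclusions,
    }


@pytest.fixture(scope="session")
def small_fits(small_screen):
    fits = sgafit.run_differential(
        small_screen["matrix"], control="ctrl", reference="mutA"
    )
    return fits
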