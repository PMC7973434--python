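"""Plate normalization, exclusion filters, matrix assembly, batch removal."""

import numpy as np
import pandas as pd
import pytest

from sgafit.errors import ProcessingError, UnknownLocusError
from sgafit.normalization import (
    apply_linkage_filter,
    assemble_matrix,
    flag_failed_mutants,
    normalize_plate,
    remove_batch_effect,
)
from sgafit.synthetic_screen import make_genome


def grid_plate(values, kinds=None):
    """Build a one-plate table from a 2D array of sizes."""
    rows, cols = values.shape
    recs = []
    for r in range(rows):
        for c in range(cols):
            kind = kinds[r][c] if kinds is not None else "library"
            gene = f"g{r}_{c}" if kind == "library" else None
            recs.append(("b1", "q", "p1", r + 1, c + 1, values[r, c], kind, gene))
    return pd.DataFrame(
        recs,
        columns=["batch", "query", "plate", "row", "col", "size", "position_kind", "gene_id"],
    )


class TestNormalizePlate:
    def test_uniform_plate_all_zero(self):
        out = normalize_plate(grid_plate(np.full((8, 12), 77.0)))
        assert np.allclose(out["value"], 0.0)

    def test_pure_row_effect_absorbed(self):
        rows, cols = 8, 12
        sizes = np.array([[2.0**r * 100 for _ in range(cols)] for r in range(rows)])
        out = normalize_plate(grid_plate(sizes))
        assert np.allclose(out["value"], 0.0, atol=1e-9)

    def test_planted_smooth_gradient_removed(self):
        # plant a radial 0.5-log2 surface; after normalization the smooth
        # component (8x8 tile means) must drop below 0.1 log2 units
        rng = np.random.default_rng(0)
        rows, cols = 32, 48
        r = np.arange(rows)[:, None] / rows
        c = np.arange(cols)[None, :] / cols
        gradient = 0.5 * np.sin(np.pi * r) * np.sin(np.pi * c)
        noise = rng.normal(0, 0.05, size=(rows, cols))
        sizes = 2.0 ** (10 + gradient + noise)

        def tile_range(grid):
            tiles = [
                np.nanmean(grid[i : i + 8, j : j + 8])
                for i in range(0, rows, 8)
                for j in range(0, cols, 8)
            ]
            return max(tiles) - min(tiles)

        assert tile_range(gradient) > 0.4  # planted surface really is there
        out = normalize_plate(grid_plate(sizes))
        grid = np.full((rows, cols), np.nan)
        grid[out["row"] - 1, out["col"] - 1] = out["value"]
        assert tile_range(grid) < 0.1

    def test_plate_row_col_medians_zero(self):
        rng = np.random.default_rng(1)
        sizes = 2.0 ** rng.normal(10, 0.4, size=(32, 48))
        out = normalize_plate(grid_plate(sizes))
        grid = np.zeros((32, 48))
        grid[out["row"] - 1, out["col"] - 1] = out["value"]
        assert abs(np.median(grid)) < 1e-9
        assert np.max(np.abs(np.median(grid, axis=0))) < 1e-9
        assert np.max(np.abs(np.median(grid, axis=1))) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        sizes = 2.0 ** rng.normal(10, 0.3, size=(16, 24))
        a = normalize_plate(grid_plate(sizes))
        b = normalize_plate(grid_plate(sizes * 37.5))
        assert np.allclose(a["value"], b["value"], atol=1e-9)

    def test_sparse_plate_rejected(self):
        sizes = np.zeros((8, 12))
        sizes[0, :6] = 100.0  # only 6 of 96 grew
        with pytest.raises(ProcessingError, match="rejected"):
            normalize_plate(grid_plate(sizes))

    def test_zero_sizes_become_missing(self):
        sizes = np.full((8, 12), 50.0)
        sizes[3, 4] = 0.0
        out = normalize_plate(grid_plate(sizes))
        val = out.set_index(["row", "col"]).loc[(4, 5), "value"]
        assert np.isnan(val)


class TestFailedMutants:
    def control_plates(self, gene_sizes):
        recs = []
        for batch, sizes in gene_sizes.items():
            for i, (gene, size) in enumerate(sizes.items()):
                for rep in range(4):
                    recs.append(
                        (batch, "ctrl", "p1", 1 + 2 * (i // 10) + rep // 2,
                         1 + 2 * (i % 10) + rep % 2, size, "library", gene)
                    )
        return pd.DataFrame(
            recs,
            columns=["batch", "query", "plate", "row", "col", "size",
                     "position_kind", "gene_id"],
        )

    def test_zero_growth_flagged(self):
        sizes = {f"g{i}": 100.0 for i in range(20)}
        sizes["g0"] = 0.0
        report = flag_failed_mutants(self.control_plates({"b1": sizes}))
        assert set(report["gene_id"]) == {"g0"}
        assert (report["reason"] == "failed_control").all()

    def test_boundary_is_strict(self):
        sizes = {f"g{i}": 100.0 for i in range(20)}
        sizes["g0"] = 10.0  # exactly min_fraction * plate median (0.1 * 100)
        report = flag_failed_mutants(self.control_plates({"b1": sizes}), min_fraction=0.1)
        assert report.empty

    def test_batches_independent(self):
        ok = {f"g{i}": 100.0 for i in range(20)}
        bad = dict(ok, g0=0.0)
        report = flag_failed_mutants(self.control_plates({"b1": bad, "b2": ok}))
        assert list(report["batch"]) == ["b1"]

    def test_no_control_plates_errors(self):
        empty = pd.DataFrame(
            columns=["batch", "query", "plate", "row", "col", "size",
                     "position_kind", "gene_id"]
        )
        with pytest.raises(ProcessingError):
            flag_failed_mutants(empty)


class TestLinkageFilter:
    @pytest.fixture()
    def genome(self):
        # midpoints every 100 kb on chr1, one distant gene on chr2
        recs = [(f"g{i}", "chr1", i * 100_000, i * 100_000 + 1000, "+") for i in range(20)]
        recs.append(("far", "chr2", 0, 1000, "+"))
        return pd.DataFrame(
            recs, columns=["gene_id", "chromosome", "start", "end", "strand"]
        )

    def test_query_gene_itself_excluded(self, genome):
        report = apply_linkage_filter(genome, "g5")
        assert "g5" in set(report["gene_id"])
        assert report.set_index("gene_id").loc["g5", "distance_bp"] == 0

    def test_window_boundary_inclusive(self, genome):
        report = apply_linkage_filter(genome, "g5", window=500_000)
        excluded = set(report["gene_id"])
        assert "g0" in excluded and "g10" in excluded  # exactly 500 kb away
        report2 = apply_linkage_filter(genome, "g5", window=499_999)
        assert "g0" not in set(report2["gene_id"])

    def test_other_chromosome_retained(self, genome):
        report = apply_linkage_filter(genome, "g0", window=500_000)
        assert "far" not in set(report["gene_id"])

    def test_zero_window_excludes_only_exact_midpoint(self, genome):
        report = apply_linkage_filter(genome, "g5", window=0)
        assert set(report["gene_id"]) == {"g5"}

    def test_unknown_locus(self, genome):
        with pytest.raises(UnknownLocusError):
            apply_linkage_filter(genome, "nope")


class TestAssembleMatrix:
    def _normalized(self, genes, queries=("ctrl", "mutA", "mutB", "mutC"),
                    batches=("b1", "b2", "b3")):
        out = {}
        layout_recs = []
        for i, g in enumerate(genes):
            for dr in (0, 1):
                for dc in (0, 1):
                    layout_recs.append(
                        (1, 2 * (i // 4) + dr + 1, 2 * (i % 4) + dc + 1,
                         f"b{i}", "library", g, False)
                    )
        layout = pd.DataFrame(
            layout_recs,
            columns=["plate", "row", "col", "block_id", "position_kind",
                     "gene_id", "control_empty"],
        )
        for q in queries:
            for b in batches:
                recs = []
                for i, g in enumerate(genes):
                    for dr in (0, 1):
                        for dc in (0, 1):
                            recs.append(
                                (2 * (i // 4) + dr + 1, 2 * (i % 4) + dc + 1, g, 0.1)
                            )
                out[(b, q, "p1")] = pd.DataFrame(
                    recs, columns=["row", "col", "gene_id", "value"]
                )
        return out, layout

    def test_full_design_48_observations(self):
        normalized, layout = self._normalized(["g1", "g2"])
        matrix = assemble_matrix(normalized, layout)
        assert (matrix.groupby("gene_id").size() == 48).all()
        assert (matrix.groupby("block_id").size() == 4).all()

    def test_failed_batch_drops_16(self):
        normalized, layout = self._normalized(["g1", "g2"])
        exclusions = pd.DataFrame(
            [("g1", "failed_control", "b2", None, np.nan)],
            columns=["gene_id", "reason", "batch", "query", "distance_bp"],
        )
        matrix = assemble_matrix(normalized, layout, exclusions)
        counts = matrix.groupby("gene_id").size()
        assert counts["g1"] == 32 and counts["g2"] == 48

    def test_linked_gene_absent_for_that_query_only(self):
        normalized, layout = self._normalized(["g1", "g2"])
        exclusions = pd.DataFrame(
            [("g1", "linked", None, "mutA", 0.0)],
            columns=["gene_id", "reason", "batch", "query", "distance_bp"],
        )
        matrix = assemble_matrix(normalized, layout, exclusions)
        g1 = matrix[matrix["gene_id"] == "g1"]
        assert "mutA" not in set(g1["query"])
        assert len(g1) == 36
        assert len(matrix[matrix["gene_id"] == "g2"]) == 48


class TestRemoveBatchEffect:
    def _means(self, query_effects, batch_offsets, genes=5):
        cols = pd.MultiIndex.from_product(
            [list(query_effects), list(batch_offsets)], names=["query", "batch"]
        )
        data = np.array(
            [
                [query_effects[q] + batch_offsets[b] + 0.1 * g for q, b in cols]
                for g in range(genes)
            ]
        )
        return pd.DataFrame(data, index=[f"g{i}" for i in range(genes)], columns=cols)

    def test_additive_model_exact(self):
        means = self._means({"ctrl": 0.0, "mutA": -1.0}, {"b1": -1.0, "b2": 0.0, "b3": 1.0})
        adjusted = remove_batch_effect(means)
        expected = self._means({"ctrl": 0.0, "mutA": -1.0}, {"b1": 0.0, "b2": 0.0, "b3": 0.0})
        assert np.allclose(adjusted.values, expected.values, atol=1e-10)

    def test_zero_offsets_identity(self):
        means = self._means({"ctrl": 0.0, "mutA": 2.0}, {"b1": 0.0, "b2": 0.0})
        adjusted = remove_batch_effect(means)
        assert np.allclose(adjusted.values, means.values, atol=1e-12)

    def test_batch_means_equalized(self):
        means = self._means({"ctrl": 0.3, "mutA": -0.7}, {"b1": -1.0, "b2": 0.0, "b3": 1.0})
        adjusted = remove_batch_effect(means)
        per_batch = adjusted.T.groupby(level="batch").mean()
        assert np.allclose(per_batch.values - per_batch.values.mean(axis=0), 0, atol=1e-10)

    def test_single_batch_is_identity(self):
        means = self._means({"ctrl": 0.0, "mutA": 1.0}, {"b1": 0.5})
        adjusted = remove_batch_effect(means)
        assert np.allclose(adjusted.values, means.values)
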