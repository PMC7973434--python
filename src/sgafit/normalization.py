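"""Raw colony sizes -> linkage-filtered, artifact-corrected log2 fitness.

Per-plate normalization subtracts the plate median (log2 scale, over library
positions only — empty control quadrants would bias it), removes row and
column effects by median polish, subtracts a smooth spatial surface (9x9
moving median of the residuals), and re-polishes to convergence so that the
plate, row and column medians are all zero on complete plates.  Zero-size
colonies are growth failures, not fitness measurements, and become missing
values.

Two exclusion rules remove genes before modelling:

* failed mutants — per batch, a library gene whose median colony size on the
  control-query plates is below ``min_fraction`` x the plate median is
  dropped from that batch for all queries (determined independently per
  batch);
* linkage — genes whose midpoint lies within ``window`` bp (default 500 kb,
  boundary inclusive) of the query-locus midpoint on the same chromosome are
  dropped for that query, removing spurious interactions caused by meiotic
  linkage.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import ProcessingError, StructuralError, UnknownLocusError

logger = logging.getLogger(__name__)

MATRIX_COLUMNS = ["gene_id", "query", "batch", "replicate", "value", "weight", "block_id"]
EXCLUSION_COLUMNS = ["gene_id", "reason", "batch", "query", "distance_bp"]


def _nanmedian(a, axis=None, keepdims=False):
    # nanmedian warns on all-NaN slices (routine on plates with empty rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(a, axis=axis, keepdims=keepdims)


def flag_failed_mutants(
    control_plates: pd.DataFrame, min_fraction: float = 0.1
) -> pd.DataFrame:
    """Flag library genes that failed to grow on the control plates.

    A gene is flagged in a batch when its median control colony size is
    strictly below ``min_fraction`` x the plate median (library positions).
    Returns an exclusion report with reason ``failed_control``.
    """
    lib = control_plates[control_plates["position_kind"] == "library"]
    if lib.empty:
        raise ProcessingError("no control-query library positions supplied")
    reports = []
    for (batch, plate), sub in lib.groupby(["batch", "plate"], sort=True):
        plate_median = float(sub["size"].median())
        gene_median = sub.groupby("gene_id")["size"].median()
        failed = gene_median.index[gene_median < min_fraction * plate_median]
        for g in failed:
            reports.append((g, "failed_control", batch, None, np.nan))
    return pd.DataFrame(reports, columns=EXCLUSION_COLUMNS)


def _median_polish(values: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Alternately subtract row, column and overall medians (NaN-aware) until
    all three vanish; converges on generic complete plates."""
    v = values.copy()
    for _ in range(max_iter):
        row_med = _nanmedian(v, axis=1, keepdims=True)
        row_med = np.where(np.isnan(row_med), 0.0, row_med)
        v -= row_med
        col_med = _nanmedian(v, axis=0, keepdims=True)
        col_med = np.where(np.isnan(col_med), 0.0, col_med)
        v -= col_med
        overall = _nanmedian(v)
        overall = 0.0 if np.isnan(overall) else overall
        v -= overall
        moved = max(np.max(np.abs(row_med)), np.max(np.abs(col_med)), abs(overall))
        if moved < tol:
            break
    return v


def _moving_median(values: np.ndarray, window: int = 9) -> np.ndarray:
    """NaN-aware 2D moving median (edge-padded with NaN); the smooth spatial
    surface estimator."""
    half = window // 2
    padded = np.pad(values, half, mode="constant", constant_values=np.nan)
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        smooth = np.nanmedian(view.reshape(*values.shape, -1), axis=2)
    return np.where(np.isnan(smooth), 0.0, smooth)


def normalize_plate(
    plate: pd.DataFrame,
    min_live_fraction: float = 0.5,
    spatial_window: int = 9,
    polish_rounds: int = 2,
) -> pd.DataFrame:
    """Normalize one plate of one (batch, query).

    Returns a long table (row, col, gene_id, value) of normalized log2 sizes
    at library positions; zero-size colonies are missing.  Raises
    :class:`ProcessingError` if fewer than ``min_live_fraction`` of library
    positions grew.
    """
    required = {"row", "col", "size", "position_kind"}
    if not required <= set(plate.columns):
        raise StructuralError(f"plate table missing columns {sorted(required - set(plate.columns))}")
    n_rows = int(plate["row"].max())
    n_cols = int(plate["col"].max())
    grid = np.full((n_rows, n_cols), np.nan)
    lib = plate[plate["position_kind"] == "library"]
    if lib.empty:
        raise ProcessingError("plate has no library positions")
    live = lib["size"] > 0
    if live.mean() < min_live_fraction:
        raise ProcessingError(
            f"plate rejected: only {live.mean():.0%} of library positions grew "
            f"(< {min_live_fraction:.0%})"
        )
    r = lib["row"].values - 1
    c = lib["col"].values - 1
    with np.errstate(divide="ignore"):
        grid[r, c] = np.where(lib["size"].values > 0, np.log2(lib["size"].values), np.nan)

    grid -= _nanmedian(grid)                         # plate median (log2 scale)
    for _ in range(polish_rounds):                   # row/column median polish
        grid -= np.where(np.isnan(row_m := _nanmedian(grid, axis=1, keepdims=True)), 0, row_m)
        grid -= np.where(np.isnan(col_m := _nanmedian(grid, axis=0, keepdims=True)), 0, col_m)
    grid -= _moving_median(grid, spatial_window)     # smooth spatial surface
    grid = _median_polish(grid)                      # re-zero plate/row/col medians

    out = lib[["row", "col", "gene_id"]].copy()
    out["value"] = grid[r, c]
    return out.reset_index(drop=True)


def apply_linkage_filter(
    genome: pd.DataFrame,
    query_locus: str,
    window: int = 500_000,
    query: str | None = None,
) -> pd.DataFrame:
    """Exclude genes genetically linked to the query locus.

    A gene is excluded iff it lies on the query chromosome and the distance
    between interval midpoints is <= ``window`` (boundary inclusive).  The
    query gene itself is always excluded (distance 0).
    """
    row = genome.loc[genome["gene_id"] == query_locus]
    if row.empty:
        raise UnknownLocusError(f"query locus '{query_locus}' not in genome")
    mid = (genome["start"].values + genome["end"].values) / 2.0
    qmid = float((row["start"].iloc[0] + row["end"].iloc[0]) / 2.0)
    same = (genome["chromosome"] == row["chromosome"].iloc[0]).values
    dist = np.abs(mid - qmid)
    mask = same & (dist <= window)
    return pd.DataFrame(
        {
            "gene_id": genome.loc[mask, "gene_id"].values,
            "reason": "linked",
            "batch": None,
            "query": query,
            "distance_bp": dist[mask],
        },
        columns=EXCLUSION_COLUMNS,
    )


def assemble_matrix(
    normalized: dict[tuple[str, str, str], pd.DataFrame],
    layout: pd.DataFrame,
    exclusions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack normalized plates into the long screen matrix.

    ``normalized`` maps (batch, query, plate) -> output of
    :func:`normalize_plate`.  Replicates are numbered 1-4 within each 2x2
    block (row-major); block_id groups the technical replicates of one
    (gene, query, batch).  Excluded genes are dropped: ``failed_control``
    removes a (gene, batch) for all queries, ``linked`` removes a
    (gene, query) for all batches.  Missing colonies are absent rows.
    """
    frames = []
    for (batch, query, plate), table in normalized.items():
        sub = table.dropna(subset=["value", "gene_id"]).copy()
        sub["batch"] = batch
        sub["query"] = query
        frames.append(sub)
    if not frames:
        raise StructuralError("no normalized plates supplied")
    long = pd.concat(frames, ignore_index=True)
    layout_genes = set(layout.loc[layout["gene_id"].notna(), "gene_id"])
    bad = set(long["gene_id"]) - layout_genes
    if bad:
        raise StructuralError(f"normalized plates contain genes absent from layout: {sorted(bad)[:5]}")

    # replicate index 1..4 inside the 2x2 block, row-major
    long["replicate"] = (
        ((long["row"] - 1) % 2) * 2 + ((long["col"] - 1) % 2) + 1
    ).astype(int)
    long["block_id"] = (
        long["gene_id"].astype(str) + "|" + long["query"].astype(str) + "|" + long["batch"].astype(str)
    )
    long["weight"] = 1.0

    if exclusions is not None and not exclusions.empty:
        failed = exclusions[exclusions["reason"] == "failed_control"]
        if not failed.empty:
            drop = set(zip(failed["gene_id"], failed["batch"]))
            mask = [
                (g, b) in drop for g, b in zip(long["gene_id"], long["batch"])
            ]
            long = long[~np.array(mask)]
        linked = exclusions[exclusions["reason"] == "linked"]
        if not linked.empty:
            if linked["query"].isna().any():
                # linkage exclusions without a query apply to every query
                drop_genes = set(linked.loc[linked["query"].isna(), "gene_id"])
                long = long[~long["gene_id"].isin(drop_genes)]
            drop_q = set(zip(linked["gene_id"], linked["query"]))
            mask = [
                (g, q) in drop_q for g, q in zip(long["gene_id"], long["query"])
            ]
            long = long[~np.array(mask)]
    return long[MATRIX_COLUMNS].reset_index(drop=True)


def normalize_screen(
    plates: pd.DataFrame,
    layout: pd.DataFrame,
    genome: pd.DataFrame,
    query_loci: dict[str, str],
    control: str,
    min_fraction: float = 0.1,
    window: int = 500_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full normalization stage on a raw plate table.

    Returns ``(screen_matrix, exclusion_report)``.  ``query_loci`` maps each
    query name to its locus gene for the linkage filter.
    """
    exclusions = [flag_failed_mutants(plates[plates["query"] == control], min_fraction)]
    for qname, locus in query_loci.items():
        exclusions.append(apply_linkage_filter(genome, locus, window, query=qname))
    nonempty = [e for e in exclusions if not e.empty]
    report = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=EXCLUSION_COLUMNS)
    )

    normalized = {}
    for (batch, query, plate), sub in plates.groupby(["batch", "query", "plate"], sort=True):
        try:
            normalized[(batch, query, plate)] = normalize_plate(sub)
        except ProcessingError as exc:
            logger.warning("plate (%s, %s, %s) rejected: %s", batch, query, plate, exc)
    matrix = assemble_matrix(normalized, layout, report)
    return matrix, report


def remove_batch_effect(means: pd.DataFrame, batch_labels: list[str] | None = None) -> pd.DataFrame:
    """Subtract per-gene batch effects from a gene x (query, batch) matrix.

    Batch and query effects are estimated jointly per gene in an additive
    model; the batch component (sum-to-zero over batches) is removed and the
    grand mean restored.  Used only for PCA / clustering displays, never for
    inference.  Columns must be a 2-level MultiIndex (query, batch).
    """
    if not isinstance(means.columns, pd.MultiIndex) or means.columns.nlevels != 2:
        raise StructuralError("means must have MultiIndex columns (query, batch)")
    batches = means.columns.get_level_values(1)
    uniq = list(pd.unique(batches)) if batch_labels is None else list(batch_labels)
    if len(uniq) < 2:
        logger.warning("single batch: batch-effect removal is the identity")
        return means.copy()
    queries = means.columns.get_level_values(0)
    uq = list(pd.unique(queries))
    # Design: query dummies (full rank, no intercept) + sum-to-zero batch contrasts.
    Xq = np.stack([(queries == q).astype(float) for q in uq], axis=1)
    Xb = np.stack(
        [
            (batches == b).astype(float) - (batches == uniq[-1]).astype(float)
            for b in uniq[:-1]
        ],
        axis=1,
    )
    X = np.hstack([Xq, Xb])
    Y = means.values.T  # conditions x genes
    ok = ~np.isnan(Y)
    if ok.all():
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        batch_fit = Xb @ beta[len(uq):]
    else:
        batch_fit = np.zeros_like(Y)
        for j in range(Y.shape[1]):
            m = ok[:, j]
            if m.sum() < X.shape[1]:
                continue
            bj, *_ = np.linalg.lstsq(X[m], Y[m, j], rcond=None)
            batch_fit[:, j] = Xb @ bj[len(uq):]
    adjusted = means.copy()
    adjusted.iloc[:, :] = (Y - batch_fit).T
    return adjusted
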