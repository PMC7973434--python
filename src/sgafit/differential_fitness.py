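"""Moderated mixed-model differential-fitness testing.

Each gene's normalized log2 colony sizes across (query, batch, replicate)
are fitted with a weighted generalized-least-squares model: fixed effects
for query and batch, a compound-symmetric correlation ``rho`` within each
quadruplicate block (the four colonies of a double mutant on one plate are
technical replicates, not independent), and precision weights derived from
a fitted mean-variance trend (small colonies are noisier).  Per-gene
residual variances are shrunk toward a common prior by empirical-Bayes
moderation; contrasts (mutant - control, mutant - reference mutant) are
tested with moderated t-statistics on ``d0 + d_g`` degrees of freedom and
corrected per contrast by Benjamini-Hochberg.

Pipeline order: preliminary fits -> mean-variance trend -> weights ->
consensus block correlation -> per-gene GLS -> moderation -> contrasts -> BH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import ProcessingError, StructuralError

logger = logging.getLogger(__name__)

FIT_COLUMNS = ["gene_id", "contrast", "effect", "se", "t", "df", "p", "padj"]


# ---------------------------------------------------------------------------
# design

def build_design(
    cells: pd.DataFrame, control: str, queries: list[str], batches: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Design rows for (query, batch) cells: intercept = control baseline,
    one column per non-control query (its effect is query - control), batch
    treatment dummies (first batch as reference)."""
    non_control = [q for q in queries if q != control]
    cols = ["(Intercept)"] + [f"query[{q}]" for q in non_control] + [
        f"batch[{b}]" for b in batches[1:]
    ]
    X = np.zeros((len(cells), len(cols)))
    X[:, 0] = 1.0
    for j, q in enumerate(non_control, start=1):
        X[:, j] = (cells["query"] == q).astype(float)
    for j, b in enumerate(batches[1:], start=1 + len(non_control)):
        X[:, j] = (cells["batch"] == b).astype(float)
    return X, cols


# ---------------------------------------------------------------------------
# mean-variance trend

@dataclass
class MeanVarTrend:
    """Piecewise-linear trend of sqrt(residual SD) against mean fitted log2
    size, with flat extrapolation beyond the outermost knots."""

    knot_x: np.ndarray
    knot_y: np.ndarray  # sqrt(SD) at each knot, > 0

    def predict_sqrt_sd(self, x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.knot_x, self.knot_y)

    def predict_sd(self, x: np.ndarray) -> np.ndarray:
        return self.predict_sqrt_sd(x) ** 2


@dataclass
class GeneFit:
    """Per-gene GLS fit: coefficients, unscaled covariance, residual
    variance and degrees of freedom."""

    gene_id: str
    beta: np.ndarray
    cov_unscaled: np.ndarray  # (X' V^-1 X)^-1
    s2: float                 # residual variance
    df: int                   # residual degrees of freedom
    colnames: list[str]


@dataclass
class ModerationParams:
    """Empirical-Bayes prior (d0, s0^2) and per-gene posterior variances."""

    d0: float                 # prior df, may be inf
    s0_sq: float
    s_tilde_sq: np.ndarray    # pooled posterior variances, aligned to genes
    gene_ids: list[str]


@dataclass
class ConsensusCorrelation:
    """Per-gene intra-quadruplicate correlations and the shared consensus."""

    per_gene: pd.Series
    consensus: float
    block_size: int


def _preliminary_fits(matrix: pd.DataFrame, control: str):
    """Unweighted OLS per gene; returns per-gene residual SD, mean fitted
    value, and per-observation fitted values (trend regressor)."""
    queries = sorted(matrix["query"].unique())
    batches = sorted(matrix["batch"].unique())
    fitted = np.full(len(matrix), np.nan)
    records = []
    X_all, _ = build_design(matrix[["query", "batch"]], control, queries, batches)
    values = matrix["value"].values
    for gene, idx in matrix.groupby("gene_id").indices.items():
        X = X_all[idx]
        y = values[idx]
        if len(y) <= X.shape[1]:
            continue
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            continue
        yhat = X @ beta
        fitted[idx] = yhat
        dfree = len(y) - X.shape[1]
        s = np.sqrt(np.sum((y - yhat) ** 2) / dfree)
        records.append((gene, s, float(np.mean(yhat)), dfree))
    prelim = pd.DataFrame(records, columns=["gene_id", "sd", "abar", "df"])
    return prelim, fitted


def fit_trend(matrix: pd.DataFrame, control: str, n_knots: int = 30) -> MeanVarTrend:
    """Fit the variance-vs-colony-size trend across genes.

    Robust lowess of sqrt(residual SD) on mean fitted log2 size from
    preliminary unweighted per-gene fits, discretized to piecewise-linear
    knots.  With fewer than 50 genes the trend degenerates to a constant.
    """
    prelim, _ = _preliminary_fits(matrix, control)
    prelim = prelim[prelim["sd"] > 0]
    if prelim.empty:
        raise ProcessingError("no genes with positive residual SD")
    y = np.sqrt(prelim["sd"].values)
    x = prelim["abar"].values
    if len(prelim) < 50:
        logger.warning("only %d genes: variance trend degenerates to a constant", len(prelim))
        const = float(np.median(y))
        return MeanVarTrend(np.array([0.0]), np.array([max(const, 1e-6)]))
    smooth = lowess(y, x, frac=0.4, it=3, return_sorted=True)
    xs, ys = smooth[:, 0], smooth[:, 1]
    keep = np.concatenate(([True], np.diff(xs) > 0))
    xs, ys = xs[keep], ys[keep]
    n_knots = min(max(n_knots, 20), len(xs))
    pick = np.unique(np.linspace(0, len(xs) - 1, n_knots).round().astype(int))
    return MeanVarTrend(xs[pick], np.maximum(ys[pick], 1e-6))


def compute_weights(trend: MeanVarTrend, fitted: np.ndarray) -> np.ndarray:
    """Precision weights: inverse predicted variance, i.e. predicted
    sqrt(SD) to the power -4.  Strictly positive."""
    return trend.predict_sqrt_sd(fitted) ** -4.0


# ---------------------------------------------------------------------------
# consensus intra-block correlation

def estimate_block_correlation(
    matrix: pd.DataFrame, control: str, trim: float = 0.15
) -> ConsensusCorrelation:
    """Estimate the technical-replicate correlation within quadruplicates.

    Per gene, a one-way ANOVA moment estimator: the within-block mean
    square estimates (1-rho) sigma^2 (the design is constant within
    blocks, so within-block deviations carry no signal), and the mean
    square of the design residuals of the block means — with the correct
    degrees of freedom, blocks minus design rank — estimates
    sigma^2 (rho + (1-rho)/k).  The per-gene variance-ratio statistics are
    scale-free, so the consensus pools their bias-corrected mean across
    genes before inverting to the correlation scale; this avoids the
    downward Jensen bias of averaging per-gene correlations directly.
    Per-gene estimates (clamped to the identifiable range) are reported
    alongside for diagnostics.
    """
    queries = sorted(matrix["query"].unique())
    batches = sorted(matrix["batch"].unique())
    X_all, _ = build_design(matrix[["query", "batch"]], control, queries, batches)
    values = matrix["value"].values
    blocks = matrix["block_id"].values
    k_max = int(matrix.groupby("block_id").size().max())
    if k_max < 2:
        raise ProcessingError("all blocks are singletons: correlation unidentifiable")
    rhos = {}
    ratios, inv_ks = [], []
    lo = -1.0 / (k_max - 1) + 0.01
    for gene, idx in matrix.groupby("gene_id").indices.items():
        X, y, blk = X_all[idx], values[idx], blocks[idx]
        _, inv = np.unique(blk, return_inverse=True)
        ni = np.bincount(inv).astype(float)
        a = len(ni)
        gmeans = np.bincount(inv, weights=y) / ni
        ssw = float(((y - gmeans[inv]) ** 2).sum())
        dfw = int(ni.sum()) - a
        if dfw < 3:
            continue
        msw = ssw / dfw
        first = np.zeros(a, dtype=int)
        first[inv[::-1]] = np.arange(len(inv))[::-1]
        Xb = X[first]
        beta, _, rank, _ = np.linalg.lstsq(Xb, gmeans, rcond=None)
        dfb = a - rank
        if dfb < 1:
            continue
        if msw <= 0:
            msw = 1e-12 * max(float(np.var(gmeans)), 1e-300)
        rb = gmeans - Xb @ beta
        msb = float(rb @ rb) / dfb
        inv_k = float(np.mean(1.0 / ni))
        # E[msb/msw] = theta * dfw/(dfw-2) with theta = (rho+(1-rho)/k)/(1-rho);
        # msw = 0 (identical replicates) caps the ratio near-perfect correlation
        ratio = min(msb / msw * (dfw - 2) / dfw, 1e4)
        ratios.append(ratio)
        inv_ks.append(inv_k)
        rho_g = (ratio - inv_k) / (ratio + 1.0 - inv_k)
        rhos[gene] = float(np.clip(rho_g, lo, 0.99))
    if not rhos:
        raise ProcessingError("no gene had enough replicated blocks")
    per_gene = pd.Series(rhos, name="rho")
    theta = float(np.mean(ratios))
    inv_k = float(np.mean(inv_ks))
    consensus = (theta - inv_k) / (theta + 1.0 - inv_k)
    consensus = float(np.clip(consensus, lo, 0.99))
    return ConsensusCorrelation(per_gene=per_gene, consensus=consensus, block_size=k_max)


# ---------------------------------------------------------------------------
# per-gene GLS

def _whiten(y, X, w, blocks, rho):
    """Transform (y, X) so GLS on V = D^-1/2 R D^-1/2 reduces to OLS.

    Rows are scaled by sqrt(w); within each block the compound-symmetric
    correlation R = (1-rho)I + rho 11' is removed analytically via its
    eigendecomposition (mean direction vs within-block contrasts).
    """
    sw = np.sqrt(w)
    y2 = y * sw
    X2 = X * sw[:, None]
    if rho == 0:
        return y2, X2
    a = 1.0 / np.sqrt(1.0 - rho)
    _, inv = np.unique(blocks, return_inverse=True)
    counts = np.bincount(inv).astype(float)
    c = 1.0 / np.sqrt(1.0 + (counts - 1) * rho)
    ym = (np.bincount(inv, weights=y2) / counts)[inv]
    out_y = a * (y2 - ym) + c[inv] * ym
    out_X = np.empty_like(X2)
    for j in range(X2.shape[1]):
        Xm = (np.bincount(inv, weights=X2[:, j]) / counts)[inv]
        out_X[:, j] = a * (X2[:, j] - Xm) + c[inv] * Xm
    return out_y, out_X


def _collapse_blocks(y, X, w, blocks, rho):
    """Collapse observations to block means with their GLS-effective weights.

    Weight of a block mean: w_bar * n / (1 + (n-1) rho), the inverse of its
    variance under the compound-symmetric model with per-observation
    inverse-variance weights (constant within a block).
    """
    _, inv = np.unique(blocks, return_inverse=True)
    n = np.bincount(inv).astype(float)
    y_b = np.bincount(inv, weights=y) / n
    w_b = np.bincount(inv, weights=w) / n
    X_b = np.empty((len(n), X.shape[1]))
    for j in range(X.shape[1]):
        X_b[:, j] = np.bincount(inv, weights=X[:, j]) / n
    u_b = w_b * n / (1.0 + (n - 1.0) * rho)
    return y_b, X_b, u_b, np.arange(len(n))


def fit_gene_model(
    gene_id: str,
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    rho: float,
    blocks: np.ndarray,
    colnames: list[str],
) -> GeneFit | None:
    """Weighted GLS with block compound-symmetric correlation for one gene.

    Returns None (caller logs and drops the gene) when the design is rank
    deficient on the available observations.
    """
    y2, X2 = _whiten(y, X, weights, blocks, rho)
    beta, _, rank, _ = np.linalg.lstsq(X2, y2, rcond=None)
    p = X.shape[1]
    if rank < p or len(y) - p < 1:
        return None
    resid = y2 - X2 @ beta
    df = len(y) - p
    s2 = float(resid @ resid) / df
    cov_unscaled = np.linalg.inv(X2.T @ X2)
    return GeneFit(gene_id, beta, cov_unscaled, s2, df, colnames)


# ---------------------------------------------------------------------------
# empirical-Bayes moderation

def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, d: np.ndarray, gene_ids=None) -> ModerationParams:
    """Estimate the variance prior (d0, s0^2) and pool per-gene variances.

    Moment matching on log s2: a scaled inverse-chi-square prior implies
    log s2_g - digamma(d_g/2) + log(d_g/2) has mean log s0^2 +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2); d0 is
    recovered by numerically inverting the trigamma function.  When the
    excess variance is <= 0 the prior is degenerate (d0 = inf) and every
    posterior variance equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.all(s2 == 0):
        raise ProcessingError("all residual variances are zero: degenerate data")
    ok = (s2 > 0) & (d > 0)
    if ok.sum() < 2:
        raise ProcessingError("need at least 2 genes with positive variance")
    z = np.log(s2[ok])
    e = z - special.digamma(d[ok] / 2.0) + np.log(d[ok] / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d[ok] / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess variance: degenerate prior, geometric-mean estimate
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(z)))
    if np.isfinite(d0):
        s_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
    else:
        s_tilde = np.full_like(s2, s0_sq)
    if gene_ids is None:
        gene_ids = list(range(len(s2)))
    return ModerationParams(d0=d0, s0_sq=s0_sq, s_tilde_sq=s_tilde, gene_ids=list(gene_ids))


# ---------------------------------------------------------------------------
# contrasts, p-values, BH

def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_contrasts(
    fits: list[GeneFit],
    moderation: ModerationParams,
    contrasts: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Moderated t-tests for each contrast across genes, BH within contrast.

    t = effect / (s_tilde * sqrt(v)) on d0 + d_g degrees of freedom; with a
    degenerate prior (d0 = inf) this is a z-like statistic with the pooled
    SD.
    """
    if len(fits) != len(moderation.s_tilde_sq):
        raise StructuralError("fits and moderation cover different gene sets")
    rows = []
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        for fit, st2 in zip(fits, moderation.s_tilde_sq):
            if len(c) != len(fit.beta):
                raise StructuralError(
                    f"contrast '{name}' has {len(c)} entries for {len(fit.beta)} columns"
                )
            effect = float(c @ fit.beta)
            v = float(c @ fit.cov_unscaled @ c)
            se = np.sqrt(st2 * v)
            df = moderation.d0 + fit.df
            if se == 0:
                t = 0.0 if effect == 0 else np.sign(effect) * np.inf
            else:
                t = effect / se
            if np.isfinite(df):
                pval = 2.0 * stats.t.sf(abs(t), df)
            else:
                pval = 2.0 * stats.norm.sf(abs(t))
            rows.append((fit.gene_id, name, effect, se, t, df, min(pval, 1.0)))
    table = pd.DataFrame(rows, columns=FIT_COLUMNS[:-1])
    table["padj"] = np.nan
    for name in contrasts:
        mask = table["contrast"] == name
        table.loc[mask, "padj"] = adjust_bh(table.loc[mask, "p"].values)
    return table


def make_contrasts(
    colnames: list[str], control: str, queries: list[str], reference: str | None
) -> dict[str, np.ndarray]:
    """Contrast vectors for mutant-control and mutant-reference comparisons."""
    non_control = [q for q in queries if q != control]
    idx = {name: i for i, name in enumerate(colnames)}
    contrasts = {}
    for q in non_control:
        c = np.zeros(len(colnames))
        c[idx[f"query[{q}]"]] = 1.0
        contrasts[f"{q}-{control}"] = c
    if reference is not None:
        for q in non_control:
            if q == reference:
                continue
            c = np.zeros(len(colnames))
            c[idx[f"query[{q}]"]] = 1.0
            c[idx[f"query[{reference}]"]] = -1.0
            contrasts[f"{q}-{reference}"] = c
    return contrasts


def run_differential(
    matrix: pd.DataFrame,
    control: str,
    reference: str | None = None,
    rho: float | None = None,
) -> pd.DataFrame:
    """Full differential-fitness analysis on a screen matrix.

    Runs trend fitting, precision weighting, consensus-correlation
    estimation (unless ``rho`` is given), per-gene GLS, moderation and all
    mutant-control / mutant-reference contrasts.  Deterministic given its
    inputs.
    """
    if control not in set(matrix["query"]):
        raise StructuralError(f"control query '{control}' absent from matrix")
    queries = sorted(matrix["query"].unique())
    batches = sorted(matrix["batch"].unique())

    prelim, fitted = _preliminary_fits(matrix, control)
    trend = fit_trend(matrix, control)
    fitted_filled = np.where(np.isnan(fitted), np.nanmean(fitted), fitted)
    weights = compute_weights(trend, fitted_filled)
    if rho is None:
        rho = estimate_block_correlation(matrix, control).consensus
    rho = float(np.clip(rho, 0.0, 0.99))

    X_all, colnames = build_design(matrix[["query", "batch"]], control, queries, batches)
    values = matrix["value"].values
    blocks = matrix["block_id"].values
    fits = []
    for gene, idx in matrix.groupby("gene_id").indices.items():
        # The design and the precision weights are constant within a
        # quadruplicate (same gene, query, batch), so the block means are
        # sufficient for the GLS fit: collapsing gives identical point
        # estimates and contrast variances, while the residual variance is
        # estimated from the block-level residuals — the stratum the
        # contrasts actually live in.  Under the compound-symmetric model
        # the variance of a block mean is sigma^2 (1+(n-1)rho) / (w n).
        y_b, X_b, u_b, blk_b = _collapse_blocks(
            values[idx], X_all[idx], weights[idx], blocks[idx], rho
        )
        fit = fit_gene_model(gene, y_b, X_b, u_b, 0.0, blk_b, colnames)
        if fit is None:
            logger.info("gene %s dropped: design rank-deficient after missingness", gene)
            continue
        fits.append(fit)
    if not fits:
        raise ProcessingError("no gene could be fitted")
    moderation = moderate_variances(
        np.array([f.s2 for f in fits]),
        np.array([f.df for f in fits]),
        gene_ids=[f.gene_id for f in fits],
    )
    contrasts = make_contrasts(colnames, control, queries, reference)
    return test_contrasts(fits, moderation, contrasts)
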