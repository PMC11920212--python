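"""Cell-state discovery and differential expression.

Quality control (gene-count and mitochondrial-fraction filters),
depth/log normalization, bin-matched module scoring and cell-cycle phase
assignment, OLS regression of covariates, highly variable gene selection,
PCA + shared-nearest-neighbor Louvain clustering, one-vs-rest Wilcoxon
marker discovery, independent-filtering differential expression, clone-level
DE, and rank-based (UCell-style) signature scoring.

All matrices are cells x genes; ``counts`` are raw non-negative integers
(sparse or dense) and ``normalized`` is the depth-normalized log1p matrix.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .enrichment import bh_adjust

__all__ = [
    "qc_filter",
    "normalize_log1p",
    "score_module",
    "assign_phase",
    "regress_out",
    "select_hvg",
    "cluster_states",
    "wilcoxon_test",
    "find_markers",
    "DEResult",
    "de_independent_filtering",
    "count_de",
    "clone_de",
    "score_signature_rank",
]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    counts,
    is_mito: np.ndarray,
    n_sd: float = 2.0,
    max_mito_frac: float = 0.10,
) -> np.ndarray:
    """Indices of cells passing quality control.

    Cells are kept when their number of detected genes lies within the
    population mean +/- ``n_sd`` standard deviations AND their fraction of
    mitochondrial reads is at most ``max_mito_frac``.  If the standard
    deviation of detected genes is 0 (identical cells) only the
    mitochondrial rule applies.
    """
    X = sp.csr_matrix(counts)
    is_mito = np.asarray(is_mito, dtype=bool)
    if is_mito.shape[0] != X.shape[1]:
        raise ValueError("is_mito length must equal number of genes")
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito = np.asarray(X[:, is_mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    ok = mito_frac <= max_mito_frac
    mu, sd = genes_detected.mean(), genes_detected.std()
    if sd > 0:
        ok &= (genes_detected >= mu - n_sd * sd) & (genes_detected <= mu + n_sd * sd)
    return np.nonzero(ok)[0]


def normalize_log1p(counts, scale: float = 1e4, cell_names=None):
    """Depth-normalize each cell to ``scale`` total counts, then log1p.

    Returns a sparse CSR float matrix.  Cells with zero total counts cannot
    be normalized and raise, listing the offending barcodes.
    """
    X = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        names = (
            [cell_names[i] for i in zero[:10]]
            if cell_names is not None
            else list(zero[:10])
        )
        raise ValueError(f"cells with zero total counts: {names}")
    X = X.multiply((scale / totals)[:, None]).tocsr()
    X.data = np.log1p(X.data)
    return X


# ---------------------------------------------------------------------------
# module scores and cell cycle
# ---------------------------------------------------------------------------

def score_module(
    normalized,
    gene_names: list[str],
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expression-bin-matched module score per cell.

    Genes are binned by average expression; for every gene in the set,
    ``n_ctrl`` control genes are drawn from the same bin, and the score is
    mean(set genes) - mean(control genes).  Deterministic under ``seed``.
    """
    names = list(gene_names)
    idx = [names.index(g) for g in gene_set if g in names]
    if len(gene_set) == 0 or len(idx) == 0:
        raise ValueError("gene set empty or absent from the matrix")
    X = _dense(normalized)
    rng = np.random.default_rng(seed)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(names), dtype=int)
    bins[order] = np.arange(len(names)) * n_bins // len(names)
    in_set = np.zeros(len(names), dtype=bool)
    in_set[idx] = True
    ctrl: list[int] = []
    for g in idx:
        pool = np.nonzero((bins == bins[g]) & ~in_set)[0]
        if pool.size == 0:  # bin holds only set genes; fall back to the bin
            pool = np.nonzero(bins == bins[g])[0]
        ctrl.extend(rng.choice(pool, size=min(n_ctrl, pool.size), replace=False))
    return X[:, idx].mean(axis=1) - X[:, sorted(set(ctrl))].mean(axis=1)


def assign_phase(s_score: float, g2m_score: float) -> str:
    """Cell-cycle phase from S and G2M module scores: the larger positive
    score wins; G1 when neither is positive."""
    if s_score <= 0 and g2m_score <= 0:
        return "G1"
    return "S" if s_score >= g2m_score else "G2M"


def regress_out(normalized, covariates) -> np.ndarray:
    """Residuals of per-gene OLS on the covariates (with intercept).

    Removes e.g. cell-cycle scores from every gene; residuals are
    orthogonal to each covariate.  Collinear covariates raise.
    """
    Y = _dense(normalized)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    design = np.column_stack([np.ones(len(C)), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"collinear covariates (design rank {np.linalg.matrix_rank(design)} "
            f"< {design.shape[1]})"
        )
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta


# ---------------------------------------------------------------------------
# feature selection and clustering
# ---------------------------------------------------------------------------

def select_hvg(normalized, gene_names: list[str], n: int = 2000) -> list[str]:
    """Top-``n`` highly variable genes by standardized variance.

    The mean-variance trend is estimated as the median variance within
    20 equal-occupancy mean-expression bins; each gene's variance is
    divided by its bin's trend value.  Constant genes are never selected.
    """
    X = _dense(normalized)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    ok = (var > 0) & (mean > 0)
    std_var = np.zeros(X.shape[1])
    if ok.any():
        idx = np.nonzero(ok)[0]
        # at least ~10 genes per bin so a single outlier cannot set its
        # own trend value
        n_bins = max(1, min(20, idx.size // 10))
        order = np.argsort(mean[idx], kind="stable")
        bins = np.empty(idx.size, dtype=int)
        bins[order] = np.arange(idx.size) * n_bins // idx.size
        trend = np.empty(idx.size)
        for b in range(n_bins):
            members = bins == b
            trend[members] = np.median(var[idx][members])
        std_var[idx] = var[idx] / np.maximum(trend, 1e-12)
    order = np.argsort(-std_var, kind="stable")
    chosen = [i for i in order if ok[i]][:n]
    return [gene_names[i] for i in chosen]


def _snn_graph(pcs: np.ndarray, k_neighbors: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Edges connect every pair of cells sharing at least one of their k
    nearest neighbors; weights below 1/15 are pruned.
    """
    n = pcs.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    A = sp.csr_matrix(
        (np.ones(idx.size), (np.repeat(np.arange(n), k + 1), idx.ravel())),
        shape=(n, n),
    )
    shared = (A @ A.T).tocoo()  # |N(i) & N(j)| for pairs with any overlap
    edges, weights = [], []
    for i, j, s in zip(shared.row, shared.col, shared.data):
        if j <= i:
            continue
        jac = s / (2 * (k + 1) - s)
        if jac > 1 / 15:  # prune weak edges, Seurat-style
            edges.append((int(i), int(j)))
            weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_states(
    normalized,
    gene_names: list[str],
    hvgs: list[str],
    dims: int = 14,
    resolution: float = 1.0,
    k_neighbors: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Cluster cells into transcriptional states.

    PCA on scaled highly variable genes to ``dims`` components, a
    shared-nearest-neighbor graph, and Louvain multilevel modularity
    optimization at the given ``resolution``.  Deterministic under ``seed``.
    """
    X = _dense(normalized)
    n_cells = X.shape[0]
    cols = [gene_names.index(g) for g in hvgs]
    if dims >= min(n_cells, len(cols)):
        raise ValueError(
            f"dims={dims} must be < min(n_cells={n_cells}, n_hvgs={len(cols)})"
        )
    H = X[:, cols]
    mu, sd = H.mean(axis=0), H.std(axis=0)
    sd[sd == 0] = 1.0
    H = np.clip((H - mu) / sd, -10, 10)
    pcs = PCA(n_components=dims, svd_solver="full", random_state=seed).fit_transform(H)
    graph = _snn_graph(pcs, k_neighbors)
    ig.set_random_number_generator(_pyrandom.Random(seed))
    part = graph.community_multilevel(
        weights="weight" if graph.ecount() else None, resolution=resolution
    )
    labels = np.asarray(part.membership, dtype=int)
    # stable renumbering by decreasing cluster size
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return np.array([remap[v] for v in labels], dtype=int)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def wilcoxon_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for small tie-free samples (both n <= 8),
    tie-corrected normal approximation otherwise.  Degenerate comparisons
    (all values identical) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    small = len(x) <= 8 and len(y) <= 8
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _log2fc(x_in: np.ndarray, x_out: np.ndarray, pseudo: float = 1e-9) -> float:
    """log2 fold change on de-logged means with a small pseudocount."""
    m_in = float(np.expm1(x_in).mean())
    m_out = float(np.expm1(x_out).mean())
    return float(np.log2((m_in + pseudo) / (m_out + pseudo)))


def find_markers(
    normalized,
    gene_names: list[str],
    labels: np.ndarray,
    min_cells: int = 3,
    lfc_cut: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers per state.

    For every state and gene: two-sided rank-sum test against all other
    cells, BH adjustment within the state's gene tests, log2 fold change on
    de-logged means.  States with fewer than ``min_cells`` cells are
    skipped.  The ``significant`` flag marks upregulated markers with
    log2fc > ``lfc_cut`` and adjusted p < ``alpha``.
    """
    X = _dense(normalized)
    labels = np.asarray(labels)
    frames = []
    for state in sorted(pd.unique(labels)):
        mask = labels == state
        if mask.sum() < min_cells:
            continue
        A, B = X[mask], X[~mask]
        pvals = np.array([wilcoxon_test(A[:, j], B[:, j]) for j in range(X.shape[1])])
        padj = bh_adjust(pvals)
        lfc = np.array([_log2fc(A[:, j], B[:, j]) for j in range(X.shape[1])])
        frames.append(
            pd.DataFrame(
                {
                    "state": state,
                    "gene": gene_names,
                    "log2fc": lfc,
                    "p": pvals,
                    "p_adj": padj,
                    "pct_in": (A > 0).mean(axis=0),
                    "pct_out": (B > 0).mean(axis=0),
                    "direction": np.where(lfc > 0, "up", "down"),
                    "significant": (lfc > lfc_cut) & (padj < alpha),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["state", "gene", "log2fc", "p", "p_adj", "pct_in",
                     "pct_out", "direction", "significant"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class DEResult:
    """Differential expression with independent filtering."""

    table: pd.DataFrame  # gene, mean_count, log2fc, p, p_adj (NaN if filtered)
    chosen_filter_threshold: float
    n_significant: int
    grid: np.ndarray
    n_significant_by_threshold: np.ndarray


def de_independent_filtering(
    counts,
    normalized,
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_names: list[str],
    n_grid: int = 100,
    alpha: float = 0.05,
) -> DEResult:
    """Two-group Wilcoxon DE with mean-count independent filtering.

    Genes with zero counts across both groups are removed.  For each
    threshold on a grid of ``n_grid`` evenly spaced quantiles of the
    per-gene mean counts, genes below the threshold are filtered out before
    BH adjustment and the number of adjusted p < ``alpha`` genes is
    counted; the threshold maximizing that count (smallest on ties) is
    applied.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.sum() < 3 or group_b.sum() < 3:
        raise ValueError("both groups need >= 3 cells")
    C = sp.csr_matrix(counts)
    X = _dense(normalized)
    cells = group_a | group_b
    mean_counts = np.asarray(C[cells].mean(axis=0)).ravel()
    totals = np.asarray(C[cells].sum(axis=0)).ravel()
    keep = totals > 0
    genes = [g for g, k in zip(gene_names, keep) if k]
    A, B = X[group_a][:, keep], X[group_b][:, keep]
    mean_counts = mean_counts[keep]
    pvals = np.array([wilcoxon_test(A[:, j], B[:, j]) for j in range(len(genes))])
    lfc = np.array([_log2fc(A[:, j], B[:, j]) for j in range(len(genes))])

    grid = np.unique(np.quantile(mean_counts, np.linspace(0, 1, n_grid)))
    counts_sig = np.zeros(len(grid), dtype=int)
    for i, thr in enumerate(grid):
        passing = mean_counts >= thr
        if passing.sum() == 0:
            continue
        counts_sig[i] = int((bh_adjust(pvals[passing]) < alpha).sum())
    best = int(np.argmax(counts_sig))  # argmax takes the first (smallest) tie
    thr = float(grid[best]) if len(grid) else 0.0
    passing = mean_counts >= thr
    padj = np.full(len(genes), np.nan)
    if passing.sum():
        padj[passing] = bh_adjust(pvals[passing])
    table = pd.DataFrame(
        {
            "gene": genes,
            "mean_count": mean_counts,
            "log2fc": lfc,
            "p": pvals,
            "p_adj": padj,
        }
    )
    return DEResult(
        table=table,
        chosen_filter_threshold=thr,
        n_significant=int(counts_sig[best]) if len(grid) else 0,
        grid=grid,
        n_significant_by_threshold=counts_sig,
    )


def count_de(table: pd.DataFrame, lfc_cut: float = 1.0,
             p_cut: float = 0.05) -> tuple[int, int]:
    """(n_up, n_down) at |log2fc| >= ``lfc_cut`` and p < ``p_cut``."""
    if len(table) == 0:
        return 0, 0
    sig = table["p"] < p_cut
    n_up = int((sig & (table["log2fc"] >= lfc_cut)).sum())
    n_down = int((sig & (table["log2fc"] <= -lfc_cut)).sum())
    return n_up, n_down


def clone_de(
    normalized,
    gene_names: list[str],
    genotypes: np.ndarray,
    clones: np.ndarray,
    min_genotype_cells: int = 200,
    min_clone_cells: int = 9,
    min_rest_clone_cells: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-clone differentially-expressed-gene counts within genotypes.

    Only genotypes with more than ``min_genotype_cells`` cells are
    analysed; each clone with more than ``min_clone_cells`` cells is
    compared (Wilcoxon + BH) against the same genotype's other clones that
    have at least ``min_rest_clone_cells`` cells.
    """
    X = _dense(normalized)
    genotypes = np.asarray(genotypes)
    clones = np.asarray(clones)
    rows = []
    for gid in pd.unique(genotypes):
        gmask = genotypes == gid
        if gmask.sum() <= min_genotype_cells:
            continue
        clone_sizes = pd.Series(clones[gmask]).value_counts()
        for clone, n in clone_sizes.items():
            if n <= min_clone_cells:
                continue
            rest_clones = [
                c for c, m in clone_sizes.items()
                if c != clone and m >= min_rest_clone_cells
            ]
            if not rest_clones:
                continue
            a = gmask & (clones == clone)
            b = gmask & np.isin(clones, rest_clones)
            pvals = np.array(
                [wilcoxon_test(X[a, j], X[b, j]) for j in range(X.shape[1])]
            )
            n_deg = int((bh_adjust(pvals) < alpha).sum())
            rows.append(
                {"genotype": gid, "clone": clone, "n_cells": int(n),
                 "n_deg": n_deg}
            )
    return pd.DataFrame(rows, columns=["genotype", "clone", "n_cells", "n_deg"])


def score_signature_rank(
    normalized,
    gene_names: list[str],
    gene_set: list[str],
    r_max: int = 1500,
) -> np.ndarray:
    """Rank-based signature score per cell, in [0, 1] (UCell-style).

    Genes are ranked by decreasing expression within each cell (average
    ranks for ties, ranks beyond ``r_max`` clipped to ``r_max`` + 1);
    U = sum of the set's ranks - n(n+1)/2 and the score is
    1 - U / (n * r_max), floored at 0.
    """
    idx = [gene_names.index(g) for g in gene_set if g in gene_names]
    if not idx:
        raise ValueError("gene set absent from the matrix")
    X = _dense(normalized)
    n = len(idx)
    ranks = np.apply_along_axis(lambda r: stats.rankdata(-r, method="average"), 1, X)
    ranks = np.minimum(ranks, r_max + 1)
    U = ranks[:, idx].sum(axis=1) - n * (n + 1) / 2
    return np.maximum(0.0, 1.0 - U / (n * r_max))
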