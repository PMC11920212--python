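"""SVD leverage scores for transcriptional heterogeneity.

Per plate, the top-k left singular vectors of the (cells x genes)
log-normalized expression matrix are computed with a partial SVD; the
row-wise squared norm of the resulting n x k matrix gives each cell's raw
leverage score, normalized so the per-plate sum is 1.  Normalized scores
are log-transformed and z-scored against the plate's wild-type cells, and
genotypes are ranked by the standard deviation of the scaled score with
wild type fixed at 1: genotypes at >= 1.3 are *negative regulators* of
heterogeneity (their cells' transcriptomes spread more than wild type) and
those at <= 0.7 are *positive regulators*.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds

__all__ = [
    "filter_genes_mean",
    "plate_leverage",
    "scale_leverage",
    "genotype_heterogeneity",
    "classify_regulators",
    "leverage_pipeline",
]


def filter_genes_mean(counts, min_mean: float = 0.25) -> np.ndarray:
    """Indices of genes with raw mean count strictly greater than
    ``min_mean`` UMI per cell."""
    X = sp.csr_matrix(counts)
    means = np.asarray(X.mean(axis=0)).ravel()
    keep = np.nonzero(means > min_mean)[0]
    if keep.size == 0:
        raise ValueError(f"no genes pass mean-count filter > {min_mean}")
    return keep


def plate_leverage(matrix, k: int = 20) -> tuple[np.ndarray, np.ndarray, int]:
    """Raw and normalized per-cell leverage for one plate.

    ``matrix`` is the plate's cells x genes submatrix.  Returns
    (raw, normalized, k_used): raw_i = sum over the top-k' left singular
    vectors of U_ij^2 (so the raw scores sum to k' by orthonormality) and
    normalized_i = raw_i / sum(raw), summing to 1 over the plate.  k is
    reduced to min(k, n_cells - 1, n_genes - 1) for small plates.
    """
    X = sp.csr_matrix(matrix, dtype=float)
    n, g = X.shape
    if n < 2:
        raise ValueError("plate needs >= 2 cells")
    if X.count_nonzero() == 0:
        raise ValueError("rank-0 (all-zero) plate matrix")
    if k < min(n, g):
        k_used = k
        U, _, _ = svds(X, k=k_used, solver="arpack", random_state=0)
    else:
        # partial SVD needs k < min(n, g); fall back to the full
        # decomposition (which also resolves degenerate tied spectra)
        k_used = min(n, g)
        warnings.warn(
            f"k reduced from {k} to {k_used} for a {n}x{g} plate",
            stacklevel=2,
        )
        U = np.linalg.svd(X.toarray(), full_matrices=False)[0][:, :k_used]
    raw = (U ** 2).sum(axis=1)
    total = raw.sum()
    if total <= 0:
        raise ValueError("degenerate leverage (zero total)")
    return raw, raw / total, k_used


def scale_leverage(normalized_leverage, wt_mask) -> np.ndarray:
    """Log-transform and z-score leverage against wild-type cells.

    z_i = (log L_i - mean_WT log L) / sd_WT log L, computed per plate (the
    caller passes one plate at a time).  Requires >= 2 wild-type cells with
    distinct leverage.
    """
    L = np.asarray(normalized_leverage, dtype=float)
    wt = np.asarray(wt_mask, dtype=bool)
    if wt.sum() < 2:
        raise ValueError("plate needs >= 2 wild-type cells for scaling")
    logL = np.log(L)
    mu = logL[wt].mean()
    sd = logL[wt].std(ddof=1)
    if sd == 0:
        raise ValueError("wild-type leverage has zero spread on this plate")
    return (logL - mu) / sd


def genotype_heterogeneity(
    scaled: np.ndarray,
    genotype_labels,
    wt_id: str = "WT",
    min_cells: int = 6,
) -> pd.DataFrame:
    """Per-genotype standard deviation of the scaled leverage score,
    rescaled so wild type equals 1.

    sd_scaled(g) = SD(z | genotype g) / SD(z | pooled wild-type cells);
    genotypes with fewer than ``min_cells`` cells are excluded.
    """
    genos = np.asarray(genotype_labels)
    z = np.asarray(scaled, dtype=float)
    wt_mask = genos == wt_id
    if wt_mask.sum() < 2:
        raise ValueError("need >= 2 pooled wild-type cells")
    sd_wt = z[wt_mask].std(ddof=1)
    rows = []
    for gid, n in pd.Series(genos).value_counts().items():
        if n < min_cells:
            continue
        sd_g = z[genos == gid].std(ddof=1)
        rows.append({"genotype": gid, "n_cells": int(n),
                     "sd_scaled": float(sd_g / sd_wt)})
    df = pd.DataFrame(rows, columns=["genotype", "n_cells", "sd_scaled"])
    return df.sort_values("genotype", ignore_index=True)


def classify_regulators(
    sd_scaled: pd.DataFrame, up: float = 1.3, down: float = 0.7
) -> pd.DataFrame:
    """Label genotypes as negative (sd_scaled >= ``up``), positive
    (<= ``down``) regulators of heterogeneity, or ns."""
    out = sd_scaled.copy()
    out["class"] = "ns"
    out.loc[out["sd_scaled"] >= up, "class"] = "negative_regulator"
    out.loc[out["sd_scaled"] <= down, "class"] = "positive_regulator"
    return out


def leverage_pipeline(
    counts,
    normalized,
    plates,
    genotypes,
    wt_id: str = "WT",
    k: int = 20,
    min_mean: float = 0.25,
    min_cells: int = 6,
    up: float = 1.3,
    down: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full leverage workflow over all plates.

    Gene filter on raw mean counts, per-plate partial SVD leverage on the
    log-normalized matrix, per-plate WT z-scaling, then per-genotype SD
    scaled to wild type and regulator classification.  Returns
    (per-cell table, per-genotype table).
    """
    plates = np.asarray(plates)
    genos = np.asarray(genotypes)
    keep_genes = filter_genes_mean(counts, min_mean)
    X = sp.csr_matrix(normalized)[:, keep_genes]
    n = X.shape[0]
    raw = np.empty(n)
    norm = np.empty(n)
    z = np.empty(n)
    k_used = {}
    for plate in pd.unique(plates):
        m = plates == plate
        r, nl, ku = plate_leverage(X[np.nonzero(m)[0]], k=k)
        wt = genos[m] == wt_id
        if wt.sum() < 2:
            raise ValueError(f"plate {plate!r} has < 2 wild-type cells")
        raw[m], norm[m] = r, nl
        z[m] = scale_leverage(nl, wt)
        k_used[str(plate)] = ku
    cell_table = pd.DataFrame(
        {
            "plate": plates,
            "genotype": genos,
            "raw_leverage": raw,
            "normalized_leverage": norm,
            "scaled_leverage": z,
        }
    )
    geno_table = classify_regulators(
        genotype_heterogeneity(z, genos, wt_id=wt_id, min_cells=min_cells),
        up=up, down=down,
    )
    cell_table.attrs["k_used"] = k_used
    return cell_table, geno_table
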