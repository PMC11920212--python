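"""Core/responsive state classification across conditions and the
fitness-set permutation test.

Two routes establish whether a cell state found in one condition persists
in another: (i) Fisher tests on the overlap of upregulated marker sets
between every pair of states, and (ii) label transfer — PCA fit on the
reference condition, query cells projected and labeled by k-NN majority
vote — after removing a set of excluded genes (e.g. the basal-stress
state's markers, which would otherwise absorb every stressed cell).  A
reference state is *core* when at least 40% of the cells transferred to it
come from a single query state (or when manually overridden), *responsive*
otherwise.

The permutation test compares the mean fitness score of a genotype set
(e.g. state-biased mutants) per stressor against means of random
equal-sized draws from the unclassified genotypes, one-sided, with the
add-one convention p = (1 + #extreme) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .enrichment import bh_adjust, fisher_2x2
from .states import normalize_log1p

__all__ = [
    "marker_overlap",
    "transfer_labels",
    "TransferMap",
    "core_states",
    "fitness_permutation",
]


def marker_overlap(
    markers_a: dict[object, set],
    markers_b: dict[object, set],
    universe_size: int,
) -> pd.DataFrame:
    """Fisher overlap tests between two conditions' marker sets.

    For each (state_a, state_b) pair the 2x2 table is built from the set
    overlap within a gene universe of ``universe_size``; two-sided Fisher,
    BH across all pairs.  Empty sets give p = 1 by convention (flagged).
    """
    rows = []
    for sa, set_a in markers_a.items():
        for sb, set_b in markers_b.items():
            union = len(set_a | set_b)
            if union > universe_size:
                raise ValueError(
                    f"universe_size={universe_size} smaller than the union "
                    f"of marker sets ({union}) for pair ({sa!r}, {sb!r})"
                )
            inter = len(set_a & set_b)
            if len(set_a) == 0 or len(set_b) == 0:
                rows.append(
                    {"state_a": sa, "state_b": sb, "n_common": inter,
                     "odds_ratio": np.nan, "p": 1.0, "empty_set": True}
                )
                continue
            a = inter
            b = len(set_a) - inter
            c = len(set_b) - inter
            d = universe_size - union
            res = fisher_2x2(a, b, c, d)
            # report the uncorrected cross-product ratio: a zero overlap
            # must read as OR = 0, not as a Haldane-inflated value
            with np.errstate(divide="ignore", invalid="ignore"):
                odds = np.divide(a * d, b * c) if b * c else (
                    np.inf if a * d else np.nan
                )
            rows.append(
                {"state_a": sa, "state_b": sb, "n_common": inter,
                 "odds_ratio": float(odds), "p": res["p_two_sided"],
                 "empty_set": False}
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


@dataclass
class TransferMap:
    """Cross-condition pairing of cell states via label transfer."""

    ref_to_query: pd.DataFrame  # rows: reference state, cols: query state
    query_to_ref: pd.DataFrame  # rows: query state, cols: reference state
    per_ref_state: pd.DataFrame  # max_share, matched_query_state, core
    manual_core_overrides: list = field(default_factory=list)
    method: str = "pca_projection_knn_majority"


def transfer_labels(
    ref_counts,
    ref_labels,
    query_counts,
    query_labels,
    gene_names: list[str],
    excluded_genes: list[str] | None = None,
    dims: int = 14,
    k_neighbors: int = 30,
    min_share: float = 0.4,
    overrides: list | None = None,
    seed: int = 0,
    scale: float = 1e4,
) -> tuple[np.ndarray, TransferMap]:
    """Transfer reference state labels onto query cells.

    ``excluded_genes`` are removed from both raw count matrices, which are
    then renormalized (depth + log1p).  PCA (``dims`` components) is fit on
    the reference, the query is projected into the same space, and each
    query cell takes the majority label among its ``k_neighbors`` nearest
    reference cells (ties resolved by the nearest neighbor's label).
    Returns the transferred labels and a :class:`TransferMap` with
    direction-wise proportion matrices and per-reference-state core calls.
    """
    excluded = set(excluded_genes or [])
    keep = [i for i, g in enumerate(gene_names) if g not in excluded]
    if not keep:
        raise ValueError("excluded_genes removes every gene; nothing shared")
    ref_labels = np.asarray(ref_labels)
    query_labels = np.asarray(query_labels)
    n_ref = ref_labels.shape[0]
    if k_neighbors > n_ref:
        raise ValueError(f"k_neighbors={k_neighbors} > n_ref={n_ref}")

    import scipy.sparse as sp

    R = normalize_log1p(sp.csr_matrix(ref_counts)[:, keep], scale=scale).toarray()
    Q = normalize_log1p(sp.csr_matrix(query_counts)[:, keep], scale=scale).toarray()
    mu, sd = R.mean(axis=0), R.std(axis=0)
    sd[sd == 0] = 1.0
    Rz = np.clip((R - mu) / sd, -10, 10)
    Qz = np.clip((Q - mu) / sd, -10, 10)

    dims_eff = min(dims, n_ref - 1, len(keep) - 1)
    pca = PCA(n_components=dims_eff, svd_solver="full", random_state=seed).fit(Rz)
    ref_pcs = pca.transform(Rz)
    query_pcs = pca.transform(Qz)

    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(ref_pcs)
    _, idx = nn.kneighbors(query_pcs)
    transferred = np.empty(len(query_pcs), dtype=ref_labels.dtype)
    for i, neigh in enumerate(idx):
        votes = pd.Series(ref_labels[neigh]).value_counts()
        top = votes.max()
        winners = set(votes.index[votes == top])
        if len(winners) == 1:
            transferred[i] = next(iter(winners))
        else:  # tie -> nearest neighbor's label among the tied
            for j in neigh:
                if ref_labels[j] in winners:
                    transferred[i] = ref_labels[j]
                    break

    ref_states = sorted(pd.unique(ref_labels))
    query_states = sorted(pd.unique(query_labels))
    r2q = pd.DataFrame(0.0, index=ref_states, columns=query_states)
    q2r = pd.DataFrame(0.0, index=query_states, columns=ref_states)
    cross = pd.crosstab(pd.Series(transferred, name="ref"),
                        pd.Series(query_labels, name="query"))
    for r in ref_states:
        if r in cross.index and cross.loc[r].sum() > 0:
            r2q.loc[r, cross.columns] = (cross.loc[r] / cross.loc[r].sum()).astype(float)
        else:
            r2q.loc[r] = np.nan
    for q in query_states:
        if q in cross.columns and cross[q].sum() > 0:
            q2r.loc[q, cross.index] = (cross[q] / cross[q].sum()).astype(float)
        else:
            q2r.loc[q] = np.nan

    per_ref = []
    for r in ref_states:
        row = r2q.loc[r]
        if row.isna().all():
            per_ref.append({"state": r, "max_share": 0.0,
                            "matched_query_state": None})
        else:
            per_ref.append(
                {"state": r, "max_share": float(row.max()),
                 "matched_query_state": row.idxmax()}
            )
    per_ref = pd.DataFrame(per_ref).set_index("state")
    tmap = TransferMap(
        ref_to_query=r2q, query_to_ref=q2r, per_ref_state=per_ref,
        manual_core_overrides=list(overrides or []),
    )
    tmap.per_ref_state["core"] = core_states(
        tmap, min_share=min_share, overrides=overrides
    )
    return transferred, tmap


def core_states(
    tmap: TransferMap, min_share: float = 0.4, overrides: list | None = None
) -> pd.Series:
    """Core/responsive flag per reference state.

    Core when the modal query-state share reaches ``min_share`` (>= 0.4 by
    default) or the state is manually overridden; responsive otherwise.
    """
    overrides = set(overrides or [])
    shares = tmap.per_ref_state["max_share"]
    return pd.Series(
        [(s >= min_share) or (state in overrides)
         for state, s in shares.items()],
        index=shares.index, name="core",
    )


def fitness_permutation(
    genotype_set: list[str],
    fitness_table: pd.DataFrame,
    n_perm: int = 1000,
    side: str = "less",
    seed: int = 0,
) -> pd.Series:
    """One-sided permutation test of a genotype set's mean fitness.

    For each stressor (column), the observed mean over ``genotype_set`` is
    compared with the means of ``n_perm`` random equal-sized draws from the
    remaining (unclassified) genotypes; p = (1 + #{draws at least as
    extreme in ``side`` direction}) / (n_perm + 1), so p is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if side not in ("less", "greater"):
        raise ValueError("side must be 'less' or 'greater'")
    if fitness_table.index.duplicated().any():
        raise ValueError("duplicated genotype rows in fitness table")
    missing = set(genotype_set) - set(fitness_table.index)
    if missing:
        raise ValueError(f"genotypes absent from fitness table: {sorted(missing)[:5]}")
    background = fitness_table.drop(index=list(genotype_set))
    n = len(genotype_set)
    if n > len(background):
        raise ValueError("set larger than the unclassified background")
    rng = np.random.default_rng(seed)
    obs = fitness_table.loc[list(genotype_set)].mean(axis=0)
    bg = background.to_numpy()
    perm_means = np.empty((n_perm, bg.shape[1]))
    for i in range(n_perm):
        draw = rng.choice(len(bg), size=n, replace=False)
        perm_means[i] = bg[draw].mean(axis=0)
    if side == "less":
        extreme = (perm_means <= obs.to_numpy()).sum(axis=0)
    else:
        extreme = (perm_means >= obs.to_numpy()).sum(axis=0)
    p = (1 + extreme) / (n_perm + 1)
    return pd.Series(p, index=fitness_table.columns, name="p")
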