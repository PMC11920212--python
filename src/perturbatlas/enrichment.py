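"""Genotype x cell-state enrichment testing.

For every genotype with at least ``min_cells`` cells and every cell state,
a 2x2 table (in-state & genotype, out-of-state & genotype; in-state &
other, out-of-state & other) is tested with a two-sided Fisher exact test.
Benjamini-Hochberg adjustment is applied across all genotype x state tests
of the condition; a genotype is classified *enriched* in a state when its
odds ratio exceeds 1 at adjusted p < alpha (a "state attractor") and
*depleted* when the odds ratio is below 1 at adjusted p < alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fisher_2x2", "bh_adjust", "state_enrichment"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def fisher_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Two-sided Fisher exact test and sample odds ratio for one 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.  The odds ratio is the cross-product ratio (a*d)/(b*c); when
    any cell is zero the Haldane-Anscombe +0.5 correction is applied and
    flagged.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) < 1:
        raise ValueError("all-zero table")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    haldane = any(x == 0 for x in cells)
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {"p_two_sided": p, "odds_ratio": float(odds), "haldane": haldane}


def state_enrichment(
    state_labels,
    genotype_labels,
    min_cells: int = 6,
    alpha: float = 0.05,
    bh_scope: str = "global",
) -> pd.DataFrame:
    """Enrichment/depletion of every genotype in every cell state.

    Returns one row per (genotype, state) with the 2x2 counts, odds ratio,
    p, BH-adjusted p and class in {enriched, depleted, ns}.  Genotypes with
    fewer than ``min_cells`` cells are excluded (listed in
    ``result.attrs['excluded_genotypes']``).  ``bh_scope`` is "global"
    (all tests of the condition, default) or "per_state".
    """
    states = np.asarray(state_labels)
    genos = np.asarray(genotype_labels)
    if states.shape != genos.shape:
        raise ValueError("label vectors must be aligned")
    uniq_states = sorted(pd.unique(states))
    if len(uniq_states) < 2:
        raise ValueError("need >= 2 states for enrichment testing")
    geno_counts = pd.Series(genos).value_counts()
    tested = sorted(geno_counts.index[geno_counts >= min_cells])
    excluded = sorted(geno_counts.index[geno_counts < min_cells])

    rows = []
    for gid in tested:
        gmask = genos == gid
        for state in uniq_states:
            smask = states == state
            a = int((gmask & smask).sum())
            b = int((gmask & ~smask).sum())
            c = int((~gmask & smask).sum())
            d = int((~gmask & ~smask).sum())
            res = fisher_2x2(a, b, c, d)
            rows.append(
                {
                    "genotype": gid, "state": state,
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": res["odds_ratio"],
                    "haldane": res["haldane"],
                    "p": res["p_two_sided"],
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        if bh_scope == "global":
            table["p_adj"] = bh_adjust(table["p"].to_numpy())
        elif bh_scope == "per_state":
            table["p_adj"] = np.nan
            for state in uniq_states:
                m = table["state"] == state
                table.loc[m, "p_adj"] = bh_adjust(table.loc[m, "p"].to_numpy())
        else:
            raise ValueError("bh_scope must be 'global' or 'per_state'")
        sig = table["p_adj"] < alpha
        table["class"] = "ns"
        table.loc[sig & (table["odds_ratio"] > 1), "class"] = "enriched"
        table.loc[sig & (table["odds_ratio"] < 1), "class"] = "depleted"
    else:
        table = pd.DataFrame(
            columns=["genotype", "state", "a", "b", "c", "d", "odds_ratio",
                     "haldane", "p", "p_adj", "class"]
        )
    table.attrs["excluded_genotypes"] = excluded
    table.attrs["odds_ratio_method"] = "sample cross-product (Haldane +0.5 on zeros)"
    return table
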