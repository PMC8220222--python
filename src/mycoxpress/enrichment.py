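"""Term enrichment for gene or orthogroup sets.

Over-representation only: for a foreground set of size n drawn from a
universe of size N, a term annotating K universe members and k foreground
members is scored with the hypergeometric tail P(X ≥ k). Bonferroni over
the terms tested controls the family-wise error (BH is reported alongside).
Orthogroups inherit a term when at least a fixed fraction (default 25%) of
their member genes — pooled over species — carry it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OrthogroupMap
from .multitest import bh_adjust, bonferroni_adjust


@dataclass
class TermMap:
    """Term id → member ids, with the universe the members are drawn from."""

    terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        for term, members in self.terms.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} has members outside the universe: {sorted(extra)[:5]}")


def invert_gene_terms(term_to_genes: Mapping[str, Sequence[str]],
                      ) -> dict[str, set[str]]:
    """term → genes mapping (the TSV layout) inverted to gene → terms."""
    out: dict[str, set[str]] = {}
    for term, genes in term_to_genes.items():
        for g in genes:
            out.setdefault(g, set()).add(term)
    return out


def annotate_orthogroups(omap: OrthogroupMap,
                         gene_terms: Mapping[str, set[str] | Sequence[str]],
                         threshold: float = 0.25) -> TermMap:
    """Majority-rule annotation transfer from genes to orthogroups.

    An orthogroup is annotated with term T iff the genes carrying T are at
    least ``threshold`` of all its member genes (all species pooled).
    Orthogroups without genes get no terms.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    terms: dict[str, set[str]] = {}
    universe = set(omap.orthogroup_ids())
    for og in omap.orthogroup_ids():
        genes = [g for sp_genes in omap.members[og].values() for g in sp_genes]
        if not genes:
            continue
        tally: dict[str, int] = {}
        for g in genes:
            for t in gene_terms.get(g, ()):
                tally[t] = tally.get(t, 0) + 1
        for t, k in tally.items():
            if k / len(genes) >= threshold:
                terms.setdefault(t, set()).add(og)
    return TermMap(terms, universe)


def hypergeom_enrich(foreground: Iterable[str], term_map: TermMap,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation test per term.

    p = P(X ≥ k) with X ~ Hypergeom(N = |universe|, K = |term|,
    n = |foreground|); Bonferroni over the terms with K ≥ 1.
    """
    fg = set(foreground)
    extra = fg - term_map.universe
    if extra:
        raise ValueError(f"foreground ids outside the universe: {sorted(extra)[:5]}")
    N = len(term_map.universe)
    n = len(fg)
    rows = []
    for term, members in sorted(term_map.terms.items()):
        K = len(members)
        if K == 0:
            continue
        k = len(fg & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["p_adjusted"] = bonferroni_adjust(df["p"].to_numpy())
        df["q_bh"] = bh_adjust(df["p"].to_numpy())
        df["enriched"] = df["p_adjusted"] < alpha
    else:
        df["p_adjusted"] = np.array([], dtype=float)
        df["q_bh"] = np.array([], dtype=float)
        df["enriched"] = np.array([], dtype=bool)
    return df
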