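"""Pathway-level gene-repertoire comparison between species groups.

The unit of comparison is the *detection* of an ortholog (a KEGG ortholog or
Mapman bin member): a species detects an ortholog iff at least one of its
genes or transcripts maps to it, independently of gene multiplicity. Per
pathway, detection events are pooled over the species of each group into a
2×2 contingency table (detected / undetected × group) and tested with
Fisher's exact test; Bonferroni over the pathways tested in the run guards
the family-wise error. A significant deficit in the focal group is a
"Losses" pathway, an excess "Gains".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OrthogroupMap
from .multitest import bonferroni_adjust


@dataclass
class DetectionMatrix:
    """Boolean ortholog × species detection table."""

    detected: pd.DataFrame  # bool, index=ortholog ids, columns=species

    @property
    def orthologs(self) -> list[str]:
        return list(self.detected.index)

    @property
    def species(self) -> list[str]:
        return list(self.detected.columns)


@dataclass
class PathwayTestResult:
    pathway_id: str
    size: int
    detected_per_species: dict[str, int]
    table2x2: tuple[int, int, int, int]
    odds_ratio: float
    p: float
    p_adjusted: float
    label: str  # Losses / Gains / NS


def build_detection_matrix(gene_to_ortholog: Mapping[str, Mapping[str, str]],
                           ) -> DetectionMatrix:
    """Collapse per-species gene→ortholog maps to presence/absence.

    ``gene_to_ortholog[species]`` maps gene id → ortholog id; multiplicity is
    deliberately ignored (two genes on the same ortholog count once). A
    species with an empty map yields an all-false column.
    """
    species = list(gene_to_ortholog)
    all_orthologs = sorted({o for m in gene_to_ortholog.values() for o in m.values()})
    det = pd.DataFrame(False, index=all_orthologs, columns=species)
    for sp, gmap in gene_to_ortholog.items():
        for ortholog in set(gmap.values()):
            det.loc[ortholog, sp] = True
    return DetectionMatrix(det)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2×2 table [[a, b], [c, d]].

    Two-sidedness follows the point-probability rule: the p-value sums the
    hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed that of the observed table. The odds
    ratio is the sample estimate ad/bc (inf when bc = 0 and ad > 0, nan when
    a margin is degenerate).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def compare_repertoires(detection: DetectionMatrix,
                        pathway_map: Mapping[str, Sequence[str]],
                        group_a: Sequence[str], group_b: Sequence[str],
                        min_size: int = 1, alpha: float = 0.05,
                        n_family: int | None = None,
                        ) -> list[PathwayTestResult]:
    """Test every pathway for differential ortholog representation.

    Group A is the reference (e.g. autotrophs), group B the focal group
    (e.g. mycoheterotrophs): "Losses" marks pathways whose detection rate is
    significantly lower in group B. The 2×2 table pools detection events
    within each group, so its margins are pathway size × group size.
    ``n_family`` overrides the Bonferroni family size (default: pathways
    with ≥ ``min_size`` orthologs actually tested here).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    missing = (set(group_a) | set(group_b)) - set(detection.species)
    if missing:
        raise ValueError(f"species not in detection matrix: {sorted(missing)}")

    tested = {pid: list(orthologs) for pid, orthologs in pathway_map.items()
              if len(orthologs) >= min_size}
    results: list[PathwayTestResult] = []
    for pid, orthologs in tested.items():
        size = len(orthologs)
        present = detection.detected.reindex(index=orthologs, fill_value=False)
        per_species = {sp: int(present[sp].sum())
                       for sp in group_a + group_b}
        det_a = sum(per_species[sp] for sp in group_a)
        det_b = sum(per_species[sp] for sp in group_b)
        a = det_a
        b = size * len(group_a) - det_a
        c = det_b
        d = size * len(group_b) - det_b
        odds, p = fisher_exact_2x2(a, b, c, d)
        results.append(PathwayTestResult(pid, size, per_species, (a, b, c, d),
                                         odds, p, np.nan, "NS"))

    n_tests = len(tested) if n_family is None else n_family
    adjusted = bonferroni_adjust([r.p for r in results], n_tests=n_tests)
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
        if p_adj < alpha:
            rate_a = r.table2x2[0] / max(r.table2x2[0] + r.table2x2[1], 1)
            rate_b = r.table2x2[2] / max(r.table2x2[2] + r.table2x2[3], 1)
            r.label = "Losses" if rate_b < rate_a else "Gains"
    return results


def results_frame(results: Sequence[PathwayTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"pathway_id": r.pathway_id, "size": r.size}
        row.update({f"detected_{sp}": n for sp, n in r.detected_per_species.items()})
        a, b, c, d = r.table2x2
        row.update({"a": a, "b": b, "c": c, "d": d, "odds_ratio": r.odds_ratio,
                    "p": r.p, "p_adjusted": r.p_adjusted, "label": r.label})
        rows.append(row)
    return pd.DataFrame(rows)


def find_group_exclusive_orthogroups(omap: OrthogroupMap,
                                     group: Sequence[str]) -> set[str]:
    """Orthogroups containing genes from *exactly* the given species set.

    Every group member must contribute at least one gene and no outside
    species may contribute any — the operation behind counting orthogroups
    exclusive to the mycoheterotrophic species.
    """
    target = frozenset(group)
    if not target <= set(omap.species):
        raise ValueError(f"group members not in map: {sorted(target - set(omap.species))}")
    return {og for og in omap.orthogroup_ids()
            if omap.species_with_genes(og) == target}
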