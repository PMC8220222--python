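"""Decontamination of field-collected de novo assemblies.

Samples dug out of forest soil carry the transcriptomes of their microbiota
(above all the mycorrhizal fungus, which dominates underground organs), so
an assembled contig is kept as bona fide plant material only if one of three
rules applies, in order:

1. TAXONOMY — its best protein hit falls inside the land-plant clade
   (Streptophyta by default);
2. ORTHOLOGY — it shares an orthogroup with at least one gene of a panel of
   reference plant species (rescues genes so conserved that their best hit
   lands outside plants);
3. EXPRESSION — it has no hit at all but is expressed in at least
   ``min_detect`` of the species' samples (rescues fast-evolving or
   unannotated plant genes while dropping low-support assembly artifacts).

A contig with a non-plant hit and no orthology rescue is a contaminant
regardless of its expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import HitRecord

PLANT_CLADE = "Streptophyta"


class Verdict(str, Enum):
    KEEP = "KEEP"
    DISCARD = "DISCARD"


class Reason(str, Enum):
    TAXONOMY = "TAXONOMY"
    ORTHOLOGY = "ORTHOLOGY"
    EXPRESSION = "EXPRESSION"
    CONTAMINANT_HIT = "CONTAMINANT_HIT"
    INSUFFICIENT_EXPRESSION = "INSUFFICIENT_EXPRESSION"


KEEP_REASONS = frozenset({Reason.TAXONOMY, Reason.ORTHOLOGY, Reason.EXPRESSION})


@dataclass
class ContigEvidence:
    """Everything known about one contig that the decision tree consults."""

    contig_id: str
    best_hit: HitRecord | None = None
    orthogroup: str | None = None
    #: orthogroup also contains ≥1 gene of the reference species panel
    reference_orthogroup_shared: bool = False
    #: per-sample detection (count > 0) across this species' samples
    detection: tuple[bool, ...] = ()

    def __post_init__(self):
        if self.reference_orthogroup_shared and self.orthogroup is None:
            raise ValueError(
                f"{self.contig_id}: reference_orthogroup_shared without an orthogroup")


@dataclass(frozen=True)
class DecontamCall:
    contig_id: str
    verdict: Verdict
    reason: Reason

    def __post_init__(self):
        if (self.verdict is Verdict.KEEP) != (self.reason in KEEP_REASONS):
            raise ValueError(f"inconsistent verdict/reason: {self.verdict}/{self.reason}")


def lineage_in_clade(lineage: Sequence[str], clade_name: str) -> bool:
    """True iff ``clade_name`` appears in the root→leaf lineage (exact match)."""
    return clade_name in lineage


def classify_contig(evidence: ContigEvidence, min_detect: int = 2,
                    plant_clade: str = PLANT_CLADE) -> DecontamCall:
    """Apply the three-rule decision tree to one contig.

    Rule order fixes the reason code, not the verdict: a plant-hit contig
    that also shares a reference orthogroup is reported as TAXONOMY.
    """
    if evidence.best_hit is not None and lineage_in_clade(
            evidence.best_hit.taxon_lineage, plant_clade):
        return DecontamCall(evidence.contig_id, Verdict.KEEP, Reason.TAXONOMY)
    if evidence.reference_orthogroup_shared:
        return DecontamCall(evidence.contig_id, Verdict.KEEP, Reason.ORTHOLOGY)
    if evidence.best_hit is None:
        if sum(evidence.detection) >= min_detect:
            return DecontamCall(evidence.contig_id, Verdict.KEEP, Reason.EXPRESSION)
        return DecontamCall(evidence.contig_id, Verdict.DISCARD,
                            Reason.INSUFFICIENT_EXPRESSION)
    return DecontamCall(evidence.contig_id, Verdict.DISCARD, Reason.CONTAMINANT_HIT)


def filter_assembly(evidence: Iterable[ContigEvidence], min_detect: int = 2,
                    plant_clade: str = PLANT_CLADE,
                    tissue_of_sample: Sequence[str] | None = None,
                    ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Classify a whole assembly; return kept ids, discarded ids and a summary.

    The summary counts calls per reason, and — when ``tissue_of_sample``
    labels the detection-vector positions — per tissue, attributing each
    contig to every tissue whose samples detect it, which is how contaminant
    load per tissue becomes visible (fungal transcripts concentrate in the
    mycorrhizal organ).
    """
    evidence = list(evidence)
    ids = [e.contig_id for e in evidence]
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        raise ValueError(f"duplicate contig ids: {dupes[dupes > 1].index.tolist()[:5]}")

    calls = [classify_contig(e, min_detect=min_detect, plant_clade=plant_clade)
             for e in evidence]
    kept = [c.contig_id for c in calls if c.verdict is Verdict.KEEP]
    discarded = [c.contig_id for c in calls if c.verdict is Verdict.DISCARD]

    rows = []
    for ev, call in zip(evidence, calls):
        tissues: set[str]
        if tissue_of_sample is not None and ev.detection:
            tissues = {t for t, d in zip(tissue_of_sample, ev.detection) if d}
        else:
            tissues = set()
        if not tissues:
            tissues = {"(undetected)"}
        for t in tissues:
            rows.append((t, call.reason.value, call.verdict.value))
    summary = (pd.DataFrame(rows, columns=["tissue", "reason", "verdict"])
               .groupby(["tissue", "reason", "verdict"]).size()
               .rename("n_contigs").reset_index())
    return kept, discarded, summary


def calls_frame(evidence: Iterable[ContigEvidence], min_detect: int = 2,
                plant_clade: str = PLANT_CLADE) -> pd.DataFrame:
    """Per-contig calls as a table (contig_id, verdict, reason)."""
    calls = [classify_contig(e, min_detect=min_detect, plant_clade=plant_clade)
             for e in evidence]
    return pd.DataFrame({
        "contig_id": [c.contig_id for c in calls],
        "verdict": [c.verdict.value for c in calls],
        "reason": [c.reason.value for c in calls],
    })


def build_evidence(hits: Mapping[str, HitRecord],
                   contig_orthogroup: Mapping[str, str],
                   reference_shared_orthogroups: frozenset[str] | set[str],
                   detection: pd.DataFrame) -> list[ContigEvidence]:
    """Assemble ContigEvidence from the three input tables.

    ``detection`` is a contigs × samples table of counts or 0/1 flags; a
    contig absent from it has an all-false detection vector.
    """
    n_samples = detection.shape[1]
    out = []
    contig_ids = set(hits) | set(contig_orthogroup) | set(detection.index)
    det = detection.to_numpy() > 0
    row_of = {c: i for i, c in enumerate(detection.index)}
    for cid in sorted(contig_ids):
        og = contig_orthogroup.get(cid)
        vec = (tuple(bool(v) for v in det[row_of[cid]])
               if cid in row_of else (False,) * n_samples)
        out.append(ContigEvidence(
            contig_id=cid,
            best_hit=hits.get(cid),
            orthogroup=og,
            reference_orthogroup_shared=og is not None and og in reference_shared_orthogroups,
            detection=vec,
        ))
    return out
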