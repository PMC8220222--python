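#!/usr/bin/env python
"""Generate the synthetic study that the downstream analyses run on.

Writes, under results/synthetic/:
- the truth labels of a contig cohort with known plant/contaminant status
  (the evidence itself is regenerated downstream from the same seed — all
  generators are pure functions of their spec);
- a 4-species × underground/stem × 2-individuals count experiment with 20%
  planted ratio inversions and 5% orthogroups silenced in one species;
- the detection table of a 140-pathway repertoire with three planted
  group-specific losses.
"""

import argparse
from pathlib import Path

import pandas as pd

from mycoxpress import io_formats
from mycoxpress.synthetic_data import (ContigCohortSpec, CountSimSpec,
                                       gen_contig_cohort,
                                       gen_count_experiment, gen_repertoire)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

COHORT_SPEC = dict(n_plant=3000, n_contaminant=1500, n_nohit=1500)
COUNT_SPEC = dict(n_orthogroups=2000, frac_inverted=0.2,
                  frac_species_missing=0.05)
REPERTOIRE_SPEC = dict(n_pathways=140, orthologs_per_pathway=40,
                       lost_pathways=3, loss_fraction=0.85)


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cohort = gen_contig_cohort(ContigCohortSpec(**COHORT_SPEC, seed=seed))
    cohort.truth.rename_axis("contig_id").to_frame().to_csv(
        OUT / "cohort_truth.tsv", sep="\t")
    print(f"contig cohort: {len(cohort.evidence)} contigs "
          f"({(cohort.truth == 'plant').sum()} true plant)")

    spec = CountSimSpec(**COUNT_SPEC, seed=seed)
    exp = gen_count_experiment(spec)
    io_formats.write_counts(exp.counts, OUT / "counts.tsv", OUT / "meta.tsv")
    io_formats.write_orthogroups(exp.orthogroups, OUT / "orthogroups.tsv")
    truth = pd.DataFrame({"orthogroup": exp.orthogroups.orthogroup_ids()})
    truth["class"] = ["inverted" if og in exp.truth_inverted
                      else "missing" if og in exp.truth_missing else "null"
                      for og in truth["orthogroup"]]
    io_formats.write_result_table(truth, OUT / "ratio_truth.tsv", {"seed": seed})
    print(f"count experiment: {spec.n_orthogroups} orthogroups, "
          f"{len(exp.truth_inverted)} inverted, {len(exp.truth_missing)} "
          f"silenced in one species, {exp.counts.counts.shape[0]} genes × "
          f"{exp.counts.counts.shape[1]} samples")

    rep = gen_repertoire(**REPERTOIRE_SPEC, seed=seed)
    rep.detection.detected.rename_axis("ortholog").to_csv(
        OUT / "repertoire_detection.tsv", sep="\t")
    print(f"repertoire: {REPERTOIRE_SPEC['n_pathways']} pathways, planted "
          f"losses in {sorted(rep.lost_pathways)}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
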