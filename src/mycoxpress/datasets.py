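"""Small published reference tables shipped as in-repo fixtures.

Per-species detected-ortholog counts for the two KEGG photosynthesis
pathways in six orchid species, as printed in the comparative study this
pipeline reimplements: three autotrophs (Apostasia shenzhenica AS,
Dendrobium catenatum DC, Phalaenopsis equestris PE) and three
mycoheterotrophs (Gastrodia elata GE, Epipogium aphyllum EA,
Neottia nidus-avis NNA). The published screen tested 140 KEGG pathways;
that family size applies when re-testing these rows.
"""

from __future__ import annotations

import pandas as pd

AUTOTROPHS = ("AS", "DC", "PE")
MYCOHETEROTROPHS = ("GE", "EA", "NNA")

#: pathway id → (name, pathway size, per-species detected-ortholog counts)
KEGG_PHOTOSYNTHESIS_ROWS = {
    "195": {"name": "Photosynthesis", "size": 63,
            "detected": {"AS": 54, "DC": 54, "PE": 33,
                         "GE": 10, "EA": 4, "NNA": 4}},
    "196": {"name": "Photosynthesis - antenna proteins", "size": 42,
            "detected": {"AS": 11, "DC": 11, "PE": 11,
                         "GE": 0, "EA": 3, "NNA": 1}},
}

#: number of KEGG pathways tested in the published screen (Bonferroni family)
KEGG_FAMILY_SIZE = 140


def kegg_photosynthesis_table() -> pd.DataFrame:
    """The published per-species detection counts as a tidy frame."""
    rows = []
    for pid, row in KEGG_PHOTOSYNTHESIS_ROWS.items():
        r = {"pathway_id": pid, "name": row["name"], "size": row["size"]}
        r.update(row["detected"])
        rows.append(r)
    return pd.DataFrame(rows)


def pooled_2x2(pathway_id: str) -> tuple[int, int, int, int]:
    """Pooled detection 2×2 table (AT detected/undetected, MH det/undet)."""
    row = KEGG_PHOTOSYNTHESIS_ROWS[pathway_id]
    size = row["size"]
    det_at = sum(row["detected"][sp] for sp in AUTOTROPHS)
    det_mh = sum(row["detected"][sp] for sp in MYCOHETEROTROPHS)
    return (det_at, size * len(AUTOTROPHS) - det_at,
            det_mh, size * len(MYCOHETEROTROPHS) - det_mh)
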