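import numpy as np
import pandas as pd
import pytest

from mycoxpress.io_formats import CountMatrix, OrthogroupMap


@pytest.fixture
def toy_orthogroups() -> OrthogroupMap:
    """Three orthogroups over three species, mixed presence patterns."""
    return OrthogroupMap(
        species=("spA", "spB", "spC"),
        members={
            "OG0000001": {"spA": ["a1", "a2"], "spB": [], "spC": ["c1"]},
            "OG0000002": {"spA": ["a3"], "spB": ["b1"], "spC": ["c2", "c3"]},
            "OG0000003": {"spA": [], "spB": ["b2"], "spC": []},
        })


@pytest.fixture
def paired_meta() -> pd.DataFrame:
    """4 species × 2 individuals × underground/stem, fully paired."""
    rows = []
    for sp, trophic in [("NNA", "MH"), ("EA", "MH"), ("ZM", "AT"), ("BD", "AT")]:
        for ind in ("ind1", "ind2"):
            for organ in ("underground", "stem"):
                rows.append((f"{sp}_{organ}_{ind}", sp, organ, ind, trophic))
    return (pd.DataFrame(rows, columns=["sample_id", "species", "organ",
                                        "individual", "trophic"])
            .set_index("sample_id"))


@pytest.fixture
def single_species_counts() -> CountMatrix:
    """One species, 3 organs × 2 individuals, deterministic small counts."""
    rng = np.random.default_rng(5)
    rows = []
    for ind in ("ind1", "ind2"):
        for organ in ("flower", "stem", "underground"):
            rows.append((f"NNA_{organ}_{ind}", "NNA", organ, ind, "MH"))
    meta = (pd.DataFrame(rows, columns=["sample_id", "species", "organ",
                                        "individual", "trophic"])
            .set_index("sample_id"))
    counts = pd.DataFrame(
        rng.poisson(50, size=(20, 6)), columns=list(meta.index),
        index=[f"g{i:03d}" for i in range(20)]).astype("int64")
    return CountMatrix(counts, meta)
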