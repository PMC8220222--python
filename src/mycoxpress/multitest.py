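"""Multiple-testing adjustments used across the pipeline.

Thin wrappers so every stage adjusts p-values the same way: BH step-up for
expression contrasts (FDR control), Bonferroni for the repertoire and
enrichment tests (family-wise control), with an explicit family size for the
latter because a run may test a subset of a larger declared family.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvalues, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni adjustment, optionally against an explicit family size.

    ``n_tests`` defaults to the length of the vector; it may be larger when
    the vector is a slice of a bigger test family (e.g. re-testing a few
    pathways out of the 140 actually screened).
    """
    p = np.asarray(pvalues, dtype=float)
    n = len(p) if n_tests is None else int(n_tests)
    if n < len(p):
        raise ValueError(f"family size {n} smaller than number of p-values {len(p)}")
    return np.minimum(p * n, 1.0)
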