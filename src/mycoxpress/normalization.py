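"""Library-size normalization (trimmed mean of M-values) and the
variance-stabilizing transform applied before ratio analysis.

TMM corrects for both sequencing depth and RNA composition: for each sample
a scaling factor is the weighted mean of gene-wise log fold changes (M)
against a reference sample, after trimming the most extreme M and A values,
so that the majority of genes — assumed not differentially expressed — end
up with log-ratio zero. Factors are rescaled to geometric mean 1, so they
redistribute, not change, the total normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors.

    ``effective_size = library_size * tmm_factor`` is the denominator for
    normalized expression. Factors have geometric mean 1.
    """

    sample_ids: list[str]
    library_size: np.ndarray
    tmm_factor: np.ndarray
    ref_sample: str

    @property
    def effective_size(self) -> np.ndarray:
        return self.library_size * self.tmm_factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "library_size": self.library_size.astype(int),
            "tmm_factor": self.tmm_factor,
        })


def _upper_quartile_nonzero_cpm(col: np.ndarray, libsize: float) -> float:
    nz = col[col > 0]
    return float(np.quantile(nz / libsize * 1e6, 0.75))


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05,
                ref_sample: str | None = None) -> NormFactors:
    """Compute TMM normalization factors for a genes × samples count matrix.

    The reference is the sample whose upper quartile of nonzero CPM is
    closest to the mean upper quartile (unless given). Per sample, M and A
    values vs the reference are computed over genes nonzero in both, the
    extreme ``trim_m`` fraction of each M tail and ``trim_a`` fraction of
    each A tail are discarded, and the factor is 2^(weighted mean M) with
    inverse asymptotic (delta-method) variance weights. Factors are rescaled
    to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = counts.to_numpy(dtype=float)
    samples = list(counts.columns)
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        empty = [s for s, n in zip(samples, libsize) if n == 0]
        raise ValueError(f"samples with zero total counts: {empty}")

    if ref_sample is None:
        uq = np.array([_upper_quartile_nonzero_cpm(mat[:, j], libsize[j])
                       for j in range(len(samples))])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = samples.index(ref_sample)

    r = mat[:, ref_idx]
    nr = libsize[ref_idx]
    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(mat[:, j], libsize[j], r, nr, trim_m, trim_a)

    log_f = np.log(factors)
    factors = np.exp(log_f - log_f.mean())
    return NormFactors(samples, libsize, factors, samples[ref_idx])


def _tmm_pair(x: np.ndarray, n: float, r: np.ndarray, nr: float,
              trim_m: float, trim_a: float) -> float:
    both = (x > 0) & (r > 0)
    if not both.any():
        raise ValueError("sample shares no nonzero gene with the reference")
    x, r = x[both], r[both]
    px, pr = x / n, r / nr
    m = np.log2(px / pr)
    a = 0.5 * np.log2(px * pr)
    # delta-method variance of M on the log2 scale
    v = (n - x) / (n * x) + (nr - r) / (nr * r)

    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    ng = len(m)
    lo_m = np.floor(ng * trim_m) + 1
    hi_m = ng + 1 - lo_m
    lo_a = np.floor(ng * trim_a) + 1
    hi_a = ng + 1 - lo_a
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), matching R's rank() used by the TMM trim."""
    from scipy.stats import rankdata
    return rankdata(x)


def normalized_expression(counts: pd.DataFrame, factors: NormFactors) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    if list(counts.columns) != factors.sample_ids:
        raise ValueError("factors were not computed on these samples (order/id mismatch)")
    eff = factors.effective_size
    return counts / eff * 1e6


def vst(x, c: float = 0.5):
    """Shifted-log variance-stabilizing transform: log2(x + c).

    Monotone, finite at zero; only differences of transformed paired samples
    enter the downstream ratio model, so the additive shift ``c`` acts as a
    pseudo-count guarding against zeros (default 0.5).
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("vst input must be non-negative")
    return np.log2(x + c)
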