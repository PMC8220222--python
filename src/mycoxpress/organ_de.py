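"""Within-species differential expression between organs.

The paper's design: one species at a time, six samples (three organs × two
individuals), NB log-linear model with a tissue factor and an individual
(replicate) factor, TMM-offset library sizes, empirical-Bayes-shrunk
tagwise dispersions, and a likelihood-ratio test of each organ contrast
against the model in which the two organs share a mean. Genes detected in
fewer than ``min_samples`` samples are dropped first. FDR is controlled by
Benjamini–Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nbglm
from .multitest import bh_adjust
from .normalization import NormFactors

LN2 = np.log(2.0)


@dataclass
class DispersionModel:
    common_phi: float
    tagwise_phi: np.ndarray
    prior_df: float


def detection_filter(counts: pd.DataFrame, min_samples: int = 3) -> list[str]:
    """Genes detected (count > 0) in at least ``min_samples`` samples."""
    n_detected = (counts.to_numpy() > 0).sum(axis=1)
    return list(counts.index[n_detected >= min_samples])


def _design_matrices(meta: pd.DataFrame, contrast: tuple[str, str],
                     ) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Full (intercept + tissue + individual) and contrast-reduced designs.

    The reduced design merges the two contrast organs into one level, so the
    LRT has exactly one degree of freedom whatever other organs are present.
    """
    organs = sorted(meta["organ"].unique())
    individuals = sorted(meta["individual"].unique())
    target, baseline = contrast
    for o in contrast:
        if o not in organs:
            raise ValueError(f"organ {o!r} absent from metadata")

    def dummies(levels, values):
        ref = levels[0]
        cols = [np.asarray(values == lv, dtype=float) for lv in levels[1:]]
        return cols, {lv: k + 1 for k, lv in enumerate(levels[1:])} | {ref: 0}

    organ_cols, organ_index = dummies(organs, meta["organ"].to_numpy())
    ind_cols, _ = dummies(individuals, meta["individual"].to_numpy())
    n = len(meta)
    full = np.column_stack([np.ones(n)] + organ_cols + ind_cols)

    merged = meta["organ"].to_numpy().copy()
    merged[merged == target] = baseline
    merged_levels = sorted(set(merged))
    merged_cols, _ = dummies(merged_levels, merged)
    reduced = np.column_stack([np.ones(n)] + merged_cols + ind_cols)
    return full, reduced, organ_index


def fit_de(counts: pd.DataFrame, meta: pd.DataFrame, contrast: tuple[str, str],
           factors: NormFactors, prior_df: float = 10.0,
           dispersion: DispersionModel | None = None) -> pd.DataFrame:
    """Test each gene for differential expression between two organs.

    ``contrast = (target, baseline)``: positive log2_fc means higher
    expression in the target organ. Returns one row per gene with the LRT
    statistic, raw p, BH q and direction; a non-converged fit is reported
    with p = 1 (and a warning) rather than failing the run.
    """
    if list(counts.columns) != factors.sample_ids:
        raise ValueError("normalization factors do not match the count columns")
    full, reduced, organ_index = _design_matrices(meta, contrast)
    n, p_full = full.shape
    if n - p_full < 1:
        raise ValueError("design leaves no residual degrees of freedom")

    y = counts.to_numpy(dtype=float)
    offset = np.log(factors.effective_size)

    if dispersion is None:
        common = nbglm.estimate_common_dispersion(y, full, offset)
        tagwise = nbglm.estimate_tagwise_dispersion(y, full, offset, common,
                                                    prior_df=prior_df)
        dispersion = DispersionModel(common, tagwise, prior_df)

    phi = dispersion.tagwise_phi
    beta_full, mu_full, conv_full = nbglm.fit_nbglm(y, full, offset, phi)
    _, mu_red, conv_red = nbglm.fit_nbglm(y, reduced, offset, phi)

    ll_full = nbglm.nb_loglik(y, mu_full, phi)
    ll_red = nbglm.nb_loglik(y, mu_red, phi)
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)

    target, baseline = contrast
    coef = np.zeros(len(y))
    for organ, col in ((target, organ_index[target]), (baseline, organ_index[baseline])):
        if col:
            coef += beta_full[:, col] * (1.0 if organ == target else -1.0)
    log2_fc = coef / LN2

    pvals = stats.chi2.sf(lrt, df=1)
    bad = ~(conv_full & conv_red)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} gene fits did not converge; p set to 1",
                      RuntimeWarning, stacklevel=2)
        pvals = np.where(bad, 1.0, pvals)
        lrt = np.where(bad, 0.0, lrt)

    out = pd.DataFrame({
        "gene_id": counts.index,
        "contrast": f"{target}_vs_{baseline}",
        "log2_fc": log2_fc,
        "lrt_stat": lrt,
        "p": pvals,
        "q": bh_adjust(pvals),
        "direction": np.where(log2_fc >= 0, "up", "down"),
        "converged": ~bad,
    })
    return out


def call_organ_specific(counts: pd.DataFrame, meta: pd.DataFrame,
                        min_on_fraction: float = 1.0,
                        max_off_count: int = 0) -> dict[str, set[str]]:
    """Genes expressed in (essentially) every sample of one organ and nowhere else.

    Defaults take the strictest reading: detected in *all* samples of the
    organ and zero counts in every sample of every other organ. The
    thresholds are exposed because other designs may want slack.
    """
    organs = sorted(meta["organ"].unique())
    for organ in organs:
        if (meta["organ"] == organ).sum() < 2:
            raise ValueError(f"organ {organ!r} has fewer than 2 samples")
    mat = counts.to_numpy()
    out: dict[str, set[str]] = {}
    for organ in organs:
        on = (meta["organ"] == organ).to_numpy()
        on_frac = (mat[:, on] > 0).mean(axis=1)
        off_ok = (mat[:, ~on] <= max_off_count).all(axis=1)
        mask = (on_frac >= min_on_fraction) & off_ok
        out[organ] = set(counts.index[mask])
    return out
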