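"""Cross-species underground/stem expression-ratio analysis.

Absolute counts cannot be compared across species (orthogroups hold
different numbers and lengths of genes per species), but each individual
plant contributes a *paired* underground and stem sample, so the per-
individual log2 underground/stem ratio is comparable. Per species, gene
counts are summed into orthogroup counts, TMM-normalized and variance-
stabilized; the ratio matrix (orthogroups × individuals) is then modeled
with a species cell-means linear model. The contrast of interest is the
difference between the average of the mycoheterotrophic (MH) species means
and the average of the autotrophic (AT) species means, tested with an
empirical-Bayes moderated t (per-orthogroup variances squeezed toward a
pooled prior), BH-adjusted. Significant orthogroups whose MH and AT group
mean ratios have opposite signs are "inverted" — the reprogramming signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from .io_formats import CountMatrix, OrthogroupMap, check_paired_design
from .multitest import bh_adjust
from .normalization import NormFactors, normalized_expression, tmm_factors, vst


@dataclass
class RatioMatrix:
    """log2 underground/stem ratios: orthogroups × individuals.

    ``col_meta`` is indexed like the ratio columns, with ``species`` and
    ``trophic`` for each individual.
    """

    ratios: pd.DataFrame
    col_meta: pd.DataFrame

    def __post_init__(self):
        if list(self.ratios.columns) != list(self.col_meta.index):
            raise ValueError("ratio columns and column metadata disagree")


@dataclass
class SqueezeResult:
    d0: float           # prior degrees of freedom (may be inf)
    s0_sq: float        # prior variance
    s2_tilde: np.ndarray


def aggregate_orthogroup_counts(cm: CountMatrix, omap: OrthogroupMap,
                                species: str) -> pd.DataFrame:
    """Sum member-gene counts into orthogroup counts for one species.

    Genes not assigned to any orthogroup drop out; orthogroups with no gene
    of this species get an all-zero row, so every orthogroup of the map is
    present and aligned across species.
    """
    gene_og = omap.gene_to_orthogroup(species)
    sample_ids = list(cm.meta.index[cm.meta["species"] == species])
    if not sample_ids:
        raise ValueError(f"no samples for species {species!r}")
    counts = cm.counts[sample_ids]
    og_ids = omap.orthogroup_ids()
    present = counts.index[counts.index.isin(gene_og)]
    groups = pd.Series({g: gene_og[g] for g in present})
    summed = counts.loc[present].groupby(groups).sum()
    out = summed.reindex(og_ids, fill_value=0).astype("int64")
    return out


def four_species_filter(per_species_counts: Mapping[str, pd.DataFrame],
                        ) -> list[str]:
    """Keep orthogroups detected in ≥1 sample of *every* species.

    An orthogroup silent in any one species has no defined ratio there and
    is removed before the cross-species model.
    """
    if len(per_species_counts) < 2:
        raise ValueError("need at least two species")
    keep: pd.Series | None = None
    for counts in per_species_counts.values():
        detected = (counts > 0).any(axis=1)
        keep = detected if keep is None else (keep & detected)
    assert keep is not None
    return list(keep.index[keep])


def ratio_matrix(per_species_counts: Mapping[str, pd.DataFrame],
                 meta: pd.DataFrame,
                 factors: Mapping[str, NormFactors] | None = None,
                 pseudo_count: float = 0.5) -> RatioMatrix:
    """Per-individual log2 underground/stem ratios of normalized expression.

    TMM and the variance-stabilizing transform are applied within species —
    absolute levels never cross a species boundary; only the within-
    individual difference of transformed values does.
    """
    check_paired_design(meta)
    ratio_cols: dict[str, np.ndarray] = {}
    col_meta_rows = []
    index = None
    for sp, counts in per_species_counts.items():
        sp_meta = meta[(meta["species"] == sp)
                       & meta["organ"].isin(["underground", "stem"])]
        sample_ids = [s for s in sp_meta.index if s in counts.columns]
        sp_counts = counts[sample_ids]
        sp_meta = sp_meta.loc[sample_ids]
        nf = factors[sp] if factors is not None else tmm_factors(sp_counts)
        norm = normalized_expression(sp_counts, nf)
        transformed = vst(norm.to_numpy(), c=pseudo_count)
        transformed = pd.DataFrame(transformed, index=sp_counts.index,
                                   columns=sp_counts.columns)
        if index is None:
            index = sp_counts.index
        elif not index.equals(sp_counts.index):
            raise ValueError("per-species count tables must share orthogroup rows")
        for ind, grp in sp_meta.groupby("individual"):
            under = grp.index[grp["organ"] == "underground"][0]
            stem = grp.index[grp["organ"] == "stem"][0]
            col = f"{sp}:{ind}"
            ratio_cols[col] = (transformed[under] - transformed[stem]).to_numpy()
            col_meta_rows.append((col, sp, ind, grp["trophic"].iloc[0]))
    ratios = pd.DataFrame(ratio_cols, index=index)
    col_meta = (pd.DataFrame(col_meta_rows,
                             columns=["column", "species", "individual", "trophic"])
                .set_index("column"))
    return RatioMatrix(ratios, col_meta)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    f = lambda x: float(special.polygamma(1, x)) - y
    lo, hi = 1e-8, 1e8
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def squeeze_variances(s2: np.ndarray, d: float) -> SqueezeResult:
    """Empirical-Bayes moderation of per-orthogroup residual variances.

    Assumes s² ~ s0² · F(d, d0); (d0, s0²) are estimated by matching the
    mean and variance of log s² on the digamma/trigamma scale, and each
    variance is replaced by the posterior compromise
    s̃² = (d0·s0² + d·s²)/(d0 + d). When the spread of log s² does not
    exceed what a chi-square with d df alone explains, d0 = ∞ and every
    s̃² = s0².
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 < 0).any():
        raise ValueError("variances must be non-negative")
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero (degenerate input)")
    if len(s2) < 2:
        raise ValueError("need at least two variances to moderate")
    # offset exact zeros to keep logs finite (limma uses a similar floor)
    floor = s2[s2 > 0].min() * 1e-8
    z = np.log(np.maximum(s2, floor))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        # no spread beyond what chi-square sampling alone explains: infinite
        # prior df; the common variance is the geometric mean of the s²
        # themselves (no chi-square bias correction — with zero excess spread
        # the observed values are the best common estimate)
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(z)))
        s2_tilde = np.full_like(s2, s0_sq)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
    return SqueezeResult(float(d0), s0_sq, s2_tilde)


def fit_ratio_model(rm: RatioMatrix, d0: float | None = None,
                    s0_sq: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Species cell-means model + moderated trophic-group contrast per orthogroup.

    Δ = mean(MH species means) − mean(AT species means); its moderated t uses
    the squeezed variance with d0 + d degrees of freedom. Passing ``d0``
    (with ``s0_sq``, ignored when d0 = 0) overrides the empirical-Bayes prior
    — d0 = 0 reduces to the ordinary per-orthogroup t-statistic.

    Returns the per-orthogroup result table and a metadata dict with the
    prior (d0, s0²) and residual df.
    """
    species = sorted(rm.col_meta["species"].unique())
    trophic_of = {sp: rm.col_meta.loc[rm.col_meta["species"] == sp, "trophic"].iloc[0]
                  for sp in species}
    mh = [sp for sp in species if trophic_of[sp] == "MH"]
    at = [sp for sp in species if trophic_of[sp] == "AT"]
    if not mh or not at:
        raise ValueError("need at least one species in each trophic group")
    n_per = {sp: int((rm.col_meta["species"] == sp).sum()) for sp in species}
    low = [sp for sp, k in n_per.items() if k < 2]
    if low:
        raise ValueError(f"species with fewer than 2 individuals: {low}")

    Y = rm.ratios.to_numpy(dtype=float)
    n = Y.shape[1]
    d = n - len(species)

    means = {}
    rss = np.zeros(Y.shape[0])
    for sp in species:
        cols = (rm.col_meta["species"] == sp).to_numpy()
        m = Y[:, cols].mean(axis=1)
        means[sp] = m
        rss += ((Y[:, cols] - m[:, None]) ** 2).sum(axis=1)
    s2 = rss / d

    if d0 is None:
        sq = squeeze_variances(s2, d)
        d0_used, s0_used, s2_tilde = sq.d0, sq.s0_sq, sq.s2_tilde
    elif d0 == 0:
        d0_used, s0_used, s2_tilde = 0.0, float("nan"), s2
    else:
        if s0_sq is None:
            raise ValueError("s0_sq required when d0 is supplied")
        d0_used, s0_used = float(d0), float(s0_sq)
        s2_tilde = ((d0_used * s0_used + d * s2) / (d0_used + d)
                    if np.isfinite(d0_used) else np.full_like(s2, s0_used))

    mean_mh = np.mean([means[sp] for sp in mh], axis=0)
    mean_at = np.mean([means[sp] for sp in at], axis=0)
    delta = mean_mh - mean_at
    # Var(Δ) = s̃² · Σ c_s²/n_s with c = ±1/|group|
    unscaled = (sum(1.0 / (len(mh) ** 2 * n_per[sp]) for sp in mh)
                + sum(1.0 / (len(at) ** 2 * n_per[sp]) for sp in at))
    se = np.sqrt(s2_tilde * unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    df_total = d0_used + d
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.where(se > 0, p, 1.0)

    out = pd.DataFrame({"orthogroup": rm.ratios.index})
    for sp in species:
        out[f"mean_{sp}"] = means[sp]
    out["mean_MH"] = mean_mh
    out["mean_AT"] = mean_at
    out["delta"] = delta
    out["s2"] = s2
    out["moderated_t"] = t
    out["p"] = p
    out["q"] = bh_adjust(p)
    info = {"d0": d0_used, "s0_sq": s0_used, "df_residual": d,
            "mh_species": mh, "at_species": at}
    return out, info


def classify_inversion(fit: pd.DataFrame, alpha: float = 0.05,
                       min_abs_mean: float = 0.0) -> pd.Series:
    """Label each orthogroup inverted / shifted / unchanged.

    Inverted: significant (q < alpha) with opposite-signed MH and AT group
    mean ratios, both exceeding ``min_abs_mean`` in magnitude. Significant
    but same-signed (or one at zero): shifted. Otherwise unchanged.
    """
    sig = fit["q"].to_numpy() < alpha
    m_mh = fit["mean_MH"].to_numpy()
    m_at = fit["mean_AT"].to_numpy()
    opposite = ((np.sign(m_mh) * np.sign(m_at)) < 0) \
        & (np.abs(m_mh) > min_abs_mean) & (np.abs(m_at) > min_abs_mean)
    labels = np.where(~sig, "unchanged", np.where(opposite, "inverted", "shifted"))
    return pd.Series(labels, index=fit.index, name="class")
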