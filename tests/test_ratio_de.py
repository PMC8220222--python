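import numpy as np
import pandas as pd
import pytest

from mycoxpress import ratio_de
from mycoxpress.io_formats import CountMatrix, OrthogroupMap
from mycoxpress.ratio_de import (RatioMatrix, aggregate_orthogroup_counts,
                                 classify_inversion, fit_ratio_model,
                                 four_species_filter, ratio_matrix,
                                 squeeze_variances)
from mycoxpress.synthetic_data import CountSimSpec, gen_count_experiment

from .oracles import contrast_t_oracle


def _pipeline(spec: CountSimSpec):
    exp = gen_count_experiment(spec)
    per = {sp: aggregate_orthogroup_counts(exp.counts, exp.orthogroups, sp)
           for sp in exp.orthogroups.species}
    kept = four_species_filter(per)
    per = {sp: df.loc[kept] for sp, df in per.items()}
    rm = ratio_matrix(per, exp.counts.meta)
    return exp, rm


class TestAggregation:
    def test_member_counts_summed(self, paired_meta):
        omap = OrthogroupMap(
            species=("NNA",),
            members={"OG1": {"NNA": ["g1", "g2"]}, "OG2": {"NNA": []}})
        samples = [s for s in paired_meta.index if s.startswith("NNA")]
        counts = pd.DataFrame(
            {s: [3, 4, 9] for s in paired_meta.index},
            index=["g1", "g2", "unassigned"]).astype("int64")
        cm = CountMatrix(counts, paired_meta)
        agg = aggregate_orthogroup_counts(cm, omap, "NNA")
        assert (agg.loc["OG1", samples] == 7).all()
        assert (agg.loc["OG2"] == 0).all()

    def test_column_sums_bounded_by_gene_sums(self):
        exp, _ = _pipeline(CountSimSpec(n_orthogroups=30, seed=0))
        agg = aggregate_orthogroup_counts(exp.counts, exp.orthogroups, "NNA")
        samples = agg.columns
        assert (agg.sum() <= exp.counts.counts[samples].sum()).all()


class TestFourSpeciesFilter:
    def test_silent_in_one_species_removed(self):
        a = pd.DataFrame({"s1": [1, 1], "s2": [0, 1]}, index=["og1", "og2"])
        b = pd.DataFrame({"t1": [0, 1], "t2": [0, 1]}, index=["og1", "og2"])
        assert four_species_filter({"A": a, "B": b}) == ["og2"]

    def test_one_nonzero_sample_per_species_suffices(self):
        a = pd.DataFrame({"s1": [1], "s2": [0]}, index=["og1"])
        b = pd.DataFrame({"t1": [0], "t2": [1]}, index=["og1"])
        assert four_species_filter({"A": a, "B": b}) == ["og1"]

    def test_monotone_in_species(self):
        exp, _ = _pipeline(CountSimSpec(n_orthogroups=100,
                                        frac_species_missing=0.2, seed=1))
        per = {sp: aggregate_orthogroup_counts(exp.counts, exp.orthogroups, sp)
               for sp in exp.orthogroups.species}
        species = list(per)
        kept_two = set(four_species_filter({s: per[s] for s in species[:2]}))
        kept_all = set(four_species_filter(per))
        assert kept_all <= kept_two


class TestRatioMatrix:
    def test_equal_pairs_give_zero(self, paired_meta):
        counts = pd.DataFrame(100, index=[f"og{i}" for i in range(5)],
                              columns=paired_meta.index, dtype="int64")
        per = {sp: counts[[s for s in paired_meta.index if s.startswith(sp)]]
               for sp in ("NNA", "EA", "ZM", "BD")}
        rm = ratio_matrix(per, paired_meta)
        assert np.allclose(rm.ratios.to_numpy(), 0.0)

    def test_fourfold_ratio_limit(self, paired_meta):
        # one orthogroup at underground = 4 × stem against a large stable
        # background: its ratio converges to log2(4) = 2.0 at high counts
        under = {s for s in paired_meta.index
                 if paired_meta.loc[s, "organ"] == "underground"}
        background = [10000, 20000, 15000, 30000, 25000, 12000, 18000]
        counts = pd.DataFrame(
            {s: [40000 if s in under else 10000] + background
             for s in paired_meta.index},
            index=[f"og{i}" for i in range(8)]).astype("int64")
        per = {sp: counts[[s for s in paired_meta.index if s.startswith(sp)]]
               for sp in ("NNA", "EA", "ZM", "BD")}
        rm = ratio_matrix(per, paired_meta)
        assert rm.ratios.iloc[0].to_numpy() == pytest.approx(2.0, abs=0.01)
        assert rm.ratios.iloc[1:].to_numpy() == pytest.approx(0.0, abs=0.01)

    def test_organ_swap_negates(self):
        spec = CountSimSpec(n_orthogroups=40, seed=5)
        exp, rm = _pipeline(spec)
        meta_swapped = exp.counts.meta.copy()
        meta_swapped["organ"] = meta_swapped["organ"].map(
            {"underground": "stem", "stem": "underground"})
        per = {sp: aggregate_orthogroup_counts(exp.counts, exp.orthogroups, sp)
               for sp in exp.orthogroups.species}
        kept = four_species_filter(per)
        per = {sp: df.loc[kept] for sp, df in per.items()}
        rm_swapped = ratio_matrix(per, meta_swapped)
        assert rm.ratios.to_numpy() == pytest.approx(
            -rm_swapped.ratios.to_numpy(), abs=1e-10)


class TestSqueezeVariances:
    def test_equal_variances_give_infinite_prior(self):
        sq = squeeze_variances(np.full(100, 2.5), d=4)
        assert np.isinf(sq.d0)
        assert sq.s2_tilde == pytest.approx(np.full(100, 2.5), rel=1e-6)

    def test_parameter_recovery_from_scaled_f(self):
        # s² ~ s0²·F(d, d0) with d0 = 4, s0² = 1, 5000 orthogroups
        rng = np.random.default_rng(123)
        d, d0, s0_sq = 4, 4.0, 1.0
        s2 = s0_sq * (rng.chisquare(d, 5000) / d) / (rng.chisquare(d0, 5000) / d0)
        sq = squeeze_variances(s2, d)
        assert 2.5 <= sq.d0 <= 6.5
        assert 0.85 <= sq.s0_sq <= 1.15

    def test_squeeze_pulls_toward_prior(self):
        rng = np.random.default_rng(5)
        s2 = rng.chisquare(4, 500) / 4
        sq = squeeze_variances(s2, d=4)
        # moderated values sit between raw values and the prior
        closer = np.abs(sq.s2_tilde - sq.s0_sq) <= np.abs(s2 - sq.s0_sq) + 1e-12
        assert closer.all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            squeeze_variances(np.zeros(10), d=4)


class TestFitRatioModel:
    def test_constant_ratios_give_null_result(self, paired_meta):
        individuals = [f"{sp}:ind{i}" for sp in ("NNA", "EA", "ZM", "BD")
                       for i in (1, 2)]
        col_meta = pd.DataFrame(
            {"species": [c.split(":")[0] for c in individuals],
             "individual": [c.split(":")[1] for c in individuals],
             "trophic": ["MH"] * 4 + ["AT"] * 4}, index=individuals)
        ratios = pd.DataFrame(0.7, index=[f"og{i}" for i in range(4)],
                              columns=individuals)
        ratios.iloc[0] += np.linspace(-0.1, 0.1, 8)  # avoid all-zero s²
        fit, info = fit_ratio_model(RatioMatrix(ratios, col_meta))
        flat = fit.iloc[1:]
        assert flat["delta"].to_numpy() == pytest.approx(0.0, abs=1e-12)
        assert flat["p"].to_numpy() == pytest.approx(1.0)

    def test_group_swap_symmetry(self):
        exp, rm = _pipeline(CountSimSpec(n_orthogroups=60, frac_inverted=0.2,
                                         seed=8))
        fit, _ = fit_ratio_model(rm)
        swapped_meta = rm.col_meta.copy()
        swapped_meta["trophic"] = swapped_meta["trophic"].map(
            {"MH": "AT", "AT": "MH"})
        fit_sw, _ = fit_ratio_model(RatioMatrix(rm.ratios, swapped_meta))
        assert fit["delta"].to_numpy() == pytest.approx(
            -fit_sw["delta"].to_numpy(), abs=1e-10)
        assert fit["p"].to_numpy() == pytest.approx(fit_sw["p"].to_numpy(),
                                                    rel=1e-9)
        cls = classify_inversion(fit)
        cls_sw = classify_inversion(fit_sw)
        assert (cls == cls_sw).all()

    def test_d0_zero_equals_ordinary_t_oracle(self):
        exp, rm = _pipeline(CountSimSpec(n_orthogroups=25, seed=9))
        fit, info = fit_ratio_model(rm, d0=0)
        mh = info["mh_species"]
        at = info["at_species"]
        for i in range(10):
            vals = {sp: rm.ratios.iloc[i][
                        rm.col_meta.index[rm.col_meta["species"] == sp]].tolist()
                    for sp in mh + at}
            delta, t, d = contrast_t_oracle(vals, mh, at)
            assert fit["delta"].iloc[i] == pytest.approx(delta, abs=1e-10)
            assert fit["moderated_t"].iloc[i] == pytest.approx(t, rel=1e-8)
        assert info["df_residual"] == d

    def test_null_type_i_rate(self):
        _, rm = _pipeline(CountSimSpec(n_orthogroups=2000, frac_inverted=0.0,
                                       seed=1))
        fit, _ = fit_ratio_model(rm)
        rate = (fit["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.08

    def test_planted_inversion_recovery(self):
        exp, rm = _pipeline(CountSimSpec(n_orthogroups=1000, frac_inverted=0.2,
                                         inversion_effect=1.5, seed=1))
        fit, _ = fit_ratio_model(rm)
        fit["class"] = classify_inversion(fit)
        sig = set(fit.loc[fit["q"] < 0.05, "orthogroup"])
        tp = len(sig & exp.truth_inverted)
        fdr = (len(sig) - tp) / max(len(sig), 1)
        sens = tp / len(exp.truth_inverted)
        assert fdr <= 0.10
        assert sens >= 0.5
        # significant planted orthogroups are predominantly classed inverted
        called_inv = set(fit.loc[fit["class"] == "inverted", "orthogroup"])
        assert len(called_inv & exp.truth_inverted) >= 0.9 * len(
            sig & exp.truth_inverted)

    def test_single_individual_species_rejected(self):
        _, rm = _pipeline(CountSimSpec(n_orthogroups=10, seed=2))
        drop = rm.col_meta.index[:-1]
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_ratio_model(RatioMatrix(rm.ratios[list(drop)],
                                        rm.col_meta.loc[list(drop)]))


class TestClassifyInversion:
    @pytest.mark.parametrize("q,m_mh,m_at,expected", [
        (0.01, 1.0, -1.0, "inverted"),
        (0.01, 2.0, 1.0, "shifted"),
        (0.2, 1.0, -1.0, "unchanged"),
        (0.01, 0.0, -1.0, "shifted"),  # a zero mean is not a sign flip
    ])
    def test_rules(self, q, m_mh, m_at, expected):
        fit = pd.DataFrame({"q": [q], "mean_MH": [m_mh], "mean_AT": [m_at]})
        assert classify_inversion(fit).iloc[0] == expected

    def test_dead_zone_option(self):
        fit = pd.DataFrame({"q": [0.01], "mean_MH": [0.05], "mean_AT": [-2.0]})
        assert classify_inversion(fit).iloc[0] == "inverted"
        assert classify_inversion(fit, min_abs_mean=0.1).iloc[0] == "shifted"
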