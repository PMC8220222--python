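import numpy as np
import pytest

from mycoxpress import datasets
from mycoxpress.repertoire import (build_detection_matrix, compare_repertoires,
                                   find_group_exclusive_orthogroups,
                                   fisher_exact_2x2, results_frame)
from mycoxpress.synthetic_data import gen_repertoire

from .oracles import fisher_two_sided_oracle


class TestDetectionMatrix:
    def test_multiplicity_ignored(self):
        det = build_detection_matrix({"sp1": {"g1": "KO1", "g2": "KO1"}})
        assert det.detected.loc["KO1", "sp1"]
        assert det.detected.shape == (1, 1)

    def test_empty_species_gives_all_false_column(self):
        det = build_detection_matrix({"sp1": {"g1": "KO1"}, "sp2": {}})
        assert not det.detected["sp2"].any()

    def test_rows_are_union_of_orthologs(self):
        det = build_detection_matrix({"sp1": {"g1": "KO1"},
                                      "sp2": {"h1": "KO2", "h2": "KO3"}})
        assert set(det.orthologs) == {"KO1", "KO2", "KO3"}


class TestFisherExact:
    @pytest.mark.parametrize("table", [
        (5, 5, 5, 5),
        (141, 48, 18, 171),
        (0, 10, 10, 0),
        (33, 93, 4, 122),
        (1, 0, 0, 1),
        (0, 0, 3, 7),
    ])
    def test_matches_enumeration_oracle(self, table):
        _, p = fisher_exact_2x2(*table)
        assert p == pytest.approx(fisher_two_sided_oracle(*table), abs=1e-12)

    def test_symmetric_table_p_one(self):
        _, p = fisher_exact_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_strong_association_tiny_p(self):
        _, p = fisher_exact_2x2(141, 48, 18, 171)
        assert p < 1e-20

    def test_odds_ratio_edge_cases(self):
        assert fisher_exact_2x2(0, 10, 10, 0)[0] == 0.0
        assert fisher_exact_2x2(10, 0, 0, 10)[0] == np.inf
        odds, p = fisher_exact_2x2(0, 0, 3, 7)  # degenerate margin
        assert np.isnan(odds) and p == 1.0

    def test_random_margins_against_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            r1, r2 = rng.integers(1, 201, 2)
            a = int(rng.integers(0, r1 + 1))
            c = int(rng.integers(0, r2 + 1))
            table = (a, int(r1) - a, c, int(r2) - c)
            _, p = fisher_exact_2x2(*table)
            assert p == pytest.approx(fisher_two_sided_oracle(*table),
                                      abs=1e-12), table

    def test_rejects_negative_or_fractional(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact_2x2(1.5, 2, 3, 4)


class TestCompareRepertoires:
    def test_published_photosynthesis_rows_are_losses(self):
        # the two KEGG pathways with printed per-species detections; tested
        # against the published family of 140 pathways
        det = datasets.kegg_photosynthesis_table().set_index("pathway_id")
        detection = build_detection_matrix({
            sp: {f"{pid}_{i}": f"{pid}_ko{i}"
                 for pid in det.index for i in range(det.loc[pid, sp])}
            for sp in datasets.AUTOTROPHS + datasets.MYCOHETEROTROPHS})
        pathway_map = {pid: [f"{pid}_ko{i}" for i in range(det.loc[pid, "size"])]
                       for pid in det.index}
        results = compare_repertoires(detection, pathway_map,
                                      list(datasets.AUTOTROPHS),
                                      list(datasets.MYCOHETEROTROPHS),
                                      n_family=datasets.KEGG_FAMILY_SIZE)
        by_id = {r.pathway_id: r for r in results}
        assert by_id["195"].table2x2 == (141, 48, 18, 171)
        assert by_id["196"].table2x2 == (33, 93, 4, 122)
        for pid in ("195", "196"):
            assert by_id[pid].p_adjusted < 0.05
            assert by_id[pid].label == "Losses"

    def test_identical_detection_is_ns(self):
        rep = gen_repertoire(n_pathways=5, loss_fraction=0.0, p_detect=1.0,
                             seed=0)
        results = compare_repertoires(rep.detection, rep.pathway_map,
                                      ["AS", "DC", "PE"], ["GE", "EA", "NNA"])
        assert all(r.p == 1.0 and r.label == "NS" for r in results)

    def test_group_swap_symmetry(self):
        rep = gen_repertoire(n_pathways=10, lost_pathways=4, loss_fraction=0.9,
                             seed=3)
        a = compare_repertoires(rep.detection, rep.pathway_map,
                                ["AS", "DC", "PE"], ["GE", "EA", "NNA"])
        b = compare_repertoires(rep.detection, rep.pathway_map,
                                ["GE", "EA", "NNA"], ["AS", "DC", "PE"])
        for ra, rb in zip(a, b):
            assert ra.p == pytest.approx(rb.p, rel=1e-12)
            if np.isfinite(ra.odds_ratio) and ra.odds_ratio > 0:
                assert rb.odds_ratio == pytest.approx(1.0 / ra.odds_ratio)
            assert {ra.label, rb.label} in ({"NS"}, {"Losses", "Gains"})

    def test_species_order_invariance(self):
        rep = gen_repertoire(n_pathways=8, lost_pathways=2, loss_fraction=0.8,
                             seed=5)
        a = compare_repertoires(rep.detection, rep.pathway_map,
                                ["AS", "DC", "PE"], ["GE", "EA", "NNA"])
        b = compare_repertoires(rep.detection, rep.pathway_map,
                                ["PE", "AS", "DC"], ["NNA", "GE", "EA"])
        assert [r.p for r in a] == [r.p for r in b]

    def test_complete_loss_flagged(self):
        rep = gen_repertoire(n_pathways=40, orthologs_per_pathway=60,
                             lost_pathways=1, loss_fraction=1.0, seed=6)
        results = compare_repertoires(rep.detection, rep.pathway_map,
                                      ["AS", "DC", "PE"], ["GE", "EA", "NNA"])
        flagged = {r.pathway_id for r in results if r.label == "Losses"}
        assert rep.lost_pathways <= flagged

    def test_null_type_i_bonferroni(self):
        # family-wise error: with no planted losses, ≥95% of seeds flag nothing
        hits = 0
        for seed in range(10):
            rep = gen_repertoire(n_pathways=200, orthologs_per_pathway=20,
                                 loss_fraction=0.0, seed=seed)
            results = compare_repertoires(rep.detection, rep.pathway_map,
                                          ["AS", "DC", "PE"],
                                          ["GE", "EA", "NNA"])
            if any(r.label != "NS" for r in results):
                hits += 1
        assert hits <= 1

    def test_overlapping_groups_rejected(self):
        rep = gen_repertoire(n_pathways=2, seed=0)
        with pytest.raises(ValueError, match="disjoint"):
            compare_repertoires(rep.detection, rep.pathway_map,
                                ["AS", "DC"], ["DC", "GE"])

    def test_results_frame_columns(self):
        rep = gen_repertoire(n_pathways=3, seed=0)
        df = results_frame(compare_repertoires(
            rep.detection, rep.pathway_map, ["AS"], ["GE"]))
        assert {"pathway_id", "p", "p_adjusted", "label"} <= set(df.columns)


class TestGroupExclusive:
    def test_exact_group_included(self, toy_orthogroups):
        # OG2 has genes from all three species; OG1 from spA+spC; OG3 spB only
        assert find_group_exclusive_orthogroups(
            toy_orthogroups, ["spA", "spC"]) == {"OG0000001"}

    def test_superset_excluded(self, toy_orthogroups):
        assert find_group_exclusive_orthogroups(
            toy_orthogroups, ["spA", "spB", "spC"]) == {"OG0000002"}

    def test_subset_excluded(self, toy_orthogroups):
        # all group members must contribute, not just some
        assert find_group_exclusive_orthogroups(
            toy_orthogroups, ["spB", "spC"]) == set()

    def test_unknown_species_rejected(self, toy_orthogroups):
        with pytest.raises(ValueError):
            find_group_exclusive_orthogroups(toy_orthogroups, ["spX"])
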