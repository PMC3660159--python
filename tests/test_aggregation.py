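"""β-pairing energies, consensus prediction, segments, and taxon calls."""

import math

import numpy as np
import pytest

from appfam.aggregation import (AMYLOID_PRONE_SET, CleavageSites,
                                EnergyProfile, NO_PAIRING,
                                PairingEnergyTable, Segment, WindowScorer,
                                annotate_tree_with_classes,
                                brute_force_profile, call_taxon,
                                classify_segments, classify_taxon,
                                consensus_predict, default_energy_table,
                                default_scorers, extract_ba4_regions,
                                pasta_energy_profile, read_cleavage_sites,
                                surrogate_energy_table, truncation_scan)
from appfam.trees import read_newick_string
from appfam.types import AlignedMatrix, DomainInterval, DomainMap

AA = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="module")
def table():
    return surrogate_energy_table()


class TestEnergyTable:
    def test_packaged_file_matches_code_surrogate(self, table):
        packaged = default_energy_table()
        assert np.allclose(packaged.parallel, table.parallel, atol=1e-7)
        assert np.allclose(packaged.antiparallel, table.antiparallel,
                           atol=1e-7)
        assert "synthetic" in packaged.provenance

    def test_tsv_round_trip(self, table, tmp_path):
        p = tmp_path / "t.tsv"
        table.to_tsv(p)
        back = PairingEnergyTable.from_tsv(p)
        assert np.allclose(back.parallel, table.parallel, atol=1e-7)
        assert back.provenance == table.provenance

    def test_hydrophobic_pairs_stabilise_polar_pairs_do_not(self, table):
        assert table.pair_energy("I", "V", "parallel") < 0
        assert table.pair_energy("S", "S", "parallel") > 0

    def test_unknown_residue_is_neutral(self, table):
        assert table.pair_energy("X", "I", "parallel") == 0.0

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((20, 20))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            PairingEnergyTable(parallel=m, antiparallel=np.zeros((20, 20)))


class TestEnergyProfile:
    def test_short_sequence_has_no_pairings(self, table):
        prof = pasta_energy_profile("IVLFIVL", table, min_strand_len=4)
        assert all(e == NO_PAIRING for e in prof.energies)

    def test_matches_brute_force_oracle(self, table):
        rng = np.random.default_rng(17)
        for _ in range(40):
            L = int(rng.integers(8, 15))
            seq = "".join(rng.choice(AA, size=L))
            fast = pasta_energy_profile(seq, table).energies
            slow = brute_force_profile(seq, table)
            assert np.allclose(fast, slow)

    def test_hydrophobic_sequence_scores_below_polar(self, table):
        polar = pasta_energy_profile("S" * 20, table)
        greasy = pasta_energy_profile("IV" * 10, table)
        assert greasy.min_energy < polar.min_energy
        assert greasy.min_energy < -4.0
        assert polar.min_energy > -2.0

    def test_human_abeta42_c_terminus_is_fibril_competent(self, table):
        # C-terminal window of Abeta42 (after the alpha site)
        prof = pasta_energy_profile("LVFFAEDVGSNKGAIIGLMVGGVVIA", table)
        assert prof.min_energy < -4.0

    def test_profile_covers_every_residue_when_long_enough(self, table):
        prof = pasta_energy_profile("SSTTNNQQDDIVLF", table)
        assert np.isfinite(prof.energies).all()
        assert set(prof.orientation) <= {"parallel", "antiparallel"}


class TestConsensusPredict:
    def test_single_permissive_scorer_flags_everything(self):
        scorer = WindowScorer("always", {c: 1.0 for c in AA}, window=3,
                              threshold=0.0)
        flags = consensus_predict("MKVLAST", [scorer], k=1)
        assert flags.all()

    def test_one_vote_is_not_consensus_at_k2(self):
        yes = WindowScorer("yes", {c: 1.0 for c in AA}, 3, 0.0)
        no1 = WindowScorer("no1", {c: 0.0 for c in AA}, 3, 5.0)
        no2 = WindowScorer("no2", {c: 0.0 for c in AA}, 3, 5.0)
        flags = consensus_predict("MKVLAST", [yes, no1, no2], k=2)
        assert not flags.any()

    def test_antitone_in_k(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            seq = "".join(rng.choice(AA, size=30))
            f2 = consensus_predict(seq, k=2)
            f3 = consensus_predict(seq, k=3)
            assert not (f3 & ~f2).any()

    def test_antitone_in_scorer_threshold(self):
        rng = np.random.default_rng(20)
        seq = "".join(rng.choice(AA, size=40))
        lo = [WindowScorer(s.name, s.scale, s.window, s.threshold, s.mode)
              for s in default_scorers()]
        hi = [WindowScorer(s.name, s.scale, s.window, s.threshold + 0.5,
                           s.mode) for s in default_scorers()]
        assert not (consensus_predict(seq, hi, 2)
                    & ~consensus_predict(seq, lo, 2)).any()

    def test_k_larger_than_scorer_count_rejected(self):
        with pytest.raises(ValueError):
            consensus_predict("MKV", k=5)

    def test_hexapeptide_scorer_needs_full_window_in_set(self):
        scorer = next(s for s in default_scorers()
                      if s.mode == "all_in_set")
        flags = scorer.flags("IVLIVL" + "DDDDDD")
        assert flags[:6].all()
        assert not flags[6:].any()


def _profile_from(energies):
    e = np.array(energies, dtype=float)
    return EnergyProfile("A" * len(e), e,
                         np.array([""] * len(e), dtype=object), 4)


class TestClassifySegments:
    def test_no_consensus_means_no_segments(self):
        prof = _profile_from([-6.0] * 10)
        assert classify_segments(prof, np.zeros(10, dtype=bool)) == []

    def test_deep_energies_with_consensus_form_high_segment(self):
        prof = _profile_from([-5.0] * 6)
        segs = classify_segments(prof, np.ones(6, dtype=bool))
        assert segs == [Segment(0, 6, "high", -5.0)]

    def test_marginal_band_forms_low_segment(self):
        prof = _profile_from([-2.0, -3.5, -3.5, -3.5, -3.5, -3.5, -3.5,
                              -3.5, -3.5, -2.0])
        segs = classify_segments(prof, np.ones(10, dtype=bool))
        assert segs == [Segment(1, 9, "low", -3.5)]

    def test_runs_shorter_than_min_run_dropped(self):
        prof = _profile_from([-5.0, -5.0, 0.0, -5.0, -5.0, -5.0])
        segs = classify_segments(prof, np.ones(6, dtype=bool))
        assert segs == [Segment(3, 6, "high", -5.0)]

    def test_boundary_minus_four_belongs_to_low_band(self):
        prof = _profile_from([-4.0] * 4)
        segs = classify_segments(prof, np.ones(4, dtype=bool))
        assert segs[0].klass == "low"

    def test_high_and_low_never_overlap_and_high_is_below_threshold(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            e = rng.uniform(-6, 0, size=40)
            cons = rng.random(40) < 0.7
            segs = classify_segments(_profile_from(e), cons)
            spans = []
            for s in segs:
                if s.klass == "high":
                    assert (e[s.start:s.end] < -4.0).all()
                spans.append((s.start, s.end))
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                assert a1 <= b0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_segments(_profile_from([-5.0] * 4),
                              np.ones(5, dtype=bool))


class TestTruncationScan:
    def test_benign_sequence_stops_immediately(self, table):
        scan = truncation_scan("S" * 20, table)
        assert len(scan) == 1
        assert scan[0][0] == 20
        assert scan[0][1] > -2.0

    def test_entries_match_one_shot_prefix_evaluations(self, table):
        seq = "SSTTIVLFIVLFSSTT"
        scan = truncation_scan(seq, table)
        for length, energy in scan:
            ref = pasta_energy_profile(seq[:length], table).min_energy
            assert energy == pytest.approx(ref)

    def test_last_entry_is_first_crossing(self, table):
        seq = "SSTTIVLFIVLFIVSS"
        scan = truncation_scan(seq, table)
        *head, (last_len, last_e) = scan
        assert last_e > -2.0 or last_len == 1
        for _, e in head:
            assert e <= -2.0
        lengths = [l for l, _ in scan]
        assert lengths == list(range(lengths[0], lengths[-1] - 1, -1))


class TestClassifyTaxon:
    def _seg(self, klass):
        return Segment(0, 5, klass, -5.0 if klass == "high" else -3.5)

    @pytest.mark.parametrize("n_class,c_class,expected", [
        (None, None, "none"),
        (None, "low", "none"),
        (None, "high", "none"),   # C-terminal alone is insufficient
        ("low", None, "none"),
        ("low", "low", "low"),
        ("low", "high", "low"),
        ("high", None, "none"),
        ("high", "low", "high"),
        ("high", "high", "high"),
    ])
    def test_two_region_rule_truth_table(self, n_class, c_class, expected):
        n = [self._seg(n_class)] if n_class else []
        c = [self._seg(c_class)] if c_class else []
        assert classify_taxon(n, c) == expected

    def test_best_n_segment_wins(self):
        n = [self._seg("low"), self._seg("high")]
        c = [self._seg("low")]
        assert classify_taxon(n, c) == "high"


class TestExtractRegions:
    def _alignment(self):
        #          0123456789012345
        ref_row = "MMSSTTIVLFWWGGHH"
        rows = {
            "ref": ref_row,
            "plain": "MMSSTTIVLFWWGGHH",
            "ins": "MMSSTT--LFWWGGHH",
        }
        return AlignedMatrix(list(rows), list(rows.values()))

    def _dmap(self):
        return DomainMap("ref", [DomainInterval("bA4", 4, 14,
                                                allow_overlap=True)])

    def test_reference_uses_its_own_annotation(self):
        m, d = self._alignment(), self._dmap()
        sites = {"ref": CleavageSites("ref", 4, 8, 14)}
        regions = extract_ba4_regions(m, d, sites)
        r = regions["ref"]
        assert r.provenance == "own"
        assert r.n_window == (4, 8)
        assert r.c_window == (8, 14)
        assert r.full_seq == "TTIVLFWWGG"

    def test_unannotated_taxon_falls_back_to_reference_projection(self):
        m, d = self._alignment(), self._dmap()
        sites = {"ref": CleavageSites("ref", 4, 8, 14)}
        regions = extract_ba4_regions(m, d, sites)
        assert regions["plain"].provenance == "fallback-reference"
        assert regions["plain"].full_seq == "TTIVLFWWGG"
        # deletion under the window shortens the extracted region
        assert regions["ins"].full_seq == "TTLFWWGG"
        assert regions["ins"].n_window == (4, 6)

    def test_insertion_inside_region_is_included(self):
        rows = {"ref": "MMSST--TIVLFWW", "ins": "MMSSTGGTIVLFWW"}
        m = AlignedMatrix(list(rows), list(rows.values()))
        d = DomainMap("ref", [DomainInterval("bA4", 2, 10,
                                             allow_overlap=True)])
        sites = {"ref": CleavageSites("ref", 2, 6, 10)}
        regions = extract_ba4_regions(m, d, sites)
        assert regions["ins"].full_seq == "SSTGGTIVLF"

    def test_nearest_annotated_neighbor_on_tree(self):
        rows = {"ref": "MMSSTTIVLFWWGGHH",
                "near": "MMSSTTIVLFWWGGHH",
                "far": "MMSSTTIVLFWWGGHH"}
        m = AlignedMatrix(list(rows), list(rows.values()))
        d = self._dmap()
        tree = read_newick_string("((near,far),ref);")
        sites = {"ref": CleavageSites("ref", 4, 8, 14),
                 "far": CleavageSites("far", 2, 8, 14)}
        regions = extract_ba4_regions(m, d, sites, tree=tree)
        assert regions["near"].provenance == "neighbor:far"
        assert regions["near"].n_window == (2, 8)

    def test_missing_reference_annotation_rejected(self):
        m, d = self._alignment(), self._dmap()
        with pytest.raises(KeyError):
            extract_ba4_regions(m, d, {})

    def test_packaged_cleavage_example_reads(self):
        from importlib import resources
        path = resources.files("appfam") / "data" / \
            "cleavage_sites_human_app770.tsv"
        sites = read_cleavage_sites(path)
        s = sites["APP_HUMAN_770"]
        assert (s.beta, s.alpha, s.gamma) == (671, 687, 713)
        assert s.gamma - s.beta == 42  # Abeta42


class TestAnnotateTree:
    def test_all_tips_annotated_and_round_trip(self, tmp_path):
        from appfam.trees import read_newick, write_newick
        t = read_newick_string("((a,b),c);")
        out = annotate_tree_with_classes(
            t, {"a": "high", "b": "low", "c": "none"})
        p = tmp_path / "t.nwk"
        write_newick(out, p)
        back = read_newick(p)
        classes = {n.label: n.annotations["class"] for n in back.tips()}
        assert classes == {"a": "high", "b": "low", "c": "none"}

    def test_missing_class_defaults_to_none_with_warning(self, caplog):
        t = read_newick_string("((a,b),c);")
        with caplog.at_level("WARNING"):
            out = annotate_tree_with_classes(t, {"a": "high"})
        classes = {n.label: n.annotations["class"] for n in out.tips()}
        assert classes["b"] == "none"


class TestPlantedMotifDetection:
    def test_two_region_plants_classify_the_planted_clade(self,
                                                          small_bundle):
        m = small_bundle.alignment
        dmap = DomainMap(m.row_ids[0],
                         [DomainInterval("bA4", 80, 110,
                                         allow_overlap=True)])
        sites = {m.row_ids[0]: CleavageSites(m.row_ids[0], 80, 93, 110)}
        regions = extract_ba4_regions(m, dmap, sites,
                                      tree=small_bundle.tree)
        app = set(small_bundle.clade_tips("APP"))
        for rid in m.row_ids:
            call = call_taxon(regions[rid])
            if rid in app:
                assert call.klass == "high"
            else:
                assert not call.has_n_segment
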