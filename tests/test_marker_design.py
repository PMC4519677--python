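"""Diagnostic-site scanning, Tm behaviour, pair design, interactions,
multiplex grouping."""

import pytest

from barcodekit.errors import DesignError
from barcodekit.insilico_pcr import predict_amplicons
from barcodekit.marker_design import (
    DesignConstraints,
    MarkerPair,
    PrimerCandidate,
    build_multiplex_groups,
    design_primer_pairs,
    find_diagnostic_sites,
    melting_temperature,
    screen_interactions,
)
from barcodekit.seqio import LabeledAlignment, revcomp


def make_aln(rows_by_species):
    ids, rows, species = [], [], {}
    for sp, sp_rows in rows_by_species.items():
        for i, r in enumerate(sp_rows):
            sid = f"{sp}_{i}"
            ids.append(sid); rows.append(r); species[sid] = sp
    return LabeledAlignment(ids=ids, rows=rows, species_of=species)


class TestDiagnosticSites:
    def test_toy_column_diagnostic_both_ways(self):
        aln = make_aln({"sp1": ["ACGT", "ACGT"], "sp2": ["ACTT", "ACTT"]})
        s1 = find_diagnostic_sites(aln, "sp1")
        s2 = find_diagnostic_sites(aln, "sp2")
        assert [s.column for s in s1] == [2]
        assert s1[0].target_state == "G"
        assert [s.column for s in s2] == [2]
        assert s2[0].target_state == "T"

    def test_identical_species_no_sites(self):
        aln = make_aln({"sp1": ["ACGT"], "sp2": ["ACGT"]})
        assert find_diagnostic_sites(aln, "sp1") == []

    def test_intraspecific_polymorphism_disqualifies(self):
        aln = make_aln({"sp1": ["ACGT", "ACAT"], "sp2": ["ACTT"]})
        assert find_diagnostic_sites(aln, "sp1") == []

    def test_background_gap_flagged_and_strict_mode_drops(self):
        aln = make_aln({"sp1": ["ACGT"], "sp2": ["AC-T"]})
        sites = find_diagnostic_sites(aln, "sp1")
        assert [s.column for s in sites] == [2]
        assert sites[0].background_ambiguous
        assert find_diagnostic_sites(aln, "sp1", strict=True) == []

    def test_row_order_and_duplication_invariance(self, panel):
        from barcodekit.alignment import progressive_msa

        aln = progressive_msa(panel.sequences, panel.species_of)
        target = aln.species_list[0]
        before = find_diagnostic_sites(aln, target)
        rev = LabeledAlignment(ids=aln.ids[::-1], rows=aln.rows[::-1],
                               species_of=aln.species_of)
        assert find_diagnostic_sites(rev, target) == before
        dup = LabeledAlignment(
            ids=aln.ids + [aln.ids[0] + "_dup"],
            rows=aln.rows + [aln.rows[0]],
            species_of={**aln.species_of,
                        aln.ids[0] + "_dup": aln.species_of[aln.ids[0]]})
        assert find_diagnostic_sites(dup, target) == before


class TestMeltingTemperature:
    def test_duplex_symmetry(self):
        for s in ("GTATATGAATGTGAATCGGTATTC", "CGATCAACATCCTTTGGG",
                  "TTGACTCCTTACTGCGGAAT"):
            assert melting_temperature(s) == pytest.approx(
                melting_temperature(revcomp(s)), abs=0.05)

    def test_gc_extension_raises_tm_for_typical_primers(self):
        # spot checks in the design Tm range (not a universal NN identity)
        for s in ("CATTTACGATCAACATCCTTTA", "GTATATGAATGTGAATCGGTATTC"):
            assert melting_temperature(s + "G") > melting_temperature(s)
            assert melting_temperature("C" + s) > melting_temperature(s)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(DesignError):
            melting_temperature("ACGTNACGTACGT")

    def test_too_short_rejected(self):
        with pytest.raises(DesignError):
            melting_temperature("ACGTACG")


class TestDesign:
    def test_no_diagnostic_sites_gives_empty_with_tally(self):
        aln = make_aln({"sp1": ["ACGT" * 10], "sp2": ["ACGT" * 10]})
        markers, tally = design_primer_pairs(aln, "sp1")
        assert markers == []
        assert tally["no_diagnostic_sites"] == 1

    def test_designed_pairs_are_anchored_and_sized(self, panel):
        from barcodekit.alignment import progressive_msa

        aln = progressive_msa(panel.sequences, panel.species_of)
        cons = DesignConstraints()
        for sp in aln.species_list:
            markers, tally = design_primer_pairs(aln, sp, cons)
            assert markers, f"no marker for {sp}: {dict(tally)}"
            for m in markers:
                assert m.forward.anchored or m.reverse.anchored
                assert cons.primer_len_min <= len(m.forward) <= cons.primer_len_max
                assert cons.primer_len_min <= len(m.reverse) <= cons.primer_len_max
                assert cons.product_min <= m.expected_size <= cons.product_max
                assert abs(m.forward.tm_celsius - m.reverse.tm_celsius) \
                    <= cons.delta_tm_max

    def test_marker_amplifies_targets_only_by_construction(self, panel):
        from barcodekit.alignment import progressive_msa

        aln = progressive_msa(panel.sequences, panel.species_of)
        sp = aln.species_list[0]
        markers, _ = design_primer_pairs(aln, sp)
        m = markers[0]
        for sid in aln.ids:
            template = aln.ungapped(sid)
            amps = predict_amplicons(m.forward.sequence, m.reverse.sequence,
                                     template, sid)
            if aln.species_of[sid] == sp:
                assert len(amps) == 1
                assert amps[0].product_length == m.expected_size
            else:
                assert amps == []


def primer(name, seq, tm=60.0, sense="F"):
    return PrimerCandidate(name, sense, seq, (0, len(seq)), tm, True)


def dummy_marker(name, size, temp, f_seq, r_seq):
    return MarkerPair(name, primer(name + "_F", f_seq),
                      primer(name + "_R", r_seq, sense="R"),
                      name, size, temp)


class TestInteractions:
    def test_exact_reverse_complement_flagged(self):
        p = "GTATATGAATGTGAATCGGTATTC"
        rep = screen_interactions([p, revcomp(p)])
        assert any(run >= len(p) for _, _, run in rep.flagged_pairs)

    def test_poly_a_vs_poly_c_clean(self):
        rep = screen_interactions(["A" * 20, "C" * 20])
        assert rep.clean

    def test_five_base_three_prime_complement_flagged_at_threshold(self):
        # 3' ends ...GCGCG and ...CGCGC: revcomp(GCGCG) = CGCGC appears in q
        p = "AATTAATTAATTGCGCG"
        q = "TTAATTAATTAACGCGC"
        rep5 = screen_interactions([p, q], threshold=5)
        assert any(run >= 5 for _, _, run in rep5.flagged_pairs)
        rep6 = screen_interactions(["AATTAATTAATTGACTG", "TTAATTAATTAAGTCCA"],
                                   threshold=5)
        assert not any(run >= 5 for _, _, run in rep6.flagged_pairs)

    def test_hairpin_detected(self):
        # GCCG ... CGGC with a 4-base loop between
        rep = screen_interactions(["AAGCCGAAAATTTTCGGCAA"])
        assert rep.hairpins


class TestMultiplex:
    def test_published_style_group_at_65(self):
        ms = [dummy_marker("chm", 396, 65, "A" * 20, "C" * 20),
              dummy_marker("ret", 364, 65, "AAC" * 7, "CCA" * 7),
              dummy_marker("mur", 332, 65, "ACA" * 7, "CAC" * 7)]
        groups, leftover = build_multiplex_groups(ms, min_separation=30)
        assert leftover == []
        assert len(groups) == 1
        assert sorted(groups[0].sizes()) == [332, 364, 396]

    def test_published_style_group_at_69(self):
        ms = [dummy_marker("squ", 315, 69, "A" * 20, "C" * 20),
              dummy_marker("mac", 644, 69, "AAC" * 7, "CCA" * 7),
              dummy_marker("gla", 476, 69, "ACA" * 7, "CAC" * 7)]
        groups, leftover = build_multiplex_groups(ms, min_separation=30)
        assert leftover == []
        assert len(groups) == 1
        assert sorted(groups[0].sizes()) == [315, 476, 644]

    def test_close_sizes_cannot_cogroup(self):
        ms = [dummy_marker("a", 300, 65, "A" * 20, "C" * 20),
              dummy_marker("b", 310, 65, "AAC" * 7, "CCA" * 7)]
        groups, leftover = build_multiplex_groups(ms, min_separation=30)
        assert groups == []
        assert len(leftover) == 2
        assert any("within 30 bp" in reason for _, reason in leftover)

    def test_different_temps_never_mix(self):
        ms = [dummy_marker("a", 300, 65, "A" * 20, "C" * 20),
              dummy_marker("b", 400, 69, "AAC" * 7, "CCA" * 7)]
        groups, leftover = build_multiplex_groups(ms)
        assert groups == []
        assert len(leftover) == 2
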