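"""ORF discovery, gene/pseudogene classification and translation."""

import pytest

from gliakit import (GeneSpec, OrfRecord, build_gamma_gene, build_locus,
                     classify_orf, find_orfs, pseudogenize, translate_orf,
                     truncate)
from gliakit.annotate import annotate_genomic
from gliakit.synthetic import glutamine_codons, reverse_complement

# stop-free filler for hand-built sequences (no ATG, no stops in any frame)
FILLER = "CCTCCACCG" * 12


def _planted_orf():
    return "ATG" + "AAA" * 40 + "TAA"


class TestFindOrfs:
    def test_single_planted_orf_recovered(self):
        seq = FILLER[:100] + _planted_orf() + FILLER[:80]
        orfs = find_orfs(seq, min_len_bp=120)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.end, o.length_bp) == (101, 226, 126)
        assert o.sequence == _planted_orf()

    def test_reverse_complement_reported_on_minus_strand(self):
        seq = FILLER[:100] + reverse_complement(_planted_orf()) + FILLER[:80]
        orfs = find_orfs(seq, min_len_bp=120)
        assert len(orfs) == 1
        assert orfs[0].strand == "-"
        assert orfs[0].sequence == _planted_orf()

    def test_locus_recovery_matches_generator_truth(self):
        genes = [build_gamma_gene(GeneSpec(seed=s)) for s in (11, 12, 13)]
        loc = build_locus(genes, seed=21)
        found = find_orfs(loc.sequence)
        assert [(o.start, o.end, o.strand) for o in found] == \
            [(g.start, g.end, g.strand) for g in loc.genes]
        for o, g in zip(found, loc.genes):
            assert o.sequence == g.truth.dna

    def test_nested_orfs_report_five_prime_most_atg(self):
        # second in-frame ATG shares the stop; only the longer ORF reported
        seq = FILLER[:99] + "ATG" + "AAA" * 10 + "ATG" + "AAA" * 30 + "TAA"
        orfs = find_orfs(seq + FILLER[:60], min_len_bp=60)
        assert len(orfs) == 1
        assert orfs[0].start == 100

    def test_input_validation(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            find_orfs("ACGTX" * 100)
        with pytest.raises(ValueError):
            find_orfs("ACGT" * 100, min_len_bp=100)  # not divisible by 3

    def test_orf_with_ambiguous_bases_skipped(self, caplog):
        seq = FILLER[:99] + "ATG" + "AAA" * 20 + "ANA" + "AAA" * 20 + "TAA"
        assert find_orfs(seq + FILLER[:60], min_len_bp=60, strands="forward") == []


class TestClassify:
    def test_full_length_gene(self):
        t = build_gamma_gene(GeneSpec(seed=1))
        m = classify_orf(OrfRecord.from_sequence("g", t.dna))
        assert m.status == "full_length" and m.premature_stops == []

    def test_pseudogene_stop_recovered_with_ancestral_codon(self):
        t = build_gamma_gene(GeneSpec(seed=1))
        ci = next(c for c in glutamine_codons(t) if c >= 35)
        ps = pseudogenize(t, ci)
        m = classify_orf(OrfRecord.from_sequence("ps", ps.dna))
        assert m.status == "pseudogene"
        assert m.premature_stops == [ps.pseudogene_stop]
        assert m.note == f"{ps.pseudogene_stop[1]} at bp {ps.pseudogene_stop[0]}"

    def test_stop_positions_congruent_one_mod_three(self):
        t = build_gamma_gene(GeneSpec(seed=8))
        for ci in glutamine_codons(t)[:20]:
            m = classify_orf(OrfRecord.from_sequence("x", pseudogenize(t, ci).dna))
            assert all(bp % 3 == 1 for bp, _, _ in m.premature_stops)

    def test_truncated_pseudogene_with_earlier_stop(self):
        # analog of a truncated avenin-like pseudogene: internal TAG plus
        # a cut ORF with no terminal stop
        t = build_gamma_gene(GeneSpec(seed=4))
        ci = next(c for c in glutamine_codons(t) if 3 * (c - 1) + 1 == 79 or c >= 27)
        ps = truncate(pseudogenize(t, ci), 465)
        m = classify_orf(OrfRecord.from_sequence("av", ps.dna),
                         expected_len_range=(450, 1100))
        assert m.status == "pseudogene"
        assert m.truncated
        assert m.premature_stops[0][:2] == ps.pseudogene_stop[:2]
        assert "Truncated at bp 465" in m.note

    def test_tga_stop_has_unknown_ancestor(self):
        seq = "ATG" + "AAA" * 10 + "TGA" + "AAA" * 10 + "TAA"
        m = classify_orf(OrfRecord.from_sequence("x", seq))
        assert m.premature_stops == [(34, "TGA", "unknown")]


class TestTranslate:
    def test_minimal_orf(self):
        assert translate_orf(OrfRecord.from_sequence("x", "ATGAAATAA")).sequence == "MK"

    def test_full_length_arithmetic(self):
        # bp/3 − 1: the identity connecting gene sizes to protein lengths
        from gliakit.synthetic import spec_for_protein_length
        t = build_gamma_gene(spec_for_protein_length(321, seed=2))
        assert len(t.dna) == 966
        p = translate_orf(OrfRecord.from_sequence("g", t.dna))
        assert len(p.sequence) == 321

    def test_readthrough_marks_internal_stop(self):
        t = build_gamma_gene(GeneSpec(seed=1))
        ci = next(c for c in glutamine_codons(t) if c >= 39)
        ps = pseudogenize(t, ci)
        orf = OrfRecord.from_sequence("ps", ps.dna)
        rt = translate_orf(orf, readthrough=True)
        assert rt.sequence[ci - 1] == "*"
        assert len(rt.sequence) == len(ps.dna) // 3 - 1
        stop_only = translate_orf(orf)
        assert len(stop_only.sequence) == ci - 1


class TestAnnotateGenomic:
    def test_mixed_locus_census(self):
        genes = [build_gamma_gene(GeneSpec(seed=s)) for s in (31, 32, 33)]
        ps = pseudogenize(genes[2],
                          next(c for c in glutamine_codons(genes[2]) if c >= 30))
        loc = build_locus([genes[0], genes[1], ps], seed=9)
        models = annotate_genomic(loc.sequence)
        assert [m.status for m in models] == \
            ["full_length", "full_length", "pseudogene"]
        assert models[2].premature_stops == [ps.pseudogene_stop]
        assert [(m.orf.start, m.orf.end) for m in models] == \
            [(g.start, g.end) for g in loc.genes]
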