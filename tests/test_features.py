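"""Domain segmentation, repeat/poly-Q/cysteine profiling, MW and pI."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gliakit import (GeneSpec, ProteinRecord, build_gamma_gene,
                     count_repeat_motif, cysteine_profile, find_polyq,
                     physchem, segment_domains)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestSegmentation:
    def test_generator_truth_recovered(self, default_gene):
        t = default_gene
        seg = segment_domains(t.protein, orf_dna=t.dna)
        assert seg.intervals == t.domain_boundaries

    def test_polyq_free_gene_merges_tail_domains(self):
        t = build_gamma_gene(GeneSpec(seed=6, polyq_length=0))
        seg = segment_domains(t.protein)
        assert seg["IV"] is None
        b = t.domain_boundaries
        assert seg["III"] == (b["III"][0], b["V"][1])
        assert any("poly-Q" in w for w in seg.warnings)

    def test_non_gliadin_architecture_flagged(self):
        seg = segment_domains("M" + "ADEKNRST" * 10)
        assert seg["II"] is None and seg["IV"] is None
        assert any("non-gliadin" in w for w in seg.warnings)

    def test_readthrough_product_refused(self):
        with pytest.raises(ValueError, match="readthrough"):
            segment_domains(
                ProteinRecord(id="x", sequence="MKL*PQ", readthrough=True))


class TestRepeatMotif:
    @pytest.mark.parametrize("seq,mode,expected", [
        ("PQQPFPQ" * 3, "overlapping", 3),
        ("PQQPFPQ" * 3, "non_overlapping", 3),
        ("PQQPFPQQPFPQ", "overlapping", 2),       # self-overlap at offset 5
        ("PQQPFPQQPFPQ", "non_overlapping", 1),
        ("AAAAAAAA", "overlapping", 0),
    ])
    def test_counts(self, seq, mode, expected):
        count, starts = count_repeat_motif(seq, mode=mode)
        assert count == expected
        if seq == "PQQPFPQQPFPQ" and mode == "overlapping":
            assert starts == [1, 6]

    def test_overlapping_at_least_non_overlapping(self, default_gene):
        over, _ = count_repeat_motif(default_gene.protein, mode="overlapping")
        non, _ = count_repeat_motif(default_gene.protein, mode="non_overlapping")
        assert over >= non
        assert over == default_gene.unit_count


class TestPolyQ:
    def test_pure_tract(self):
        orf = "ATG" + "CCT" * 5 + "CAA" * 10 + "CCT" * 5 + "TAA"
        tract = find_polyq(orf)
        assert (tract.start_codon, tract.end_codon) == (7, 16)
        assert tract.n_caa == 10 and tract.interruptions == []

    def test_single_interruption_keeps_one_tract(self):
        orf = "ATG" + "CCT" * 5 + "CAA" * 4 + "CAG" + "CAA" * 4 + "CCT" * 5 + "TAA"
        tract = find_polyq(orf)
        assert tract.length == 9
        assert tract.interruptions == [(5, "CAG")]

    def test_non_family_codon_splits_run(self):
        # TTT differs from CAA at all three bases: two runs of 3, both < 5
        orf = "ATG" + "CAA" * 3 + "TTT" + "CAA" * 3 + "TAA"
        assert find_polyq(orf).is_empty

    def test_generator_tract_recovered_with_interruptions(self):
        spec = GeneSpec(seed=9, polyq_length=20,
                        polyq_interruptions=((5, "GAA"), (12, "CTA")))
        t = build_gamma_gene(spec)
        tract = find_polyq(t.dna)
        assert (tract.start_codon, tract.end_codon) == t.polyq
        assert tract.interruptions == [(5, "GAA"), (12, "CTA")]


class TestCysteines:
    def test_canonical_skeleton(self, default_gene):
        seg = segment_domains(default_gene.protein, orf_dna=default_gene.dna)
        prof = cysteine_profile(default_gene.protein, seg)
        assert prof.total == 8 and prof.canonical
        assert prof.per_domain["III"] == 6 and prof.per_domain["V"] == 2
        assert prof.positions == default_gene.cysteine_positions

    def test_extra_cysteine_in_domain_ii(self):
        t = build_gamma_gene(GeneSpec(
            seed=9, cysteine_layout={"II": 1, "III": 6, "V": 2},
            embedded_epitopes=(("QQPQQPFPQ", 2),)))
        seg = segment_domains(t.protein, orf_dna=t.dna)
        prof = cysteine_profile(t.protein, seg)
        assert prof.total == 9 and not prof.canonical
        assert prof.per_domain["II"] == 1
        assert len(prof.extra_positions) == 1
        ii = seg["II"]
        assert ii[0] <= prof.extra_positions[0] <= ii[1]

    def test_cysteine_free_protein(self):
        seg = segment_domains("M" + "PQQPFPQ" * 4 + "P" + "Q" * 10 + "PLS")
        prof = cysteine_profile("M" + "PQQPFPQ" * 4 + "P" + "Q" * 10 + "PLS", seg)
        assert prof.total == 0 and not prof.canonical


class TestPhysChem:
    def test_glycine_dipeptide_mass(self):
        # 2 × 57.052 + 18.02 from the standard average residue-mass table
        assert physchem("GG").molecular_weight == pytest.approx(132.12, abs=0.01)

    def test_composition_percentages(self):
        pc = physchem("QQP")
        assert pc.composition["Q"] == pytest.approx(66.7, abs=0.05)
        assert pc.composition["P"] == pytest.approx(33.3, abs=0.05)

    def test_composition_sums_to_100(self, default_gene):
        pc = physchem(default_gene.protein)
        assert sum(pc.composition.values()) == pytest.approx(100.0, abs=0.05)

    def test_undefined_residues_refuse_mw_pi(self):
        pc = physchem(ProteinRecord(id="x", sequence="MK*QP", readthrough=True))
        assert pc.molecular_weight is None and pc.isoelectric_point is None
        assert pc.composition  # still computed over defined residues

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            physchem(ProteinRecord(id="x", sequence="X"))

    @given(st.text(alphabet=AA20, min_size=1, max_size=40),
           st.text(alphabet=AA20, min_size=1, max_size=40))
    def test_mw_additivity(self, a, b):
        water = 18.0153
        combined = physchem(a + b).molecular_weight
        assert combined == pytest.approx(
            physchem(a).molecular_weight + physchem(b).molecular_weight - water,
            abs=0.05)

    @given(st.text(alphabet=AA20, min_size=2, max_size=40))
    def test_pi_monotonicity(self, s):
        pi = physchem(s).isoelectric_point
        assert physchem(s + "K").isoelectric_point >= pi - 0.01
        assert physchem(s + "D").isoelectric_point <= pi + 0.01
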