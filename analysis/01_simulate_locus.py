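#!/usr/bin/env python
"""Build the synthetic study locus: nine γ-gliadin-like genes, of which two
are pseudogenized by the family's C→T glutamine-codon mechanism.

Writes results/synthetic/locus.fasta, genes.fasta, truth.gff3 and
gene_specs.json. The locus mirrors the family composition reported for a
tetraploid wheat cultivar: seven functional genes and two pseudogenes.
"""

from pathlib import Path

from gliakit import GeneSpec, build_gamma_gene, build_locus, pseudogenize
from gliakit.io import (write_fasta, write_gene_spec_json,
                        write_locus_truth_gff3)
from gliakit.synthetic import glutamine_codons

SEED = 2021
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = []
    for i in range(9):
        t = build_gamma_gene(GeneSpec(
            seed=SEED + i, embedded_epitopes=(("QQPQQPFPQ", 1 + i % 3),)))
        if i in (3, 7):      # the two pseudogene members
            ci = next(c for c in glutamine_codons(t) if c >= 27)
            t = pseudogenize(t, ci)
        genes.append(t)
    locus = build_locus(genes, seed=SEED)
    write_fasta({"synthetic_locus": locus.sequence}, OUT / "locus.fasta")
    write_fasta({f"gene{i + 1}": g.dna for i, g in enumerate(genes)},
                OUT / "genes.fasta")
    write_locus_truth_gff3(locus, "synthetic_locus", OUT / "truth.gff3")
    write_gene_spec_json(genes, OUT / "gene_specs.json")
    n_pseudo = sum(g.is_pseudogene for g in genes)
    print(f"wrote {len(locus.sequence)} bp locus with {len(genes)} genes "
          f"({len(genes) - n_pseudo} functional, {n_pseudo} pseudogenes) "
          f"to {OUT}")
    for g in locus.genes:
        note = ""
        if g.truth.pseudogene_stop:
            bp, stop, anc = g.truth.pseudogene_stop
            note = f"  [{stop} at bp {bp}, ancestral {anc}]"
        print(f"  gene{g.index + 1}: {g.start}-{g.end} ({g.strand}){note}")


if __name__ == "__main__":
    main()
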