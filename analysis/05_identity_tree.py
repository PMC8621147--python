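#!/usr/bin/env python
"""Pairwise identity matrix and neighbor-joining tree of the gene family.

All-pairs Needleman–Wunsch global alignments of the functional genes'
coding and protein sequences give the dual-triangle identity matrix
(nucleotide above the diagonal, amino acid below); the NJ tree is built
on 100 − AA identity. Writes results/identity_matrix.tsv and
results/tree.nwk.
"""

from pathlib import Path

from gliakit import identity_matrix, translate_orf, tree_from_identity
from gliakit.annotate import annotate_genomic
from gliakit.io import read_fasta

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    seqs = read_fasta(ROOT / "synthetic" / "locus.fasta")
    nt, aa = {}, {}
    for seqid, seq in seqs.items():
        for m in annotate_genomic(seq, id_prefix=seqid):
            if m.status != "full_length":
                continue
            nt[m.id] = m.orf.sequence
            aa[m.id] = translate_orf(m.orf).sequence
    im = identity_matrix(nt, aa)
    dual = im.dual_triangle()
    with open(ROOT / "identity_matrix.tsv", "w") as fh:
        fh.write("# upper triangle = NT identity %, lower = AA identity %\n")
        dual.to_csv(fh, sep="\t", float_format="%.1f")
    tree = tree_from_identity(im)
    (ROOT / "tree.nwk").write_text(tree.to_newick() + "\n")
    print(dual.to_string(float_format=lambda v: f"{v:.1f}"))
    print("\nNJ tree:", tree.to_newick())


if __name__ == "__main__":
    main()
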