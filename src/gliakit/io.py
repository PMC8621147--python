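"""Readers and writers for the pipeline's standard formats.

FASTA goes through Biopython; GFF3 and the tabular reports are plain
writers with fixed column orders so re-runs are byte-identical. All
coordinates written are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .annotate import GeneModel
from .synthetic import LocusTruth, SyntheticTruth

GFF_HEADER = "##gff-version 3"


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _gff_line(seqid: str, type_: str, start: int, end: int, strand: str,
              attrs: dict[str, str], source: str = "gliakit") -> str:
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{seqid}\t{source}\t{type_}\t{start}\t{end}\t.\t{strand}\t.\t{attr_s}"


def write_locus_truth_gff3(locus: LocusTruth, seqid: str, path: str | Path) -> None:
    """Ground-truth annotation of a synthetic locus (gene + sub-features).

    Protein-coordinate features (domains, epitopes, cysteines) are
    projected onto the genome only for forward-strand genes; on the minus
    strand they are written with the gene's own coordinates in a
    ``protein_start`` attribute instead.
    """
    lines = [GFF_HEADER]
    for g in locus.genes:
        gid = f"gene{g.index + 1}"
        attrs = {"ID": gid, "status": "pseudogene" if g.truth.is_pseudogene
                 else "full_length"}
        if g.truth.pseudogene_stop:
            bp, stop, anc = g.truth.pseudogene_stop
            attrs["Note"] = f"{stop} at bp {bp} (ancestral {anc})"
        lines.append(_gff_line(seqid, "gene", g.start, g.end, g.strand, attrs))
        for name, iv in g.truth.domain_boundaries.items():
            if iv is None:
                continue
            feat = "signal_peptide" if name == "S" else f"domain_{name}"
            if g.strand == "+":
                gs = g.start + 3 * (iv[0] - 1)
                ge = g.start + 3 * iv[1] - 1
                lines.append(_gff_line(seqid, feat, gs, ge, "+",
                                       {"Parent": gid}))
            else:
                lines.append(_gff_line(seqid, feat, g.start, g.end, "-",
                                       {"Parent": gid,
                                        "protein_start": str(iv[0]),
                                        "protein_end": str(iv[1])}))
        for ename, p in g.truth.epitope_positions:
            if g.strand == "+":
                gs = g.start + 3 * (p - 1)
                lines.append(_gff_line(seqid, "epitope", gs, gs + 26, "+",
                                       {"Parent": gid, "Name": ename}))
        if g.truth.pseudogene_stop:
            bp = g.truth.pseudogene_stop[0]
            if g.strand == "+":
                gs = g.start + bp - 1
                lines.append(_gff_line(seqid, "premature_stop", gs, gs + 2, "+",
                                       {"Parent": gid}))
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_spec_json(truths: list[SyntheticTruth], path: str | Path) -> None:
    payload = []
    for t in truths:
        spec = t.spec
        payload.append({
            "n_heptapeptide_repeats": spec.n_heptapeptide_repeats,
            "embedded_epitopes": [list(e) for e in spec.embedded_epitopes],
            "polyq_length": spec.polyq_length,
            "polyq_interruptions": [list(i) for i in spec.polyq_interruptions],
            "cysteine_layout": spec.cysteine_layout,
            "signal_length": spec.signal_length,
            "seed": spec.seed,
            "pseudogene_stop": t.pseudogene_stop,
            "truncated_at": t.truncated_at,
        })
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_annotation_gff3(models: list[GeneModel], seqid: str,
                          path: str | Path) -> None:
    lines = [GFF_HEADER]
    for m in models:
        attrs = {"ID": m.id, "status": m.status, "family_class": m.family_class}
        if m.note:
            attrs["Note"] = m.note
        lines.append(_gff_line(seqid, "gene", m.orf.start, m.orf.end,
                               m.orf.strand, attrs))
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation_tsv(models: list[GeneModel], path: str | Path) -> None:
    """Family-census table: one row per ORF with status and stop notes."""
    lines = [f"# gliakit {__version__}",
             "id\tstart\tstop\tstrand\tsize_bp\tfamily_class\tgene_pseudogene\tnote"]
    for m in models:
        lines.append("\t".join([
            m.id, str(m.orf.start), str(m.orf.end), m.orf.strand,
            str(m.orf.length_bp), m.family_class,
            "pseudogene" if m.status == "pseudogene" else "gene", m.note,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed_map(entries: list[tuple[str, int, int, str]],
                  path: str | Path) -> None:
    """BED-like positional map on protein coordinates (0-based half-open)."""
    lines = [f"{pid}\t{start - 1}\t{end}\t{name}"
             for pid, start, end, name in entries]
    Path(path).write_text("\n".join(lines) + "\n")
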