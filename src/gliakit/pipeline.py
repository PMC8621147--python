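"""End-to-end orchestration: genomic FASTA → annotation, features,
epitopes, identity matrix and NJ tree, with a JSON run manifest.

Pseudogenes are excluded from the protein-level reports by default (the
family's published characterization covers the full-length genes); with
``readthrough`` their deduced products — internal stops removed by
conceptual readthrough — are carried into the comparative stage the way
pseudogene sequences are usually displayed in family trees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (DEFAULT_MIN_ORF_BP, GeneModel, OrfRecord, ProteinRecord,
                       annotate_genomic, classify_orf, translate_orf)
from .compare import AlignParams, identity_matrix, tree_from_identity
from .epitopes import load_epitope_db, scan_epitopes, epitope_summary
from .features import (SegmentationConfig, cysteine_profile, physchem,
                       segment_domains)
from .io import (read_fasta, write_annotation_gff3, write_annotation_tsv,
                 write_bed_map)

logger = logging.getLogger(__name__)


#: Family assignment by motif content: first rule whose motif occurs at
#: least min_count times in the (readthrough-stripped) protein wins.
DEFAULT_FAMILY_RULES: tuple[tuple[str, int, str], ...] = (
    ("PQQPFPQ", 2, "gamma_gliadin"),
)


def _family_class(model: GeneModel,
                  rules: tuple[tuple[str, int, str], ...] = DEFAULT_FAMILY_RULES
                  ) -> str:
    """Motif-content family call (homology search is deliberately not used)."""
    try:
        prot = translate_orf(model.orf, readthrough=True).sequence.replace("*", "")
    except Exception:
        return model.family_class
    for motif, min_count, label in rules:
        if sum(1 for i in range(len(prot) - len(motif) + 1)
               if prot.startswith(motif, i)) >= min_count:
            return label
    return "other"


@dataclass
class PipelineConfig:
    input_fasta: str
    output_dir: str
    input_kind: str = "genomic"          # "genomic" | "orf"
    min_orf_bp: int = DEFAULT_MIN_ORF_BP
    strands: str = "both"
    max_internal_stops: int = 2
    expected_len_range: tuple[int, int] = (450, 1100)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    epitope_db: str | None = None
    align: AlignParams = field(default_factory=AlignParams)
    identity_convention: str = "columns"
    readthrough: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.input_fasta).exists():
            raise FileNotFoundError(f"input FASTA not found: {self.input_fasta}")
        if self.epitope_db is not None and not Path(self.epitope_db).exists():
            raise FileNotFoundError(f"epitope database not found: {self.epitope_db}")
        if self.input_kind not in ("genomic", "orf"):
            raise ValueError("input_kind must be genomic|orf")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = read_fasta(config.input_fasta)

    # --- stage 1: gene annotation -----------------------------------------
    models: list[GeneModel] = []
    if config.input_kind == "genomic":
        for seqid, seq in seqs.items():
            found = annotate_genomic(
                seq, min_len_bp=config.min_orf_bp, strands=config.strands,
                expected_len_range=config.expected_len_range,
                max_internal_stops=config.max_internal_stops,
                id_prefix=seqid)
            write_annotation_gff3(found, seqid, out / f"{seqid}.annotation.gff3")
            models.extend(found)
    else:
        for seqid, seq in seqs.items():
            models.append(classify_orf(
                OrfRecord.from_sequence(seqid, seq),
                expected_len_range=config.expected_len_range))

    full_length = [m for m in models if m.status == "full_length"]
    pseudo = [m for m in models if m.status == "pseudogene"]
    logger.info("annotated %d full-length genes, %d pseudogenes",
                len(full_length), len(pseudo))

    # --- stage 2: translation ---------------------------------------------
    proteins: list[tuple[GeneModel, ProteinRecord]] = [
        (m, translate_orf(m.orf)) for m in full_length]
    for m in models:
        m.family_class = _family_class(m)
    write_annotation_tsv(models, out / "annotation.tsv")
    readthrough_proteins: list[tuple[GeneModel, ProteinRecord]] = []
    if config.readthrough:
        for m in pseudo:
            if m.orf.has_terminal_stop:
                rt = translate_orf(m.orf, readthrough=True)
                readthrough_proteins.append(
                    (m, ProteinRecord(id=m.id, sequence=rt.sequence.replace("*", ""),
                                      source_gene=m.id)))

    # --- stage 3: protein features ----------------------------------------
    feature_rows = []
    segs = {}
    for m, prot in proteins:
        seg = segment_domains(prot, config.segmentation, orf_dna=m.orf.sequence)
        segs[m.id] = seg
        cys = cysteine_profile(prot, seg)
        pc = physchem(prot)
        feature_rows.append({
            "protein": m.id,
            "length_aa": len(prot),
            "n_cysteines": cys.total,
            "predicted_mw_da": None if pc.molecular_weight is None
            else round(pc.molecular_weight),
            "predicted_pi": pc.isoelectric_point,
            "glutamine_pct": round(pc.glutamine_pct, 1),
            "proline_pct": round(pc.proline_pct, 1),
            "essential_aa_pct": round(pc.essential_pct, 1),
            "canonical_cys_skeleton": cys.canonical,
        })
    features_df = pd.DataFrame(feature_rows)
    with open(out / "protein_features.tsv", "w") as fh:
        fh.write(f"# gliakit {__version__}\n")
        features_df.to_csv(fh, sep="\t", index=False)
    (out / "protein_features.json").write_text(
        json.dumps(feature_rows, indent=2) + "\n")
    # domain annotations on protein coordinates
    gff = ["##gff-version 3"]
    for m, prot in proteins:
        for name, iv in segs[m.id].intervals.items():
            if iv is None:
                continue
            feat = "signal_peptide" if name == "S" else f"domain_{name}"
            gff.append(f"{m.id}\tgliakit\t{feat}\t{iv[0]}\t{iv[1]}"
                       f"\t.\t+\t.\tParent={m.id}")
    (out / "protein_domains.gff3").write_text("\n".join(gff) + "\n")

    # --- stage 4: epitopes -------------------------------------------------
    db = load_epitope_db(config.epitope_db)
    counts = {}
    bed_entries = []
    for m, prot in proteins:
        hits = scan_epitopes(prot, db)
        summary = epitope_summary(hits, segs[m.id], prot, db=db)
        counts[m.id] = summary.counts | {
            "B-cell-7mer": summary.bcell_7mer_count,
            "clustering_fraction": round(summary.clustering_fraction, 3),
        }
        bed_entries.extend((prot.id, s, e, n) for s, e, n in summary.positional_map)
    counts_df = pd.DataFrame(counts).astype(object)
    counts_df.index.name = "epitope"
    with open(out / "epitope_counts.tsv", "w") as fh:
        fh.write(f"# gliakit {__version__}\n")
        counts_df.to_csv(fh, sep="\t")
    write_bed_map(bed_entries, out / "epitope_map.bed")

    # --- stage 5: identity matrix + tree -----------------------------------
    comparative_set = proteins + readthrough_proteins
    manifest_extra = {}
    if len(comparative_set) >= 2:
        nt_seqs = {m.id: m.orf.sequence for m, _ in comparative_set}
        aa_seqs = {m.id: p.sequence for m, p in comparative_set}
        im = identity_matrix(nt_seqs, aa_seqs, config.align,
                             config.identity_convention)
        with open(out / "identity_matrix.tsv", "w") as fh:
            fh.write(f"# gliakit {__version__}; upper=NT lower=AA "
                     f"({config.identity_convention} convention)\n")
            im.dual_triangle().to_csv(fh, sep="\t", float_format="%.1f")
        tree = tree_from_identity(im)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        manifest_extra["newick"] = tree.to_newick()
    else:
        logger.info("fewer than 2 comparable proteins; skipping identity/tree stage")

    manifest = {
        "tool": "gliakit",
        "version": __version__,
        "seed": config.seed,
        "settings": {
            "input_fasta": config.input_fasta,
            "input_kind": config.input_kind,
            "min_orf_bp": config.min_orf_bp,
            "strands": config.strands,
            "expected_len_range": list(config.expected_len_range),
            "segmentation": asdict(config.segmentation),
            "align": asdict(config.align),
            "identity_convention": config.identity_convention,
            "readthrough": config.readthrough,
            "epitope_db": config.epitope_db or "bundled",
        },
        "n_full_length": len(full_length),
        "n_pseudogenes": len(pseudo),
        **manifest_extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
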