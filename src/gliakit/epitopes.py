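"""Exact-match scanning of gliadin proteins for celiac-disease epitopes.

CD epitopes are 9-residue T-cell cores named by HLA restriction
(DQ2.5/DQ8/DQ8.5) and source protein. Matching is exact on the native
(glutamine) sequence — deamidation annotations travel as metadata only —
and overlapping occurrences are counted by default, since published copy
numbers state no convention and overlapping counting is the conservative
superset. The bundled database holds the ten γ/ω-gliadin entries relevant
to the family (several share a 9-mer: QQPQQPFPQ, QQPQQPYPQ and PQQSFPQQQ
each appear under two names, which must therefore always report identical
hits). The B-cell heptamer QPQQPFP is counted alongside with the same
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .annotate import ProteinRecord
from .features import DomainSegmentation

logger = logging.getLogger(__name__)

BCELL_7MER = "QPQQPFP"
EPITOPE_LENGTH = 9
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class EpitopeRecord:
    name: str
    hla: str
    sequence: str
    deamidation_mask: str = ""


@dataclass(frozen=True)
class EpitopeHit:
    epitope: str
    protein_id: str
    start: int                       # 1-based


@dataclass
class EpitopeSummary:
    protein_id: str
    counts: dict[str, int]
    total_hits: int
    clustering_fraction: float
    clustering_defined: bool
    bcell_7mer_count: int
    positional_map: list[tuple[int, int, str]] = field(default_factory=list)


def bundled_db_path() -> Path:
    return Path(resources.files("gliakit").joinpath("data/cd_epitopes.tsv"))


def load_epitope_db(path: str | Path | None = None) -> list[EpitopeRecord]:
    """Load an epitope database from TSV (name, hla, sequence[, mask]).

    Rows with a non-9-mer or illegal residues are rejected with their line
    number; duplicate names are rejected, duplicate sequences under
    different names are expected and allowed.
    """
    path = bundled_db_path() if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(f"epitope database not found: {path}")
    records: list[EpitopeRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for col in ("name", "hla", "sequence"):
            if col not in cols:
                raise ValueError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[cols["name"]].strip()
            hla = fields[cols["hla"]].strip()
            seq = fields[cols["sequence"]].strip().upper()
            mask = ""
            if "deamidation_mask" in cols and len(fields) > cols["deamidation_mask"]:
                mask = fields[cols["deamidation_mask"]].strip()
            if len(seq) != EPITOPE_LENGTH:
                raise ValueError(
                    f"{path}:{lineno}: epitope {name!r} has length {len(seq)}, "
                    f"expected {EPITOPE_LENGTH}"
                )
            if set(seq) - _VALID_AA:
                raise ValueError(
                    f"{path}:{lineno}: epitope {name!r} contains illegal residues "
                    f"{sorted(set(seq) - _VALID_AA)}"
                )
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate epitope name {name!r}")
            seen.add(name)
            records.append(EpitopeRecord(name, hla, seq, mask))
    return records


def scan_epitopes(protein: ProteinRecord | str, db: list[EpitopeRecord],
                  mode: str = "overlapping") -> list[EpitopeHit]:
    """Every exact-match start position of every epitope in the protein."""
    if isinstance(protein, str):
        protein = ProteinRecord(id="protein", sequence=protein)
    if mode not in ("overlapping", "non_overlapping"):
        raise ValueError("mode must be overlapping|non_overlapping")
    seq = protein.sequence.upper()
    hits: list[EpitopeHit] = []
    for rec in db:
        i = 0
        while True:
            j = seq.find(rec.sequence, i)
            if j == -1:
                break
            hits.append(EpitopeHit(rec.name, protein.id, j + 1))
            i = j + (len(rec.sequence) if mode == "non_overlapping" else 1)
    hits.sort(key=lambda h: (h.start, h.epitope))
    return hits


def epitope_summary(hits: list[EpitopeHit], segmentation: DomainSegmentation,
                    protein: ProteinRecord | str,
                    db: list[EpitopeRecord] | None = None,
                    mode: str = "overlapping") -> EpitopeSummary:
    """Aggregate hits into copy counts, positional clustering and a map.

    The clustering fraction is the share of hits whose start lies inside
    domain II; with no hits it is reported as 0 with
    ``clustering_defined=False``.
    """
    if isinstance(protein, str):
        protein = ProteinRecord(id="protein", sequence=protein)
    n = len(protein.sequence)
    lengths = {r.name: len(r.sequence) for r in db} if db else {}
    counts: dict[str, int] = {r.name: 0 for r in db} if db else {}
    pos_map: list[tuple[int, int, str]] = []
    ii = segmentation["II"]
    in_ii = 0
    for h in hits:
        if h.protein_id != protein.id:
            raise ValueError(f"hit for {h.protein_id!r} does not belong to "
                             f"protein {protein.id!r}")
        length = lengths.get(h.epitope, EPITOPE_LENGTH)
        if not 1 <= h.start <= n - length + 1:
            raise ValueError(f"hit at {h.start} outside protein of length {n}")
        counts[h.epitope] = counts.get(h.epitope, 0) + 1
        pos_map.append((h.start, h.start + length - 1, h.epitope))
        if ii and ii[0] <= h.start <= ii[1]:
            in_ii += 1
    total = len(hits)
    defined = total > 0
    fraction = in_ii / total if defined else 0.0
    b_count, b_starts = _count_7mer(protein.sequence, mode)
    pos_map.extend((s, s + len(BCELL_7MER) - 1, "B-cell-7mer") for s in b_starts)
    pos_map.sort()
    return EpitopeSummary(
        protein_id=protein.id, counts=counts, total_hits=total,
        clustering_fraction=fraction, clustering_defined=defined,
        bcell_7mer_count=b_count, positional_map=pos_map,
    )


def _count_7mer(seq: str, mode: str) -> tuple[int, list[int]]:
    starts: list[int] = []
    i = 0
    while True:
        j = seq.find(BCELL_7MER, i)
        if j == -1:
            break
        starts.append(j + 1)
        i = j + (len(BCELL_7MER) if mode == "non_overlapping" else 1)
    return len(starts), starts
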