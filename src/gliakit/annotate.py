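"""Intronless ORF discovery, gene/pseudogene classification and translation.

γ-gliadin, δ-gliadin and avenin-like genes at the wheat Gli-1 loci are
intronless, so gene discovery reduces to finding maximal ATG→stop open
reading frames on either strand. Pseudogenes in these families carry a
premature TAA/TAG stop created by a C→T transition in a glutamine CAA/CAG
codon (or are truncated); classification therefore scans the internal
codons of each ORF and infers the ancestral glutamine codon from the stop
observed. Stop positions are reported as the 1-based position of the stop
codon's first base counted from the ATG's first base, the convention under
which every stop position in the family census (115, 163, 196, 247, 277,
169, 79) is ≡ 1 (mod 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .synthetic import STOP_CODONS, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MIN_ORF_BP = 450

_ANCESTRAL = {"TAA": "CAA", "TAG": "CAG", "TGA": "unknown"}


@dataclass
class OrfRecord:
    """One open reading frame, reported on the forward genomic axis.

    ``sequence`` is the sense-strand ORF (ATG…stop) regardless of strand;
    ``start``/``end`` are 1-based inclusive on the forward axis.
    """

    id: str
    start: int
    end: int
    strand: str
    sequence: str
    has_terminal_stop: bool = True
    n_internal_stops: int = 0

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, id: str, sequence: str) -> "OrfRecord":
        """Wrap a standalone ORF sequence (e.g. one FASTA record)."""
        seq = sequence.upper()
        if not seq.startswith("ATG"):
            raise ValueError(f"{id}: ORF must begin with ATG")
        has_stop = len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS
        n_internal = sum(
            1 for i in range(3, (len(seq) // 3 - 1) * 3, 3)
            if seq[i:i + 3] in STOP_CODONS
        )
        return cls(id=id, start=1, end=len(seq), strand="+", sequence=seq,
                   has_terminal_stop=has_stop, n_internal_stops=n_internal)


@dataclass
class GeneModel:
    """Table-1-style annotation row for one ORF."""

    id: str
    status: str                      # "full_length" | "pseudogene"
    premature_stops: list[tuple[int, str, str]] = field(default_factory=list)
    truncated: bool = False
    family_class: str = "other"
    orf: OrfRecord | None = None

    @property
    def note(self) -> str:
        """Human-readable annotation note, e.g. ``TAG at bp 115``."""
        parts = [f"{stop} at bp {bp}" for bp, stop, _ in self.premature_stops]
        if self.truncated and self.orf is not None:
            parts.append(f"Truncated at bp {self.orf.length_bp}")
        return "; ".join(parts)


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    source_gene: str | None = None
    readthrough: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty protein sequence")
        if "*" in self.sequence and not self.readthrough:
            raise ValueError(
                "internal stop markers are only allowed in readthrough translations"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _scan_strand(seq: str, min_len_bp: int, max_internal_stops: int
                 ) -> list[tuple[int, int, int]]:
    """Yield (start0, end0_exclusive, n_internal_stops) on one strand.

    Maximal ATG-to-stop stretches; nested ORFs sharing a stop report only
    the 5'-most ATG. With ``max_internal_stops`` > 0 an ORF shorter than
    ``min_len_bp`` is extended through up to that many premature stops
    until it reaches the threshold — the mechanism by which pseudogene
    footprints (premature stop well before the minimum gene length) are
    recovered whole.
    """
    n = len(seq)
    results = []
    for frame in range(3):
        consumed = frame
        while True:
            atg = seq.find("ATG", consumed)
            while atg != -1 and (atg - frame) % 3 != 0:
                atg = seq.find("ATG", atg + 1)
            if atg == -1:
                break
            stops = []
            j = atg
            while j + 3 <= n:
                if seq[j:j + 3] in STOP_CODONS:
                    stops.append(j)
                    if len(stops) > max_internal_stops + 1:
                        break
                j += 3
            recorded = False
            for k, s in enumerate(stops[:max_internal_stops + 1]):
                length = s + 3 - atg
                if length >= min_len_bp:
                    results.append((atg, s + 3, k))
                    consumed = s + 3
                    recorded = True
                    break
            if not recorded:
                consumed = (stops[0] + 3) if stops else n
            if consumed >= n:
                break
    return results


def find_orfs(genomic: str, min_len_bp: int = DEFAULT_MIN_ORF_BP,
              strands: str = "both", max_internal_stops: int = 0,
              id_prefix: str = "orf") -> list[OrfRecord]:
    """Find intronless ORFs ≥ ``min_len_bp`` on the requested strands.

    Coordinates are 1-based inclusive on the forward axis; minus-strand
    ORFs carry their sense-strand sequence. ORFs containing N are skipped
    with a warning; characters outside {A,C,G,T,N} are rejected.
    """
    if min_len_bp < 6 or min_len_bp % 3:
        raise ValueError("min_len_bp must be >= 6 and divisible by 3")
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    seq = genomic.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(
            f"non-nucleotide characters in input: {sorted(set(seq) - set('ACGTN'))}"
        )
    n = len(seq)
    hits: list[OrfRecord] = []
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for strand in strand_list:
        s = seq if strand == "+" else reverse_complement(seq)
        for start0, end0, k in _scan_strand(s, min_len_bp, max_internal_stops):
            orf_seq = s[start0:end0]
            if "N" in orf_seq:
                logger.warning("skipping ORF with ambiguous bases at %d-%d (%s)",
                               start0 + 1, end0, strand)
                continue
            if strand == "+":
                g_start, g_end = start0 + 1, end0
            else:
                g_start, g_end = n - end0 + 1, n - start0
            hits.append(OrfRecord(
                id="", start=g_start, end=g_end, strand=strand,
                sequence=orf_seq, has_terminal_stop=True, n_internal_stops=k,
            ))
    hits.sort(key=lambda o: (o.start, o.end, o.strand))
    for i, o in enumerate(hits, start=1):
        o.id = f"{id_prefix}_{i:03d}"
    return hits


def select_gene_candidates(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Resolve overlapping ORF candidates into a non-overlapping gene set.

    When pseudogene recovery is on (``max_internal_stops`` > 0), an ATG in
    flanking sequence can ride through its own local stops into a real
    gene body, producing a shadow candidate that contains or overlaps the
    true ORF in another frame or strand. Manual annotation resolves these
    by parsimony; here candidates with fewer internal stops win, then the
    longer one, and the survivors must not overlap on the genomic axis.
    """
    order = sorted(orfs, key=lambda o: (o.n_internal_stops, -o.length_bp,
                                        o.start, o.strand))
    chosen: list[OrfRecord] = []
    for o in order:
        if all(o.end < c.start or o.start > c.end for c in chosen):
            chosen.append(o)
    return sorted(chosen, key=lambda o: (o.start, o.end))


def classify_orf(orf: OrfRecord,
                 expected_len_range: tuple[int, int] | None = None,
                 family_class: str = "other") -> GeneModel:
    """Classify an ORF as a full-length gene or a pseudogene.

    Internal codons (2 … n−1) are scanned for in-frame stops; each is
    recorded as (bp of first base from ATG, stop codon, inferred ancestral
    codon) where TAA→CAA and TAG→CAG per the C→T glutamine-codon
    mechanism, and TGA→"unknown". An ORF with no terminal stop is a
    truncated pseudogene; ``expected_len_range`` only adds a length
    warning for full-length calls outside the family's size range.
    """
    seq = orf.sequence
    n_codons = len(seq) // 3
    last = n_codons - 1 if orf.has_terminal_stop else n_codons
    stops: list[tuple[int, str, str]] = []
    for ci in range(1, last):
        codon = seq[3 * ci:3 * ci + 3]
        if codon in STOP_CODONS:
            stops.append((3 * ci + 1, codon, _ANCESTRAL[codon]))
    truncated = not orf.has_terminal_stop
    status = "pseudogene" if (stops or truncated) else "full_length"
    if (status == "full_length" and expected_len_range is not None
            and not expected_len_range[0] <= orf.length_bp <= expected_len_range[1]):
        logger.warning("%s: full-length ORF of %d bp outside expected range %s",
                       orf.id, orf.length_bp, expected_len_range)
    return GeneModel(id=orf.id, status=status, premature_stops=stops,
                     truncated=truncated, family_class=family_class, orf=orf)


def translate_orf(orf: OrfRecord, readthrough: bool = False) -> ProteinRecord:
    """Translate with the standard code, dropping the terminal stop.

    Without ``readthrough`` translation ends at the first stop codon; with
    it, internal stops are rendered as ``*`` and translation continues to
    the terminal stop (the readthrough display used for pseudogene
    products). A codon containing N translates to X with a warning.
    """
    seq = orf.sequence
    trailing = len(seq) % 3
    if trailing:
        logger.warning("%s: dropping %d-base trailing partial codon", orf.id, trailing)
        seq = seq[:-trailing]
    aa = str(Seq(seq).translate())
    if "X" in aa:
        logger.warning("%s: ambiguous codons translated as X", orf.id)
    if aa.endswith("*"):
        aa = aa[:-1]
    if not readthrough:
        aa = aa.split("*", 1)[0]
        return ProteinRecord(id=orf.id, sequence=aa, source_gene=orf.id)
    return ProteinRecord(id=orf.id, sequence=aa, source_gene=orf.id,
                         readthrough=True)


def annotate_genomic(genomic: str, min_len_bp: int = DEFAULT_MIN_ORF_BP,
                     strands: str = "both",
                     expected_len_range: tuple[int, int] | None = (450, 1100),
                     max_internal_stops: int = 2,
                     id_prefix: str = "gene") -> list[GeneModel]:
    """Discover and classify every gene-sized ORF in a genomic sequence.

    Overlapping candidates are resolved by :func:`select_gene_candidates`
    before classification, and ids are reassigned in genomic order.
    """
    orfs = find_orfs(genomic, min_len_bp=min_len_bp, strands=strands,
                     max_internal_stops=max_internal_stops, id_prefix=id_prefix)
    orfs = select_gene_candidates(orfs)
    for i, o in enumerate(orfs, start=1):
        o.id = f"{id_prefix}_{i:03d}"
    return [classify_orf(o, expected_len_range=expected_len_range) for o in orfs]
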