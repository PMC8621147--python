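"""Domain segmentation and protein-level characterization of γ-gliadins.

The six-part architecture (signal peptide S, unique N-terminal domain I,
repetitive domain II, cysteine-rich domain III, poly-glutamine domain IV,
C-terminal domain V) is recovered from sequence alone: domain II as the
maximal stretch tiled by PQQPFPQ-family heptapeptide units, domain IV as
the poly-Q tract (detected on the ORF codons when available, or projected
onto the protein), and I/III/V as the regions in between. On top of the
segmentation the module computes the family's descriptive statistics:
heptapeptide repeat counts, the cysteine skeleton (canonically six in
domain III and two in domain V, eight in total), amino-acid composition,
and ProtParam-style average molecular weight and isoelectric point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .annotate import ProteinRecord
from .synthetic import (HEPTAD_UNIT, POLYQ_INTERRUPTION_CODONS,
                        heptad_tiling_window, protein_polyq_window)

logger = logging.getLogger(__name__)

Interval = tuple[int, int]          # 1-based inclusive

#: Default essential-amino-acid set (histidine included).
ESSENTIAL_AA = frozenset("HIKLMFTWV")


@dataclass(frozen=True)
class SegmentationConfig:
    signal_length: int = 19
    unit: str = HEPTAD_UNIT
    max_unit_mismatch: int = 1
    min_units: int = 2
    max_inter_unit_gap: int = 9      # residues; a 9-mer epitope between units
    polyq_min_len: int = 5
    polyq_min_q_frac: float = 0.6


@dataclass
class DomainSegmentation:
    """1-based inclusive intervals for S, I, II, III, IV, V (None = empty)."""

    intervals: dict[str, Interval | None]
    warnings: list[str] = field(default_factory=list)

    def domain_of(self, position: int) -> str | None:
        for name, iv in self.intervals.items():
            if iv and iv[0] <= position <= iv[1]:
                return name
        return None

    def __getitem__(self, name: str) -> Interval | None:
        return self.intervals[name]


@dataclass
class PolyQTract:
    start_codon: int = 0             # 1-based within the ORF, 0 if empty
    end_codon: int = 0
    n_caa: int = 0
    interruptions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return 0 if not self.start_codon else self.end_codon - self.start_codon + 1

    @property
    def is_empty(self) -> bool:
        return self.start_codon == 0


@dataclass
class CysteineProfile:
    total: int
    positions: list[int]
    per_domain: dict[str, int]
    canonical: bool
    extra_positions: list[int]
    checked_pair_consecutive: bool | None = None


@dataclass
class PhysChem:
    molecular_weight: float | None
    isoelectric_point: float | None
    composition: dict[str, float]
    glutamine_pct: float
    proline_pct: float
    essential_pct: float


def _hamming_le(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def count_repeat_motif(protein: ProteinRecord | str, motif: str = HEPTAD_UNIT,
                       mode: str = "overlapping") -> tuple[int, list[int]]:
    """Exact occurrences of a short repeat motif; 1-based start positions.

    ``overlapping`` reports every start; ``non_overlapping`` tiles greedily
    left to right.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not motif or len(motif) > len(seq):
        raise ValueError("motif must be non-empty and shorter than the protein")
    if mode not in ("overlapping", "non_overlapping"):
        raise ValueError("mode must be overlapping|non_overlapping")
    starts: list[int] = []
    i = 0
    while True:
        j = seq.find(motif, i)
        if j == -1:
            break
        starts.append(j + 1)
        i = j + (len(motif) if mode == "non_overlapping" else 1)
    return len(starts), starts


def find_polyq(orf_dna: str,
               min_len: int = 5, min_caa_frac: float = 0.6) -> PolyQTract:
    """Locate the domain-IV poly-Q tract on the ORF codons.

    The tract is the longest codon run in which every codon is CAA or one
    of its single-base mutants {CAG, GAA, CTA}, with no two consecutive
    non-CAA codons, at least ``min_caa_frac`` CAA, and CAA at both ends;
    runs shorter than ``min_len`` yield an empty tract. Ties go to the
    leftmost run.
    """
    if len(orf_dna) % 3:
        raise ValueError("ORF length must be divisible by 3")
    codons = [orf_dna[i:i + 3] for i in range(0, len(orf_dna), 3)]
    member = [c == "CAA" or c in POLYQ_INTERRUPTION_CODONS for c in codons]
    is_caa = [c == "CAA" for c in codons]
    best: tuple[int, int] | None = None

    i = 0
    n = len(codons)
    while i < n:
        if not member[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and member[j + 1] and not (not is_caa[j] and not is_caa[j + 1]):
            j += 1
        # maximal member-run without two consecutive non-CAA: trim to CAA ends
        a, b = i, j
        while a <= b and not is_caa[a]:
            a += 1
        while b >= a and not is_caa[b]:
            b -= 1
        if a <= b:
            length = b - a + 1
            n_caa = sum(is_caa[a:b + 1])
            if (length >= min_len and n_caa >= math.ceil(min_caa_frac * length)
                    and (best is None or length > best[1] - best[0] + 1)):
                best = (a, b)
        i = j + 1
    if best is None:
        return PolyQTract()
    a, b = best
    return PolyQTract(
        start_codon=a + 1, end_codon=b + 1,
        n_caa=sum(is_caa[a:b + 1]),
        interruptions=[(k - a + 1, codons[k]) for k in range(a, b + 1)
                       if not is_caa[k]],
    )


def _find_polyq_protein(seq: str, min_len: int, min_q_frac: float
                        ) -> Interval | None:
    """Protein-level projection of the poly-Q rule (Q with isolated non-Q)."""
    return protein_polyq_window(seq, min_len, min_q_frac)


def _tile_units(seq: str, cfg: SegmentationConfig) -> Interval | None:
    """Maximal span tiled by heptapeptide-family units with short gaps."""
    return heptad_tiling_window(seq, cfg.unit, cfg.max_unit_mismatch,
                                cfg.min_units, cfg.max_inter_unit_gap)


def segment_domains(protein: ProteinRecord | str,
                    config: SegmentationConfig = SegmentationConfig(),
                    orf_dna: str | None = None) -> DomainSegmentation:
    """Segment a γ-gliadin protein into S, I, II, III, IV, V.

    S is the first ``signal_length`` residues; II the maximal
    heptapeptide-tiled window; IV the poly-Q tract (taken from the ORF
    codons when ``orf_dna`` is given, else projected on the protein);
    I, III, V fill the gaps. Readthrough products (containing ``*``)
    are refused. When neither a repeat window nor a poly-Q tract exists
    only S and I are returned, with a warning recorded on the result.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if "*" in seq:
        raise ValueError("segment the readthrough product only on request: "
                         "translate without readthrough first")
    n = len(seq)
    warnings: list[str] = []
    s_end = min(config.signal_length, n)
    intervals: dict[str, Interval | None] = dict.fromkeys(
        ("S", "I", "II", "III", "IV", "V"))
    intervals["S"] = (1, s_end)

    ii = _tile_units(seq, config)
    if orf_dna is not None:
        tract = find_polyq(orf_dna, config.polyq_min_len, config.polyq_min_q_frac)
        iv = None if tract.is_empty else (tract.start_codon, tract.end_codon)
    else:
        iv = _find_polyq_protein(seq, config.polyq_min_len, config.polyq_min_q_frac)
    if ii is not None and iv is not None and iv[0] <= ii[1]:
        # poly-Q window inside/before the repeat window: search after II
        tail = _find_polyq_protein(seq[ii[1]:], config.polyq_min_len,
                                   config.polyq_min_q_frac)
        iv = (tail[0] + ii[1], tail[1] + ii[1]) if tail else None

    if ii is None and iv is None:
        warnings.append("non-gliadin-like architecture: no heptapeptide "
                        "window and no poly-Q tract; only S and I assigned")
        if s_end < n:
            intervals["I"] = (s_end + 1, n)
        return DomainSegmentation(intervals, warnings)

    intervals["II"] = ii
    intervals["IV"] = iv
    if ii is not None:
        if ii[0] > s_end + 1:
            intervals["I"] = (s_end + 1, ii[0] - 1)
        after_ii = ii[1] + 1
    else:
        warnings.append("no heptapeptide repeat window; domain II empty")
        after_ii = s_end + 1
        if iv is not None and iv[0] > after_ii:
            intervals["I"] = (after_ii, iv[0] - 1)
            after_ii = iv[0]
    if iv is not None:
        if iv[0] > after_ii:
            intervals["III"] = (after_ii, iv[0] - 1)
        if iv[1] < n:
            intervals["V"] = (iv[1] + 1, n)
    else:
        warnings.append("no poly-Q tract; domains III and V merged after II")
        if after_ii <= n:
            intervals["III"] = (after_ii, n)
    return DomainSegmentation(intervals, warnings)


def cysteine_profile(protein: ProteinRecord | str,
                     segmentation: DomainSegmentation,
                     check_pair: tuple[int, int] = (4, 6)) -> CysteineProfile:
    """Cysteine skeleton of a segmented γ-gliadin.

    Canonical means exactly eight cysteines with six in domain III and two
    in domain V. ``check_pair`` asks whether the i-th and j-th domain-III
    cysteines sit in consecutive positions (reported, not part of the
    canonical call).
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    positions = [i + 1 for i, r in enumerate(seq) if r == "C"]
    per_domain = dict.fromkeys(("S", "I", "II", "III", "IV", "V"), 0)
    outside = 0
    for p in positions:
        d = segmentation.domain_of(p)
        if d is None:
            outside += 1
        else:
            per_domain[d] += 1
    if outside:
        per_domain["outside"] = outside
    canonical = (len(positions) == 8
                 and per_domain.get("III", 0) == 6 and per_domain.get("V", 0) == 2)
    iii = segmentation["III"]
    extra = [p for p in positions
             if segmentation.domain_of(p) not in ("III", "V")]
    pair_consecutive = None
    if iii:
        in_iii = [p for p in positions if iii[0] <= p <= iii[1]]
        i, j = check_pair
        if len(in_iii) >= max(i, j):
            pair_consecutive = abs(in_iii[j - 1] - in_iii[i - 1]) == 1
    return CysteineProfile(total=len(positions), positions=positions,
                           per_domain=per_domain, canonical=canonical,
                           extra_positions=extra,
                           checked_pair_consecutive=pair_consecutive)


def physchem(protein: ProteinRecord | str,
             essential: frozenset[str] = ESSENTIAL_AA) -> PhysChem:
    """Average MW, theoretical pI and residue composition.

    MW is the sum of average residue masses plus one water; pI is the
    Henderson–Hasselbalch net-charge zero solved with the
    Bjellqvist/ProtParam pK set (the method behind the family's published
    values), reported to 2 decimals. Sequences containing ``*`` or ``X``
    get composition over the defined residues only, with MW/pI refused
    (None).
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not seq:
        raise ValueError("empty sequence")
    defined = [r for r in seq if r not in "*X"]
    if not defined:
        raise ValueError("no defined residues")
    n = len(defined)
    composition = {r: 100.0 * defined.count(r) / n
                   for r in sorted(set(defined))}
    mw = pi = None
    if len(defined) == len(seq):
        pa = ProteinAnalysis(seq)
        mw = round(pa.molecular_weight(), 2)
        pi = round(pa.isoelectric_point(), 2)
    else:
        logger.warning("sequence contains */X: MW and pI not computed")
    return PhysChem(
        molecular_weight=mw,
        isoelectric_point=pi,
        composition=composition,
        glutamine_pct=composition.get("Q", 0.0),
        proline_pct=composition.get("P", 0.0),
        essential_pct=sum(v for r, v in composition.items() if r in essential),
    )
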