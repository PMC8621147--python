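"""Synthetic γ-gliadin gene and locus generator with exact ground truth.

γ-gliadins are seed storage prolamins with a stereotyped six-part primary
structure: a hydrophobic signal peptide (S), a short unique N-terminal
region (domain I), a repetitive domain II tiled by PQQPFPQ-family
heptapeptide units (where the celiac-disease epitope 9-mers live), a
cysteine-rich non-repetitive domain III, a poly-glutamine domain IV encoded
by a run of CAA codons with occasional single-base-mutant interruptions
(CAG, GAA, CTA), and a C-terminal domain V carrying two further cysteines.
The genes are intronless, and pseudogenes in the family arise from C→T
transitions that convert a glutamine CAA/CAG codon into a TAA/TAG stop.

This module emits genes of that architecture from an explicit ``GeneSpec``
and returns a ``SyntheticTruth`` that records every planted feature
(domain boundaries, epitope copies and positions, cysteine positions,
poly-Q tract, premature stop), so every downstream stage of the pipeline
has an exact recovery test without any external data.

Determinism contract: identical (spec, seed) always produces byte-identical
DNA. Codon choice is a fixed table (one codon per residue) so the DNA is a
pure function of the protein plus the planted poly-Q codons; the RNG only
chooses filler residues and cysteine placement. CAA is reserved for the
planted poly-Q tract and CAT (a reverse-strand ATG) is never emitted, so
feature recovery is exact, not merely probable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

HEPTAD_UNIT = "PQQPFPQ"
STOP_CODONS = ("TAA", "TAG", "TGA")
POLYQ_INTERRUPTION_CODONS = ("CAG", "GAA", "CTA")
DOMAIN_NAMES = ("S", "I", "II", "III", "IV", "V")

# Fixed back-translation table. Q→CAG (not CAA) and E→GAG, L→CTT keep the
# CAA-family codons out of everything but the planted domain-IV tract;
# H→CAC avoids CAT, the reverse-complement start codon.
CODON_OF = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAG", "F": "TTC",
    "G": "GGT", "H": "CAC", "I": "ATT", "K": "AAG", "L": "CTT",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAC",
}

# Filler composition for the non-repetitive regions (I, III, V): Q/P-rich,
# approximating the family's measured bulk composition (Q ≈ 30%, P ≈ 16%).
# Cysteine is excluded; it is planted explicitly.
_FILLER_RESIDUES = "QPLFSVIATYNGEHRKMW"
_FILLER_WEIGHTS = np.array(
    [0.30, 0.16, 0.08, 0.06, 0.06, 0.05, 0.04, 0.04, 0.03, 0.02,
     0.03, 0.03, 0.03, 0.02, 0.02, 0.01, 0.01, 0.01]
)
_FILLER_WEIGHTS = _FILLER_WEIGHTS / _FILLER_WEIGHTS.sum()

_SIGNAL_RESIDUES = "LAVIFTS"
_SIGNAL_WEIGHTS = np.array([0.35, 0.16, 0.16, 0.12, 0.11, 0.05, 0.05])
_SIGNAL_WEIGHTS = _SIGNAL_WEIGHTS / _SIGNAL_WEIGHTS.sum()


class SpecError(ValueError):
    """A GeneSpec is internally contradictory or violates an invariant."""


@dataclass(frozen=True)
class GeneSpec:
    """Blueprint for one synthetic γ-gliadin gene.

    Lengths are residues for protein-level fields and codons for
    ``polyq_length``. ``embedded_epitopes`` lists (9-mer, copy count)
    pairs planted at internal junctions of domain II; when non-empty,
    ``n_heptapeptide_repeats`` must be ≥ 2 so domain II starts and ends
    with a canonical unit. ``polyq_interruptions`` gives (1-based offset
    within the tract, codon) pairs; offsets must be strictly inside the
    tract, non-adjacent, and leave at least 60% CAA so the tract remains
    detectable as a single run.
    """

    n_heptapeptide_repeats: int = 5
    embedded_epitopes: tuple[tuple[str, int], ...] = ()
    polyq_length: int = 24
    polyq_interruptions: tuple[tuple[int, str], ...] = ()
    cysteine_layout: dict[str, int] = field(
        default_factory=lambda: {"III": 6, "V": 2}
    )
    signal_length: int = 19
    domain_i_length: int = 24
    domain_iii_length: int = 95
    domain_v_length: int = 70
    seed: int = 0

    def __post_init__(self):
        if self.n_heptapeptide_repeats < 0:
            raise SpecError("n_heptapeptide_repeats must be >= 0")
        if self.polyq_length < 0:
            raise SpecError("polyq_length must be >= 0")
        if 0 < self.polyq_length < 5:
            raise SpecError(
                "polyq_length must be 0 or >= 5: a 1-4 codon tract is below "
                "the poly-Q detector's minimum run and could never be recovered"
            )
        if self.signal_length < 1:
            raise SpecError("signal_length must be >= 1")
        if min(self.domain_i_length, self.domain_iii_length,
               self.domain_v_length) < 2:
            raise SpecError("filler domains need >= 2 residues")
        for name, count in self.cysteine_layout.items():
            if name not in ("I", "II", "III", "V"):
                raise SpecError(f"cysteines cannot be planted in domain {name!r}")
            if count < 0:
                raise SpecError("cysteine counts must be >= 0")
        for seq, copies in self.embedded_epitopes:
            if copies < 0:
                raise SpecError("epitope copy counts must be >= 0")
            if not seq or any(r not in CODON_OF for r in seq):
                raise SpecError(f"epitope {seq!r} has residues outside the 20-AA alphabet")
        total_copies = sum(c for _, c in self.embedded_epitopes)
        if total_copies and self.n_heptapeptide_repeats < 2:
            raise SpecError(
                "embedding epitopes requires >= 2 heptapeptide units so that "
                "domain II starts and ends on a canonical unit"
            )
        offsets = sorted(off for off, _ in self.polyq_interruptions)
        for off, codon in self.polyq_interruptions:
            if codon not in POLYQ_INTERRUPTION_CODONS:
                raise SpecError(
                    f"interruption codon {codon!r} is not a single-base CAA mutant "
                    f"from {POLYQ_INTERRUPTION_CODONS}"
                )
            if not 1 < off < self.polyq_length:
                raise SpecError("interruption offsets must be strictly inside the tract")
        if any(b - a < 2 for a, b in zip(offsets, offsets[1:])):
            raise SpecError("interruptions may not occupy adjacent codons")
        if self.polyq_length:
            n_caa = self.polyq_length - len(offsets)
            if n_caa < int(np.ceil(0.6 * self.polyq_length)):
                raise SpecError("poly-Q tract must remain >= 60% CAA")


@dataclass
class SyntheticTruth:
    """Ground truth for one emitted gene.

    ``domain_boundaries`` maps S/I/II/III/IV/V to 1-based inclusive
    protein-coordinate intervals (None for an empty domain); positions in
    ``epitope_positions`` and ``cysteine_positions`` are 1-based protein
    coordinates; ``pseudogene_stop`` is (bp of the stop codon's first base,
    1-based from the ATG's A; stop codon; ancestral codon) or None.
    """

    dna: str
    protein: str
    domain_boundaries: dict[str, tuple[int, int] | None]
    epitope_positions: list[tuple[str, int]]
    cysteine_positions: list[int]
    polyq: tuple[int, int] | None           # codon interval, 1-based within ORF
    polyq_interruptions: list[tuple[int, str]]
    unit_count: int                          # exact PQQPFPQ substring count
    pseudogene_stop: tuple[int, str, str] | None = None
    truncated_at: int | None = None
    spec: GeneSpec | None = None

    @property
    def is_pseudogene(self) -> bool:
        return self.pseudogene_stop is not None or self.truncated_at is not None


def _sample_filler(rng: np.random.Generator, length: int,
                   forbid_q_runs: bool = True) -> str:
    """Q/P-rich filler without cysteines, unit-like 7-mers, or long Q runs.

    Windows within Hamming distance 1 of PQQPFPQ and runs of >= 4 Q are
    resampled so filler can never masquerade as domain II or domain IV.
    """
    if length <= 0:
        return ""
    for _ in range(200):
        res = rng.choice(list(_FILLER_RESIDUES), size=length, p=_FILLER_WEIGHTS)
        s = "".join(res)
        if forbid_q_runs and ("QQQQ" in s or protein_polyq_window(s)):
            continue
        if _has_unitlike(s):
            continue
        return s
    raise RuntimeError("could not sample admissible filler (length too constrained)")


def _has_unitlike(s: str, unit: str = HEPTAD_UNIT, max_mismatch: int = 1) -> bool:
    k = len(unit)
    for i in range(len(s) - k + 1):
        if sum(a != b for a, b in zip(s[i:i + k], unit)) <= max_mismatch:
            return True
    return False


def heptad_tiling_window(seq: str, unit: str = HEPTAD_UNIT,
                         max_mismatch: int = 1, min_units: int = 2,
                         max_gap: int = 9) -> tuple[int, int] | None:
    """Maximal span tiled by heptapeptide-family units (1-based) or None.

    A unit match is any window within ``max_mismatch`` of ``unit``;
    consecutive units in a chain may be separated by up to ``max_gap``
    residues (room for one embedded 9-mer epitope); chains need at least
    ``min_units`` units. Ties go to the leftmost longest span. This is the
    domain-II definition shared by the segmenter and by the generator's
    self-validation.
    """
    k = len(unit)
    matches = [i for i in range(len(seq) - k + 1)
               if sum(a != b for a, b in zip(seq[i:i + k], unit)) <= max_mismatch]
    if not matches:
        return None
    span_end: dict[int, int] = {}
    units: dict[int, int] = {}
    for i in reversed(matches):
        lo, hi = i + k, i + k + max_gap
        nxt = [j for j in matches if lo <= j <= hi]
        if nxt:
            j_best = max(nxt, key=lambda j: (span_end[j], units[j], -j))
            span_end[i] = span_end[j_best]
            units[i] = units[j_best] + 1
        else:
            span_end[i] = i + k
            units[i] = 1
    candidates = [(i, span_end[i]) for i in matches if units[i] >= min_units]
    if not candidates:
        return None
    i, e = max(candidates, key=lambda c: (c[1] - c[0], -c[0]))
    return (i + 1, e)


def protein_polyq_window(seq: str, min_len: int = 5,
                         min_q_frac: float = 0.6) -> tuple[int, int] | None:
    """Longest protein-level poly-Q window (1-based inclusive) or None.

    The protein projection of the codon-level tract rule: a run starting
    and ending with Q, with no two consecutive non-Q residues, at least
    ``min_q_frac`` glutamine, and length ≥ ``min_len``. Shared by the
    domain-IV segmenter and by the generator's filler rejection (filler
    must never contain a qualifying window, or a gene built without a
    tract would grow a spurious domain IV).
    """
    n = len(seq)
    best: tuple[int, int] | None = None
    i = 0
    while i < n:
        if seq[i] != "Q":
            i += 1
            continue
        j = i
        while j + 1 < n:
            if seq[j + 1] == "Q":
                j += 1
            elif j + 2 < n and seq[j + 2] == "Q":
                j += 2          # absorb an isolated non-Q interruption
            else:
                break
        length = j - i + 1
        n_q = seq[i:j + 1].count("Q")
        if (length >= min_len and n_q >= min_q_frac * length
                and (best is None or length > best[1] - best[0] + 1)):
            best = (i + 1, j + 1)
        i = j + 1
    return best


def _place_positions(rng: np.random.Generator, length: int, count: int,
                     margin: int = 1) -> list[int]:
    """Distinct, non-adjacent 0-based offsets inside [margin, length-margin)."""
    lo, hi = margin, length - margin
    if count == 0:
        return []
    if hi - lo < 2 * count - 1:
        raise SpecError(f"cannot place {count} separated positions in {length} residues")
    while True:
        pos = sorted(rng.choice(np.arange(lo, hi), size=count, replace=False).tolist())
        if all(b - a >= 2 for a, b in zip(pos, pos[1:])):
            return pos


def _build_domain_ii(spec: GeneSpec, rng: np.random.Generator
                     ) -> tuple[str, list[tuple[str, int]]]:
    """Assemble domain II: heptapeptide units with epitopes at internal junctions.

    Returns the domain II string and the 0-based offsets (within domain II)
    of each planted epitope copy.
    """
    n = spec.n_heptapeptide_repeats
    if n == 0:
        return "", []
    # Epitopes that themselves contain a unit-like 7-mer (e.g. QQPQQPFPQ)
    # keep the heptapeptide tiling anchored; copies without one (e.g.
    # IQPQQPAQL) open a 9-residue gap, so at most one of those may sit at
    # any junction — and it goes last, directly against the next unit —
    # or the tiled window would no longer span the whole domain.
    anchored: list[str] = []
    unanchored: list[str] = []
    for seq, k in spec.embedded_epitopes:
        (anchored if _has_unitlike(seq) else unanchored).extend([seq] * k)
    n_junctions = n - 1
    if len(unanchored) > n_junctions:
        raise SpecError(
            f"{len(unanchored)} epitope copies without an internal repeat "
            f"unit need {len(unanchored)} distinct junctions but only "
            f"{n_junctions} exist; increase n_heptapeptide_repeats"
        )
    junction_content: dict[int, list[str]] = {j: [] for j in range(1, n_junctions + 1)}
    taken: set[int] = set()
    if unanchored:
        rng.shuffle(unanchored)
        slots = rng.choice(np.arange(1, n_junctions + 1),
                           size=len(unanchored), replace=False)
        for e, j in zip(unanchored, slots):
            junction_content[int(j)].append(e)   # sole occupant of its junction
            taken.add(int(j))
    if anchored:
        free = [j for j in range(1, n_junctions + 1) if j not in taken]
        if not free:
            raise SpecError(
                "no junction left for unit-anchored epitope copies; "
                "increase n_heptapeptide_repeats"
            )
        rng.shuffle(anchored)
        for e in anchored:
            junction_content[int(rng.choice(free))].append(e)
    parts: list[str] = []
    placements: list[tuple[str, int]] = []
    offset = 0
    for u in range(1, n + 1):
        parts.append(HEPTAD_UNIT)
        offset += len(HEPTAD_UNIT)
        for e in junction_content.get(u, ()):
            parts.append(e)
            placements.append((e, offset))
            offset += len(e)
    return "".join(parts), placements


def build_gamma_gene(spec: GeneSpec) -> SyntheticTruth:
    """Emit one intronless γ-gliadin-like ORF with exact ground truth.

    The ORF is ATG…TGA; the returned truth exactly describes the emitted
    sequence and the construction is validated (each planted epitope's
    global exact-match count must equal the requested copy number, the
    canonical-unit count must equal its analytic expectation, and the
    poly-Q tract must be the only CAA-family run). Some epitope orderings
    at domain-II junctions spell out incidental extra copies (e.g.
    PQQSFPQQQ directly before a unit reads …QQ+PQQPFPQ = QQPQQPFPQ);
    the builder redraws the arrangement deterministically until the
    validation passes, and a spec whose epitopes can never be placed
    without collision is rejected with :class:`SpecError`.
    """
    rng = np.random.default_rng(spec.seed)
    last_err: SpecError | None = None
    for _attempt in range(20):
        try:
            return _assemble_gene(spec, rng)
        except SpecError as err:
            last_err = err
    raise last_err


def _assemble_gene(spec: GeneSpec, rng: np.random.Generator) -> SyntheticTruth:
    # --- protein-level assembly -------------------------------------------
    signal = "MK" + "".join(
        rng.choice(list(_SIGNAL_RESIDUES), size=spec.signal_length - 2,
                   p=_SIGNAL_WEIGHTS)
    )
    dom_i = _sample_filler(rng, spec.domain_i_length)
    dom_ii, epi_local = _build_domain_ii(spec, rng)
    dom_iii = list(_sample_filler(rng, spec.domain_iii_length))
    dom_v = list(_sample_filler(rng, spec.domain_v_length))
    # Residues flanking the poly-Q tract must not read as CAA-family codons.
    if spec.polyq_length:
        dom_iii[-1] = "P"
        dom_v[0] = "P"

    cys_positions_local: dict[str, list[int]] = {}
    layout = dict(spec.cysteine_layout)
    for name, count in layout.items():
        if count == 0:
            continue
        if name == "I":
            pos = _place_positions(rng, len(dom_i), count)
            for p in pos:
                dom_i = dom_i[:p] + "C" + dom_i[p + 1:]
        elif name == "III":
            pos = _place_positions(rng, len(dom_iii) - 2, count, margin=1)
            for p in pos:
                dom_iii[p] = "C"
        elif name == "V":
            pos = [p + 1 for p in _place_positions(rng, len(dom_v) - 2, count, margin=1)]
            for p in pos:
                dom_v[p] = "C"
        elif name == "II":
            # An extra domain-II cysteine is modelled as the paper's
            # Gli-γ1b case: a single-residue variant of one unit
            # (TCC/TAC→TGC analog), here the unit's F→C, which still
            # tiles under the <=1-mismatch rule.
            if spec.n_heptapeptide_repeats < count:
                raise SpecError("not enough units to host domain-II cysteines")
            pos = []
            epi_spans = [(off, off + len(e)) for e, off in epi_local]
            starts = [m for m in range(len(dom_ii))
                      if dom_ii.startswith(HEPTAD_UNIT, m)
                      and not any(a < m + len(HEPTAD_UNIT) and m < b
                                  for a, b in epi_spans)]
            if len(starts) < count:
                raise SpecError("not enough standalone units to host "
                                "domain-II cysteines")
            chosen = rng.choice(len(starts), size=count, replace=False)
            for idx in sorted(int(i) for i in chosen):
                p = starts[idx] + HEPTAD_UNIT.index("F")
                dom_ii = dom_ii[:p] + "C" + dom_ii[p + 1:]
                pos.append(p)
        cys_positions_local[name] = pos

    dom_iii = "".join(dom_iii)
    dom_v = "".join(dom_v)
    polyq_protein = ""
    interruption_residues = {"CAG": "Q", "GAA": "E", "CTA": "L"}
    if spec.polyq_length:
        tract = ["Q"] * spec.polyq_length
        for off, codon in spec.polyq_interruptions:
            tract[off - 1] = interruption_residues[codon]
        polyq_protein = "".join(tract)

    segments = [("S", signal), ("I", dom_i), ("II", dom_ii),
                ("III", dom_iii), ("IV", polyq_protein), ("V", dom_v)]
    protein_parts: list[str] = []
    boundaries: dict[str, tuple[int, int] | None] = {}
    pos = 1
    seg_start: dict[str, int] = {}
    for name, seg in segments:
        seg_start[name] = pos
        boundaries[name] = (pos, pos + len(seg) - 1) if seg else None
        protein_parts.append(seg)
        pos += len(seg)
    protein = "".join(protein_parts)

    # --- truth bookkeeping -------------------------------------------------
    epitope_positions = sorted(
        (name, seg_start["II"] + off) for name, off in epi_local
    )
    cysteine_positions = sorted(
        seg_start[name] + p
        for name, plist in cys_positions_local.items() for p in plist
    )

    # --- DNA ---------------------------------------------------------------
    codons: list[str] = []
    polyq_interval = None
    for name, seg in segments:
        if name == "IV" and seg:
            polyq_interval = (len(codons) + 1, len(codons) + spec.polyq_length)
            tract_codons = ["CAA"] * spec.polyq_length
            for off, codon in spec.polyq_interruptions:
                tract_codons[off - 1] = codon
            codons.extend(tract_codons)
        else:
            codons.extend(CODON_OF[r] for r in seg)
    codons.append("TGA")
    dna = "".join(codons)

    truth = SyntheticTruth(
        dna=dna,
        protein=protein,
        domain_boundaries=boundaries,
        epitope_positions=epitope_positions,
        cysteine_positions=cysteine_positions,
        polyq=polyq_interval,
        polyq_interruptions=list(spec.polyq_interruptions),
        unit_count=_count_substring(protein, HEPTAD_UNIT),
        spec=spec,
    )
    _validate_truth(truth, spec)
    return truth


def _count_substring(s: str, sub: str) -> int:
    return sum(1 for i in range(len(s) - len(sub) + 1) if s.startswith(sub, i))


def _validate_truth(truth: SyntheticTruth, spec: GeneSpec) -> None:
    for seq, k in spec.embedded_epitopes:
        found = _count_substring(truth.protein, seq)
        if found != k:
            raise SpecError(
                f"epitope {seq} requested {k}x but the assembled protein "
                f"contains {found} exact copies (collision with the repeat "
                "lattice or filler); adjust the spec"
            )
        planted = [p for name, p in truth.epitope_positions if name == seq]
        for p in planted:
            if not truth.protein.startswith(seq, p - 1):
                raise AssertionError("truth epitope position does not match sequence")
    expected_units = spec.n_heptapeptide_repeats
    for seq, k in spec.embedded_epitopes:
        expected_units += _count_substring(seq, HEPTAD_UNIT) * k
    expected_units -= spec.cysteine_layout.get("II", 0)  # F→C variant units
    if truth.unit_count != expected_units:
        raise SpecError(
            f"canonical unit count {truth.unit_count} != analytic expectation "
            f"{expected_units}; the spec's epitope placement collides with the lattice"
        )
    # self-validation against the shared window definitions: the tiled
    # repeat window and the poly-Q window on the finished protein must
    # land exactly on the planted boundaries (a near-unit 7-mer straddling
    # a domain edge, or a Q-rich filler window, would silently shift them)
    b = truth.domain_boundaries
    if spec.n_heptapeptide_repeats >= 2:
        if heptad_tiling_window(truth.protein) != b["II"]:
            raise SpecError("repeat window drifted off the planted domain II")
    # mirror the segmenter's domain-IV logic: a Q-rich window inside the
    # repeat region (QQPQQ occurs inside epitopes) is not a tract; the
    # tract window is searched after domain II
    w = protein_polyq_window(truth.protein)
    ii = b["II"]
    if ii is not None and w is not None and w[0] <= ii[1]:
        tail = protein_polyq_window(truth.protein[ii[1]:])
        w = (tail[0] + ii[1], tail[1] + ii[1]) if tail else None
    if spec.polyq_length:
        if w != b["IV"]:
            raise SpecError("poly-Q window drifted off the planted domain IV")
    elif w is not None:
        raise SpecError("spurious poly-Q window in a tract-free gene")
    if len(truth.dna) % 3:
        raise AssertionError("ORF length not divisible by 3")
    if not truth.dna.startswith("ATG") or truth.dna[-3:] not in STOP_CODONS:
        raise AssertionError("ORF must start ATG and end with a stop codon")


def glutamine_codons(truth: SyntheticTruth) -> list[int]:
    """1-based indices of CAA/CAG codons, the targets of pseudogenization."""
    return [i // 3 + 1 for i in range(0, len(truth.dna) - 3, 3)
            if truth.dna[i:i + 3] in ("CAA", "CAG")]


def pseudogenize(truth: SyntheticTruth, codon_index: int) -> SyntheticTruth:
    """Inactivate a gene by the family's C→T transition mechanism.

    The codon at ``codon_index`` (1-based from the ATG) must be a glutamine
    CAA or CAG; its first base is mutated C→T, yielding TAA or TAG. The
    recorded stop position is the 1-based bp of the stop codon's first
    base, 3·(codon_index−1)+1.
    """
    start = 3 * (codon_index - 1)
    codon = truth.dna[start:start + 3]
    if codon not in ("CAA", "CAG"):
        raise ValueError(
            f"codon {codon_index} is {codon!r}, not CAA/CAG: the C→T "
            "pseudogenization mechanism only applies to glutamine codons"
        )
    new_codon = "T" + codon[1:]
    dna = truth.dna[:start] + new_codon + truth.dna[start + 3:]
    return replace(
        truth,
        dna=dna,
        pseudogene_stop=(start + 1, new_codon, codon),
    )


def truncate(truth: SyntheticTruth, at_bp: int) -> SyntheticTruth:
    """Cut the ORF after ``at_bp`` bases, leaving no terminal stop codon."""
    if not 3 <= at_bp < len(truth.dna):
        raise ValueError("truncation point must be inside the ORF")
    return replace(truth, dna=truth.dna[:at_bp], truncated_at=at_bp)


def sample_gene_spec(rng: np.random.Generator) -> GeneSpec:
    """Draw a random feasible GeneSpec across the family's architecture space.

    Used by the recovery test-bench: repeat counts 0–7, epitope subsets of
    the bundled Table of cores with 0–3 copies, poly-Q tracts of 0 or 8–30
    codons with up to two interruptions, canonical or extended cysteine
    layouts. Draws respect junction feasibility (epitope copies without an
    internal repeat unit each need their own junction).
    """
    epitopes = []
    k = int(rng.integers(0, 4))
    if k:
        epitopes.append(("QQPQQPFPQ", k))
    n_unanchored = 0
    if rng.random() < 0.4:
        epitopes.append(("QQPFPQQPQ", 1))
        n_unanchored += 1
    if rng.random() < 0.3:
        epitopes.append(("IQPQQPAQL", 1))
        n_unanchored += 1
    min_repeats = 1 + n_unanchored + (1 if k else 0) if epitopes else 0
    if epitopes:
        repeats = int(rng.integers(max(2, min_repeats), 8))
    else:
        repeats = int(rng.choice([0, 2, 3, 4, 5, 6, 7]))
    polyq = 0 if rng.random() < 0.15 else int(rng.integers(8, 31))
    interruptions = []
    if polyq >= 10 and rng.random() < 0.6:
        offs = sorted(rng.choice(np.arange(3, polyq - 1), size=2,
                                 replace=False).tolist())
        codons = rng.choice(POLYQ_INTERRUPTION_CODONS, size=2)
        interruptions = [(int(o), str(c)) for o, c in zip(offs, codons)]
        if interruptions[1][0] - interruptions[0][0] < 2:
            interruptions = interruptions[:1]
    layout = {"III": 6, "V": 2}
    if repeats >= 2 and rng.random() < 0.25:
        layout["II"] = 1
    return GeneSpec(
        n_heptapeptide_repeats=repeats,
        embedded_epitopes=tuple(epitopes),
        polyq_length=polyq,
        polyq_interruptions=tuple(interruptions),
        cysteine_layout=layout,
        domain_i_length=int(rng.integers(15, 31)),
        domain_iii_length=int(rng.integers(60, 121)),
        domain_v_length=int(rng.integers(40, 91)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def spec_for_protein_length(target_aa: int, seed: int = 0,
                            **overrides) -> GeneSpec:
    """A GeneSpec whose translated product has exactly ``target_aa`` residues.

    All architecture knobs can be overridden; the C-terminal domain V
    length absorbs the remainder. Rejects targets too short for the
    requested architecture.
    """
    base = GeneSpec(seed=seed, **overrides)
    fixed = (base.signal_length + base.domain_i_length
             + 7 * base.n_heptapeptide_repeats
             + sum(len(s) * k for s, k in base.embedded_epitopes)
             + base.domain_iii_length + base.polyq_length)
    v = target_aa - fixed
    if v < 2:
        raise SpecError(f"target {target_aa} aa too short for this architecture "
                        f"({fixed} residues before domain V)")
    return replace(base, domain_v_length=v)


# Synonymous third-base swaps and single-base nonsynonymous swaps that stay
# inside the generator's codon conventions (no stops, no CAA/CAT, no new
# cysteine or glutamine).
_SYNONYMOUS_SWAP = {"CCA": "CCG", "CTT": "CTC", "TCT": "TCC", "GCT": "GCC",
                    "GTT": "GTC", "ACT": "ACC", "TTC": "TTT", "TAC": "TAT"}
_NONSYN_SWAP = {"TCT": "ACT", "GCT": "GTT", "CTT": "ATT", "TTC": "TAC"}
_NONSYN_RESIDUE = {"ACT": "T", "GTT": "V", "ATT": "I", "TAC": "Y"}


def diverge(truth: SyntheticTruth, n_synonymous: int, n_nonsynonymous: int,
            seed: int = 0) -> SyntheticTruth:
    """Derive a paralog by planting point substitutions in filler regions.

    Emulates the near-identical duplicated gene pairs seen in prolamin
    loci: ``n_synonymous`` third-base swaps plus ``n_nonsynonymous``
    single-base residue changes, all placed inside domains III and V away
    from cysteines and tract-flanking prolines, so every truth annotation
    (domains, epitopes, cysteines, poly-Q) remains valid for the paralog.
    """
    rng = np.random.default_rng(seed)
    bounds = truth.domain_boundaries
    candidates_syn: list[int] = []
    candidates_non: list[int] = []
    for name in ("III", "V"):
        iv = bounds[name]
        if iv is None:
            continue
        for res in range(iv[0] + 1, iv[1] - 1):   # keep flanks untouched
            codon = truth.dna[3 * (res - 1):3 * res]
            if codon in _SYNONYMOUS_SWAP:
                candidates_syn.append(res)
            if codon in _NONSYN_SWAP:
                candidates_non.append(res)
    if (len(candidates_syn) < n_synonymous
            or len(candidates_non) < n_synonymous + n_nonsynonymous):
        raise SpecError("not enough mutable filler positions for divergence")
    picked_non = sorted(rng.choice(candidates_non, size=n_nonsynonymous,
                                   replace=False).tolist())
    pool_syn = [r for r in candidates_syn if r not in picked_non]
    picked_syn = sorted(rng.choice(pool_syn, size=n_synonymous,
                                   replace=False).tolist())
    dna = list(truth.dna)
    protein = list(truth.protein)
    for res in picked_syn:
        codon = truth.dna[3 * (res - 1):3 * res]
        dna[3 * (res - 1):3 * res] = _SYNONYMOUS_SWAP[codon]
    for res in picked_non:
        codon = truth.dna[3 * (res - 1):3 * res]
        new = _NONSYN_SWAP[codon]
        dna[3 * (res - 1):3 * res] = new
        protein[res - 1] = _NONSYN_RESIDUE[new]
    return replace(truth, dna="".join(dna), protein="".join(protein))


def reference_gamma_analog(seed: int = 20) -> SyntheticTruth:
    """SYNTHETIC stand-in for the family's reference γ-gliadin gene.

    A 966-bp intronless ORF translating to 321 residues with the canonical
    eight-cysteine skeleton (six in domain III, two in domain V) and the
    reference epitope complement planted in domain II: QQPQQPFPQ ×3,
    QQPFPQQPQ ×1 and IQPQQPAQL ×1. The residue-level sequence is
    synthetic — generator filler, not the deposited gene — so
    sequence-derived scalars (MW, pI) are analog values, while length,
    cysteine count and epitope copy numbers are exact by construction.
    """
    spec = spec_for_protein_length(
        321, seed=seed,
        n_heptapeptide_repeats=4,
        embedded_epitopes=(("QQPQQPFPQ", 3), ("QQPFPQQPQ", 1),
                           ("IQPQQPAQL", 1)),
        polyq_length=26,
        polyq_interruptions=((8, "CAG"), (17, "GAA")),
    )
    truth = build_gamma_gene(spec)
    assert len(truth.dna) == 966 and len(truth.protein) == 321
    return truth


# --------------------------------------------------------------------------
# locus assembly
# --------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sample_spacer(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    """i.i.d. intergenic spacer with the requested GC fraction."""
    bases = rng.choice(list("ACGT"), size=length,
                       p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(bases)


# Stop-codon walls flanking each placed gene: TAA in all three forward
# frames (three per frame, so ORF extension through premature stops cannot
# tunnel out of a spacer), and the reverse complement downstream for the
# three reverse frames. Neither wall contains ATG on either strand.
FORWARD_STOP_WALL = "TAAATAAATAA" * 3
REVERSE_STOP_WALL = FORWARD_STOP_WALL.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class LocusGene:
    index: int
    start: int       # 1-based inclusive, forward axis
    end: int
    strand: str      # "+" or "-"
    truth: SyntheticTruth


@dataclass
class LocusTruth:
    sequence: str
    genes: list[LocusGene]


def build_locus(genes: list[SyntheticTruth],
                spacer_range: tuple[int, int] = (200, 400),
                gc: float = 0.45,
                strands: list[str] | None = None,
                seed: int = 0,
                min_orf_len: int = 450,
                max_tries: int = 50) -> LocusTruth:
    """Place genes in order on a synthetic genomic region.

    Genes are separated (and flanked) by random spacers; spacers are
    resampled until the assembled region contains no ORF ≥ ``min_orf_len``
    other than the planted genes, so an ORF scanner at that threshold
    recovers exactly the planted set.
    """
    if not genes:
        raise ValueError("need at least one gene")
    if any(g.truncated_at is not None for g in genes):
        raise ValueError(
            "truncated genes cannot be placed on a locus: without a terminal "
            "stop their ORF would run into the spacer; feed them to the "
            "annotator as standalone FASTA records instead"
        )
    if spacer_range[0] < 0 or spacer_range[1] < spacer_range[0]:
        raise ValueError("invalid spacer length range")
    if strands is None:
        strands = ["+"] * len(genes)
    if len(strands) != len(genes) or any(s not in "+-" for s in strands):
        raise ValueError("strands must be '+'/'-' per gene")
    rng = np.random.default_rng(seed)

    from .annotate import find_orfs, select_gene_candidates  # deferred: avoids import cycle

    for _ in range(max_tries):
        parts: list[str] = []
        placed: list[LocusGene] = []
        pos = 0
        for i, (g, st) in enumerate(zip(genes, strands)):
            spacer = sample_spacer(rng, int(rng.integers(spacer_range[0],
                                                         spacer_range[1] + 1)), gc)
            # stop walls on both sides of every gene, both orientations:
            # no spacer ORF can tunnel into a gene body and no shadow ORF
            # on either strand can read through one
            lead = FORWARD_STOP_WALL + REVERSE_STOP_WALL
            tail = REVERSE_STOP_WALL + FORWARD_STOP_WALL
            parts.extend([spacer, lead])
            pos += len(spacer) + len(lead)
            seq = g.dna if st == "+" else reverse_complement(g.dna)
            placed.append(LocusGene(i, pos + 1, pos + len(seq), st, g))
            parts.extend([seq, tail])
            pos += len(seq) + len(tail)
        parts.append(sample_spacer(rng, int(rng.integers(spacer_range[0],
                                                         spacer_range[1] + 1)), gc))
        sequence = "".join(parts)
        found = {(o.start, o.end, o.strand)
                 for o in select_gene_candidates(
                     find_orfs(sequence, min_len_bp=min_orf_len,
                               max_internal_stops=2))}
        planted = {(g.start, g.end, g.strand) for g in placed
                   if len(g.truth.dna) >= min_orf_len}
        strict = {(o.start, o.end, o.strand)
                  for o in find_orfs(sequence, min_len_bp=min_orf_len)}
        strict_planted = {(g.start, g.end, g.strand) for g in placed
                          if len(g.truth.dna) >= min_orf_len
                          and g.truth.pseudogene_stop is None}
        pseudo_spans = [(g.start, g.end) for g in placed
                        if g.truth.pseudogene_stop is not None]
        # a pseudogene legitimately leaves a remnant sub-ORF downstream of
        # its premature stop; anything else outside the planted set is a
        # spurious draw and forces a spacer resample
        strict_ok = (strict_planted <= strict and all(
            hit in strict_planted
            or any(s <= hit[0] and hit[1] <= e for s, e in pseudo_spans)
            for hit in strict))
        if found == planted and strict_ok:
            return LocusTruth(sequence=sequence, genes=placed)
        logger.debug("locus draw produced spurious/shadowed ORFs; resampling spacers")
    raise RuntimeError("could not assemble a clean locus within max_tries")
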