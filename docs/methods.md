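# Methods

`gliakit` re-implements, as a tested pipeline, the characterization
workflow for γ-gliadin gene families in wheat: discovery of intronless
prolamin ORFs in genomic sequence, classification of full-length genes
versus pseudogenes, protein-level profiling (domain architecture,
heptapeptide repeats, poly-glutamine tract, cysteine skeleton,
composition, MW and pI), exact-match scanning for celiac-disease (CD)
epitopes, and comparative analysis (percent-identity matrices and a
neighbor-joining tree). Because the underlying genomic data (a specific
cultivar assembly) cannot be bundled, every stage is validated against a
synthetic-gene generator that emits γ-gliadin-like sequences with exact,
machine-checkable ground truth.

## The gene model

γ-gliadins are seed storage prolamins with a conserved six-part primary
structure:

| part | content |
|------|---------|
| S    | hydrophobic signal peptide (default 19 aa) |
| I    | short unique N-terminal region |
| II   | repetitive region tiled by PQQPFPQ-family heptapeptide units; hosts the CD epitope 9-mers |
| III  | non-repetitive, cysteine-rich (canonically six cysteines) |
| IV   | poly-glutamine tract encoded by a run of CAA codons |
| V    | C-terminal non-repetitive region (canonically two cysteines) |

The genes are intronless, so an ORF is the gene. Functional family
members carry an eight-cysteine skeleton (6 in III + 2 in V); occasional
variants carry an extra cysteine in domain II arising from a point
mutation in a serine/tyrosine codon. Pseudogenes arise by a C→T
transition converting a glutamine codon (CAA/CAG) into a premature stop
(TAA/TAG), or by truncation.

## Synthetic-gene generator

`build_gamma_gene(GeneSpec)` assembles the six parts at the protein level
and back-translates with a **fixed one-codon-per-residue table**. Two
deliberate conventions make downstream recovery exact rather than
probable:

* Glutamine is encoded CAG everywhere except the planted domain-IV
  tract, which is pure CAA plus the requested single-base-mutant
  interruptions (CAG/GAA/CTA). Hence the tract detector's CAA-family run
  has exactly one qualifying window, the planted one. Residues flanking
  the tract are forced to proline so the run cannot extend.
* CAT never occurs inside a gene (histidine is encoded CAC), so no
  reverse-strand start codon exists within a gene body.

Filler for domains I, III and V is drawn from a Q/P-rich alphabet
(Q ≈ 30%, P ≈ 16%, remainder spread over a gliadin-like residue pool,
no cysteine) and rejection-sampled so it contains no 7-mer within
Hamming distance 1 of PQQPFPQ, no run of ≥4 Q, and no window satisfying
the protein-level poly-Q rule. Cysteines are planted explicitly at
separated positions per the requested layout; a domain-II cysteine is
realized as a single-residue unit variant (F→C), mirroring the
TCC/TAC→TGC mechanism seen in real variants, and still tiles under the
≤1-mismatch rule.

Epitope 9-mers are inserted at internal junctions of the domain-II unit
lattice. Copies that contain a unit-like 7-mer themselves (e.g.
QQPQQPFPQ = QQ + PQQPFPQ) keep the tiling anchored and may stack;
copies without one (e.g. IQPQQPAQL) open a 9-residue gap and therefore
each occupy a junction alone. Some orderings spell incidental extra
copies across junctions (PQQSFPQQQ directly before a unit reads
…QQ+PQQPFPQ = QQPQQPFPQ); the builder redraws the arrangement with the
seeded RNG until a self-validation pass confirms that every planted
epitope's global exact-match count equals the request, the canonical
unit count matches its analytic expectation, and the repeat-tiling and
poly-Q windows computed on the finished protein land exactly on the
planted boundaries. A spec that can never satisfy these (e.g. epitope
copies that cannot fit) is rejected with an explanation.

One emergent feature is worth knowing: a perfect PQQPFPQ·PQQPFPQ
junction spells PFPQPQQPF, the ω-gliadin epitope, so synthetic proteins
with tandem canonical units report ω1 copies that were never "planted".
Real γ-gliadin repeats are imperfect, which is why this epitope is rare
in nature; in the synthetic material it is legitimate sequence content
and the scanner is right to count it. Recovery tests assert counts only
for planted epitopes.

`pseudogenize(truth, codon_index)` applies the C→T mechanism to a
CAA/CAG codon and records the stop as (bp, stop codon, ancestral codon),
where bp = 3·(codon_index−1)+1 — the 1-based position of the stop's
first base from the ATG. Under this convention every premature stop
position is ≡ 1 (mod 3), which the suite asserts throughout.
`truncate` cuts the ORF with no terminal stop. `diverge` derives a
near-identical paralog by planting a chosen number of synonymous and
nonsynonymous single-base substitutions in filler regions, leaving all
truth annotations valid — six substitutions in an 858-bp pair give the
99.3% NT / 98.9% AA identity relationship typical of recently duplicated
family members.

### Locus assembly

`build_locus` places genes (either strand) between i.i.d. random spacers
of configurable length range and GC fraction. Each gene is flanked on
both sides by short stop-codon "walls" (TAA in all three frames, both
orientations, three deep per frame). Real intergenic DNA is stop-dense;
the walls guarantee it: no spacer ATG can extend into a gene body even
when the scanner is allowed to read through premature stops, and no
opposite-strand shadow ORF can span a gene. After assembly the locus is
checked by running the ORF scanner itself: the recovered footprints must
equal the planted ones exactly (pseudogene remnant sub-ORFs downstream
of a premature stop are accepted), otherwise spacers are resampled —
deterministically under the seed.

## ORF discovery and classification

`find_orfs` reports every maximal ATG→stop stretch ≥ `min_len_bp`
(default 450 bp, below the shortest family member worth reporting) on
the requested strands, with 1-based inclusive coordinates on the forward
axis and the stop codon included in the span (an n-bp ORF encodes
n/3 − 1 residues). Nested ORFs sharing a stop report only the 5′-most
ATG. ORFs containing N are skipped with a warning.

A pure ATG→first-stop scanner can never span a pseudogene, whose
defining feature is an internal stop. `max_internal_stops` (pipeline
default 2) lets a candidate shorter than the threshold extend through
premature stops until it reaches the minimum length — the family's
documented premature stops all sit at bp 79–277, far below the 450-bp
threshold, so the extension recovers pseudogene footprints whole.
Because extension can also let a flanking ATG ride into a real gene in
another frame, overlapping candidates are resolved by parsimony
(`select_gene_candidates`): fewer internal stops win, then the longer
candidate, and survivors must not overlap. Genuinely overlapping genes
on opposite strands would be mis-resolved by this rule; the loci this
package targets do not contain them.

`classify_orf` scans codons 2…n−1; any internal TAA/TAG/TGA is recorded
with its inferred ancestral codon (TAA→CAA, TAG→CAG per the C→T
mechanism; TGA→"unknown", since no single C→T step produces TGA from a
glutamine codon). An ORF without a terminal stop is a truncated
pseudogene. Status is pseudogene iff internal stops exist or the ORF is
truncated. Family class is assigned from motif content (default: ≥2
exact PQQPFPQ units → `gamma_gliadin`), deliberately not by homology
search.

## Protein features

**Segmentation.** S is a fixed prefix (default 19 aa — the boundary is
not derivable from sequence alone here, so it is a documented,
overridable constant). Domain II is the maximal window tiled by
heptapeptide units at ≤1 mismatch each, ≥2 units, with inter-unit gaps
of ≤9 residues (room for one embedded 9-mer); computed by a
longest-span chain dynamic program over match positions, leftmost on
ties. Domain IV is the poly-Q tract: on the ORF codons, the longest run
where every codon is CAA or a single-base mutant from {CAG, GAA, CTA},
with no two consecutive non-CAA codons, ≥60% CAA, CAA at both ends and
length ≥5 (empty otherwise); on protein input alone, the projected rule
(Q with isolated non-Q interruptions, ≥60% Q, length ≥5), searched after
domain II because QQPQQ inside epitopes would otherwise qualify.
Domains I, III, V fill the gaps. Degenerate architectures degrade
gracefully: without a tract, III runs to the C-terminus (III/V cannot
be separated); without a repeat window, I runs to the tract; with
neither, only S+I are assigned and a "non-gliadin-like architecture"
warning is attached.

**Cysteine profile.** Positions, per-domain counts, and a `canonical`
flag that is true iff total = 8 with 6 in III and 2 in V. The classical
description of the skeleton says the "fourth and sixth" domain-III
cysteines are adjacent, which is internally puzzling (a fifth would lie
between them); the adjacency check is therefore configurable
(`check_pair`, default (4, 6)) and reported separately, never part of
the canonical flag.

**Physicochemistry.** Average molecular weight (sum of average residue
masses + one water) and theoretical pI (Henderson–Hasselbalch net
charge solved by bisection with the Bjellqvist pK set) are computed via
Biopython's ProtParam implementation — the same method behind the
published values this pipeline is meant to reproduce; reported to 2
decimals. MW/pI are refused (None) for sequences containing `*` or `X`;
composition is still computed over defined residues. MW and pI are
computed on the full preprotein (signal peptide included), consistent
with the n/3 − 1 arithmetic of the published tables. The essential-AA
set is configurable and defaults to {H, I, K, L, M, F, T, W, V}
(histidine included), since published "essential amino acid" totals
never enumerate the set.

## Epitope scanning

Matching is exact on the native glutamine-form sequence ("only exact
matches"); deamidation annotations are metadata. Overlapping occurrences
are counted by default — published copy numbers state no convention, and
overlapping counting is the conservative superset; a non-overlapping
mode exists and is labelled in output. The bundled database carries the
ten γ/ω 9-mer cores relevant to the family, including three
sequence-duplicated pairs (QQPQQPFPQ, QQPQQPYPQ, PQQSFPQQQ each under
two HLA-restriction names); duplicated sequences must — and do — report
identical hits. The B-cell heptamer QPQQPFP is counted with the same
convention. The summary reports the clustering fraction: hits starting
inside domain II ÷ total hits (0 with a `clustering_defined=False` flag
when there are no hits).

## Comparative stage

**Alignment.** Needleman–Wunsch with affine gaps (Gotoh three-state DP,
numpy row-vectorized; the within-row gap state is closed-form via a
running maximum). Defaults: NT match +1 / mismatch −1, gap open −5 /
extend −1; AA BLOSUM62, open −10 / extend −1; the first gapped position
scores the open penalty. The original study's GUI alignment parameters
are unpublished, so the scoring is fully exposed and identity
reproduction is tolerance-based. Traceback tie-break is deterministic:
diagonal over gap-in-second-sequence over gap-in-first. Scores are
symmetric under argument swap; the alignment strings need not be when
multiple optima exist, because the tie-break is inherently directional.

**Identity.** Default denominator is all alignment columns (gaps
included); the gap-free-columns convention is also available since the
published convention is unrecoverable. Values are reported to 1 decimal
in a dual-triangle matrix: NT identities above the diagonal, AA below,
100 on the diagonal.

**Tree.** Saitou–Nei neighbor joining on d = 100 − AA identity (no
multiple-hit correction — the source analysis used none). Q-criterion
minimized each step; ties broken by the lexicographically smallest pair
of cluster representative labels; negative branch lengths clamped to 0
with a warning; the final edge attaches with its full length at the
internal node (trifurcating root), or is split equally in the two-taxon
case. Newick output carries branch lengths to 4 decimals. On additive
matrices NJ reconstructs the generating tree exactly; the suite verifies
path-length recovery to 1e-9 and topology (RF = 0) against an
independent implementation.

## Validation strategy and what it does not show

The synthetic generator is the test bed: every recovery test plants
features and requires byte-exact recovery, and the acceptance script
recomputes the family's headline numbers (length arithmetic 858→285 /
909→302 / 966→321, eight-cysteine skeleton, epitope complement 3/1/1 of
the reference architecture, 99.3%/98.9% paralog identity, 7+2 family
census) from fresh synthetic material at run time. Problem sizes: 100
randomized genes for feature recovery, 1000 random protein/epitope
pairs against the naive scanning oracle, 100 random additive 5–8-taxon
trees, 1000 random peptides for MW/pI properties — sizes chosen so the
whole suite stays interactive while the estimates are stable.

Synthetic material differs from real data in known ways: codon usage is
degenerate (one codon per residue outside the tract), repeats are
perfect unless variants are requested (hence the emergent ω1 epitope),
spacers are i.i.d. with stop walls rather than repeat-laden intergenic
DNA, and filler composition only approximates real domain composition.
Passing tests therefore demonstrate the correctness of the *operations*
(scanning, segmentation, classification, alignment, NJ) and the
pipeline's plumbing — not the biological fidelity of any particular
sequence. Sequence-specific scalars of the real deposited gene (its MW
of ~36.6 kDa and pI of 8.16) depend on the exact residue string and are
reproduced here only as analog values on the synthetic stand-in, which
is labelled synthetic wherever it appears.

## Known limitations

* No spliced gene models, homology search, synteny, MSA figures,
  bootstrap values, disulfide pairing, structure, or GRAVY — out of
  scope by design.
* The signal-peptide boundary is a constant, not a prediction.
* `select_gene_candidates` assumes genes do not genuinely overlap.
* Protein-only segmentation cannot separate III from V without a tract,
  or I from III without a repeat window.
* Truncated genes cannot be placed on a synthetic locus (their ORF
  would run into the spacer); they are exercised as standalone records.
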