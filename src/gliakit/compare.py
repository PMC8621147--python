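"""Pairwise global alignment, percent-identity matrices, and NJ trees.

Gene-family relationships are summarized the classical way: optimal global
(Needleman–Wunsch) alignment of every sequence pair under affine gap
scoring, percent identity per pair arranged as a dual-triangle matrix
(nucleotide identities above the diagonal, amino-acid identities below),
and a Saitou–Nei neighbor-joining tree on 100 − identity distances,
serialized to Newick.

The aligner is an explicit Gotoh three-state dynamic program with a
deterministic traceback (diagonal preferred over a gap in the second
sequence, preferred over a gap in the first). Because the identity
convention of legacy alignment GUIs is not recoverable, both identity
denominators (all alignment columns; gap-free columns only) are available
and the scoring is fully exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

_NT_CHARS = set("ACGTUN")
NEG_INF = -1e30


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring. The first gapped position scores ``gap_open``,
    each subsequent one ``gap_extend`` (set them equal for linear gaps)."""

    nt_match: float = 1.0
    nt_mismatch: float = -1.0
    nt_gap_open: float = -5.0
    nt_gap_extend: float = -1.0
    aa_matrix: str = "BLOSUM62"
    aa_gap_open: float = -10.0
    aa_gap_extend: float = -1.0


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    params: AlignParams

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")


def _alphabet(seq: str) -> str:
    return "nt" if set(seq.upper()) <= _NT_CHARS else "aa"


def _substitution_scores(a: str, b: str, params: AlignParams,
                         kind: str) -> np.ndarray:
    """(len(a) × len(b)) substitution score matrix."""
    if kind == "nt":
        eq = np.frombuffer(a.encode(), dtype=np.uint8)[:, None] == \
            np.frombuffer(b.encode(), dtype=np.uint8)[None, :]
        return np.where(eq, params.nt_match, params.nt_mismatch).astype(float)
    mat = substitution_matrices.load(params.aa_matrix)
    lookup = np.full((128, 128), NEG_INF)
    for x in mat.alphabet:
        for y in mat.alphabet:
            lookup[ord(x), ord(y)] = mat[x, y]
    ai = np.frombuffer(a.encode(), dtype=np.uint8)
    bi = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = lookup[ai[:, None], bi[None, :]]
    if (sub <= NEG_INF / 2).any():
        bad = sorted({c for c in a + b if ord(c) >= 128
                      or lookup[ord(c), ord(c)] <= NEG_INF / 2})
        raise ValueError(f"residues outside the {params.aa_matrix} alphabet: {bad}")
    return sub


def global_align(a: str, b: str,
                 params: AlignParams = AlignParams()) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring (Gotoh).

    Nucleotide vs amino-acid scoring is chosen from the sequence alphabet;
    mixing the two is rejected. Tie-breaking in the traceback is
    deterministic: diagonal (match/mismatch) over gap-in-``b`` over
    gap-in-``a``.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    kind_a, kind_b = _alphabet(a), _alphabet(b)
    if kind_a != kind_b:
        raise ValueError("mixed alphabets: one sequence looks like DNA, the other protein")
    kind = kind_a
    if kind == "nt":
        go, ge = params.nt_gap_open, params.nt_gap_extend
    else:
        go, ge = params.aa_gap_open, params.aa_gap_extend
    sub = _substitution_scores(a, b, params, kind)
    n, m = len(a), len(b)

    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)   # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG_INF)   # gap in a (consumes b)
    M[0, 0] = 0.0
    idx = np.arange(1, m + 1)
    Iy[0, 1:] = go + (idx - 1) * ge
    col = np.arange(1, n + 1)
    Ix[1:, 0] = go + (col - 1) * ge

    jdx = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub[i - 1] + best_prev[:-1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + go, Ix[i - 1, 1:] + ge)
        base = np.maximum(M[i], Ix[i])
        t = np.maximum.accumulate(base - jdx * ge)
        Iy[i, 1:] = t[:-1] + go + (jdx[1:] - 1) * ge

    # deterministic traceback, preference M > Ix > Iy
    i, j = n, m
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax(finals))          # argmax takes the first maximum
    score = float(finals[state])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:                       # M: diagonal
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:                     # Ix: consume a, gap in b
            out_a.append(a[i - 1])
            out_b.append("-")
            opts = (M[i - 1, j] + go, Ix[i - 1, j] + ge)
            state = 0 if opts[0] >= opts[1] else 1
            i -= 1
        else:                                # Iy: consume b, gap in a
            out_a.append("-")
            out_b.append(b[j - 1])
            opts = (M[i, j - 1] + go, Ix[i, j - 1] + go, Iy[i, j - 1] + ge)
            state = int(np.argmax(opts))
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             score, params)


def percent_identity(aln: PairwiseAlignment,
                     convention: str = "columns") -> float:
    """Percent identity of an alignment.

    ``columns`` divides identities by all alignment columns (gaps count in
    the denominator); ``ungapped`` divides by gap-free columns only.
    """
    if convention not in ("columns", "ungapped"):
        raise ValueError("convention must be columns|ungapped")
    pairs = list(zip(aln.aligned_a, aln.aligned_b))
    ident = sum(1 for x, y in pairs if x == y and x != "-")
    if convention == "columns":
        denom = len(pairs)
    else:
        denom = sum(1 for x, y in pairs if x != "-" and y != "-")
    return 100.0 * ident / denom if denom else 0.0


@dataclass
class IdentityMatrix:
    """Pairwise percent identities: NT above the diagonal, AA below."""

    labels: list[str]
    nt: pd.DataFrame
    aa: pd.DataFrame
    convention: str = "columns"

    def dual_triangle(self) -> pd.DataFrame:
        """Single table: upper triangle NT, lower triangle AA, diagonal 100."""
        k = len(self.labels)
        out = pd.DataFrame(np.full((k, k), 100.0),
                           index=self.labels, columns=self.labels)
        for i in range(k):
            for j in range(k):
                if i < j:
                    out.iloc[i, j] = self.nt.iloc[i, j]
                elif i > j:
                    out.iloc[i, j] = self.aa.iloc[i, j]
        return out


def identity_matrix(nt_seqs: dict[str, str], aa_seqs: dict[str, str],
                    params: AlignParams = AlignParams(),
                    convention: str = "columns") -> IdentityMatrix:
    """All-pairs NT and AA percent identities over global alignments."""
    if set(nt_seqs) != set(aa_seqs):
        raise ValueError("nucleotide and protein label sets differ: "
                         f"{sorted(set(nt_seqs) ^ set(aa_seqs))}")
    labels = list(nt_seqs)
    k = len(labels)
    nt = pd.DataFrame(np.full((k, k), 100.0), index=labels, columns=labels)
    aa = nt.copy()
    for i in range(k):
        for j in range(i + 1, k):
            li, lj = labels[i], labels[j]
            v_nt = round(percent_identity(
                global_align(nt_seqs[li], nt_seqs[lj], params), convention), 1)
            v_aa = round(percent_identity(
                global_align(aa_seqs[li], aa_seqs[lj], params), convention), 1)
            nt.iloc[i, j] = nt.iloc[j, i] = v_nt
            aa.iloc[i, j] = aa.iloc[j, i] = v_aa
    return IdentityMatrix(labels, nt, aa, convention)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(n: TreeNode):
            if n.is_leaf:
                out.append(n.name)
            for c, _ in n.children:
                walk(c)
        walk(self.root)
        return out

    def to_newick(self, precision: int = 4) -> str:
        def fmt(n: TreeNode, length: float | None) -> str:
            if n.is_leaf:
                body = n.name
            else:
                body = "(" + ",".join(fmt(c, l) for c, l in n.children) + ")"
            return body if length is None else f"{body}:{length:.{precision}f}"
        return fmt(self.root, None) + ";"

    def pairwise_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (for additivity checks)."""
        dists: dict[tuple[str, str], float] = {}

        def below(n: TreeNode) -> list[tuple[str, float]]:
            if n.is_leaf:
                return [(n.name, 0.0)]
            groups = []
            for c, length in n.children:
                groups.append([(nm, d + length) for nm, d in below(c)])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for na, da in groups[gi]:
                        for nb, db in groups[gj]:
                            key = tuple(sorted((na, nb)))
                            dists[key] = da + db
            return [x for g in groups for x in g]
        below(self.root)
        return dists


def nj_tree(distances: np.ndarray | pd.DataFrame,
            labels: list[str] | None = None) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion is minimized at each step; among tied pairs the one
    whose (lexicographically smallest member-leaf labels) sort first is
    joined. Negative branch lengths are clamped to 0 with a warning. The
    final two clusters are connected by an edge of their remaining
    distance, split equally for serialization.
    """
    if isinstance(distances, pd.DataFrame):
        if labels is None:
            labels = list(distances.index)
        distances = distances.to_numpy(dtype=float)
    D = np.asarray(distances, dtype=float)
    if labels is None:
        labels = [f"t{i}" for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes = [TreeNode(name=l) for l in labels]
    reps = list(labels)                 # lexicographic representative per cluster

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 2:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        pairs = sorted(
            {tuple(sorted((int(i), int(j)))) for i, j in ties},
            key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))),
        )
        i, j = pairs[0]
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        u = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        du = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D_new = np.zeros((n - 1, n - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = du[keep]
        D = D_new
        rep_u = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [u]
        reps = [reps[k] for k in keep] + [rep_u]

    d = float(D[0, 1])
    a, b = nodes
    if not a.is_leaf:
        a.children.append((b, clamp(d)))
        root = a
    elif not b.is_leaf:
        b.children.append((a, clamp(d)))
        root = b
    else:                               # two-taxon input: split the edge
        root = TreeNode(children=[(a, clamp(d / 2)), (b, clamp(d / 2))])
    return PhyloTree(root)


def tree_from_identity(im: IdentityMatrix) -> PhyloTree:
    """NJ tree on d = 100 − amino-acid percent identity."""
    D = 100.0 - im.aa.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    return nj_tree(D, im.labels)
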