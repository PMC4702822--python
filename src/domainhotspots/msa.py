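"""Progressive multiple sequence alignment of domain instances.

Homologous positions across paralogous domain instances are recovered by a
conventional progressive scheme: k-mer distances feed a UPGMA guide tree,
and partial alignments (profiles) are merged bottom-up with a global
affine-gap dynamic program (Gotoh) scored by BLOSUM80 expected
(frequency-weighted sum-of-pairs) substitution scores.

Conventions, fixed for determinism:

* a gap of length ℓ costs ``gap_open + ℓ·gap_extend`` (subtracted), so the
  first gapped residue already pays both open and extend;
* traceback tie order is diagonal > up > left (up consumes the first
  profile, left the second);
* terminal gaps are penalized like internal gaps unless ``free_end_gaps``;
* UPGMA merge ties break toward the lexicographically smallest member
  instance_id;
* nonstandard residues (B, J, O, U, X, Z) score the matrix minimum against
  everything.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .alignment import GAP, DomainAlignment
from .errors import ValidationError
from .families import DomainFamily
from .io import AA_ALPHABET

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0

_UNKNOWN = len(AA_ALPHABET)  # sentinel index for nonstandard residues
_NEG = -np.inf


class SubstitutionMatrix:
    """Symmetric 20x20 amino-acid log-odds score matrix.

    Internally extended with a 21st row/column holding the matrix minimum,
    used for any residue outside the standard alphabet.
    """

    def __init__(self, alphabet: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(alphabet), len(alphabet)):
            raise ValidationError("score matrix shape does not match alphabet")
        if not np.array_equal(scores, scores.T):
            raise ValidationError("substitution matrix must be symmetric")
        self.alphabet = alphabet
        self.scores = scores
        worst = scores.min()
        ext = np.full((len(alphabet) + 1, len(alphabet) + 1), worst)
        ext[: len(alphabet), : len(alphabet)] = scores
        self._ext = ext
        self._index = {aa: i for i, aa in enumerate(alphabet)}

    @classmethod
    def blosum80(cls) -> "SubstitutionMatrix":
        m = substitution_matrices.load("BLOSUM80")
        idx = [m.alphabet.index(aa) for aa in AA_ALPHABET]
        scores = np.asarray(m)[np.ix_(idx, idx)]
        return cls(AA_ALPHABET, scores)

    def encode(self, seq: str) -> np.ndarray:
        return np.array([self._index.get(aa, _UNKNOWN) for aa in seq], dtype=np.intp)

    def score(self, a: str, b: str) -> float:
        return float(self._ext[self._index.get(a, _UNKNOWN),
                               self._index.get(b, _UNKNOWN)])

    @property
    def extended(self) -> np.ndarray:
        """(21, 21) matrix including the worst-case unknown row/column."""
        return self._ext


_BLOSUM80: SubstitutionMatrix | None = None


def blosum80() -> SubstitutionMatrix:
    global _BLOSUM80
    if _BLOSUM80 is None:
        _BLOSUM80 = SubstitutionMatrix.blosum80()
    return _BLOSUM80


# ---------------------------------------------------------------------------
# affine-gap dynamic program (Gotoh), shared by pairwise and profile paths


def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float,
               free_end_gaps: bool = False) -> tuple[float, str]:
    """Global alignment over a precomputed (n, m) column-pair score matrix.

    Returns the optimal score and the move string over {'D','U','L'} where
    D pairs a column of each side, U consumes side a (gap in b), L consumes
    side b (gap in a). The traceback only ever *selects* among forward
    values computed with identical float operations, so it is exact.
    """
    n, m = S.shape
    go, ge = float(gap_open), float(gap_extend)
    M = np.full((n + 1, m + 1), _NEG)
    Ia = np.full((n + 1, m + 1), _NEG)   # gap in b: vertical ("up") moves
    Ib = np.full((n + 1, m + 1), _NEG)   # gap in a: horizontal ("left") moves
    T = np.full((n + 1, m + 1), _NEG)    # K + j*ge, for horizontal-gap origin
    PM = np.full((n + 1, m + 1), _NEG)   # running prefix max of T per row
    M[0, 0] = 0.0
    jj = np.arange(1, m + 1)
    col_pen = np.arange(m + 1) * ge

    def fill_horizontal(i: int) -> None:
        K = np.maximum(M[i], Ia[i])
        T[i] = K + col_pen
        PM[i] = np.maximum.accumulate(T[i])
        Ib[i, 1:] = PM[i, :-1] - go - jj * ge
        if free_end_gaps and i == 0:
            Ib[0, 1:] = 0.0

    fill_horizontal(0)
    for i in range(1, n + 1):
        Ia[i, 0] = 0.0 if free_end_gaps else -(go + i * ge)
        open_a = np.maximum(M[i - 1], Ib[i - 1]) - go - ge
        Ia[i, 1:] = np.maximum(open_a[1:], Ia[i - 1, 1:] - ge)
        prev = np.maximum(np.maximum(M[i - 1], Ia[i - 1]), Ib[i - 1])
        M[i, 1:] = S[i - 1] + prev[:-1]
        fill_horizontal(i)

    def cell_state(i: int, j: int) -> tuple[float, str]:
        cands = (M[i, j], Ia[i, j], Ib[i, j])
        best = max(cands)
        return best, ("M", "Ia", "Ib")[cands.index(best)]

    # choose the traceback start; with free end gaps the alignment may end
    # anywhere on the last row/column, trailing gaps appended cost-free
    moves: list[str] = []
    i0, j0 = n, m
    if free_end_gaps:
        best_val, _ = cell_state(n, m)
        for i in range(n - 1, -1, -1):
            v, _ = cell_state(i, m)
            if v > best_val:
                best_val, i0, j0 = v, i, m
        for j in range(m - 1, -1, -1):
            v, _ = cell_state(n, j)
            if v > best_val:
                best_val, i0, j0 = v, n, j
        moves.extend("U" * (n - i0))
        moves.extend("L" * (m - j0))
    score, state = cell_state(i0, j0)

    i, j = i0, j0
    while i > 0 or j > 0:
        if j == 0:
            moves.append("U")
            i -= 1
            continue
        if i == 0:
            moves.append("L")
            j -= 1
            continue
        if state == "M":
            moves.append("D")
            i, j = i - 1, j - 1
            if i or j:
                _, state = cell_state(i, j)
        elif state == "Ia":
            v = Ia[i, j]
            moves.append("U")
            i -= 1
            opened = max(M[i, j], Ib[i, j]) - go - ge
            if opened == v:
                state = "M" if M[i, j] >= Ib[i, j] else "Ib"
            else:
                state = "Ia"
        else:  # Ib: gap run opened at column k+1 where PM picked T[k]
            moves.append("L")
            j -= 1
            if T[i, j] == PM[i, j]:
                state = "M" if M[i, j] >= Ia[i, j] else "Ia"
            else:
                state = "Ib"
    moves.reverse()
    return float(score), "".join(moves)


def pairwise_global_align(seq_a: str, seq_b: str,
                          matrix: SubstitutionMatrix | None = None,
                          gap_open: float = DEFAULT_GAP_OPEN,
                          gap_extend: float = DEFAULT_GAP_EXTEND,
                          free_end_gaps: bool = False,
                          ) -> tuple[float, tuple[str, str]]:
    """Optimal global alignment of two sequences under affine gap costs.

    One side may be empty (forcing a single terminal gap); both empty is an
    error. Returns ``(score, (aligned_a, aligned_b))``.
    """
    if not seq_a and not seq_b:
        raise ValidationError("cannot align two empty sequences")
    matrix = matrix or blosum80()
    ea, eb = matrix.encode(seq_a), matrix.encode(seq_b)
    if len(ea) and len(eb):
        S = matrix.extended[np.ix_(ea, eb)]
    else:
        S = np.zeros((len(ea), len(eb)))
    score, moves = _affine_dp(S, gap_open, gap_extend, free_end_gaps)
    out_a, out_b = [], []
    i = j = 0
    for mv in moves:
        if mv == "D":
            out_a.append(seq_a[i]); out_b.append(seq_b[j]); i += 1; j += 1
        elif mv == "U":
            out_a.append(seq_a[i]); out_b.append(GAP); i += 1
        else:
            out_a.append(GAP); out_b.append(seq_b[j]); j += 1
    return score, ("".join(out_a), "".join(out_b))


# ---------------------------------------------------------------------------
# guide tree


def kmer_distance(seq_a: str, seq_b: str, k: int = 3) -> float:
    """Multiset k-mer distance in [0, 1].

    1 − shared_kmers / min(#kmers_a, #kmers_b); falls back to k=1 when a
    sequence is shorter than k. Identical sequences score 0.
    """
    if not seq_a or not seq_b:
        raise ValidationError("kmer_distance requires non-empty sequences")
    if min(len(seq_a), len(seq_b)) < k:
        k = 1
    ca = Counter(seq_a[i: i + k] for i in range(len(seq_a) - k + 1))
    cb = Counter(seq_b[i: i + k] for i in range(len(seq_b) - k + 1))
    shared = sum((ca & cb).values())
    denom = min(len(seq_a), len(seq_b)) - k + 1
    return 1.0 - shared / denom


@dataclass
class GuideTree:
    """Rooted binary guide tree; leaves carry instance ids.

    Internal nodes carry the UPGMA merge height (half the cluster distance);
    heights are non-decreasing toward the root.
    """

    height: float
    leaf_id: str | None = None
    left: "GuideTree | None" = None
    right: "GuideTree | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id is not None

    @property
    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_id]
        return self.left.leaves + self.right.leaves

    @property
    def min_id(self) -> str:
        return min(self.leaves)


def build_guide_tree(ids: list[str], seqs: dict[str, str],
                     distance=kmer_distance) -> GuideTree:
    """UPGMA agglomeration over pairwise distances.

    Merge ties break toward the pair whose (smallest, second-smallest)
    member instance_ids sort lexicographically first; deterministic.
    """
    if len(ids) < 2:
        raise ValidationError("guide tree requires at least 2 instances")
    nodes: dict[str, GuideTree] = {i: GuideTree(0.0, leaf_id=i) for i in ids}
    sizes: dict[str, int] = {i: 1 for i in ids}
    dist: dict[frozenset, float] = {}
    ordered = sorted(ids)
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            dist[frozenset((ordered[a], ordered[b]))] = distance(
                seqs[ordered[a]], seqs[ordered[b]])

    active = set(ids)
    while len(active) > 1:
        best_pair = None
        best_key = None
        for pair, d in dist.items():
            a, b = sorted(pair, key=lambda x: nodes[x].min_id)
            key = (d, nodes[a].min_id, nodes[b].min_id)
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (a, b)
        a, b = best_pair
        d = dist.pop(frozenset((a, b)))
        left, right = (a, b) if nodes[a].min_id <= nodes[b].min_id else (b, a)
        merged = GuideTree(d / 2.0, left=nodes[left], right=nodes[right])
        new_id = merged.min_id
        for other in list(active):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dm = (da * sizes[a] + db * sizes[b]) / (sizes[a] + sizes[b])
            dist[frozenset((new_id, other))] = dm
        active.difference_update((a, b))
        sizes[new_id] = sizes.pop(a) + sizes.pop(b)
        nodes.pop(a)
        nodes.pop(b)
        nodes[new_id] = merged
        active.add(new_id)
    return nodes[active.pop()]


# ---------------------------------------------------------------------------
# profiles and progressive alignment


@dataclass
class Profile:
    """A partial alignment: ordered rows of equal-length gapped strings."""

    rows: list[tuple[str, str]]

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    def frequencies(self, matrix: SubstitutionMatrix) -> np.ndarray:
        """(21, L) residue frequency matrix; gaps drop out of the numerator
        but stay in the denominator, so gap-vs-anything scores zero."""
        L = self.length
        freq = np.zeros((len(matrix.alphabet) + 1, L))
        for _, seq in self.rows:
            for c, ch in enumerate(seq):
                if ch != GAP:
                    freq[matrix._index.get(ch, _UNKNOWN), c] += 1.0
        return freq / len(self.rows)


def align_profiles(profile_a: Profile, profile_b: Profile,
                   matrix: SubstitutionMatrix | None = None,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND,
                   free_end_gaps: bool = False) -> Profile:
    """Merge two profiles by global affine-gap alignment.

    Column pairs score the expected (frequency-weighted sum-of-pairs)
    substitution score; gap mass contributes zero. Single-sequence profiles
    reproduce :func:`pairwise_global_align` exactly.
    """
    matrix = matrix or blosum80()
    fa = profile_a.frequencies(matrix)
    fb = profile_b.frequencies(matrix)
    S = fa.T @ matrix.extended @ fb
    _, moves = _affine_dp(S, gap_open, gap_extend, free_end_gaps)
    new_rows: list[tuple[str, str]] = []
    for rid, seq in profile_a.rows:
        out, i = [], 0
        for mv in moves:
            if mv in ("D", "U"):
                out.append(seq[i]); i += 1
            else:
                out.append(GAP)
        new_rows.append((rid, "".join(out)))
    for rid, seq in profile_b.rows:
        out, j = [], 0
        for mv in moves:
            if mv in ("D", "L"):
                out.append(seq[j]); j += 1
            else:
                out.append(GAP)
        new_rows.append((rid, "".join(out)))
    return Profile(new_rows)


def progressive_align(family: DomainFamily,
                      matrix: SubstitutionMatrix | None = None,
                      gap_open: float = DEFAULT_GAP_OPEN,
                      gap_extend: float = DEFAULT_GAP_EXTEND,
                      free_end_gaps: bool = False) -> DomainAlignment:
    """Align all instances of a family along a UPGMA guide tree.

    Output row order follows the family's instance order. Deterministic:
    identical inputs yield byte-identical alignments.
    """
    if len(family.instances) < 2:
        raise ValidationError(
            f"family {family.domain_acc} has fewer than 2 instances"
        )
    matrix = matrix or blosum80()
    seqs = {i.instance_id: i.sequence for i in family.instances}
    tree = build_guide_tree([i.instance_id for i in family.instances], seqs)

    def merge(node: GuideTree) -> Profile:
        if node.is_leaf:
            return Profile([(node.leaf_id, seqs[node.leaf_id])])
        return align_profiles(merge(node.left), merge(node.right),
                              matrix, gap_open, gap_extend, free_end_gaps)

    prof = merge(tree)
    by_id = dict(prof.rows)
    rows = [(i.instance_id, by_id[i.instance_id]) for i in family.instances]
    return DomainAlignment(domain_acc=family.domain_acc, rows=rows)


def load_external_alignment(path, family: DomainFamily) -> DomainAlignment:
    """Load a precomputed aligned FASTA for a family (curated alignments).

    Row ids must match the family's instance ids exactly and each degapped
    row must equal its instance sequence.
    """
    from .io import read_aligned_fasta

    aln = read_aligned_fasta(path, domain_acc=family.domain_acc)
    have = set(aln.row_ids)
    want = {i.instance_id for i in family.instances}
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValidationError(
            f"alignment rows do not match instances of {family.domain_acc}: "
            f"missing {missing}, unexpected {extra}"
        )
    for inst in family.instances:
        if aln.ungapped(inst.instance_id) != inst.sequence:
            raise ValidationError(
                f"row {inst.instance_id} does not match its instance sequence"
            )
    by_id = dict(aln.rows)
    rows = [(i.instance_id, by_id[i.instance_id]) for i in family.instances]
    return DomainAlignment(domain_acc=family.domain_acc, rows=rows)
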