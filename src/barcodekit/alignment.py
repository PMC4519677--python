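"""Native multiple alignment for barcode sequences.

A global (Needleman-Wunsch/Gotoh) pairwise aligner with affine gap costs and
a progressive profile aligner built on it: pairwise p-distances feed a UPGMA
guide tree (scipy linkage), and profiles are merged in guide-tree order with
the same affine DP over expected column scores.  Chloroplast barcodes are
nearly gap-free coding sequence, so this deliberately simple scheme (no
iterative refinement) is adequate; externally produced alignments are
accepted as first-class input via :func:`ingest_alignment`.

Scoring conventions: a gap of length L costs ``gap_open + (L-1)*gap_extend``
(both negative); N scores as a mismatch against everything, including N.
Traceback ties resolve diagonal > up > left, and guide-tree ties follow
input order, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from .errors import AlignmentError, SpeciesMapError
from .seqio import LabeledAlignment, read_fasta

_CODE = {c: i for i, c in enumerate("ACGTN-")}
NEG = -1e30  # acts as -inf without nan propagation


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0   # cost of a gap's first base
    gap_extend: float = -1.0  # cost of each further base

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0 <= self.match):
            raise AlignmentError(
                "require gap_open <= gap_extend <= 0 <= match "
                f"(got {self.gap_open}, {self.gap_extend}, {self.match})"
            )

    def substitution_matrix(self) -> np.ndarray:
        """6x6 expected-score matrix over A,C,G,T,N,- used for profiles.

        Base-base: match/mismatch with N mismatching everything.  A residue
        against an existing profile gap scores ``gap_extend``; gap-gap
        scores 0 (those columns carry no signal).
        """
        s = np.full((6, 6), self.mismatch)
        for i in range(4):
            s[i, i] = self.match
        s[4, :] = s[:, 4] = self.mismatch  # N
        s[5, :] = s[:, 5] = self.gap_extend
        s[5, 5] = 0.0
        return s


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Column base-frequency matrix, shape (L, 6)."""
    enc = np.stack([_encode(r) for r in rows])
    prof = np.zeros((enc.shape[1], 6))
    for k in range(6):
        prof[:, k] = (enc == k).mean(axis=0)
    return prof


def _affine_dp(score: np.ndarray, open_: float, ext: float
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill Gotoh matrices for a precomputed (n, m) column-score matrix.

    M: last column is a substitution; X: gap in the second sequence (up);
    Y: gap in the first (left).  Rows are vectorized; the within-row Y
    recurrence is solved with a prefix-max scan.
    """
    n, m = score.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    js = np.arange(1, m + 1)
    Y[0, 1:] = open_ + (js - 1) * ext
    is_ = np.arange(1, n + 1)
    X[1:, 0] = open_ + (is_ - 1) * ext
    for i in range(1, n + 1):
        diag = np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        M[i, 1:] = score[i - 1] + diag
        X[i, 1:] = np.maximum.reduce([
            M[i - 1, 1:] + open_, X[i - 1, 1:] + ext, Y[i - 1, 1:] + open_,
        ])
        X[i, 0] = open_ + (i - 1) * ext
        # Y[i, j] = max(base[j-1] + open, Y[i, j-1] + ext), base = max(M, X)
        base = np.maximum(M[i, :-1], X[i, :-1])
        z = np.maximum.accumulate(base + open_ - ext * js)
        Y[i, 1:] = z + ext * js
    return M, X, Y


def _traceback(M: np.ndarray, X: np.ndarray, Y: np.ndarray, score: np.ndarray,
               open_: float, ext: float) -> list[str]:
    """Recover the operation list ('D' diag, 'U' up, 'L' left), 5'→3'.

    Ties resolve diagonal > up > left at every step.  Scores are sums of a
    few small floats, so exact equality comparisons are safe here given the
    half-ulp-free inputs; a tiny tolerance guards against accumulation.
    """
    n, m = score.shape
    tol = 1e-9
    i, j = n, m
    vals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(vals))  # argmax takes first max: M > X > Y
    ops: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            ops.append("L"); j -= 1; continue
        if j == 0:
            ops.append("U"); i -= 1; continue
        if state == 0:  # M: consumed both
            ops.append("D")
            target = M[i, j] - score[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, v in ((0, M[i, j]), (1, X[i, j]), (2, Y[i, j])):
                if abs(v - target) <= tol:
                    state = cand
                    break
        elif state == 1:  # X: gap in second sequence (up)
            ops.append("U")
            target = X[i, j]
            i -= 1
            for cand, v in ((0, M[i, j] + open_), (1, X[i, j] + ext),
                            (2, Y[i, j] + open_)):
                if abs(v - target) <= tol:
                    state = cand
                    break
        else:  # Y: gap in first sequence (left)
            ops.append("L")
            target = Y[i, j]
            j -= 1
            for cand, v in ((0, M[i, j] + open_), (1, X[i, j] + ext),
                            (2, Y[i, j] + open_)):
                if abs(v - target) <= tol:
                    state = cand
                    break
    ops.reverse()
    return ops


def pairwise_align(a: str, b: str, params: AlignParams | None = None
                   ) -> tuple[str, str, float]:
    """Optimal global alignment of two ungapped sequences.

    Returns the two gapped strings and the optimal score.
    """
    params = params or AlignParams()
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    if "-" in a or "-" in b:
        raise AlignmentError("pairwise_align expects ungapped input")
    sub = params.substitution_matrix()
    ea, eb = _encode(a), _encode(b)
    score = sub[np.ix_(ea, eb)]
    M, X, Y = _affine_dp(score, params.gap_open, params.gap_extend)
    best = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    ops = _traceback(M, X, Y, score, params.gap_open, params.gap_extend)
    ga, gb = [], []
    i = j = 0
    for op in ops:
        if op == "D":
            ga.append(a[i]); gb.append(b[j]); i += 1; j += 1
        elif op == "U":
            ga.append(a[i]); gb.append("-"); i += 1
        else:
            ga.append("-"); gb.append(b[j]); j += 1
    return "".join(ga), "".join(gb), best


def _merge_profiles(rows_a: list[str], rows_b: list[str], params: AlignParams
                    ) -> list[str]:
    """Align two sub-alignments (profile vs profile) and merge their rows."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    sub = params.substitution_matrix()
    score = pa @ sub @ pb.T
    M, X, Y = _affine_dp(score, params.gap_open, params.gap_extend)
    ops = _traceback(M, X, Y, score, params.gap_open, params.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == "D":
            for k, r in enumerate(rows_a):
                out_a[k] += r[i]
            for k, r in enumerate(rows_b):
                out_b[k] += r[j]
            i += 1; j += 1
        elif op == "U":
            for k, r in enumerate(rows_a):
                out_a[k] += r[i]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[j]
            j += 1
    return out_a + out_b


def _p_distance_pair(ga: str, gb: str) -> float:
    """Observed difference proportion over gap-free column pairs."""
    pairs = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(x != y for x, y in pairs) / len(pairs)


def progressive_msa(seqs: Mapping[str, str],
                    species_of: Mapping[str, str] | None = None,
                    params: AlignParams | None = None) -> LabeledAlignment:
    """Progressive multiple alignment in UPGMA guide-tree order.

    Guide distances are p-distances of the optimal pairwise alignments.
    With a single input sequence pair this reduces to :func:`pairwise_align`.
    All-gap columns are never produced (each merged column draws a residue
    from at least one profile); residues of every input sequence are
    conserved.
    """
    params = params or AlignParams()
    ids = list(seqs)
    n = len(ids)
    if n < 2:
        raise AlignmentError("progressive_msa requires at least 2 sequences")
    # condensed pairwise guide distances
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, _ = pairwise_align(seqs[ids[i]], seqs[ids[j]], params)
            cond.append(_p_distance_pair(ga, gb))
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(n)
    }
    if n == 2:
        merges = [(0, 1)]
    else:
        merges = [(int(a), int(b)) for a, b, _, _ in linkage(np.asarray(cond),
                                                             method="average")]
    nxt = n
    for a, b in merges:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        merged_rows = _merge_profiles(rows_a, rows_b, params)
        clusters[nxt] = (ids_a + ids_b, merged_rows)
        nxt += 1
    (final_ids, final_rows), = clusters.values()
    # restore input order
    order = {sid: k for k, sid in enumerate(final_ids)}
    rows = [final_rows[order[sid]] for sid in ids]
    if species_of is None:
        species_of = {sid: sid for sid in ids}
    return LabeledAlignment(ids=list(ids), rows=rows,
                            species_of={sid: species_of[sid] for sid in ids})


def ingest_alignment(path, species_of: Mapping[str, str]) -> LabeledAlignment:
    """Load a pre-aligned gapped FASTA and attach species labels.

    Ragged rows or an unlabeled ID raise a named error; the file is
    otherwise taken verbatim (orientation and columns are authoritative).
    """
    seqs = read_fasta(path, allow_gaps=True)
    missing = [sid for sid in seqs if sid not in species_of]
    if missing:
        raise SpeciesMapError(f"unlabeled sample(s) in alignment: {missing}")
    return LabeledAlignment(
        ids=list(seqs),
        rows=list(seqs.values()),
        species_of={sid: species_of[sid] for sid in seqs},
    )
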