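"""Pairwise Kimura 2-parameter (K2P) and p-distances from an alignment.

K2P corrects observed divergence with separate transition (P) and
transversion (Q) proportions:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Columns where either row carries a gap or N are excluded pair by pair
(pairwise deletion), so ragged-ended barcodes keep their informative
overlap; the per-pair count of compared sites is retained for audit.
Saturated pairs (either log argument <= 0) surface as an explicit error or
NaN flag, never as a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SaturationError, UndefinedDistanceError
from .seqio import LabeledAlignment

_CODE = {c: i for i, c in enumerate("ACGTN-")}


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion proportions over the compared sites of a pair."""

    P: float  # transition proportion (A<->G, C<->T)
    Q: float  # transversion proportion
    n: int    # compared (gap- and N-free) sites

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise UndefinedDistanceError(f"invalid proportions P={self.P}, Q={self.Q}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair compared-site counts.

    ``d`` holds NaN for undefined (saturated or zero-overlap) pairs when
    built in non-strict mode.
    """

    labels: list[str]
    d: np.ndarray
    sites_used: np.ndarray | None
    model: str

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.d).any())


def _encode_rows(rows: list[str]) -> np.ndarray:
    return np.array([[_CODE[c] for c in r] for r in rows], dtype=np.int8)


def pair_counts(row_a: str, row_b: str) -> PairCounts:
    """Count transitions and transversions between two equal-length gapped
    rows under pairwise deletion of gap/N columns.

    Raises :class:`UndefinedDistanceError` when no column is comparable.
    """
    if len(row_a) != len(row_b):
        raise UndefinedDistanceError("rows differ in length")
    a = np.array([_CODE[c] for c in row_a], dtype=np.int8)
    b = np.array([_CODE[c] for c in row_b], dtype=np.int8)
    usable = (a < 4) & (b < 4)
    n = int(usable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites (all gap/N)")
    a, b = a[usable], b[usable]
    differ = a != b
    # purines encode to {0:A, 2:G}; pyrimidines to {1:C, 3:T}; a change within
    # the same parity class is a transition.
    transition = differ & ((a % 2) == (b % 2))
    P = int(transition.sum()) / n
    Q = int((differ & ~transition).sum()) / n
    return PairCounts(P=P, Q=Q, n=n)


def k2p(counts: PairCounts) -> float:
    """Kimura's two-parameter distance for one pair.

    Raises :class:`SaturationError` when the correction is undefined.
    """
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair: P={counts.P:.4f}, Q={counts.Q:.4f}"
        )
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


def p_distance(counts: PairCounts) -> float:
    """Observed proportion of differing sites."""
    return counts.P + counts.Q


def _pairwise_pq(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs P, Q proportions and site counts via broadcasting.

    ``enc`` is the (n_rows, n_cols) encoded alignment.  Returns (P, Q, n)
    matrices of shape (n_rows, n_rows); entries with n == 0 are NaN.
    """
    usable = enc < 4
    both = usable[:, None, :] & usable[None, :, :]
    n = both.sum(axis=2)
    differ = (enc[:, None, :] != enc[None, :, :]) & both
    same_parity = (enc[:, None, :] % 2) == (enc[None, :, :] % 2)
    ts = (differ & same_parity).sum(axis=2)
    tv = differ.sum(axis=2) - ts
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(n > 0, ts / np.maximum(n, 1), np.nan)
        Q = np.where(n > 0, tv / np.maximum(n, 1), np.nan)
    return P, Q, n


def k2p_matrix_from_pq(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Vectorized K2P; undefined entries become NaN."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -0.5 * np.log(np.where((w1 > 0) & (w2 > 0), w1 * np.sqrt(np.abs(w2)), np.nan))
    return d + 0.0  # normalizes -0.0 from identical pairs


def distance_matrix(aln: LabeledAlignment, model: str = "K2P",
                    strict: bool = True) -> DistanceMatrix:
    """Compute all pairwise distances of an alignment.

    model:  "K2P" or "p".
    strict: raise on any undefined pair; otherwise leave NaN entries.
    """
    if len(aln) < 2:
        raise UndefinedDistanceError("need at least 2 rows")
    if model not in ("K2P", "p"):
        raise ValueError(f"unknown model {model!r}")
    enc = _encode_rows(aln.rows)
    P, Q, n = _pairwise_pq(enc)
    if model == "K2P":
        d = k2p_matrix_from_pq(P, Q)
    else:
        d = P + Q
    np.fill_diagonal(d, 0.0)
    if strict and np.isnan(d).any():
        bad = [
            (aln.ids[i], aln.ids[j])
            for i, j in zip(*np.where(np.isnan(d))) if i < j
        ]
        raise UndefinedDistanceError(f"undefined distance for pair(s) {bad}")
    return DistanceMatrix(labels=list(aln.ids), d=d, sites_used=n, model=model)
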