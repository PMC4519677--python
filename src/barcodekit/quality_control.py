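"""Sequence acceptance rules for single-direction barcode reads.

Three criteria, applied in order:

(i)   end trimming — bases are deleted from each end until the retained
      stretch is bounded by runs of ``window`` consecutive bases whose PHRED
      scores are all strictly above ``window_min_phred``;
(ii)  masking — every retained base with a score strictly below
      ``mask_below_phred`` is recorded as N;
(iii) rejection — a read whose retained stretch contains more than
      ``max_n_fraction`` N calls (or no qualifying window at all) is deleted.

The thresholds are deliberately asymmetric at the boundary score of 20:
a score of exactly 20 cannot anchor a trim window (criterion i is strict
">20") but is kept unmasked (criterion ii is strict "<20").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BarcodeKitError
from .seqio import MAX_PHRED, QualitySequence

REASON_NO_WINDOW = "no qualifying window"
REASON_N_FRACTION = "n_fraction above threshold"


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the three acceptance criteria.

    window:           run length of the trim criterion (bases).
    window_min_phred: trim threshold; a run qualifies when every score is
                      strictly greater than this.
    mask_below_phred: masking threshold; bases strictly below become N.
    max_n_fraction:   rejection bound; reads with N fraction strictly above
                      it are deleted.
    """

    window: int = 10
    window_min_phred: int = 20
    mask_below_phred: int = 20
    max_n_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.window < 1:
            raise BarcodeKitError("window must be >= 1")
        for t in (self.window_min_phred, self.mask_below_phred):
            if not 0 <= t <= MAX_PHRED:
                raise BarcodeKitError(f"PHRED threshold {t} outside [0, {MAX_PHRED}]")
        if not 0 < self.max_n_fraction <= 1:
            raise BarcodeKitError("max_n_fraction must be in (0, 1]")


@dataclass(frozen=True)
class QCResult:
    """Outcome of the full QC pass for one read."""

    sample_id: str
    status: str  # "accepted" | "rejected"
    sequence: QualitySequence
    masked_count: int
    n_fraction: float
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def _qualifying_interval(scores: np.ndarray, window: int, min_phred: int
                         ) -> tuple[int, int] | None:
    """Return the maximal interval bounded by the outermost qualifying
    windows (first window start to last window end), or None."""
    n = scores.size
    if n < window:
        return None
    ok = scores > min_phred
    wins = np.lib.stride_tricks.sliding_window_view(ok, window).all(axis=1)
    starts = np.flatnonzero(wins)
    if starts.size == 0:
        return None
    return int(starts[0]), int(starts[-1]) + window


def trim_ends(qseq: QualitySequence, params: QCParams) -> QualitySequence:
    """Criterion (i): delete bases from both ends until the read is bounded
    by runs of ``window`` bases all scoring above ``window_min_phred``.

    The retained interval spans from the first such run's start to the last
    such run's end; if no run exists the retained interval is empty (the
    read will be rejected downstream).  Trimming decisions use the raw
    scores, never masked bases.
    """
    interval = _qualifying_interval(qseq.scores, params.window, params.window_min_phred)
    off = qseq.trimmed_range[0]
    if interval is None:
        return QualitySequence(qseq.sample_id, "", (), (off, off))
    s, e = interval
    return QualitySequence(
        qseq.sample_id, qseq.bases[s:e], qseq.phred[s:e], (off + s, off + e)
    )


def mask_low_quality(qseq: QualitySequence, params: QCParams) -> tuple[QualitySequence, int]:
    """Criterion (ii): record retained bases scoring strictly below
    ``mask_below_phred`` as N.  Returns the masked read and the count of
    newly masked (previously non-N) bases."""
    bases = np.frombuffer(qseq.bases.encode(), dtype="S1").copy()
    low = qseq.scores < params.mask_below_phred
    newly = int(np.count_nonzero(low & (bases != b"N")))
    bases[low] = b"N"
    return (
        QualitySequence(qseq.sample_id, bases.tobytes().decode(), qseq.phred,
                        qseq.trimmed_range),
        newly,
    )


def accept_or_reject(qseq: QualitySequence, params: QCParams,
                     masked_count: int = 0) -> QCResult:
    """Criterion (iii): reject when the retained interval is empty or the N
    fraction strictly exceeds ``max_n_fraction``.  Input N's count toward
    the fraction identically to masked N's."""
    if len(qseq) == 0:
        return QCResult(qseq.sample_id, "rejected", qseq, masked_count, 0.0,
                        REASON_NO_WINDOW)
    nf = qseq.n_fraction
    if nf > params.max_n_fraction:
        return QCResult(qseq.sample_id, "rejected", qseq, masked_count, nf,
                        REASON_N_FRACTION)
    return QCResult(qseq.sample_id, "accepted", qseq, masked_count, nf)


def run_qc(qseq: QualitySequence, params: QCParams | None = None) -> QCResult:
    """Apply criteria (i)-(iii) in order to one read."""
    params = params or QCParams()
    trimmed = trim_ends(qseq, params)
    masked, count = mask_low_quality(trimmed, params)
    return accept_or_reject(masked, params, count)


def run_qc_batch(qseqs: dict[str, QualitySequence],
                 params: QCParams | None = None) -> dict[str, QCResult]:
    return {sid: run_qc(q, params) for sid, q in qseqs.items()}
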