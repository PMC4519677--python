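"""In-silico PCR: primer binding-site search, amplicon prediction, and the
marker-by-species specificity matrix.

Binding is modelled as (near-)exact hybridization: at most ``max_mismatch``
mismatches overall and zero mismatches in the 3'-terminal ``clamp`` bases
(3' mismatches abolish polymerase extension).  The default is fully exact
matching, which is what a clean single gel band implies.  N in a template
never matches any primer base.

Amplicon lengths are inclusive of both primer footprints, the gel-facing
convention: product = (rightmost template base of the reverse footprint) -
(leftmost base of the forward footprint) + 1.

Because chloroplast markers are maternally inherited, presence/absence of
species markers on a hybrid's template identifies the seed parent; the
other candidate parent is then the pollen donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import BarcodeKitError
from .marker_design import MarkerPair
from .seqio import revcomp

_CODE = {c: i for i, c in enumerate("ACGTN")}


@dataclass(frozen=True)
class PCRParams:
    max_mismatch: int = 0
    clamp: int = 3  # 3'-terminal bases that must match exactly
    max_product: int = 5000


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str  # "plus" | "minus"
    start: int  # leftmost plus-strand position of the footprint (0-based)
    length: int
    mismatches: int
    three_prime_clamp_ok: bool = True

    @property
    def end(self) -> int:
        """Half-open right edge of the footprint on the plus strand."""
        return self.start + self.length


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise BarcodeKitError(f"illegal template/primer character {exc}") from exc


def _scan(primer_enc: np.ndarray, template_enc: np.ndarray, max_mismatch: int,
          clamp_right: bool, clamp: int) -> list[tuple[int, int]]:
    """All start positions where primer matches template with <= max_mismatch
    mismatches and an exact 3' clamp.  ``clamp_right`` says whether the
    primer's 3' end maps to the right edge of the window.  Template N never
    matches."""
    k = primer_enc.size
    L = template_enc.size
    if L < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template_enc, k)
    mism = (windows != primer_enc) | (windows == _CODE["N"])
    total = mism.sum(axis=1)
    clamp = min(clamp, k)
    clamp_zone = mism[:, -clamp:] if clamp_right else mism[:, :clamp]
    ok = (total <= max_mismatch) & ~clamp_zone.any(axis=1)
    return [(int(s), int(total[s])) for s in np.flatnonzero(ok)]


def find_binding_sites(primer: str, template: str, template_id: str = "template",
                       params: PCRParams | None = None) -> list[BindingSite]:
    """Forward (plus-strand) and reverse (minus-strand) binding sites of one
    primer on an ungapped template."""
    params = params or PCRParams()
    if "-" in template:
        raise BarcodeKitError("template must be ungapped")
    t = _encode(template)
    p = _encode(primer)
    sites = []
    for start, mm in _scan(p, t, params.max_mismatch, True, params.clamp):
        sites.append(BindingSite(template_id, "plus", start, len(primer), mm))
    # a minus-strand site: the primer's reverse complement on the plus strand;
    # the primer's 3' end then maps to the footprint's LEFT edge
    prc = _encode(revcomp(primer))
    for start, mm in _scan(prc, t, params.max_mismatch, False, params.clamp):
        sites.append(BindingSite(template_id, "minus", start, len(primer), mm))
    return sites


@dataclass(frozen=True)
class AmpliconPrediction:
    marker: str
    template_id: str
    product_length: int
    fwd_site: BindingSite
    rev_site: BindingSite


def predict_amplicons(fwd: str, rev: str, template: str,
                      template_id: str = "template",
                      marker: str = "marker",
                      params: PCRParams | None = None) -> list[AmpliconPrediction]:
    """All products of a forward/reverse primer pair on one template.

    Every pairing of a plus-strand forward site with a downstream
    minus-strand reverse site yields a product up to ``max_product`` bp.
    """
    params = params or PCRParams()
    f_sites = [s for s in find_binding_sites(fwd, template, template_id, params)
               if s.strand == "plus"]
    r_sites = [s for s in find_binding_sites(rev, template, template_id, params)
               if s.strand == "minus"]
    out = []
    for fs in f_sites:
        for rs in r_sites:
            if rs.start < fs.start or rs.end < fs.end:
                continue
            length = rs.end - fs.start  # inclusive of both footprints
            if length < max(fs.length, rs.length) or length > params.max_product:
                continue
            out.append(AmpliconPrediction(marker, template_id, length, fs, rs))
    out.sort(key=lambda a: (a.product_length, a.fwd_site.start))
    return out


def predict_pool(primers: Mapping[str, str], template: str,
                 template_id: str = "template",
                 params: PCRParams | None = None) -> list[AmpliconPrediction]:
    """Products formed by ANY ordered primer combination in a pooled
    (multiplex) reaction, including a primer acting on both strands.

    This is what reveals extra gel bands from cross-binding primers."""
    params = params or PCRParams()
    names = list(primers)
    out: list[AmpliconPrediction] = []
    seen = set()
    for na in names:
        for nb in names:
            for amp in predict_amplicons(primers[na], primers[nb], template,
                                         template_id, f"{na}+{nb}", params):
                key = (amp.fwd_site.start, amp.fwd_site.length,
                       amp.rev_site.start, amp.rev_site.length)
                if key not in seen:
                    seen.add(key)
                    out.append(amp)
    out.sort(key=lambda a: (a.product_length, a.fwd_site.start))
    return out


@dataclass
class SpecificityMatrix:
    """Marker-by-sample table of predicted product lengths (ascending;
    an empty cell means no band)."""

    marker_names: list[str]
    sample_ids: list[str]
    species_of: dict[str, str]
    cells: dict[tuple[str, str], tuple[int, ...]]  # (marker, sample) -> lengths
    target_of: dict[str, str]  # marker -> target species

    def bands(self, marker: str, sample: str) -> tuple[int, ...]:
        return self.cells[(marker, sample)]

    def is_specific(self, marker: str) -> bool:
        """Exactly one product on every target-species sample, none elsewhere."""
        target = self.target_of[marker]
        for sid in self.sample_ids:
            n = len(self.cells[(marker, sid)])
            if self.species_of[sid] == target:
                if n != 1:
                    return False
            elif n != 0:
                return False
        return True

    def is_diagonal(self) -> bool:
        return all(self.is_specific(m) for m in self.marker_names)

    def to_dataframe(self):
        import pandas as pd

        data = {
            sid: [",".join(map(str, self.cells[(m, sid)])) for m in self.marker_names]
            for sid in self.sample_ids
        }
        return pd.DataFrame(data, index=self.marker_names)


def specificity_matrix(markers: Sequence[MarkerPair], templates: Mapping[str, str],
                       species_of: Mapping[str, str],
                       params: PCRParams | None = None) -> SpecificityMatrix:
    """Run every marker against every template and tabulate band sizes."""
    if not markers or not templates:
        raise BarcodeKitError("need at least one marker and one template")
    params = params or PCRParams()
    cells = {}
    for m in markers:
        for sid, tpl in templates.items():
            amps = predict_amplicons(m.forward.sequence, m.reverse.sequence,
                                     tpl, sid, m.name, params)
            cells[(m.name, sid)] = tuple(sorted(a.product_length for a in amps))
    return SpecificityMatrix(
        marker_names=[m.name for m in markers],
        sample_ids=list(templates),
        species_of={sid: species_of[sid] for sid in templates},
        cells=cells,
        target_of={m.name: m.target_species for m in markers},
    )


def infer_maternal_parent(hybrid_template: str,
                          candidate_markers: Mapping[str, MarkerPair],
                          params: PCRParams | None = None
                          ) -> tuple[str | None, dict[str, int]]:
    """Infer the seed (maternal) parent of a hybrid from marker presence.

    ``candidate_markers`` maps candidate parent species to their specific
    marker.  Returns (species, band counts per species); species is None
    (inconclusive) when zero or more than one candidate marker amplifies.
    """
    if len(candidate_markers) < 2:
        raise BarcodeKitError("need markers for at least 2 candidate parents")
    params = params or PCRParams()
    bands = {}
    for sp, m in candidate_markers.items():
        amps = predict_amplicons(m.forward.sequence, m.reverse.sequence,
                                 hybrid_template, "hybrid", m.name, params)
        bands[sp] = len(amps)
    amplifying = [sp for sp, n in bands.items() if n > 0]
    if len(amplifying) == 1:
        return amplifying[0], bands
    return None, bands
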