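"""Species-specific PCR marker design anchored on diagnostic alignment sites.

A diagnostic site is an alignment column whose state is fixed (unanimous
and unambiguous) in the target species and absent from every other species
in the reference alignment.  Primer pairs are designed so that at least one
primer places its 3'-terminal base on such a site — a 3' mismatch on
non-target templates blocks extension, which is what makes the marker
species-specific.  Candidate pairs are screened for melting-temperature
agreement, primer-primer 3' complementarity and hairpins, and ranked;
amplicon lengths can be staggered across species so several markers can be
read out side by side on one gel.

Melting temperatures use nearest-neighbor thermodynamics through Biopython.
The default :class:`ThermoParams` (Breslauer 1986 stacking parameters,
Schildkraut-Lifson salt correction, 54 mM Na+, 5 uM per primer strand) was
calibrated once against a reference panel of published primer Tm values
(see ``scripts/calibrate_tm.py``) and is not meant to be tuned per run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

from .errors import DesignError
from .seqio import LabeledAlignment, revcomp

NN_TABLES = {
    "breslauer1986": mt.DNA_NN1,
    "sugimoto1996": mt.DNA_NN2,
    "santalucia1997": mt.DNA_NN3,
    "santalucia2004": mt.DNA_NN4,
}


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor duplex Tm settings (concentrations in nM, salts mM)."""

    nn_table: str = "breslauer1986"
    Na: float = 54.0
    K: float = 0.0
    Mg: float = 0.0
    dNTPs: float = 0.0
    dnac1: float = 5000.0
    dnac2: float = 5000.0
    saltcorr: int = 1  # Schildkraut-Lifson 16.6*log10([Na+])


def melting_temperature(primer: str, thermo: ThermoParams | None = None) -> float:
    """Nearest-neighbor duplex Tm in Celsius, reported to 1 decimal.

    Only unambiguous A/C/G/T primers of length >= 8 are accepted.
    """
    thermo = thermo or ThermoParams()
    if len(primer) < 8:
        raise DesignError(f"primer too short for a duplex Tm: {primer!r}")
    if set(primer) - set("ACGT"):
        raise DesignError(f"ambiguous base in primer {primer!r}")
    tm = mt.Tm_NN(
        primer,
        nn_table=NN_TABLES[thermo.nn_table],
        Na=thermo.Na, K=thermo.K, Mg=thermo.Mg, dNTPs=thermo.dNTPs,
        dnac1=thermo.dnac1, dnac2=thermo.dnac2,
        saltcorr=thermo.saltcorr,
    )
    return round(float(tm), 1)


@dataclass(frozen=True)
class DiagnosticSite:
    """An alignment column fixed in the target species and absent elsewhere."""

    column: int  # 0-based alignment column
    target_species: str
    target_state: str
    background_states: frozenset[str]
    background_ambiguous: bool = False  # N or gap seen in the background

    def __post_init__(self) -> None:
        if self.target_state in self.background_states:
            raise DesignError("target state present in background")


@dataclass(frozen=True)
class PrimerCandidate:
    name: str
    sense: str  # "F" | "R"
    sequence: str  # 5'->3'
    span: tuple[int, int]  # alignment columns, half-open
    tm_celsius: float
    anchored: bool

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MarkerPair:
    name: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    target_species: str
    expected_size: int
    annealing_temp: float

    @property
    def primers(self) -> tuple[PrimerCandidate, PrimerCandidate]:
        return (self.forward, self.reverse)


@dataclass(frozen=True)
class DesignConstraints:
    primer_len_min: int = 17
    primer_len_max: int = 27
    tm_min: float = 50.0
    tm_max: float = 68.0
    delta_tm_max: float = 5.0
    product_min: int = 150
    product_max: int = 800
    size_target: int | None = None
    interaction_threshold: int = 5
    max_candidates: int = 10
    annealing_offset: float = 0.0  # added to min primer Tm for the default
    strict_background: bool = False  # drop sites with background N/gap
    thermo: ThermoParams = field(default_factory=ThermoParams)


# ---------------------------------------------------------------------------
# diagnostic sites


def find_diagnostic_sites(aln: LabeledAlignment, target_species: str,
                          strict: bool = False) -> list[DiagnosticSite]:
    """Columns where every target sequence carries one unambiguous base that
    no non-target sequence carries.

    Intraspecific polymorphism disqualifies a column (fixation in the target
    is required, so a marker amplifies every target genotype).  Background
    N/gap never *matches* the target state, but such columns are flagged
    ``background_ambiguous`` and dropped entirely when ``strict``.
    """
    if len(aln.species_list) < 2:
        raise DesignError("need at least 2 species to find diagnostic sites")
    t_rows = aln.rows_for_species(target_species)
    if not t_rows:
        raise DesignError(f"no sequences for target species {target_species!r}")
    b_rows = [r for sid, r in zip(aln.ids, aln.rows)
              if aln.species_of[sid] != target_species]
    code = {c: i for i, c in enumerate("ACGTN-")}
    t = np.array([[code[c] for c in r] for r in t_rows], dtype=np.int8)
    b = np.array([[code[c] for c in r] for r in b_rows], dtype=np.int8)
    fixed = (t == t[0]).all(axis=0) & (t[0] < 4)
    present_in_bg = (b == t[0]).any(axis=0)
    ambiguous = (b >= 4).any(axis=0)
    keep = fixed & ~present_in_bg
    if strict:
        keep &= ~ambiguous
    alphabet = "ACGTN-"
    sites = []
    for c in np.flatnonzero(keep):
        bg = frozenset(alphabet[k] for k in np.unique(b[:, c]))
        sites.append(DiagnosticSite(
            column=int(c),
            target_species=target_species,
            target_state=alphabet[t[0, c]],
            background_states=bg,
            background_ambiguous=bool(ambiguous[c]),
        ))
    return sites


# ---------------------------------------------------------------------------
# primer/pair enumeration


class _TargetTemplate:
    """Per-target-species view of the alignment used by the enumerators."""

    def __init__(self, aln: LabeledAlignment, target_species: str):
        self.rows = aln.rows_for_species(target_species)
        ncol = aln.column_count
        code = {c: i for i, c in enumerate("ACGTN-")}
        enc = np.array([[code[c] for c in r] for r in self.rows], dtype=np.int8)
        self.valid = (enc == enc[0]).all(axis=0) & (enc[0] < 4)
        self.consensus = self.rows[0]
        # cumulative non-gap counts per row for product-length arithmetic
        self.cum = np.stack([
            np.concatenate([[0], np.cumsum([c != "-" for c in r])])
            for r in self.rows
        ])
        self._valid_prefix = np.concatenate([[0], np.cumsum(self.valid)])
        self.ncol = ncol

    def window_valid(self, s: int, e: int) -> bool:
        return bool(self._valid_prefix[e] - self._valid_prefix[s] == e - s)

    def window_seq(self, s: int, e: int) -> str:
        return self.consensus[s:e]

    def product_size(self, f_start: int, r_end: int) -> int | None:
        """Ungapped template length from forward 5' to reverse 5' inclusive;
        None when target genotypes disagree (an indel between the primers)."""
        sizes = self.cum[:, r_end] - self.cum[:, f_start]
        if not (sizes == sizes[0]).all():
            return None
        return int(sizes[0])


def _tm_cached(seq: str, thermo: ThermoParams, cache: dict[str, float]) -> float:
    tm = cache.get(seq)
    if tm is None:
        tm = melting_temperature(seq, thermo)
        cache[seq] = tm
    return tm


def _anchored_windows(tpl: _TargetTemplate, sites: Sequence[DiagnosticSite],
                      sense: str, cons: DesignConstraints,
                      cache: dict[str, float]) -> list[PrimerCandidate]:
    out = []
    for site in sites:
        c = site.column
        for L in range(cons.primer_len_min, cons.primer_len_max + 1):
            s, e = (c - L + 1, c + 1) if sense == "F" else (c, c + L)
            if s < 0 or e > tpl.ncol or not tpl.window_valid(s, e):
                continue
            seq = tpl.window_seq(s, e)
            if sense == "R":
                seq = revcomp(seq)
            tm = _tm_cached(seq, cons.thermo, cache)
            if not cons.tm_min <= tm <= cons.tm_max:
                continue
            out.append(PrimerCandidate("", sense, seq, (s, e), tm, True))
    return out


def _free_windows(tpl: _TargetTemplate, sense: str, col_lo: int, col_hi: int,
                  cons: DesignConstraints, cache: dict[str, float]
                  ) -> Iterable[PrimerCandidate]:
    """Unanchored valid windows whose 5'-most column lies in [col_lo, col_hi)
    for F, or whose end column lies in that range for R."""
    for edge in range(col_lo, col_hi):
        for L in range(cons.primer_len_min, cons.primer_len_max + 1):
            s, e = (edge, edge + L) if sense == "F" else (edge - L, edge)
            if s < 0 or e > tpl.ncol or not tpl.window_valid(s, e):
                continue
            seq = tpl.window_seq(s, e)
            if sense == "R":
                seq = revcomp(seq)
            tm = _tm_cached(seq, cons.thermo, cache)
            if not cons.tm_min <= tm <= cons.tm_max:
                continue
            yield PrimerCandidate("", sense, seq, (s, e), tm, False)


def _evaluate_pair(f: PrimerCandidate, r: PrimerCandidate, tpl: _TargetTemplate,
                   cons: DesignConstraints, tally: Counter) -> int | None:
    """Return the expected product size, or None (with the failure tallied)."""
    if f.span[1] > r.span[0]:
        tally["overlap"] += 1
        return None
    size = tpl.product_size(f.span[0], r.span[1])
    if size is None:
        tally["indel_between_genotypes"] += 1
        return None
    if not cons.product_min <= size <= cons.product_max:
        tally["product_size"] += 1
        return None
    if abs(f.tm_celsius - r.tm_celsius) > cons.delta_tm_max:
        tally["delta_tm"] += 1
        return None
    rep = screen_interactions([f.sequence, r.sequence],
                              threshold=cons.interaction_threshold)
    if rep.flagged_pairs or rep.hairpins:
        tally["interaction"] += 1
        return None
    return size


def design_primer_pairs(aln: LabeledAlignment, target_species: str,
                        constraints: DesignConstraints | None = None
                        ) -> tuple[list[MarkerPair], Counter]:
    """Design ranked species-specific primer pairs for one target species.

    Each returned pair has at least one primer 3'-anchored on a diagnostic
    site; pairs with both primers anchored rank first, then Tm closeness,
    then proximity to ``size_target`` (when set).  Returns the ranked list
    (up to ``max_candidates``) and a per-constraint failure tally — an empty
    list with the tally is the answer when nothing is feasible.
    """
    cons = constraints or DesignConstraints()
    sites = find_diagnostic_sites(aln, target_species, strict=cons.strict_background)
    tally: Counter = Counter()
    if not sites:
        tally["no_diagnostic_sites"] += 1
        return [], tally
    tpl = _TargetTemplate(aln, target_species)
    cache: dict[str, float] = {}
    anchored_f = _anchored_windows(tpl, sites, "F", cons, cache)
    anchored_r = _anchored_windows(tpl, sites, "R", cons, cache)

    scored: list[tuple[tuple, PrimerCandidate, PrimerCandidate, int]] = []

    def consider(f: PrimerCandidate, r: PrimerCandidate) -> None:
        size = _evaluate_pair(f, r, tpl, cons, tally)
        if size is None:
            return
        both = f.anchored and r.anchored
        sizekey = abs(size - cons.size_target) if cons.size_target else 0
        key = (0 if both else 1, abs(f.tm_celsius - r.tm_celsius), sizekey,
               f.span, r.span)
        scored.append((key, f, r, size))

    for f in anchored_f:
        for r in anchored_r:
            consider(f, r)

    if not any(k[0] == 0 for k, *_ in scored) or not scored:
        # fall back to one anchored primer plus a free partner; bound the
        # partner's columns by the feasible product-size window
        cum0 = tpl.cum[0]
        for f in anchored_f:
            lo = int(np.searchsorted(cum0, cum0[f.span[0]] + cons.product_min))
            hi = int(np.searchsorted(cum0, cum0[f.span[0]] + cons.product_max,
                                     side="right"))
            lo = max(lo, f.span[1] + cons.primer_len_min)
            for r in _free_windows(tpl, "R", lo, min(hi, tpl.ncol) + 1, cons, cache):
                consider(f, r)
        for r in anchored_r:
            hi_v = cum0[r.span[1]] - cons.product_min
            lo_v = cum0[r.span[1]] - cons.product_max
            lo = int(np.searchsorted(cum0, max(lo_v, 0)))
            hi = min(int(np.searchsorted(cum0, max(hi_v, 0), side="right")),
                     r.span[0] - cons.primer_len_min)
            for f in _free_windows(tpl, "F", max(lo, 0), max(hi, 0), cons, cache):
                consider(f, r)

    scored.sort(key=lambda t: t[0])
    markers = []
    seen_spans = set()
    for key, f, r, size in scored:
        span_key = (f.span, r.span)
        if span_key in seen_spans:
            continue
        seen_spans.add(span_key)
        idx = len(markers) + 1
        name = f"{target_species}_mk{idx}"
        fwd = replace(f, name=f"{name}_F")
        rev = replace(r, name=f"{name}_R")
        anneal = min(f.tm_celsius, r.tm_celsius) + cons.annealing_offset
        markers.append(MarkerPair(name, fwd, rev, target_species, size,
                                  round(anneal)))
        if len(markers) >= cons.max_candidates:
            break
    return markers, tally


def design_all_species(aln: LabeledAlignment,
                       constraints: DesignConstraints | None = None,
                       stagger: int | None = 60
                       ) -> tuple[dict[str, list[MarkerPair]], dict[str, Counter]]:
    """Design markers for every species; optionally stagger the amplicon
    size targets so products are separable on one gel."""
    cons = constraints or DesignConstraints()
    out: dict[str, list[MarkerPair]] = {}
    tallies: dict[str, Counter] = {}
    for i, sp in enumerate(aln.species_list):
        sp_cons = cons
        if stagger is not None:
            sp_cons = replace(cons, size_target=cons.product_min + 50 + i * stagger)
        out[sp], tallies[sp] = design_primer_pairs(aln, sp, sp_cons)
    return out, tallies


# ---------------------------------------------------------------------------
# interaction screening


@dataclass(frozen=True)
class InteractionReport:
    flagged_pairs: tuple[tuple[str, str, int], ...]  # (name_i, name_j, run length)
    hairpins: tuple[tuple[str, int], ...]  # (name, stem length)

    @property
    def clean(self) -> bool:
        return not self.flagged_pairs and not self.hairpins


def _three_prime_run(p: str, q: str) -> int:
    """Longest k such that the 3'-terminal k bases of p can pair
    (antiparallel, perfect complement) with some k-mer of q."""
    best = 0
    for k in range(1, min(len(p), len(q)) + 1):
        if revcomp(p[-k:]) in q:
            best = k
        else:
            break
    return best


def _hairpin_stem(p: str, min_loop: int = 3) -> int:
    """Longest self-complementary stem with a loop of at least min_loop."""
    n = len(p)
    best = 0
    for k in range(2, n // 2 + 1):
        for i in range(0, n - 2 * k - min_loop + 1):
            stem = p[i:i + k]
            rc = revcomp(stem)
            j = p.find(rc, i + k + min_loop)
            if j >= 0:
                best = max(best, k)
    return best


def screen_interactions(primers: Sequence[str] | Sequence[PrimerCandidate],
                        threshold: int = 5) -> InteractionReport:
    """Flag 3'-terminal complementary runs >= threshold for every ordered
    pair (self included) and hairpins with stem >= 4 over a >= 3-base loop."""
    if not primers:
        raise DesignError("no primers to screen")
    named: list[tuple[str, str]] = []
    for i, p in enumerate(primers):
        if isinstance(p, PrimerCandidate):
            named.append((p.name or f"primer{i + 1}", p.sequence))
        else:
            named.append((f"primer{i + 1}", p))
    flagged = []
    for ni, si in named:
        for nj, sj in named:
            run = _three_prime_run(si, sj)
            if run >= threshold:
                flagged.append((ni, nj, run))
    hairpins = []
    for ni, si in named:
        stem = _hairpin_stem(si)
        if stem >= 4:
            hairpins.append((ni, stem))
    return InteractionReport(tuple(flagged), tuple(hairpins))


# ---------------------------------------------------------------------------
# multiplex grouping


@dataclass(frozen=True)
class MultiplexGroup:
    annealing_temp: float
    members: tuple[MarkerPair, ...]
    min_size_separation: int

    def sizes(self) -> list[int]:
        return [m.expected_size for m in self.members]


def build_multiplex_groups(markers: Sequence[MarkerPair],
                           min_separation: int = 30,
                           interaction_threshold: int = 5,
                           temp_tolerance: float = 0.0
                           ) -> tuple[list[MultiplexGroup], list[tuple[MarkerPair, str]]]:
    """Greedy grouping of markers sharing an annealing temperature.

    Markers are binned by annealing temperature (exactly by default;
    ``temp_tolerance`` lets near-equal temperatures share a reaction, run at
    the bin's minimum).  Within a group every pairwise amplicon-size
    difference must be at least ``min_separation`` bp and the pooled primers
    must screen clean at the 3' interaction threshold; violating markers are
    left ungrouped with the reason."""
    by_temp: dict[float, list[MarkerPair]] = {}
    if temp_tolerance > 0:
        for m in sorted(markers, key=lambda m: m.annealing_temp):
            for temp in by_temp:
                if m.annealing_temp - temp <= temp_tolerance:
                    by_temp[temp].append(m)
                    break
            else:
                by_temp[m.annealing_temp] = [m]
    else:
        for m in markers:
            by_temp.setdefault(m.annealing_temp, []).append(m)
    groups: list[MultiplexGroup] = []
    leftover: list[tuple[MarkerPair, str]] = []
    for temp in sorted(by_temp):
        members: list[MarkerPair] = []
        for m in sorted(by_temp[temp], key=lambda m: m.expected_size):
            clash = [g for g in members
                     if abs(g.expected_size - m.expected_size) < min_separation]
            if clash:
                leftover.append((m, f"amplicon size within {min_separation} bp "
                                    f"of {clash[0].name}"))
                continue
            pool = [p.sequence for g in members for p in g.primers]
            pool += [m.forward.sequence, m.reverse.sequence]
            rep = screen_interactions(pool, threshold=interaction_threshold)
            if members and not rep.clean:
                leftover.append((m, "primer interaction in pooled reaction"))
                continue
            members.append(m)
        if len(members) >= 2:
            groups.append(MultiplexGroup(temp, tuple(members), min_separation))
        else:
            leftover.extend((m, "no co-groupable marker at this temperature")
                            for m in members)
    return groups, leftover
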