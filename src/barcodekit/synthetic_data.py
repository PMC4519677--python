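"""Simulated barcode datasets with the statistical structure the analysis
assumes, so every stage is testable without external downloads.

The generator emulates a panel of closely related species sampled at a few
genotypes each, sequenced over a single chloroplast-like coding region of
roughly 800 bp: interspecific divergence on the order of 0.008-0.024
substitutions/site, near-zero intraspecific divergence, and a guaranteed
number of planted diagnostic sites per species.  Substitutions follow a
per-site independent two-rate process with transition/transversion rate
ratio ``kappa`` — exactly the model the K2P distance inverts, so estimator
recovery is a closed loop.  Species diverge from a common ancestor on a
star tree (every pair of species ancestors separated by ``d_inter``
expected substitutions/site); genotypes diverge from their species
ancestor by ``d_intra``.  Indels are off by default (barcode regions here
are coding and nearly gap-free) and exist only to exercise the aligner.

Quality-profile simulation produces reads with low-quality ramps at both
ends and random mid-read dips, together with the ground-truth trim/mask/
reject outcome computed by an independent brute-force restatement of the
acceptance rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SimulationError
from .seqio import QualitySequence, SampleRecord

_BASES = "ACGT"
# transition partner of each base (A<->G, C<->T) under the ACGT encoding
_TS_PARTNER = np.array([2, 3, 0, 1])


@dataclass(frozen=True)
class SimParams:
    """Study-condition parameters of the species-set simulator."""

    n_species: int = 7
    n_per_species: int = 3
    seq_length: int = 800
    kappa: float = 2.0
    d_inter: float = 0.016  # expected pairwise divergence between species
    d_intra: float = 0.0005  # expected pairwise divergence within a species
    n_planted_diagnostic: int = 3
    indel_rate: float = 0.0
    seed: int = None  # type: ignore[assignment]  # mandatory

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory for reproducibility")
        if min(self.d_inter, self.d_intra, self.kappa, self.indel_rate) < 0:
            raise SimulationError("rates must be >= 0")
        if self.d_intra > self.d_inter:
            raise SimulationError("d_intra must not exceed d_inter")
        if self.d_inter > 0.7:
            raise SimulationError("d_inter too high (saturated regime)")
        reserved = self.n_species * self.n_planted_diagnostic
        if reserved > self.seq_length // 4:
            raise SimulationError(
                f"{reserved} planted sites will not fit in {self.seq_length} bp"
            )


@dataclass(frozen=True)
class PlantedSite:
    position: int  # 0-based position in the ungapped simulated sequences
    species: str
    target_state: str
    background_state: str


@dataclass
class SimulatedDataset:
    sequences: dict[str, str]
    records: list[SampleRecord]
    tree_newick: str
    planted_sites: list[PlantedSite]
    params: SimParams

    @property
    def species_of(self) -> dict[str, str]:
        return {r.sample_id: r.species for r in self.records}


def _k2p_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """4x4 base-substitution probabilities after d expected subs/site."""
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    p_tv_each = 0.25 - 0.25 * np.exp(-4.0 * beta_t)  # each of the 2 transversions
    P = np.full((4, 4), p_tv_each)
    for b in range(4):
        P[b, b] = 1.0 - p_ts - 2.0 * p_tv_each
        P[b, _TS_PARTNER[b]] = p_ts
    return P


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator,
            frozen: np.ndarray | None = None) -> np.ndarray:
    """Evolve an encoded sequence by branch length d; ``frozen`` positions
    never change (used to protect planted diagnostic sites)."""
    if d == 0:
        return seq.copy()
    P = _k2p_transition_matrix(d, kappa)
    cum = P.cumsum(axis=1)
    u = rng.random(seq.size)
    out = (u[:, None] > cum[seq]).sum(axis=1).astype(np.int8)
    if frozen is not None:
        out[frozen] = seq[frozen]
    return out


def simulate_species_set(params: SimParams) -> SimulatedDataset:
    """Generate the labelled species panel plus ground truth.

    Returns sequences, sample records, the generating (star) tree, and the
    registry of planted diagnostic sites.  Identical parameters and seed
    give byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    L = params.seq_length
    ancestor = rng.integers(0, 4, size=L).astype(np.int8)

    # reserve distinct columns for planted diagnostic sites
    n_reserved = params.n_species * params.n_planted_diagnostic
    reserved = rng.choice(L, size=n_reserved, replace=False) if n_reserved else \
        np.empty(0, dtype=int)
    frozen = np.zeros(L, dtype=bool)
    frozen[reserved] = True

    species_names = [f"species{i + 1:02d}" for i in range(params.n_species)]
    # species ancestors: star tree, branch d_inter/2 each
    sp_anc = {
        sp: _evolve(ancestor, params.d_inter / 2.0, params.kappa, rng, frozen)
        for sp in species_names
    }

    # plant diagnostic sites: one shared background state, a different fixed
    # state in the target species only
    planted: list[PlantedSite] = []
    cursor = 0
    for sp in species_names:
        for _ in range(params.n_planted_diagnostic):
            pos = int(reserved[cursor]); cursor += 1
            bg = int(rng.integers(0, 4))
            tgt = int((bg + 1 + rng.integers(0, 3)) % 4)
            for other in species_names:
                sp_anc[other][pos] = tgt if other == sp else bg
            planted.append(PlantedSite(pos, sp, _BASES[tgt], _BASES[bg]))

    sequences: dict[str, str] = {}
    records: list[SampleRecord] = []
    for sp in species_names:
        for g in range(params.n_per_species):
            sid = f"{sp}_g{g + 1}"
            enc = _evolve(sp_anc[sp], params.d_intra / 2.0, params.kappa, rng, frozen)
            if params.indel_rate > 0:
                enc = _apply_indels(enc, params.indel_rate, rng)
            sequences[sid] = "".join(_BASES[b] for b in enc)
            records.append(SampleRecord(sid, sp, origin="simulated"))

    half = params.d_inter / 2.0
    tips = []
    for sp in species_names:
        leaves = ",".join(
            f"{sp}_g{g + 1}:{params.d_intra / 2.0:.6f}"
            for g in range(params.n_per_species)
        )
        tips.append(f"({leaves}):{half:.6f}")
    newick = "(" + ",".join(tips) + ");"
    return SimulatedDataset(sequences, records, newick, planted, params)


def _apply_indels(enc: np.ndarray, rate: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Short deletions/insertions at the given per-base rate (aligner tests
    only; off by default)."""
    out: list[int] = []
    i = 0
    while i < enc.size:
        if rng.random() < rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                i += length  # deletion
                continue
            out.extend(int(b) for b in rng.integers(0, 4, size=length))
        out.append(int(enc[i]))
        i += 1
    return np.array(out, dtype=np.int8)


# ---------------------------------------------------------------------------
# quality profiles


@dataclass(frozen=True)
class QualityProfile:
    """Read-quality shape: low ramps at both ends, a high plateau, and
    random low-quality dips."""

    mid_phred: int = 35
    end_phred: int = 10
    ramp_length: int = 30
    dip_rate: float = 0.01
    dip_phred: int = 10

    def __post_init__(self) -> None:
        for v in (self.mid_phred, self.end_phred, self.dip_phred):
            if not 0 <= v <= 93:
                raise SimulationError(f"PHRED value {v} outside [0, 93]")


@dataclass(frozen=True)
class QualityTruth:
    """Ground-truth QC outcome, derived by brute force from the rules."""

    retained_range: tuple[int, int]
    masked_positions: tuple[int, ...]  # within the retained interval
    n_fraction: float
    accepted: bool
    reason: str | None


def simulate_quality(sequence: str, profile: QualityProfile | None = None,
                     seed: int | None = 0) -> tuple[QualitySequence, QualityTruth]:
    """Attach a simulated PHRED track to a sequence, plus the expected QC
    outcome under the default acceptance thresholds."""
    profile = profile or QualityProfile()
    rng = np.random.default_rng(seed)
    L = len(sequence)
    scores = np.full(L, profile.mid_phred)
    ramp = min(profile.ramp_length, L)
    if ramp > 0:
        grades = np.linspace(profile.end_phred, profile.mid_phred, ramp, endpoint=False)
        scores[:ramp] = np.minimum(scores[:ramp], grades.astype(int))
        scores[L - ramp:] = np.minimum(scores[L - ramp:], grades.astype(int)[::-1])
    dips = rng.random(L) < profile.dip_rate
    scores[dips] = profile.dip_phred
    qseq = QualitySequence("sim", sequence, tuple(int(s) for s in scores))
    truth = _qc_truth_bruteforce(sequence, scores.tolist())
    return qseq, truth


def _qc_truth_bruteforce(bases: str, scores: list[int], window: int = 10,
                         window_min: int = 20, mask_below: int = 20,
                         max_n_fraction: float = 0.40) -> QualityTruth:
    """Plain-loop restatement of the three acceptance rules, kept
    independent of the quality_control module as an oracle."""
    n = len(scores)
    starts = [i for i in range(0, n - window + 1)
              if all(scores[i + k] > window_min for k in range(window))]
    if not starts:
        return QualityTruth((0, 0), (), 0.0, False, "no qualifying window")
    s, e = starts[0], starts[-1] + window
    masked = tuple(i - s for i in range(s, e) if scores[i] < mask_below)
    n_count = sum(
        1 for i in range(s, e) if scores[i] < mask_below or bases[i] == "N"
    )
    nf = n_count / (e - s)
    if nf > max_n_fraction:
        return QualityTruth((s, e), masked, nf, False, "n_fraction above threshold")
    return QualityTruth((s, e), masked, nf, True, None)


def make_hybrid(maternal_sequence: str, label: str = "hybrid") -> tuple[str, str]:
    """A hybrid's chloroplast template: copied from the maternal lineage
    (plastids are uniparentally inherited)."""
    return label, maternal_sequence
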