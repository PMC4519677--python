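# Methods

This note documents the models, rules and numerical choices implemented in
barcodekit, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate.

## Sequence acceptance (quality control)

A read is processed by three ordered rules. (i) *Trimming*: bases are
deleted from each end until the retained stretch is bounded by runs of
`window` (default 10) consecutive bases whose PHRED scores are all
**strictly greater than** `window_min_phred` (default 20); the retained
interval runs from the first such run's start to the last run's end. If no
run exists the retained interval is empty and the read is rejected.
(ii) *Masking*: retained bases scoring **strictly below**
`mask_below_phred` (default 20) are recorded as N. The two thresholds are
deliberately asymmetric at exactly 20: a score of 20 cannot anchor a trim
window but is not masked. (iii) *Rejection*: reads whose retained N
fraction strictly exceeds `max_n_fraction` (default 0.40) are deleted;
N's present in the input count the same as masked N's. Trimming decisions
use raw scores (masking happens afterwards), and one full pass is
idempotent. "Retain the maximal interval bounded by the outermost
qualifying windows" is the simplest reading of "trim to minimize
low-quality calls at each end" and is the package's fixed operational
definition; alternates would need a different `trim_ends`.

## Alignment

Barcode amplicons from one coding locus are nearly gap-free, so the native
aligner is intentionally plain: global pairwise alignment by Gotoh's
affine-gap DP (a gap of length L costs `gap_open + (L−1)·gap_extend`,
defaults −5/−1, match +1, mismatch −1, N mismatches everything including
N), a UPGMA guide tree built from p-distances of the optimal pairwise
alignments (scipy average-linkage), and profile–profile merging with the
same DP over expected column scores (frequency-weighted substitution
scores; residue-vs-existing-gap scores `gap_extend`, gap-vs-gap 0). There
is no iterative refinement. Traceback ties resolve diagonal > up > left and
guide-tree ties follow input order, making output deterministic. Externally
produced alignments are first-class input (`--pre-aligned`), which is the
recommended route for published data; consequently distance values on real
data are alignment-dependent and should be compared with tolerance, not
bit-exactly.

## Distances

K2P: d = −½·ln[(1−2P−Q)·√(1−2Q)] with P, Q the transition/transversion
proportions over compared sites. Columns with a gap or N in either row of
a pair are excluded *for that pair only* (pairwise deletion) — this is the
distance-per-pair semantics used by the common MEGA-style implementations
and preserves signal in ragged-ended barcodes; the per-pair compared-site
count is kept in the matrix for audit. Saturated pairs (either log
argument ≤ 0) raise an error in strict mode or carry NaN otherwise; they
are never silently zeroed, because a silent zero would corrupt the
barcoding-gap extrema. Distances are computed in double precision and
rounded only at reporting (6 decimals).

## Barcoding gap

Per species: intraspecific pairs are pairs within the species;
interspecific pairs pool the species against all others (single min/max
per species, not per species-pair). The verdict is the strict CBOL
inequality `max_intra < min_inter`. Single-sample species have no
intraspecific pairs and are reported "not assessable" rather than counted
as successes. Undefined distances are excluded from extrema with a
warning.

## Neighbor joining and bootstrap

Standard Saitou–Nei agglomeration on the Q-criterion; exact (topology and
branch lengths) on additive matrices, which the test suite exercises
against path-length oracles on random trees. Ties in the Q minimum resolve
to the pair whose sorted representative labels (smallest leaf label per
cluster) are lexicographically smallest. Negative branch-length estimates
are clamped to zero with the deficit transferred to the sister branch, the
conventional remedy. Bootstrap: alignment columns resampled with
replacement; distances + NJ per replicate; the support of each internal
edge of the point-estimate tree is the percentage of *successful*
replicates containing its bipartition (replicates with saturated distances
are dropped and their count reported). Supports are mapped onto the
point-estimate tree, not a consensus tree. Rendered Newick output can
suppress supports below a display threshold (e.g. 50 %) while the full
values remain available programmatically.

## Melting temperatures and their calibration

Primer Tm is the nearest-neighbor duplex melting temperature (Biopython's
implementation). The free parameters — stacking table, monovalent-salt
correction and concentration, primer strand concentration — are not
derivable from first principles for a given lab protocol, so the default
`ThermoParams` were calibrated once against a bundled reference panel of
14 species-specific primers with published Tm values: Breslauer 1986 table,
Schildkraut–Lifson correction (16.6·log₁₀[Na⁺]), Na⁺ = 54.0 mM,
5000 nM per strand. The fit (`scripts/calibrate_tm.py`, Nelder–Mead over
salt and strand concentration per table/correction) reproduces all 14
published values to ≤ 0.1 °C; the parameters are a package constant, not a
per-run tunable. Note that Tm is *not* exactly monotone under single-base
G/C extension with this table (terminal-stack effects), so only verified
spot cases are asserted. Annealing temperature is treated as an input with
default `min(primer Tms) + offset`: published annealing choices in this
domain routinely exceed primer Tms, so no formula is inferred from them.

## Marker design

A diagnostic site is an alignment column whose state is unanimous and
unambiguous (A/C/G/T) in the target species and absent from every
non-target row. Fixation in the target is required — intraspecific
polymorphism disqualifies a column — so a marker amplifies every target
genotype. Background N/gap at the column never counts as a match but flags
the site lower-confidence; strict mode drops such sites. Candidate primers
are 17–27-nt windows conserved across target genotypes; anchored
candidates place their 3′-terminal base on a diagnostic site (a 3′
mismatch on non-targets blocks extension). Pairs require at least one
anchored primer, ΔTm ≤ 5 °C, product size within [150, 800] bp by default,
and a clean interaction screen (no ≥ 5-base complementary run involving
either 3′ terminus, ordered pairs and self-pairs; no hairpin stem ≥ 4 over
a ≥ 3-base loop). Ranking: both-primers-anchored first, then Tm closeness,
then proximity to an optional size target; when designing for a whole
panel the size targets are staggered (default 60 bp apart) so products are
gel-separable. Multiplex grouping is greedy within annealing-temperature
bins (exact by default; the pipeline allows a 3 °C tolerance, running the
bin at its minimum temperature) subject to ≥ 30 bp pairwise size
separation and a clean pooled interaction screen; violators are reported
with reasons rather than silently dropped.

## In-silico PCR

Binding requires ≤ `max_mismatch` mismatches (default 0 — a clean single
gel band implies effectively exact matching) with zero mismatches in the
3′-terminal `clamp` bases (default 3); template N never matches. Product
length is inclusive of both primer footprints (the gel-facing size).
All products up to 5000 bp are reported; a marker is *specific* only when
every target sample yields exactly one product and every non-target yields
none. `predict_pool` evaluates every ordered primer combination of a
pooled reaction and is what surfaces cross-binding extra bands.
Maternal-parent inference calls the candidate species whose marker (alone)
amplifies on the hybrid's plastid template; zero or multiple amplifying
markers give "inconclusive".

## Synthetic data

The generator emulates the study conditions: `n_species=7` ×
`n_per_species=3` genotypes of `seq_length=800` bp; species ancestors
diverge on a star tree so every species pair is separated by `d_inter`
expected substitutions/site (default 0.016, the middle of the observed
0.008–0.024 interspecific range); genotypes diverge by `d_intra` (default
0.0005, matching near-zero observed intraspecific divergence); the
substitution process is per-site independent with
transition/transversion rate ratio `kappa=2`, i.e. exactly the model K2P
inverts, so estimator recovery is a closed loop. `n_planted_diagnostic=3`
columns per species are fixed to a target-only state and frozen, so marker
design always has raw material; planting freezes ≈ 2.6 % of sites, a
negligible depression of realized divergence. Indels are off by default
(coding, nearly gap-free loci) and exist only to exercise the aligner.
Quality profiles are a plateau (`mid_phred=35`) with linear end ramps down
to `end_phred=10` and Bernoulli dips; the generator also returns the
ground-truth QC outcome computed by an independent plain-loop restatement
of the three rules, which is the oracle the QC tests compare against.

What passing synthetic tests shows: the estimators and decision rules are
correct *under their own model assumptions* at study scale. What they do
not show: robustness to alignment error on diverged loci, rate variation
across sites, chloroplast structural variation, chimeric or
mis-identified reference sequences, or PCR chemistry beyond
complementarity — the in-silico PCR model has no thermodynamic extension
efficiency and will not predict weak or spurious bands that perfect-match
logic excludes.

## Problem sizes in the shipped checks

The default test suite runs the full seven-species regime end to end
(alignment of 21 × 800 bp, distance/gap/tree/design/PCR), 200 random QC
profiles against the brute-force oracle, 100 random additive trees (4–8
taxa) for NJ exactness, 100 replicate species pairs for K2P parameter
recovery, and 1000 random pairs for the K2P ≥ p inequality; bootstrap
tests use 20–200 replicates. These sizes were chosen to keep the suite
fast while leaving sampling error far below the asserted margins.

## Known limitations

- The progressive aligner is adequate for near-gap-free barcodes but is
  not a general MSA tool; for indel-rich loci supply an external
  alignment.
- Reported distance extrema on real data depend on the upstream alignment
  and on gap handling; comparisons against published three-decimal tables
  should use ± 0.001.
- Multiplex grouping is greedy, not optimal; with many markers a set-cover
  style optimizer would do better.
- Tm calibration is tied to one published panel's convention; laboratories
  using other calculators should recalibrate with their own reference
  values (`scripts/calibrate_tm.py`).
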