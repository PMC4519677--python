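"""Input/output for all external formats and the sample-to-species labeling.

Formats handled: FASTA (plain or gapped), FASTQ (Sanger +33), paired
FASTA/.qual, tab-separated species maps and distance matrices, Newick trees,
and the tabular marker report.  Parsing of the standard sequence formats is
delegated to Biopython; this module adds validation (alphabet, duplicate IDs,
length agreement) and the package's domain types.

Coordinates are 0-based half-open everywhere internally; 1-based positions
appear only in human-readable report columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    DuplicateIdError,
    IllegalCharacterError,
    LengthMismatchError,
    SequenceFormatError,
    SpeciesMapError,
)

#: Characters accepted in an ungapped or gapped nucleotide sequence.
ALPHABET = set("ACGTN-")

MAX_PHRED = 93


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual: a sequence identifier plus its species label.

    ``species`` is a free string (binomial or code); no taxonomy validation
    is attempted, since real datasets mix codes like ``Che1`` with binomials
    like ``A. cherimola``.
    """

    sample_id: str
    species: str
    origin: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise SpeciesMapError("sample_id must be nonempty")
        if not self.species:
            raise SpeciesMapError(f"empty species for sample {self.sample_id!r}")


@dataclass(frozen=True)
class QualitySequence:
    """Bases plus per-base PHRED scores and the retained interval.

    ``bases``/``phred`` always describe the *currently retained* stretch;
    ``trimmed_range`` records where that stretch sits in the originally
    ingested read (0-based, half-open).  An empty retained interval is a
    valid state (the read failed to open any qualifying window).
    """

    sample_id: str
    bases: str
    phred: tuple[int, ...]
    trimmed_range: tuple[int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.trimmed_range is None:
            object.__setattr__(self, "trimmed_range", (0, len(self.bases)))
        if len(self.phred) != len(self.bases):
            raise LengthMismatchError(
                f"record {self.sample_id!r}: {len(self.bases)} bases but "
                f"{len(self.phred)} quality scores"
            )
        bad = set(self.bases) - ALPHABET
        if bad:
            raise IllegalCharacterError(
                f"record {self.sample_id!r}: illegal character(s) {sorted(bad)}"
            )
        for q in self.phred:
            if not 0 <= q <= MAX_PHRED:
                raise SequenceFormatError(
                    f"record {self.sample_id!r}: PHRED score {q} outside [0, {MAX_PHRED}]"
                )
        start, end = self.trimmed_range
        if not (0 <= start <= end):
            raise SequenceFormatError(
                f"record {self.sample_id!r}: invalid trimmed_range {self.trimmed_range}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_fraction(self) -> float:
        """Fraction of N among retained bases (0.0 for an empty interval)."""
        if not self.bases:
            return 0.0
        return self.bases.count("N") / len(self.bases)

    @property
    def scores(self) -> np.ndarray:
        return np.asarray(self.phred, dtype=int)


@dataclass
class LabeledAlignment:
    """Gapped, equal-length rows with a species label for every row."""

    ids: list[str]
    rows: list[str]
    species_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SequenceFormatError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError("duplicate sample_id in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise LengthMismatchError(f"ragged alignment rows: lengths {sorted(lengths)}")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - ALPHABET
            if bad:
                raise IllegalCharacterError(
                    f"alignment row {sid!r}: illegal character(s) {sorted(bad)}"
                )
            if sid not in self.species_of:
                raise SpeciesMapError(f"sample {sid!r} has no species label")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def species_list(self) -> list[str]:
        """Distinct species in first-appearance order."""
        seen: dict[str, None] = {}
        for sid in self.ids:
            seen.setdefault(self.species_of[sid], None)
        return list(seen)

    def rows_for_species(self, species: str) -> list[str]:
        return [r for sid, r in zip(self.ids, self.rows) if self.species_of[sid] == species]

    def ungapped(self, sample_id: str) -> str:
        row = self.rows[self.ids.index(sample_id)]
        return row.replace("-", "")


# ---------------------------------------------------------------------------
# sequence input


def _normalize(seq: str, record_id: str, allow_gaps: bool) -> str:
    s = seq.upper().replace("U", "T")
    allowed = ALPHABET if allow_gaps else ALPHABET - {"-"}
    bad = set(s) - allowed
    if bad:
        raise IllegalCharacterError(
            f"record {record_id!r}: illegal character(s) {sorted(bad)}"
        )
    return s


def read_fasta(path: str | Path, allow_gaps: bool = True) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased and U is mapped to T.  Characters outside
    ``{A,C,G,T,N,-}`` raise :class:`IllegalCharacterError` naming the record;
    duplicate identifiers and empty files are likewise rejected, so counts
    in always equal counts out.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DuplicateIdError(f"duplicate record ID {rec.id!r} in {path}")
        out[rec.id] = _normalize(str(rec.seq), rec.id, allow_gaps)
    if not out:
        raise SequenceFormatError(f"no FASTA records found in {path}")
    return out


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    with open(path, "w") as fh:
        for sid, seq in items:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> dict[str, QualitySequence]:
    """Read Sanger-encoded (+33 offset) FASTQ into QualitySequence records."""
    out: dict[str, QualitySequence] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in out:
            raise DuplicateIdError(f"duplicate record ID {rec.id!r} in {path}")
        seq = _normalize(str(rec.seq), rec.id, allow_gaps=False)
        out[rec.id] = QualitySequence(
            rec.id, seq, tuple(rec.letter_annotations["phred_quality"])
        )
    if not out:
        raise SequenceFormatError(f"no FASTQ records found in {path}")
    return out


def read_fasta_qual(seq_path: str | Path, qual_path: str | Path) -> dict[str, QualitySequence]:
    """Read a FASTA file paired with a PHRED ``.qual`` file.

    IDs must match one-to-one and per-record lengths must agree; any
    asymmetry raises a named error identifying the record.
    """
    seqs = read_fasta(seq_path, allow_gaps=False)
    quals: dict[str, list[int]] = {}
    for rec in SeqIO.parse(str(qual_path), "qual"):
        if rec.id in quals:
            raise DuplicateIdError(f"duplicate record ID {rec.id!r} in {qual_path}")
        quals[rec.id] = list(rec.letter_annotations["phred_quality"])
    only_seq = set(seqs) - set(quals)
    only_qual = set(quals) - set(seqs)
    if only_seq or only_qual:
        raise SequenceFormatError(
            f"ID mismatch between {seq_path} and {qual_path}: "
            f"sequence-only {sorted(only_seq)}, quality-only {sorted(only_qual)}"
        )
    out = {}
    for sid, seq in seqs.items():
        if len(quals[sid]) != len(seq):
            raise LengthMismatchError(
                f"record {sid!r}: {len(seq)} bases but {len(quals[sid])} quality scores"
            )
        out[sid] = QualitySequence(sid, seq, tuple(quals[sid]))
    return out


def read_quality(seq_path: str | Path, qual_path: str | Path | None = None
                 ) -> dict[str, QualitySequence]:
    """Dispatch: FASTQ if a single path is given, FASTA+qual if two."""
    if qual_path is None:
        return read_fastq(seq_path)
    return read_fasta_qual(seq_path, qual_path)


# ---------------------------------------------------------------------------
# species map


def read_species_map(path: str | Path) -> dict[str, SampleRecord]:
    """Read a TSV with header columns ``sample_id``, ``species`` (optional
    ``origin``) into an ordered mapping of :class:`SampleRecord`."""
    out: dict[str, SampleRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SpeciesMapError(f"empty species map {path}")
        missing = {"sample_id", "species"} - set(reader.fieldnames)
        if missing:
            raise SpeciesMapError(f"{path}: missing column(s) {sorted(missing)}")
        for row in reader:
            sid = (row["sample_id"] or "").strip()
            if sid in out:
                raise DuplicateIdError(f"duplicate sample_id {sid!r} in {path}")
            out[sid] = SampleRecord(sid, (row["species"] or "").strip(),
                                    (row.get("origin") or "").strip() or None)
    if not out:
        raise SpeciesMapError(f"no samples in species map {path}")
    return out


def write_species_map(records: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id", "species", "origin"])
        for r in records:
            w.writerow([r.sample_id, r.species, r.origin or ""])


def species_lookup(records: Mapping[str, SampleRecord]) -> dict[str, str]:
    return {sid: rec.species for sid, rec in records.items()}


# ---------------------------------------------------------------------------
# distance matrices


def write_distance_tsv(matrix, path: str | Path) -> None:
    """Write a square labelled TSV with 6-decimal distances.

    Undefined (saturated) pairs are written as ``NA`` rather than a number.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([""] + list(matrix.labels))
        for i, lab in enumerate(matrix.labels):
            row = [lab]
            for j in range(len(matrix.labels)):
                v = matrix.d[i, j]
                row.append("NA" if np.isnan(v) else f"{v:.6f}")
            w.writerow(row)


def read_distance_tsv(path: str | Path):
    """Read a square labelled distance TSV back into a DistanceMatrix."""
    from .distances import DistanceMatrix  # local import avoids a cycle

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise SequenceFormatError(f"empty distance file {path}")
    labels = rows[0][1:]
    n = len(labels)
    d = np.zeros((n, n))
    for i, row in enumerate(rows[1:]):
        if row[0] != labels[i]:
            raise SequenceFormatError(f"{path}: row label {row[0]!r} != column label {labels[i]!r}")
        for j, cell in enumerate(row[1:]):
            d[i, j] = np.nan if cell == "NA" else float(cell)
    return DistanceMatrix(labels=list(labels), d=d, sites_used=None, model="unknown")


# ---------------------------------------------------------------------------
# trees


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (``nj_phylo.PhyloTree``) as Newick with 6-decimal branch
    lengths and integer bootstrap labels on internal nodes."""
    with open(path, "w") as fh:
        fh.write(tree.newick(decimals=6) + "\n")


def read_newick(path: str | Path):
    """Parse a Newick file via dendropy (used for round-trip verification)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# marker report

MARKER_REPORT_COLUMNS = [
    "name", "sense", "sequence_5p_3p", "tm_celsius",
    "annealing_temp_celsius", "expected_size_bp", "specificity",
]


def write_marker_report(markers: Sequence, path: str | Path) -> None:
    """Write one data row per marker pair with the 7 report columns.

    Forward/reverse fields are joined with ``/`` so each marker occupies a
    single row; :func:`write_primer_table` gives the one-row-per-primer
    layout instead.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(MARKER_REPORT_COLUMNS)
        for m in markers:
            w.writerow([
                m.name,
                "F/R",
                f"{m.forward.sequence}/{m.reverse.sequence}",
                f"{m.forward.tm_celsius:.1f}/{m.reverse.tm_celsius:.1f}",
                f"{m.annealing_temp:.0f}",
                str(m.expected_size),
                m.target_species,
            ])


def read_marker_report(path: str | Path) -> list:
    """Load marker pairs back from the one-row-per-pair report."""
    from .marker_design import MarkerPair, PrimerCandidate  # avoid cycle

    markers = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            fseq, rseq = row["sequence_5p_3p"].split("/")
            tmf, tmr = (float(x) for x in row["tm_celsius"].split("/"))
            name = row["name"]
            fwd = PrimerCandidate(f"{name}_F", "F", fseq, (0, len(fseq)), tmf, True)
            rev = PrimerCandidate(f"{name}_R", "R", rseq, (0, len(rseq)), tmr, True)
            markers.append(MarkerPair(
                name, fwd, rev, row["specificity"],
                int(row["expected_size_bp"]),
                float(row["annealing_temp_celsius"])))
    return markers


def write_primer_table(markers: Sequence, path: str | Path) -> None:
    """Write one row per primer (forward then reverse), gel-notebook style."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(MARKER_REPORT_COLUMNS)
        for m in markers:
            for p in (m.forward, m.reverse):
                w.writerow([
                    p.name, p.sense, p.sequence, f"{p.tm_celsius:.1f}",
                    f"{m.annealing_temp:.0f}", str(m.expected_size), m.target_species,
                ])


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N,-} alphabet."""
    comp = str.maketrans("ACGTN-", "TGCAN-")
    return seq.translate(comp)[::-1]
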