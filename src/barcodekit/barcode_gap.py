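"""Per-species barcoding-gap verdicts on a labelled distance matrix.

Discrimination follows the CBOL criterion: a species is considered
discriminated when its maximum intraspecific distance is strictly lower
than its minimum interspecific distance (species versus all other species
pooled).  Species with a single sample have no intraspecific pairs and are
reported as not assessable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .distances import DistanceMatrix
from .errors import BarcodeKitError


@dataclass(frozen=True)
class GapReport:
    species: str
    n_samples: int
    min_intra: float | None
    max_intra: float | None
    min_inter: float
    max_inter: float
    discriminated: bool | None  # None = not assessable (single sample)

    @property
    def assessable(self) -> bool:
        return self.discriminated is not None


def _extrema(values: np.ndarray) -> tuple[float | None, float | None]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return None, None
    return float(values.min()), float(values.max())


def gap_analysis(matrix: DistanceMatrix, species_of: Mapping[str, str]
                 ) -> list[GapReport]:
    """One :class:`GapReport` per species, in first-appearance order.

    Intraspecific pairs are those within the species; interspecific pairs
    are between the species and all others pooled.  Undefined (NaN)
    distances are excluded from the extrema with a warning.
    """
    labels = matrix.labels
    missing = [l for l in labels if l not in species_of]
    if missing:
        raise BarcodeKitError(f"unlabeled sample(s): {missing}")
    species_arr = np.array([species_of[l] for l in labels])
    species_order = list(dict.fromkeys(species_arr))
    if len(species_order) < 2:
        raise BarcodeKitError("gap analysis needs at least 2 species")
    if np.isnan(matrix.d).any():
        warnings.warn("undefined distances excluded from gap extrema")
    iu = np.triu_indices(len(labels), k=1)
    pair_species = (species_arr[iu[0]], species_arr[iu[1]])
    pair_d = matrix.d[iu]
    reports = []
    for sp in species_order:
        in_a = pair_species[0] == sp
        in_b = pair_species[1] == sp
        intra = pair_d[in_a & in_b]
        inter = pair_d[in_a ^ in_b]
        min_intra, max_intra = _extrema(intra)
        min_inter, max_inter = _extrema(inter)
        if min_inter is None:
            raise BarcodeKitError(f"species {sp!r}: no interspecific pairs")
        verdict = None if max_intra is None else bool(max_intra < min_inter)
        reports.append(GapReport(
            species=sp,
            n_samples=int((species_arr == sp).sum()),
            min_intra=min_intra, max_intra=max_intra,
            min_inter=min_inter, max_inter=max_inter,
            discriminated=verdict,
        ))
    return reports


def discrimination_count(reports: list[GapReport]) -> int:
    """Number of species with a positive discrimination verdict."""
    if not reports:
        raise BarcodeKitError("no reports")
    return sum(1 for r in reports if r.discriminated is True)


def write_gap_report(reports: list[GapReport], path) -> None:
    """Species-by-species min/max intra- and interspecific distances, TSV."""
    import csv

    def fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.6f}"

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["species", "n_samples", "min_intra", "max_intra",
                    "min_inter", "max_inter", "discriminated"])
        for r in reports:
            w.writerow([r.species, r.n_samples, fmt(r.min_intra), fmt(r.max_intra),
                        fmt(r.min_inter), fmt(r.max_inter),
                        "NA" if r.discriminated is None else str(r.discriminated).lower()])
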