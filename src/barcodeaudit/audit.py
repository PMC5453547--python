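"""Species-level diagnosability audit and summary tables.

Each barcoded species is classified into a *set* of categories:

* ``SHARING`` — some haplotype group contains specimens of at least one
  other species (destroys distance-based diagnosability);
* ``LOW_DIVERGENCE`` — nearest neighbor below the low-divergence ceiling
  but no sharing;
* ``DEEP_SPLIT`` — maximum intraspecific divergence above the deep-split
  floor (can coexist with either of the above);
* ``DIAGNOSTIC`` — the complement of SHARING;
* ``UNASSESSED`` — no defined interspecific comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Optional, Sequence

from .distance import (
    DEFAULT_HAPLOTYPE_MIN_OVERLAP,
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    NNRecord,
    collapse_haplotypes,
    pairwise_matrix,
    species_nn,
)
from .records import SpecimenCollection, Status

DEFAULT_LOW_DIV_MAX = 1.0   # percent
DEFAULT_DEEP_SPLIT_MIN = 2.0  # percent


class Category(str, Enum):
    SHARING = "SHARING"
    LOW_DIVERGENCE = "LOW_DIVERGENCE"
    DEEP_SPLIT = "DEEP_SPLIT"
    DIAGNOSTIC = "DIAGNOSTIC"
    UNASSESSED = "UNASSESSED"


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """``100*count/total`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding, to match conventional one-decimal
    percentage reporting on .x5 boundaries.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def classify_species(
    nn: Optional[NNRecord],
    sharing_flag: bool,
    low_div_max: float = DEFAULT_LOW_DIV_MAX,
    deep_split_min: float = DEFAULT_DEEP_SPLIT_MIN,
) -> frozenset[Category]:
    """Category set for one species (thresholds in percent)."""
    if nn is None or not nn.defined:
        return frozenset({Category.UNASSESSED})
    cats: set[Category] = set()
    if sharing_flag:
        cats.add(Category.SHARING)
    else:
        cats.add(Category.DIAGNOSTIC)
        if nn.nn_distance is not None and 0.0 < nn.nn_distance < low_div_max:
            cats.add(Category.LOW_DIVERGENCE)
    if nn.intra_max is not None and nn.intra_max > deep_split_min:
        cats.add(Category.DEEP_SPLIT)
    return frozenset(cats)


@dataclass
class SpeciesSummary:
    """Per-species audit row."""

    species: str
    genus: str
    family: str
    n_specimens: int
    n_haplotypes: int
    intra_mean: Optional[float]
    intra_max: Optional[float]
    nn_distance: Optional[float]
    nn_species: Optional[str]
    categories: frozenset[Category]
    status: Status = Status.UNKNOWN

    @property
    def assessed(self) -> bool:
        return Category.UNASSESSED not in self.categories

    def to_dict(self) -> dict:
        d = {
            "species": self.species,
            "genus": self.genus,
            "family": self.family,
            "n_specimens": self.n_specimens,
            "n_haplotypes": self.n_haplotypes,
            "intra_mean": self.intra_mean,
            "intra_max": self.intra_max,
            "nn_distance": self.nn_distance,
            "nn_species": self.nn_species,
            "categories": ";".join(sorted(c.value for c in self.categories)),
            "status": self.status.value,
        }
        return d


def sharing_species(matrix: DistanceMatrix, species_of: dict[str, str],
                    hap_min_overlap: int = DEFAULT_HAPLOTYPE_MIN_OVERLAP) -> set[str]:
    """Species occurring in a haplotype group with at least one other species."""
    groups = collapse_haplotypes(matrix, hap_min_overlap)
    shared: set[str] = set()
    for members in groups.groups:
        sp = {species_of[m] for m in members}
        if len(sp) >= 2:
            shared |= sp
    return shared


def build_species_summaries(
    collection: SpecimenCollection,
    matrix: Optional[DistanceMatrix] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    hap_min_overlap: int = DEFAULT_HAPLOTYPE_MIN_OVERLAP,
    low_div_max: float = DEFAULT_LOW_DIV_MAX,
    deep_split_min: float = DEFAULT_DEEP_SPLIT_MIN,
) -> list[SpeciesSummary]:
    """Full audit of the sequenced specimens in a collection."""
    if matrix is None:
        matrix = pairwise_matrix(collection, min_overlap)
    species_of = collection.species_of()
    genus_of = collection.genus_of_species()
    family_of = collection.family_of_species()
    status_of: dict[str, Status] = {}
    for rec in collection:
        if rec.species not in status_of or rec.status != Status.UNKNOWN:
            status_of[rec.species] = rec.status

    groups = collapse_haplotypes(matrix, hap_min_overlap)
    shared: set[str] = set()
    hapcount: dict[str, set[int]] = {}
    for gi, members in enumerate(groups.groups):
        sp = {species_of[m] for m in members}
        if len(sp) >= 2:
            shared |= sp
        for s in sp:
            hapcount.setdefault(s, set()).add(gi)

    nn_records = {r.species: r for r in species_nn(matrix, species_of)}
    summaries = []
    for species in sorted(nn_records):
        nn = nn_records[species]
        cats = classify_species(nn, species in shared, low_div_max, deep_split_min)
        summaries.append(
            SpeciesSummary(
                species=species,
                genus=genus_of.get(species, species.split()[0]),
                family=family_of.get(species, ""),
                n_specimens=nn.n_specimens,
                n_haplotypes=len(hapcount.get(species, ())),
                intra_mean=nn.intra_mean,
                intra_max=nn.intra_max,
                nn_distance=nn.nn_distance,
                nn_species=nn.nn_species,
                categories=cats,
                status=status_of.get(species, Status.UNKNOWN),
            )
        )
    summaries.sort(key=lambda s: (s.family, s.genus, s.species))
    return summaries


def identification_success(summaries: Iterable[SpeciesSummary], decimals: int = 1) -> float:
    """Percent of assessed species that are DIAGNOSTIC (not SHARING)."""
    assessed = [s for s in summaries if s.assessed]
    if not assessed:
        raise ValueError("no assessed species: identification success undefined")
    diagnostic = sum(1 for s in assessed if Category.DIAGNOSTIC in s.categories)
    return percentage(diagnostic, len(assessed), decimals)


def category_incidence(
    summaries: Iterable[SpeciesSummary], category: Category, decimals: int = 1
) -> float:
    """Percent of assessed species carrying ``category``."""
    assessed = [s for s in summaries if s.assessed]
    if not assessed:
        raise ValueError("no assessed species")
    n = sum(1 for s in assessed if category in s.categories)
    return percentage(n, len(assessed), decimals)


@dataclass
class FamilyRow:
    family: str
    species_total: int
    species_barcoded: int
    coverage_pct: Optional[float]
    n_sequences: int
    n_clusters: Optional[int]
    mean_nnd: Optional[float]
    mean_intra: Optional[float]
    id_success_pct: Optional[float]
    sharing_pct: Optional[float]
    n_sharing: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _mean(values: Sequence[float]) -> Optional[float]:
    vals = [v for v in values if v is not None and not math.isnan(v)]
    return sum(vals) / len(vals) if vals else None


def _family_row(
    name: str,
    all_species: set[str],
    summaries: list[SpeciesSummary],
    n_sequences: int,
    n_clusters: Optional[int],
) -> FamilyRow:
    barcoded = [s for s in summaries if s.assessed]
    n_sharing = sum(1 for s in barcoded if Category.SHARING in s.categories)
    nb = len(barcoded)
    return FamilyRow(
        family=name,
        species_total=len(all_species),
        species_barcoded=nb,
        coverage_pct=percentage(nb, len(all_species)) if all_species else None,
        n_sequences=n_sequences,
        n_clusters=n_clusters,
        mean_nnd=_mean([s.nn_distance for s in barcoded]),
        mean_intra=_mean([s.intra_mean for s in barcoded]),
        id_success_pct=percentage(nb - n_sharing, nb) if nb else None,
        sharing_pct=percentage(n_sharing, nb) if nb else None,
        n_sharing=n_sharing,
    )


def family_table(
    collection: SpecimenCollection,
    summaries: Sequence[SpeciesSummary],
    partition=None,
) -> list[FamilyRow]:
    """One row per family plus a pooled ``Total`` row.

    Species totals include sequence-less species (no-barcode coverage
    accounting); per-species means are taken over assessed species.  When a
    cluster partition is supplied, per-family cluster counts are included.
    """
    fam_species: dict[str, set[str]] = {}
    fam_nseq: dict[str, int] = {}
    for rec in collection:
        fam_species.setdefault(rec.family, set()).add(rec.species)
        if rec.has_sequence:
            fam_nseq[rec.family] = fam_nseq.get(rec.family, 0) + 1
    fam_clusters: dict[str, set[str]] = {}
    total_clusters: Optional[int] = None
    if partition is not None:
        fam_of_id = {r.specimen_id: r.family for r in collection}
        for sid, label in partition.assignments.items():
            fam = fam_of_id.get(sid)
            if fam is not None:
                fam_clusters.setdefault(fam, set()).add(label)
        total_clusters = len(set(partition.assignments.values()))

    by_family: dict[str, list[SpeciesSummary]] = {}
    for s in summaries:
        by_family.setdefault(s.family, []).append(s)

    rows = []
    for fam in sorted(fam_species):
        rows.append(
            _family_row(
                fam,
                fam_species[fam],
                by_family.get(fam, []),
                fam_nseq.get(fam, 0),
                len(fam_clusters[fam]) if fam in fam_clusters else None,
            )
        )
    rows.append(
        _family_row(
            "Total",
            set().union(*fam_species.values()) if fam_species else set(),
            list(summaries),
            sum(fam_nseq.values()),
            total_clusters,
        )
    )
    return rows


# Fig-2-style genus-size bins: {1}, {2-3}, {4-7}, {8-15}, {16-31}, {32-63}, {>=64}
N_GENUS_BINS = 7


def genus_size_bin(n_species: int) -> int:
    if n_species < 1:
        raise ValueError("genus must contain at least one species")
    return min(N_GENUS_BINS, n_species.bit_length())


@dataclass
class GenusProfile:
    genus: str
    n_species: int
    n_sharing: int
    log2_bin: int


@dataclass
class BinStats:
    log2_bin: int
    n_genera: int
    n_species: int
    n_sharing: int
    sharing_pct: Optional[float]


def genus_sharing_profile(summaries: Iterable[SpeciesSummary]) -> list[GenusProfile]:
    """Per-genus species and sharing counts with log2 size bin."""
    by_genus: dict[str, list[SpeciesSummary]] = {}
    for s in summaries:
        by_genus.setdefault(s.genus, []).append(s)
    out = []
    for genus in sorted(by_genus):
        members = by_genus[genus]
        n_sharing = sum(1 for s in members if Category.SHARING in s.categories)
        out.append(GenusProfile(genus, len(members), n_sharing, genus_size_bin(len(members))))
    return out


def bin_profile(profile: Iterable[GenusProfile]) -> dict[int, BinStats]:
    """Pool the per-genus profile into the seven log2 size bins."""
    stats = {
        k: BinStats(k, 0, 0, 0, None) for k in range(1, N_GENUS_BINS + 1)
    }
    for g in profile:
        b = stats[g.log2_bin]
        b.n_genera += 1
        b.n_species += g.n_species
        b.n_sharing += g.n_sharing
    for b in stats.values():
        if b.n_species:
            b.sharing_pct = percentage(b.n_sharing, b.n_species)
    return stats


def pooled_sharing_pct(
    profile: Iterable[GenusProfile], bins: Iterable[int], decimals: int = 1
) -> float:
    """Sharing percentage pooled over a selection of genus-size bins."""
    wanted = set(bins)
    n_species = n_sharing = 0
    for g in profile:
        if g.log2_bin in wanted:
            n_species += g.n_species
            n_sharing += g.n_sharing
    if n_species == 0:
        raise ValueError("selected bins contain no species")
    return percentage(n_sharing, n_species, decimals)


def write_species_summaries(summaries: Sequence[SpeciesSummary], tsv_path, json_path=None) -> None:
    import pandas as pd

    df = pd.DataFrame([s.to_dict() for s in summaries])
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump([s.to_dict() for s in summaries], fh, indent=2)


def write_family_table(rows: Sequence[FamilyRow], tsv_path, json_path=None) -> None:
    import pandas as pd

    df = pd.DataFrame([r.to_dict() for r in rows])
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump([r.to_dict() for r in rows], fh, indent=2)
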