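"""Assemblage partitioning: regional re-analysis, bands, overlap/endemism.

GIS is out of scope — ecoregion and zoogeographic labels arrive as inputs;
only latitude/longitude band assignment is computed here (pure arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .audit import (
    Category,
    DEFAULT_DEEP_SPLIT_MIN,
    DEFAULT_LOW_DIV_MAX,
    SpeciesSummary,
    build_species_summaries,
    identification_success,
    percentage,
)
from .clustering import DEFAULT_CLUSTER_THRESHOLD_PCT, ClusterPartition, single_linkage_clusters
from .distance import (
    DEFAULT_HAPLOTYPE_MIN_OVERLAP,
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    pairwise_matrix,
)
from .records import SpecimenCollection, ZOOGEO_REGIONS

#: 15-label input scheme
ECOREGIONS_15 = (
    "Arctic Cordillera",
    "Tundra",
    "Taiga",
    "Hudson Plains",
    "Northern Forests",
    "Northwestern Forested Mountains",
    "Marine West Coast Forests",
    "Eastern Temperate Forests",
    "Great Plains",
    "North American Deserts",
    "Mediterranean California",
    "Southern Semi-Arid Highlands",
    "Temperate Sierras",
    "Tropical Dry Forests",
    "Tropical Wet Forests",
)

_COLLAPSE = {
    "Arctic Cordillera": "Arctic",
    "Tundra": "Arctic",
    "Taiga": "Boreal",
    "Hudson Plains": "Boreal",
    "Hudson Plain": "Boreal",
    "Northern Forests": "Boreal",
}

#: 12-label analysis scheme after collapsing
ECOREGIONS_12 = ("Arctic", "Boreal") + ECOREGIONS_15[5:]

LATITUDE_EDGES = (25, 30, 35, 40, 45, 50, 55)
LONGITUDE_EDGES = (75, 85, 95, 105, 115, 125, 135)

PARTITION_KEYS = ("ecoregion", "lat_band", "lon_band", "zoogeo_region")


def collapse_ecoregions(label: str) -> str:
    """Map a 15-scheme ecoregion label to the 12-region analysis scheme."""
    if label in _COLLAPSE:
        return _COLLAPSE[label]
    if label in ECOREGIONS_15 or label in ECOREGIONS_12:
        return label
    valid = sorted(set(ECOREGIONS_15) | set(ECOREGIONS_12))
    raise ValueError(f"unknown ecoregion {label!r}; valid labels: {valid}")


def _band(value: float, edges: Sequence[int]) -> str:
    # lower-inclusive, upper-exclusive; extremes open
    if value < edges[0]:
        return f"<{edges[0]}"
    if value >= edges[-1]:
        return f">{edges[-1]}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= value < hi:
            return f"{lo}-{hi}"
    raise AssertionError("unreachable")


def latitude_band(lat: float) -> str:
    """5-degree latitude band label (edges 25..55)."""
    if not -90 <= lat <= 90:
        raise ValueError(f"latitude out of range: {lat}")
    return _band(lat, LATITUDE_EDGES)


def longitude_band(lon: float) -> Optional[str]:
    """10-degree band over \\|lon\\| for western longitudes (edges 75..135).

    Returns None for eastern (positive) longitudes, which fall outside the
    west-longitude banding scheme.
    """
    if not -180 <= lon <= 180:
        raise ValueError(f"longitude out of range: {lon}")
    if lon > 0:
        return None
    return _band(abs(lon), LONGITUDE_EDGES)


def partition_label(record, key: str) -> Optional[str]:
    """The partition label of one specimen under ``key`` (None = skipped)."""
    if key == "ecoregion":
        return collapse_ecoregions(record.ecoregion) if record.ecoregion else None
    if key == "lat_band":
        return latitude_band(record.latitude) if record.latitude is not None else None
    if key == "lon_band":
        return longitude_band(record.longitude) if record.longitude is not None else None
    if key == "zoogeo_region":
        return record.zoogeo_region
    raise ValueError(f"unknown partition key {key!r}; expected one of {PARTITION_KEYS}")


@dataclass
class AssemblageSummary:
    """Audit statistics recomputed within one partition."""

    label: str
    n_sequences: int
    n_clusters: Optional[int]
    n_species: int
    n_genera: int
    mean_nnd: Optional[float]
    max_nnd: Optional[float]
    mean_intra: Optional[float]
    max_intra: Optional[float]
    id_success_pct: Optional[float]
    n_sharing: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _summarize(label: str, sub: SpecimenCollection, matrix: Optional[DistanceMatrix],
               cluster_threshold_pct: float, hap_min_overlap: int,
               low_div_max: float, deep_split_min: float) -> AssemblageSummary:
    seqd = sub.sequenced()
    n_species = len({r.species for r in seqd})
    n_genera = len({r.genus for r in seqd})
    n_clusters = None
    mean_nnd = max_nnd = mean_intra = max_intra = id_pct = None
    n_sharing = 0
    if matrix is not None and n_species >= 2:
        summaries = build_species_summaries(
            sub, matrix, hap_min_overlap=hap_min_overlap,
            low_div_max=low_div_max, deep_split_min=deep_split_min,
        )
        nnds = [s.nn_distance for s in summaries if s.nn_distance is not None]
        intras_mean = [s.intra_mean for s in summaries if s.intra_mean is not None]
        intras_max = [s.intra_max for s in summaries if s.intra_max is not None]
        mean_nnd = sum(nnds) / len(nnds) if nnds else None
        max_nnd = max(nnds) if nnds else None
        mean_intra = sum(intras_mean) / len(intras_mean) if intras_mean else None
        max_intra = max(intras_max) if intras_max else None
        assessed = [s for s in summaries if s.assessed]
        if assessed:
            id_pct = identification_success(summaries)
            n_sharing = sum(1 for s in assessed if Category.SHARING in s.categories)
        n_clusters = single_linkage_clusters(matrix, cluster_threshold_pct).n_clusters()
    elif matrix is not None and len(matrix) >= 1:
        n_clusters = single_linkage_clusters(matrix, cluster_threshold_pct).n_clusters()
    return AssemblageSummary(
        label=label,
        n_sequences=len(seqd),
        n_clusters=n_clusters,
        n_species=n_species,
        n_genera=n_genera,
        mean_nnd=mean_nnd,
        max_nnd=max_nnd,
        mean_intra=mean_intra,
        max_intra=max_intra,
        id_success_pct=id_pct,
        n_sharing=n_sharing,
    )


def partition_and_summarize(
    collection: SpecimenCollection,
    key: str,
    matrix: Optional[DistanceMatrix] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    hap_min_overlap: int = DEFAULT_HAPLOTYPE_MIN_OVERLAP,
    cluster_threshold_pct: float = DEFAULT_CLUSTER_THRESHOLD_PCT,
    low_div_max: float = DEFAULT_LOW_DIV_MAX,
    deep_split_min: float = DEFAULT_DEEP_SPLIT_MIN,
) -> tuple[list[AssemblageSummary], int]:
    """Recompute the audit within every partition under ``key``.

    Only each partition's own specimens (and hence species) enter its
    statistics.  A pooled ``Total`` row over all partitioned specimens is
    appended.  Returns the summaries and the number of specimens skipped
    for missing the partitioning field.
    """
    if key not in PARTITION_KEYS:
        raise ValueError(f"unknown partition key {key!r}; expected one of {PARTITION_KEYS}")
    groups: dict[str, list[str]] = {}
    skipped = 0
    for rec in collection.sequenced():
        label = partition_label(rec, key)
        if label is None:
            skipped += 1
            continue
        groups.setdefault(label, []).append(rec.specimen_id)
    if matrix is None and len(collection.sequenced()) >= 2:
        matrix = pairwise_matrix(collection, min_overlap)

    out: list[AssemblageSummary] = []
    for label in sorted(groups):
        ids = groups[label]
        sub = collection.subset(ids)
        sub_matrix = matrix.subset(ids) if (matrix is not None and len(ids) >= 2) else None
        out.append(_summarize(label, sub, sub_matrix, cluster_threshold_pct,
                              hap_min_overlap, low_div_max, deep_split_min))
    pooled_ids = [sid for ids in groups.values() for sid in ids]
    if pooled_ids:
        sub = collection.subset(pooled_ids)
        sub_matrix = matrix.subset(pooled_ids) if (matrix is not None and len(pooled_ids) >= 2) else None
        out.append(_summarize("Total", sub, sub_matrix, cluster_threshold_pct,
                              hap_min_overlap, low_div_max, deep_split_min))
    return out, skipped


def presence_absence_matrix(
    collection: SpecimenCollection, key: str
) -> tuple[pd.DataFrame, int]:
    """Species x partition boolean matrix plus count of skipped specimens."""
    rows: dict[str, set[str]] = {}
    labels: set[str] = set()
    skipped = 0
    for rec in collection:
        label = partition_label(rec, key)
        if label is None:
            skipped += 1
            continue
        rows.setdefault(rec.species, set()).add(label)
        labels.add(label)
    cols = sorted(labels)
    data = {
        sp: [label in present for label in cols]
        for sp, present in sorted(rows.items())
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    df.index.name = "species"
    return df, skipped


@dataclass
class OverlapMatrix:
    """Cluster presence across zoogeographic regions, by family and total."""

    regions: tuple[str, ...]
    counts: pd.DataFrame        # family rows + "Total"; per-region cluster counts
    pcts: pd.DataFrame          # same shape; percentages of the family's clusters
    n_clusters: dict[str, int]  # per family + "Total"
    endemic_region: str
    n_endemic: int
    endemic_pct: Optional[float]
    n_excluded: int = 0         # clusters with no region information

    def region_pct(self, region: str, decimals: int = 1) -> float:
        """Overall share of clusters present in ``region``."""
        return percentage(int(self.counts.loc["Total", region]),
                          self.n_clusters["Total"], decimals)

    def write_tsv(self, path) -> None:
        cells = self.counts.astype(str) + "/" + self.pcts.round(2).astype(str)
        cells.insert(0, "n_clusters", [self.n_clusters[f] for f in cells.index])
        cells.index.name = "family"
        cells.to_csv(path, sep="\t")


def region_overlap(
    cluster_regions: Mapping[str, Iterable[str]],
    cluster_families: Optional[Mapping[str, str]] = None,
    regions: Sequence[str] = ZOOGEO_REGIONS,
    endemic_region: str = "Nearctic",
) -> OverlapMatrix:
    """Overlap/endemism table from per-cluster region sets.

    ``cluster_regions`` maps a cluster label to the set of zoogeographic
    regions where its members were recorded.  Clusters with an empty region
    set are excluded (counted).  Endemics are clusters present only in
    ``endemic_region``.
    """
    regions = tuple(regions)
    fams = cluster_families or {}
    per_family: dict[str, dict[str, int]] = {}
    totals = {r: 0 for r in regions}
    n_by_family: dict[str, int] = {}
    n_total = 0
    n_endemic = 0
    n_excluded = 0
    for cluster, rset in cluster_regions.items():
        rset = {r for r in rset if r}
        if not rset:
            n_excluded += 1
            continue
        unknown = rset - set(regions)
        if unknown:
            raise ValueError(f"cluster {cluster!r} has unknown region(s) {sorted(unknown)}")
        fam = fams.get(cluster, "unassigned")
        row = per_family.setdefault(fam, {r: 0 for r in regions})
        n_by_family[fam] = n_by_family.get(fam, 0) + 1
        n_total += 1
        for r in rset:
            row[r] += 1
            totals[r] += 1
        if rset == {endemic_region}:
            n_endemic += 1
    if n_total == 0:
        raise ValueError("no clusters with region information")
    families = sorted(per_family)
    counts = pd.DataFrame(
        [[per_family[f][r] for r in regions] for f in families] + [[totals[r] for r in regions]],
        index=families + ["Total"],
        columns=list(regions),
    )
    n_clusters = dict(n_by_family)
    n_clusters["Total"] = n_total
    pcts = counts.copy().astype(float)
    for f in pcts.index:
        pcts.loc[f] = 100.0 * counts.loc[f] / n_clusters[f]
    return OverlapMatrix(
        regions=regions,
        counts=counts,
        pcts=pcts,
        n_clusters=n_clusters,
        endemic_region=endemic_region,
        n_endemic=n_endemic,
        endemic_pct=percentage(n_endemic, n_total),
        n_excluded=n_excluded,
    )


def cluster_regions_from_collection(
    partition: ClusterPartition, collection: SpecimenCollection
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Derive per-cluster region sets and family labels from specimens.

    A cluster's family is the most common family among its members (ties
    broken lexicographically).
    """
    regions: dict[str, set[str]] = {}
    fam_votes: dict[str, dict[str, int]] = {}
    for sid, label in partition.assignments.items():
        rec = collection.by_id[sid]
        regions.setdefault(label, set())
        if rec.zoogeo_region:
            regions[label].add(rec.zoogeo_region)
        if rec.family:
            votes = fam_votes.setdefault(label, {})
            votes[rec.family] = votes.get(rec.family, 0) + 1
    families = {}
    for label, votes in fam_votes.items():
        families[label] = min(votes, key=lambda f: (-votes[f], f))
    return regions, families


def write_assemblage_tsv(summaries: Sequence[AssemblageSummary], path) -> None:
    pd.DataFrame([s.to_dict() for s in summaries]).to_csv(path, sep="\t", index=False)
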