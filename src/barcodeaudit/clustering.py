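"""Cluster assignment and species/cluster concordance.

Clusters are either supplied externally (e.g. registry-assigned BIN labels
carried in the specimen table) or computed as a documented surrogate:
single-linkage connected components over pairs at or below a distance
threshold.  The surrogate is *not* the registry algorithm; externally
supplied labels are preferred when present.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .audit import percentage
from .distance import DistanceMatrix, _UnionFind
from .records import SpecimenCollection

DEFAULT_CLUSTER_THRESHOLD_PCT = 2.2


@dataclass
class ClusterPartition:
    """Specimen -> cluster label assignment."""

    assignments: dict[str, str]
    source: str  # "supplied_bins" | "single_linkage"
    threshold_pct: Optional[float] = None
    flagged_singletons: tuple[str, ...] = ()

    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, label in self.assignments.items():
            out.setdefault(label, []).append(sid)
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("specimen_id\tcluster\tsource\n")
            for sid in sorted(self.assignments):
                fh.write(f"{sid}\t{self.assignments[sid]}\t{self.source}\n")


def single_linkage_clusters(
    matrix: DistanceMatrix, threshold_pct: float = DEFAULT_CLUSTER_THRESHOLD_PCT
) -> ClusterPartition:
    """Single-linkage clusters at a distance threshold (percent).

    Clusters are connected components of the graph joining pairs with a
    defined distance at or below the threshold.  Labels are deterministic:
    the lexicographically smallest member id.  Specimens with no defined
    comparison become flagged singletons.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    thr = threshold_pct / 100.0
    n = len(matrix)
    uf = _UnionFind(n)
    edges = matrix.defined & (matrix.distance <= thr)
    ii, jj = np.nonzero(np.triu(edges, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        uf.union(i, j)

    comp_members: dict[int, list[str]] = {}
    for i, sid in enumerate(matrix.ids):
        comp_members.setdefault(uf.find(i), []).append(sid)

    # a specimen is flagged when it has no defined off-diagonal comparison
    off = matrix.defined.copy()
    np.fill_diagonal(off, False)
    no_comparison = ~off.any(axis=1)

    assignments: dict[str, str] = {}
    flagged: list[str] = []
    for members in comp_members.values():
        label = min(members)
        for sid in members:
            assignments[sid] = label
    for i, sid in enumerate(matrix.ids):
        if no_comparison[i] and len(comp_members[uf.find(i)]) == 1:
            flagged.append(sid)
    return ClusterPartition(
        assignments, "single_linkage", threshold_pct, tuple(sorted(flagged))
    )


def partition_from_bins(collection: SpecimenCollection) -> ClusterPartition:
    """Pass through externally supplied bin_id labels.

    Sequenced specimens lacking a bin_id become flagged singleton clusters
    labelled by their own id.
    """
    assignments: dict[str, str] = {}
    flagged: list[str] = []
    for rec in collection.sequenced():
        if rec.bin_id:
            assignments[rec.specimen_id] = rec.bin_id
        else:
            assignments[rec.specimen_id] = rec.specimen_id
            flagged.append(rec.specimen_id)
    return ClusterPartition(assignments, "supplied_bins", None, tuple(sorted(flagged)))


class ConcordanceCategory(str, Enum):
    MATCH = "MATCH"      # one cluster, unshared
    SPLIT = "SPLIT"      # >=2 clusters, none shared
    MERGE = "MERGE"      # one cluster, shared
    MIXTURE = "MIXTURE"  # >=2 clusters, >=1 shared


@dataclass
class ConcordanceRecord:
    species: str
    clusters: tuple[str, ...]
    shares_cluster: bool
    category: ConcordanceCategory

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def concordance_classify(
    species_of: Mapping[str, str], partition: ClusterPartition
) -> list[ConcordanceRecord]:
    """Classify every species by its cluster occupancy.

    A cluster is *shared* when it holds specimens of two or more species.
    """
    cluster_species: dict[str, set[str]] = {}
    species_clusters: dict[str, set[str]] = {}
    for sid, label in partition.assignments.items():
        if sid not in species_of:
            raise KeyError(f"specimen {sid!r} has a cluster but no species")
        sp = species_of[sid]
        cluster_species.setdefault(label, set()).add(sp)
        species_clusters.setdefault(sp, set()).add(label)
    out = []
    for sp in sorted(species_clusters):
        clusters = tuple(sorted(species_clusters[sp]))
        shared = any(len(cluster_species[c]) >= 2 for c in clusters)
        if len(clusters) == 1:
            cat = ConcordanceCategory.MERGE if shared else ConcordanceCategory.MATCH
        else:
            cat = ConcordanceCategory.MIXTURE if shared else ConcordanceCategory.SPLIT
        out.append(ConcordanceRecord(sp, clusters, shared, cat))
    return out


def concordance_counts(records: Sequence[ConcordanceRecord]) -> dict:
    """Counts, split-multiplicity histogram and MATCH percentage."""
    if not records:
        raise ValueError("no concordance records")
    counts = Counter(r.category for r in records)
    histogram = {"2": 0, "3": 0, "4+": 0}
    for r in records:
        if r.n_clusters == 2:
            histogram["2"] += 1
        elif r.n_clusters == 3:
            histogram["3"] += 1
        elif r.n_clusters >= 4:
            histogram["4+"] += 1
    n = len(records)
    return {
        "n_species": n,
        "n_match": counts.get(ConcordanceCategory.MATCH, 0),
        "n_split": counts.get(ConcordanceCategory.SPLIT, 0),
        "n_merge": counts.get(ConcordanceCategory.MERGE, 0),
        "n_mixture": counts.get(ConcordanceCategory.MIXTURE, 0),
        "histogram": histogram,
        "pct_match": percentage(counts.get(ConcordanceCategory.MATCH, 0), n),
    }


def bin_count_vs_species(
    partition: ClusterPartition, species_of: Mapping[str, str]
) -> dict:
    """Cluster count vs species count with signed excess percentage."""
    n_clusters = partition.n_clusters()
    n_species = len({species_of[s] for s in partition.assignments})
    if n_species == 0:
        raise ValueError("no species in partition")
    return {
        "n_clusters": n_clusters,
        "n_species": n_species,
        "excess_pct": percentage(n_clusters - n_species, n_species),
    }


def write_concordance_tsv(records: Sequence[ConcordanceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tcategory\tn_clusters\tclusters\n")
        for r in records:
            fh.write(f"{r.species}\t{r.category.value}\t{r.n_clusters}\t{','.join(r.clusters)}\n")
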