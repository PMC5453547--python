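"""Kimura-2-parameter distances, haplotype collapsing and nearest neighbors.

Distances are computed under pairwise deletion: only positions where both
sequences carry A/C/G/T contribute.  They are stored as fractions and
rendered as percentages only at reporting boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import AlignedSequence, FRAME_LENGTH, SpecimenCollection

#: default minimum overlap (defined positions in both sequences) for a
#: distance to be considered defined
DEFAULT_MIN_OVERLAP = 300
#: stricter overlap floor for calling two sequences the same haplotype
DEFAULT_HAPLOTYPE_MIN_OVERLAP = 500

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def encode_sequences(residues: Sequence[str], frame_length: int) -> np.ndarray:
    """Encode sequences as a (n, L) uint8 array; 0..3 = ACGT, 4 = missing."""
    n = len(residues)
    arr = np.full((n, frame_length), 4, dtype=np.uint8)
    for i, s in enumerate(residues):
        row = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        out = np.full(frame_length, 4, dtype=np.uint8)
        for base, code in _CODE.items():
            out[: len(row)][row == ord(base)] = code
        arr[i] = out
    return arr


@dataclass(frozen=True)
class PairwiseComparison:
    """K2P comparison of one sequence pair under pairwise deletion."""

    overlap: int
    transitions_p: float
    transversions_q: float
    distance: Optional[float]
    defined: bool


def _k2p_from_counts(overlap: int, ts: int, tv: int, min_overlap: int) -> PairwiseComparison:
    if overlap == 0:
        return PairwiseComparison(0, 0.0, 0.0, None, False)
    p = ts / overlap
    q = tv / overlap
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if overlap < min_overlap or w1 <= 0.0 or w2 <= 0.0:
        return PairwiseComparison(overlap, p, q, None, False)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseComparison(overlap, p, q, d, True)


def k2p_distance(
    a: AlignedSequence, b: AlignedSequence, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> PairwiseComparison:
    """K2P distance between two frame-aligned sequences.

    ``distance = -0.5*ln(1-2P-Q) - 0.25*ln(1-2Q)`` where P and Q are the
    transition and transversion proportions over the pairwise-deleted
    overlap.  The comparison is undefined when the overlap is below
    ``min_overlap`` or either logarithm argument is non-positive.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    sa = a.padded()
    sb = b.padded()
    if len(sa) != len(sb):
        raise ValueError("sequences are not in the same coordinate frame")
    overlap = ts = tv = 0
    for ca, cb in zip(sa, sb):
        if ca not in _CODE or cb not in _CODE:
            continue
        overlap += 1
        if ca == cb:
            continue
        if _TRANSITION_PARTNER[ca] == cb:
            ts += 1
        else:
            tv += 1
    return _k2p_from_counts(overlap, ts, tv, min_overlap)


class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair overlap bookkeeping.

    ``distance`` holds fractions with NaN for undefined pairs; ``defined``
    is the companion boolean mask.  ``overlap``/``transitions``/
    ``transversions`` carry the per-pair counts when the matrix was built
    from sequences (they are ``None`` for matrices constructed directly
    from a square array, e.g. in tests).
    """

    def __init__(
        self,
        ids: Sequence[str],
        distance: np.ndarray,
        defined: np.ndarray,
        overlap: Optional[np.ndarray] = None,
        transitions: Optional[np.ndarray] = None,
        transversions: Optional[np.ndarray] = None,
        min_overlap: int = DEFAULT_MIN_OVERLAP,
    ):
        self.ids = list(ids)
        self.index = {sid: i for i, sid in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise ValueError("duplicate ids in distance matrix")
        self.distance = distance
        self.defined = defined
        self.overlap = overlap
        self.transitions = transitions
        self.transversions = transversions
        self.min_overlap = min_overlap

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_square(
        cls, ids: Sequence[str], distance: np.ndarray, defined: Optional[np.ndarray] = None
    ) -> "DistanceMatrix":
        """Build a matrix from a square distance array (testing/oracles)."""
        distance = np.asarray(distance, dtype=float)
        if defined is None:
            defined = ~np.isnan(distance)
        return cls(ids, distance, np.asarray(defined, dtype=bool))

    def get(self, id1: str, id2: str) -> PairwiseComparison:
        i, j = self.index[id1], self.index[id2]
        if self.overlap is None:
            d = self.distance[i, j]
            ok = bool(self.defined[i, j])
            return PairwiseComparison(
                FRAME_LENGTH, 0.0, 0.0, float(d) if ok else None, ok
            )
        return _k2p_from_counts(
            int(self.overlap[i, j]),
            int(self.transitions[i, j]),
            int(self.transversions[i, j]),
            self.min_overlap,
        )

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.index[s] for s in ids], dtype=int)
        grid = np.ix_(idx, idx)
        return DistanceMatrix(
            ids,
            self.distance[grid],
            self.defined[grid],
            None if self.overlap is None else self.overlap[grid],
            None if self.transitions is None else self.transitions[grid],
            None if self.transversions is None else self.transversions[grid],
            self.min_overlap,
        )

    def write_phylip(self, path) -> None:
        """Square PHYLIP-style matrix; undefined pairs written as -1."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            d = np.where(self.defined, self.distance, -1.0)
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in d[i])
                fh.write(f"{sid:<12s}{row}\n")

    def write_tsv(self, path) -> None:
        """Long-form export: id1, id2, overlap, P, Q, distance."""
        with open(path, "w") as fh:
            fh.write("id1\tid2\toverlap\tP\tQ\tdistance\n")
            n = len(self.ids)
            for i in range(n):
                for j in range(i + 1, n):
                    c = self.get(self.ids[i], self.ids[j])
                    dist = "" if c.distance is None else f"{c.distance:.8f}"
                    fh.write(
                        f"{self.ids[i]}\t{self.ids[j]}\t{c.overlap}\t"
                        f"{c.transitions_p:.8f}\t{c.transversions_q:.8f}\t{dist}\n"
                    )


def pairwise_matrix(
    collection, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs K2P matrix for the sequenced specimens of a collection.

    Accepts a :class:`SpecimenCollection` or a mapping id -> AlignedSequence.
    Vectorized via one-hot matrix products, so exact integer pair counts
    are recovered for the K2P closed form.
    """
    if isinstance(collection, SpecimenCollection):
        seqs = {r.specimen_id: r.sequence for r in collection.sequenced()}
    else:
        seqs = dict(collection)
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequenced specimens for a distance matrix")
    enc = encode_sequences([seqs[s].padded() for s in ids], FRAME_LENGTH)

    onehot = [(enc == c).astype(np.float64) for c in range(4)]
    definedmask = (enc < 4).astype(np.float64)

    overlap = definedmask @ definedmask.T
    matches = sum(x @ x.T for x in onehot)
    m_ag = onehot[_CODE["A"]] @ onehot[_CODE["G"]].T
    m_ct = onehot[_CODE["C"]] @ onehot[_CODE["T"]].T
    ts = m_ag + m_ag.T + m_ct + m_ct.T

    overlap = np.rint(overlap).astype(np.int64)
    ts = np.rint(ts).astype(np.int64)
    tv = overlap - np.rint(matches).astype(np.int64) - ts

    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(overlap > 0, ts / np.maximum(overlap, 1), 0.0)
        q = np.where(overlap > 0, tv / np.maximum(overlap, 1), 0.0)
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        defined = (overlap >= min_overlap) & (w1 > 0.0) & (w2 > 0.0)
        dist = np.where(
            defined, -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
            - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)), np.nan
        )
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(defined, True)
    return DistanceMatrix(ids, dist, defined, overlap, ts, tv, min_overlap)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


@dataclass
class HaplotypeGroups:
    """Connected components of the shared-haplotype relation."""

    groups: list[list[str]]
    group_of: dict[str, int]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def collapse_haplotypes(
    matrix: DistanceMatrix, min_overlap: int = DEFAULT_HAPLOTYPE_MIN_OVERLAP
) -> HaplotypeGroups:
    """Group specimens sharing a haplotype.

    Two specimens share iff they have zero mismatches over an overlap of at
    least ``min_overlap`` defined positions.  The relation is not transitive
    for partial fragments, so groups are its connected components.
    """
    n = len(matrix)
    uf = _UnionFind(n)
    if matrix.overlap is not None:
        mism = matrix.transitions + matrix.transversions
        edges = (matrix.overlap >= min_overlap) & (mism == 0)
    else:
        edges = matrix.defined & (matrix.distance == 0.0)
    ii, jj = np.nonzero(np.triu(edges, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        uf.union(i, j)
    roots: dict[int, int] = {}
    groups: list[list[str]] = []
    group_of: dict[str, int] = {}
    for i, sid in enumerate(matrix.ids):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(groups)
            groups.append([])
        groups[roots[r]].append(sid)
        group_of[sid] = roots[r]
    return HaplotypeGroups(groups, group_of)


@dataclass
class NNRecord:
    """Per-species nearest-neighbor and intraspecific divergence (percent)."""

    species: str
    nn_species: Optional[str]
    nn_distance: Optional[float]
    intra_mean: Optional[float]
    intra_max: Optional[float]
    n_specimens: int
    defined: bool


def species_nn(matrix: DistanceMatrix, species_of: Mapping[str, str]) -> list[NNRecord]:
    """Nearest-neighbor and intraspecific quantities for every species.

    ``nn_distance`` is the minimum defined interspecific specimen-pair
    distance; ``intra_mean``/``intra_max`` summarize defined within-species
    pairs (missing with <2 specimens or no defined pair).  All values are
    percentages.
    """
    ids = matrix.ids
    sp = [species_of[s] for s in ids]
    species_list = sorted(set(sp))
    if len(species_list) < 2:
        raise ValueError("need at least 2 species for nearest-neighbor analysis")
    dm = np.where(matrix.defined, matrix.distance, np.nan)
    sp_arr = np.array(sp)
    out: list[NNRecord] = []
    for species in species_list:
        rows = np.nonzero(sp_arr == species)[0]
        others = np.nonzero(sp_arr != species)[0]
        inter = dm[np.ix_(rows, others)]
        nn_d = nn_sp = None
        if inter.size and not np.all(np.isnan(inter)):
            flat = np.nanargmin(inter)
            r, c = np.unravel_index(flat, inter.shape)
            nn_d = float(inter[r, c]) * 100.0
            nn_sp = sp_arr[others[c]]
        intra_mean = intra_max = None
        if len(rows) >= 2:
            sub = dm[np.ix_(rows, rows)]
            vals = sub[np.triu_indices(len(rows), k=1)]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                intra_mean = float(vals.mean()) * 100.0
                intra_max = float(vals.max()) * 100.0
        out.append(
            NNRecord(
                species=species,
                nn_species=nn_sp,
                nn_distance=nn_d,
                intra_mean=intra_mean,
                intra_max=intra_max,
                n_specimens=len(rows),
                defined=nn_d is not None,
            )
        )
    return out
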