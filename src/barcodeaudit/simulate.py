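"""Synthetic barcode libraries with planted, verifiable truth.

The generator is phenomenological: species founders are created by drawing
substitution counts that target the configured realized divergences (it is
not a coalescent model).  Diagnosability edge cases are planted explicitly:

* *sharing pairs* — two species carrying an identical haplotype;
* *low-divergence pairs* — two species whose founders differ by a handful
  of substitutions, landing the nearest-neighbor distance in a window
  below the low-divergence ceiling;
* *deep splits* — a second founder placed at a stated depth inside one
  species;
* *introduced species* — shrunken intraspecific scale and inflated
  nearest-neighbor distance.

All sequences derive from a stop-free template and every substitution is
re-sampled if it would create an in-frame stop codon, so the reading-frame
screen passes by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .clustering import single_linkage_clusters, concordance_classify
from .distance import k2p_distance, pairwise_matrix
from .records import (
    AlignedSequence,
    FRAME_LENGTH,
    SpecimenCollection,
    SpecimenRecord,
    Status,
)

_STOPS = frozenset(CodonTable.unambiguous_dna_by_id[5].stop_codons)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_BASES = "ACGT"

DEFAULT_REGIONS = (
    "Arctic",
    "Boreal",
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


@dataclass
class SimConfig:
    """Parameters of one synthetic library.

    Defaults are desk-scale; the field survey this emulates ran at
    ~19.5 specimens per species over thousands of species.
    """

    seed: int = 0
    n_families: int = 3
    n_genera: int = 20
    n_species: int = 60
    mean_specimens: float = 5.0
    min_specimens: int = 1
    max_specimens: int = 614
    target_nnd: float = 0.027       # fraction; mean congener founder gap ~ 2.7%
    target_intra: float = 0.0045    # fraction; mean within-species pair ~ 0.45%
    genus_divergence_subs: float = 22.0
    ti_tv_ratio: float = 3.0
    n_sharing_pairs: int = 3
    n_deep_splits: int = 3
    deep_split_range: tuple[float, float] = (0.028, 0.08)
    n_low_div_pairs: int = 3
    low_div_range: tuple[float, float] = (0.003, 0.009)
    n_introduced: int = 4
    introduced_intra_factor: float = 0.45
    introduced_nnd_factor: float = 1.6
    regions: tuple[str, ...] = DEFAULT_REGIONS
    mean_regions_per_species: float = 2.0
    concordance_threshold_pct: float = 2.2
    record_expected_concordance: bool = True

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        reserved = 2 * self.n_sharing_pairs + 2 * self.n_low_div_pairs
        background = self.n_species - reserved
        if background < max(1, self.n_deep_splits + self.n_introduced):
            raise ValueError(
                "infeasible planting: not enough background species for "
                "deep splits and introduced species"
            )
        if self.n_genera < 1 or self.n_families < 1:
            raise ValueError("need >= 1 genus and family")
        for name in ("target_nnd", "target_intra", "ti_tv_ratio", "mean_specimens"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.low_div_range
        if round(hi * FRAME_LENGTH) < 2 or lo > hi:
            raise ValueError(
                "infeasible low-divergence window: below one mutation's resolution"
            )
        if self.deep_split_range[0] <= 0.02:
            raise ValueError("deep split depths must exceed the 2% floor with margin")


@dataclass
class PlantedTruth:
    """What the generator planted, verified against the emitted sequences."""

    seed: int
    sharing_pairs: list[tuple[str, str]] = field(default_factory=list)
    low_div_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    deep_splits: dict[str, float] = field(default_factory=dict)
    introduced: list[str] = field(default_factory=list)
    specimen_regions: dict[str, str] = field(default_factory=dict)
    species_regions: dict[str, list[str]] = field(default_factory=dict)
    expected_concordance: dict[str, str] = field(default_factory=dict)
    concordance_threshold_pct: Optional[float] = None

    def to_json(self, path) -> None:
        d = asdict(self)
        d["sharing_pairs"] = [list(p) for p in self.sharing_pairs]
        d["low_div_pairs"] = [list(p) for p in self.low_div_pairs]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["sharing_pairs"] = [tuple(p) for p in d["sharing_pairs"]]
        d["low_div_pairs"] = [tuple(p) for p in d["low_div_pairs"]]
        return cls(**d)


def random_template(rng: np.random.Generator, length: int = FRAME_LENGTH) -> str:
    """A stop-free frame-0 template of codons drawn from the non-stop set."""
    codons = []
    n_codons = length // 3
    all_codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                  if a + b + c not in _STOPS]
    idx = rng.integers(0, len(all_codons), size=n_codons)
    codons = [all_codons[i] for i in idx]
    tail = "".join(_BASES[i] for i in rng.integers(0, 4, size=length - 3 * n_codons))
    return "".join(codons) + tail


def mutate_sequence(
    residues: str,
    n_substitutions: int,
    ti_tv_ratio: float,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> str:
    """Substitute exactly ``n_substitutions`` distinct defined positions.

    Transitions are chosen with probability ti_tv/(ti_tv+1) per site.  A
    substitution that would create an in-frame (frame 0) stop codon is
    re-sampled; after ``max_tries`` failures at a site the site itself is
    re-drawn, and the whole request errors out if no feasible site remains.
    """
    seq = list(residues)
    defined = [i for i, c in enumerate(seq) if c in _BASES]
    if n_substitutions > len(defined):
        raise ValueError("more substitutions requested than defined positions")
    if n_substitutions == 0:
        return residues
    p_ts = ti_tv_ratio / (ti_tv_ratio + 1.0)
    order = rng.permutation(len(defined))
    done = 0
    cursor = 0
    while done < n_substitutions:
        if cursor >= len(order):
            raise RuntimeError("retry bound exceeded: infeasible substitution request")
        pos = defined[order[cursor]]
        cursor += 1
        old = seq[pos]
        placed = False
        for _ in range(max_tries):
            if rng.random() < p_ts:
                new = _TRANSITION[old]
            else:
                new = _TRANSVERSIONS[old][int(rng.integers(0, 2))]
            seq[pos] = new
            start = pos - pos % 3
            codon = "".join(seq[start : start + 3]) if start + 3 <= len(seq) else ""
            if codon in _STOPS:
                seq[pos] = old
                continue
            placed = True
            break
        if placed:
            done += 1
    return "".join(seq)


def _draw_counts(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    p = min(1.0, 1.0 / cfg.mean_specimens)
    counts = rng.geometric(p, size=n)
    return np.clip(counts, cfg.min_specimens, cfg.max_specimens)


def generate_library(config: SimConfig) -> tuple[SpecimenCollection, PlantedTruth]:
    """Generate a library plus its planted truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = FRAME_LENGTH
    template = random_template(rng)
    lam_intra = config.target_intra * L / 2.0
    mu_species = max(1.0, config.target_nnd * L / 2.0)

    families = [f"Family{i + 1}" for i in range(config.n_families)]
    truth = PlantedTruth(seed=config.seed)

    # ---- taxonomy scaffold ------------------------------------------------
    n_pair_genera = config.n_sharing_pairs + config.n_low_div_pairs
    n_background_genera = max(1, config.n_genera - n_pair_genera)
    n_background_species = config.n_species - 2 * n_pair_genera

    weights = rng.dirichlet(np.full(n_background_genera, 0.6))
    genus_of_species: list[int] = list(
        rng.choice(n_background_genera, size=n_background_species, p=weights)
    )
    genus_names = [f"Genus{g + 1:03d}" for g in range(n_background_genera)]
    genus_family = {g: families[int(rng.integers(0, len(families)))]
                    for g in range(n_background_genera)}

    def new_genus(tag: str) -> int:
        g = len(genus_names)
        genus_names.append(f"Genus{tag}{g + 1:03d}")
        genus_family[g] = families[int(rng.integers(0, len(families)))]
        return g

    # ---- founders ---------------------------------------------------------
    genus_founders: dict[int, str] = {}

    def founder_for_genus(g: int) -> str:
        if g not in genus_founders:
            n = max(1, int(rng.poisson(config.genus_divergence_subs)))
            genus_founders[g] = mutate_sequence(template, n, config.ti_tv_ratio, rng)
        return genus_founders[g]

    @dataclass
    class _Species:
        name: str
        genus: int
        founders: list[str]
        lam: float
        status: Status = Status.NATIVE
        forced_min: int = 1
        exact_copies: int = 0   # specimens emitted as exact founder copies
        noiseless: bool = False

    species_plan: list[_Species] = []
    per_genus_counter: dict[int, int] = {}

    def add_species(g: int, founder: str, **kw) -> _Species:
        per_genus_counter[g] = per_genus_counter.get(g, 0) + 1
        name = f"{genus_names[g]} species{per_genus_counter[g]:03d}"
        sp = _Species(name=name, genus=g, founders=[founder], lam=lam_intra, **kw)
        species_plan.append(sp)
        return sp

    for g in genus_of_species:
        gf = founder_for_genus(g)
        n = max(1, int(rng.poisson(mu_species)))
        add_species(g, mutate_sequence(gf, n, config.ti_tv_ratio, rng))

    # planted sharing pairs: identical founders in a dedicated genus
    for _ in range(config.n_sharing_pairs):
        g = new_genus("S")
        gf = founder_for_genus(g)
        fa = mutate_sequence(gf, max(1, int(rng.poisson(mu_species))), config.ti_tv_ratio, rng)
        a = add_species(g, fa, forced_min=2, exact_copies=1)
        b = add_species(g, fa, forced_min=2, exact_copies=1)
        truth.sharing_pairs.append((a.name, b.name))

    # planted low-divergence pairs: founders a few substitutions apart,
    # specimens emitted noiselessly so the planted gap is exact
    d_lo = max(2, round(config.low_div_range[0] * L))
    d_hi = max(d_lo, round(config.low_div_range[1] * L))
    for _ in range(config.n_low_div_pairs):
        g = new_genus("L")
        gf = founder_for_genus(g)
        fa = mutate_sequence(gf, max(1, int(rng.poisson(mu_species))), config.ti_tv_ratio, rng)
        d = int(rng.integers(d_lo, d_hi + 1))
        fb = mutate_sequence(fa, d, config.ti_tv_ratio, rng)
        a = add_species(g, fa, noiseless=True, forced_min=1)
        b = add_species(g, fb, noiseless=True, forced_min=1)
        planted_nn = k2p_distance(AlignedSequence(fa), AlignedSequence(fb)).distance
        truth.low_div_pairs.append((a.name, b.name, planted_nn))

    # deep splits and introduced species live among background species
    background = [sp for sp in species_plan if sp.genus < n_background_genera]
    rng.shuffle(background)
    for sp in background[: config.n_deep_splits]:
        lo, hi = config.deep_split_range
        depth_subs = round(float(rng.uniform(lo, hi)) * L)
        sp.founders.append(mutate_sequence(sp.founders[0], depth_subs, config.ti_tv_ratio, rng))
        sp.forced_min = max(sp.forced_min, 4)
        depth = k2p_distance(
            AlignedSequence(sp.founders[0]), AlignedSequence(sp.founders[1])
        ).distance
        truth.deep_splits[sp.name] = depth
    for sp in background[config.n_deep_splits : config.n_deep_splits + config.n_introduced]:
        extra = max(1, round((config.introduced_nnd_factor - 1.0) * config.target_nnd * L))
        sp.founders = [mutate_sequence(sp.founders[0], extra, config.ti_tv_ratio, rng)]
        sp.lam = lam_intra * config.introduced_intra_factor
        sp.status = Status.INTRODUCED
        truth.introduced.append(sp.name)

    # ---- specimens --------------------------------------------------------
    species_plan.sort(key=lambda s: s.name)
    counts = _draw_counts(rng, config, len(species_plan))
    records: list[SpecimenRecord] = []
    counter = 0
    for sp, n_spec in zip(species_plan, counts):
        n_spec = max(int(n_spec), sp.forced_min)
        k_regions = min(len(config.regions),
                        max(1, int(rng.geometric(1.0 / config.mean_regions_per_species))))
        sp_regions = sorted(
            rng.choice(len(config.regions), size=k_regions, replace=False).tolist()
        )
        sp_region_labels = [config.regions[i] for i in sp_regions]
        truth.species_regions[sp.name] = sp_region_labels
        home_lat = float(rng.uniform(27.0, 58.0))
        home_lon = float(rng.uniform(-128.0, -72.0))
        for k in range(n_spec):
            counter += 1
            sid = f"SP{counter:05d}"
            founder = sp.founders[k % len(sp.founders)]
            if sp.noiseless or k < sp.exact_copies:
                seq = founder
            else:
                seq = mutate_sequence(founder, int(rng.poisson(sp.lam)),
                                      config.ti_tv_ratio, rng)
            region = sp_region_labels[int(rng.integers(0, len(sp_region_labels)))]
            truth.specimen_regions[sid] = region
            lat = float(np.clip(home_lat + rng.normal(0.0, 1.5), -90.0, 90.0))
            lon = float(np.clip(home_lon + rng.normal(0.0, 1.5), -180.0, 180.0))
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    species=sp.name,
                    genus=genus_names[sp.genus],
                    family=genus_family[sp.genus],
                    latitude=round(lat, 4),
                    longitude=round(lon, 4),
                    ecoregion=region,
                    zoogeo_region="Nearctic",
                    status=sp.status,
                    sequence=AlignedSequence(seq),
                )
            )
    collection = SpecimenCollection(records)

    _verify_truth(collection, truth, config)

    if config.record_expected_concordance:
        matrix = pairwise_matrix(collection)
        partition = single_linkage_clusters(matrix, config.concordance_threshold_pct)
        for rec in concordance_classify(collection.species_of(), partition):
            truth.expected_concordance[rec.species] = rec.category.value
        truth.concordance_threshold_pct = config.concordance_threshold_pct
    return collection, truth


def _verify_truth(collection: SpecimenCollection, truth: PlantedTruth, config: SimConfig) -> None:
    """Check planted structure against the emitted sequences before returning."""
    by_species: dict[str, list[SpecimenRecord]] = {}
    for rec in collection:
        by_species.setdefault(rec.species, []).append(rec)
    for a, b in truth.sharing_pairs:
        found = False
        for ra in by_species[a]:
            for rb in by_species[b]:
                if ra.sequence.residues == rb.sequence.residues:
                    found = True
        if not found:
            raise RuntimeError(f"planted sharing pair {a}/{b} has no identical haplotype")
    for a, b, planted_nn in truth.low_div_pairs:
        best = min(
            k2p_distance(ra.sequence, rb.sequence).distance
            for ra in by_species[a]
            for rb in by_species[b]
        )
        lo, hi = config.low_div_range
        if not (lo * 0.5 <= best <= hi * 1.5):
            raise RuntimeError(f"planted low-divergence pair {a}/{b} out of window: {best}")
    for sp, depth in truth.deep_splits.items():
        recs = by_species[sp]
        dmax = max(
            k2p_distance(recs[i].sequence, recs[j].sequence).distance
            for i in range(len(recs))
            for j in range(i + 1, len(recs))
        )
        if dmax < 0.02:
            raise RuntimeError(f"planted deep split {sp} too shallow: {dmax}")


def write_library(collection: SpecimenCollection, truth: PlantedTruth, outdir) -> None:
    """Emit the FASTA + TSV dialect the readers consume, plus truth.json."""
    import os

    from .io import write_fasta, write_specimen_table

    os.makedirs(outdir, exist_ok=True)
    seqs = {r.specimen_id: r.sequence for r in collection.sequenced()}
    write_fasta(seqs, os.path.join(outdir, "library.fasta"))
    write_specimen_table(collection, os.path.join(outdir, "library.tsv"))
    truth.to_json(os.path.join(outdir, "truth.json"))
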