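"""Core domain types for barcode reference-library audits.

A library is a set of :class:`SpecimenRecord` objects, each pairing a
voucher's metadata with a COI barcode laid out in a fixed 658-position
coordinate frame.  Sequences shorter than the frame are padded with ``-``;
positions that were sequenced but are uncertain carry ``N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

FRAME_LENGTH = 658

DEFINED_BASES = frozenset("ACGT")
SEQUENCE_ALPHABET = frozenset("ACGTN-")

#: IUPAC ambiguity codes (other than N) that are demoted to N on input.
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")

ZOOGEO_REGIONS = (
    "Nearctic",
    "Neotropical",
    "Palaearctic",
    "Ethiopian",
    "Oriental",
    "Australian",
)


class Status(str, Enum):
    """Provenance flag for a specimen's species."""

    NATIVE = "native"
    INTRODUCED = "introduced"
    EXTRATERRITORIAL = "extraterritorial"
    UNKNOWN = "unknown"


def normalize_residues(raw: str) -> tuple[str, list[tuple[str, str]]]:
    """Normalize raw sequence text into the frame alphabet.

    Upper-cases, maps U->T and '.'/'~'->'-', demotes non-N ambiguity codes
    to N, and replaces unrecognized characters with N.

    Returns the cleaned string and a list of ``(kind, detail)`` notes where
    kind is ``"ambiguity_code"`` or ``"unknown_character"``.
    """
    notes: list[tuple[str, str]] = []
    out = []
    for ch in raw.strip().upper():
        if ch == "U":
            ch = "T"
        elif ch in ".~":
            ch = "-"
        if ch in SEQUENCE_ALPHABET:
            out.append(ch)
        elif ch in AMBIGUITY_CODES:
            notes.append(("ambiguity_code", ch))
            out.append("N")
        else:
            notes.append(("unknown_character", ch))
            out.append("N")
    return "".join(out), notes


@dataclass(frozen=True)
class AlignedSequence:
    """A barcode in the common 658-position frame.

    ``residues`` may be shorter than the frame (a fragment); positions
    outside the sequenced stretch are ``-``.
    """

    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)!r}")
        if len(self.residues) > FRAME_LENGTH:
            raise ValueError(
                f"sequence length {len(self.residues)} exceeds frame length {FRAME_LENGTH}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def defined_length(self) -> int:
        """Number of unambiguous A/C/G/T positions."""
        return sum(1 for c in self.residues if c in DEFINED_BASES)

    @property
    def defined_span(self) -> tuple[int, int]:
        """Half-open ``(start, stop)`` covering the first..last defined base.

        ``(0, 0)`` when the sequence has no defined positions.
        """
        first = None
        last = None
        for i, c in enumerate(self.residues):
            if c in DEFINED_BASES:
                if first is None:
                    first = i
                last = i
        if first is None:
            return (0, 0)
        return (first, last + 1)

    def padded(self, length: int = FRAME_LENGTH) -> str:
        """Residues right-padded with '-' to the frame length."""
        return self.residues.ljust(length, "-")


@dataclass
class SpecimenRecord:
    """One barcoded voucher: identifiers, taxonomy, geography, sequence."""

    specimen_id: str
    species: str
    genus: str = ""
    family: str = ""
    bin_id: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    ecoregion: Optional[str] = None
    zoogeo_region: Optional[str] = None
    status: Status = Status.UNKNOWN
    sequence: Optional[AlignedSequence] = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if not self.species:
            raise ValueError(f"{self.specimen_id}: species must be non-empty")
        if not self.genus:
            # genus defaults to the first token of a binomial
            self.genus = self.species.split()[0]

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None and len(self.sequence.residues) > 0


class SpecimenCollection:
    """An ordered set of specimen records with unique ids."""

    def __init__(self, records: Iterable[SpecimenRecord]):
        self.records: list[SpecimenRecord] = list(records)
        self.by_id: dict[str, SpecimenRecord] = {}
        for rec in self.records:
            if rec.specimen_id in self.by_id:
                raise ValueError(f"duplicate specimen_id: {rec.specimen_id!r}")
            self.by_id[rec.specimen_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def sequenced(self) -> list[SpecimenRecord]:
        return [r for r in self.records if r.has_sequence]

    def species_of(self) -> dict[str, str]:
        """Map specimen_id -> species for sequenced records."""
        return {r.specimen_id: r.species for r in self.sequenced()}

    def species(self) -> set[str]:
        return {r.species for r in self.records}

    def genus_of_species(self) -> dict[str, str]:
        return {r.species: r.genus for r in self.records}

    def family_of_species(self) -> dict[str, str]:
        return {r.species: r.family for r in self.records}

    def subset(self, ids: Iterable[str]) -> "SpecimenCollection":
        wanted = set(ids)
        return SpecimenCollection(r for r in self.records if r.specimen_id in wanted)


@dataclass
class ValidationReport:
    """Per-record violations plus accepted/rejected bookkeeping.

    Invariant: ``n_accepted + n_rejected`` equals the number of input
    records the producing operation saw.
    """

    violations: list[dict] = field(default_factory=list)
    n_accepted: int = 0
    n_rejected: int = 0

    def add(self, record: str, problem: str, detail: str = "", fatal: bool = False) -> None:
        self.violations.append(
            {"record": record, "problem": problem, "detail": detail, "fatal": fatal}
        )

    @property
    def n_total(self) -> int:
        return self.n_accepted + self.n_rejected

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_accepted": self.n_accepted,
                    "n_rejected": self.n_rejected,
                    "violations": self.violations,
                },
                fh,
                indent=2,
            )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("record\tproblem\tdetail\tfatal\n")
            for v in self.violations:
                fh.write(f"{v['record']}\t{v['problem']}\t{v['detail']}\t{v['fatal']}\n")
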