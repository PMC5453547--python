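"""Reading, validation and writing of library artifacts.

Two inputs: a FASTA of frame-aligned barcodes and a UTF-8 TSV specimen
table (header row, columns named as in :class:`~barcodeaudit.records.SpecimenRecord`).
Rows without a matching sequence are kept so that species lacking barcodes
still appear in coverage reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .records import (
    AlignedSequence,
    DEFINED_BASES,
    SpecimenCollection,
    SpecimenRecord,
    Status,
    ValidationReport,
    normalize_residues,
)

REQUIRED_COLUMNS = ("specimen_id", "species")
OPTIONAL_COLUMNS = (
    "genus",
    "family",
    "bin_id",
    "latitude",
    "longitude",
    "ecoregion",
    "zoogeo_region",
    "status",
)

#: invertebrate mitochondrial code
GENETIC_CODE_ID = 5
_STOP_CODONS = frozenset(CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID].stop_codons)


def read_fasta(
    path, header_delimiter: Optional[str] = None
) -> tuple[dict[str, AlignedSequence], ValidationReport]:
    """Parse a FASTA file into ``specimen_id -> AlignedSequence``.

    The id is the first whitespace token of the header, further split on
    ``header_delimiter`` when given.  Residues are normalized (upper-case,
    U->T, '.'/'~'->'-', ambiguity codes -> N).  Duplicate ids are a hard
    error; empty sequences are rejected with a report entry.
    """
    report = ValidationReport()
    sequences: dict[str, AlignedSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if header_delimiter:
            sid = sid.split(header_delimiter)[0]
        if sid in sequences:
            raise ValueError(f"duplicate FASTA id {sid!r}: two records share this id")
        residues, notes = normalize_residues(str(rec.seq))
        for kind, detail in notes:
            report.add(sid, kind, detail)
        if not residues or not any(c in DEFINED_BASES for c in residues):
            report.add(sid, "empty_sequence", fatal=True)
            report.n_rejected += 1
            continue
        sequences[sid] = AlignedSequence(residues)
        report.n_accepted += 1
    return sequences, report


def write_fasta(sequences: Mapping[str, AlignedSequence], path) -> None:
    """Write sequences as plain unwrapped FASTA, in mapping order."""
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n{seq.residues}\n")


def _parse_coord(value: str, lo: float, hi: float) -> tuple[Optional[float], Optional[str]]:
    if value is None or value == "":
        return None, None
    try:
        x = float(value)
    except ValueError:
        return None, f"unparseable: {value!r}"
    if not (lo <= x <= hi):
        return None, f"out of range [{lo}, {hi}]: {value}"
    return x, None


def read_specimen_table(
    path, sequences: Optional[Mapping[str, AlignedSequence]] = None
) -> tuple[SpecimenCollection, ValidationReport]:
    """Read the TSV specimen table and join sequences by specimen_id.

    Rows lacking a sequence are kept but remain sequence-less (they still
    count toward species-without-barcodes reporting).  Bad coordinates are
    cleared with a report entry; a missing required column is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"specimen table missing required column(s): {missing}")
    report = ValidationReport()
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = d["specimen_id"].strip()
        species = d["species"].strip()
        if not sid or not species:
            report.add(sid or "<blank>", "missing_required_field", fatal=True)
            report.n_rejected += 1
            continue
        if sid in seen:
            raise ValueError(f"duplicate specimen_id in table: {sid!r}")
        seen.add(sid)

        lat, err = _parse_coord(d.get("latitude", ""), -90.0, 90.0)
        if err:
            report.add(sid, "bad_latitude", err)
        lon, err = _parse_coord(d.get("longitude", ""), -180.0, 180.0)
        if err:
            report.add(sid, "bad_longitude", err)

        status_raw = (d.get("status") or "").strip().lower()
        try:
            status = Status(status_raw) if status_raw else Status.UNKNOWN
        except ValueError:
            report.add(sid, "unknown_status", status_raw)
            status = Status.UNKNOWN

        seq = sequences.get(sid) if sequences else None
        if sequences is not None and seq is None:
            report.add(sid, "no_sequence", "row kept without a barcode")

        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species=species,
                genus=(d.get("genus") or "").strip(),
                family=(d.get("family") or "").strip(),
                bin_id=(d.get("bin_id") or "").strip() or None,
                latitude=lat,
                longitude=lon,
                ecoregion=(d.get("ecoregion") or "").strip() or None,
                zoogeo_region=(d.get("zoogeo_region") or "").strip() or None,
                status=status,
                sequence=seq,
            )
        )
        report.n_accepted += 1
    return SpecimenCollection(records), report


def write_specimen_table(collection: SpecimenCollection, path) -> None:
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    rows = []
    for r in collection:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "genus": r.genus,
                "family": r.family,
                "bin_id": r.bin_id or "",
                "latitude": "" if r.latitude is None else repr(r.latitude),
                "longitude": "" if r.longitude is None else repr(r.longitude),
                "ecoregion": r.ecoregion or "",
                "zoogeo_region": r.zoogeo_region or "",
                "status": r.status.value,
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def length_filter(
    collection: SpecimenCollection,
    min_len: int = 500,
    whitelist: Iterable[str] = (),
) -> tuple[SpecimenCollection, ValidationReport]:
    """Drop sequenced records with fewer than ``min_len`` defined positions.

    Whitelisted specimen_ids are exempt (short-but-diagnostic fragments).
    Sequence-less records are not subject to the filter.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    keep_ids = set(whitelist)
    report = ValidationReport()
    kept: list[SpecimenRecord] = []
    for rec in collection:
        if rec.has_sequence and rec.sequence.defined_length < min_len:
            if rec.specimen_id in keep_ids:
                report.add(rec.specimen_id, "short_whitelisted",
                           f"defined_length={rec.sequence.defined_length}")
            else:
                report.add(rec.specimen_id, "too_short",
                           f"defined_length={rec.sequence.defined_length} < {min_len}",
                           fatal=True)
                report.n_rejected += 1
                continue
        kept.append(rec)
        report.n_accepted += 1
    return SpecimenCollection(kept), report


@dataclass(frozen=True)
class FrameCheckResult:
    frame_chosen: Optional[int]
    stop_codons: Optional[int]
    passed: bool
    indeterminate: bool = False
    frameshift: bool = False


def reading_frame_check(seq: AlignedSequence, min_defined: int = 30) -> FrameCheckResult:
    """Screen a barcode for pseudogene signatures by translation.

    The defined region (first..last A/C/G/T) is read in all three frames
    under the invertebrate mitochondrial code; the frame with the fewest
    stop codons wins (ties -> lowest frame index) and the check passes iff
    that minimum is zero.  Codons containing N are skipped.  An internal
    ``-`` inside the defined region is a frameshift failure.  Fewer than
    ``min_defined`` defined positions yields an indeterminate (non-failing)
    result.
    """
    if seq.defined_length < min_defined:
        return FrameCheckResult(None, None, passed=False, indeterminate=True)
    start, stop = seq.defined_span
    region = seq.residues[start:stop]
    if "-" in region:
        return FrameCheckResult(None, None, passed=False, frameshift=True)
    best_frame, best_stops = 0, None
    for frame in range(3):
        stops = 0
        for i in range(frame, len(region) - 2, 3):
            codon = region[i : i + 3]
            if "N" in codon:
                continue
            if codon in _STOP_CODONS:
                stops += 1
        if best_stops is None or stops < best_stops:
            best_frame, best_stops = frame, stops
    return FrameCheckResult(best_frame, best_stops, passed=best_stops == 0)
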