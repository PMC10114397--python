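"""Cohort CSV reading/writing and the packaged validation cohort.

A cohort file has one row per subject-phase:

``subject_id, phase {pre|post}, va_logmar`` (or ``va_decimal``),
``brbp_right, brbp_left, pep_h_deg, [pep_v_deg,] stereo_arcsec``

with a header, UTF-8 encoding and "." decimals. ``stereo_arcsec`` is one of
100/200/300/400 or the string ``none`` (no measurable stereopsis); the
``pep_v_deg`` column is optional. An empty BRBP cell is read as missing and
flagged on the record rather than rejected.

The packaged fixture ``validation_cohort.csv`` holds the 8-subject
validation cohort used to sanity-check composite-index orderings. One cell
(S1's pre-treatment right-eye BRBP level) is not reliably recoverable from
the source tabulation and ships empty; ``load_validation_cohort`` can fill
it with level 8, the only value consistent with that subject's recorded
post-treatment levels and narrated left-eye trajectory.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CohortFormatError, DomainError, PairingError
from .vision_metrics import (
    ExamRecord,
    compute_difference_vector,
    decimal_to_logmar,
    decode_stereoacuity,
    encode_stereoacuity,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "pair_cohort",
    "cohort_differences",
    "load_validation_cohort",
]

logger = logging.getLogger(__name__)

_REQUIRED = ("subject_id", "phase", "brbp_right", "brbp_left", "pep_h_deg", "stereo_arcsec")


def _parse_float(cell: str, name: str, row: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise CohortFormatError(f"unparseable number {cell!r} in column {name!r}", row=row)


def _parse_level(cell: str, name: str, row: int) -> int | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError:
        raise CohortFormatError(f"unparseable level {cell!r} in column {name!r}", row=row)


def read_cohort(path: str | Path) -> list[ExamRecord]:
    """Read and validate a cohort CSV into examination records.

    Decimal visual acuity (a ``va_decimal`` column) is converted to logMAR
    on ingest with a logged notice. Errors carry the offending row number;
    every subject must have exactly one ``pre`` and one ``post`` row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFormatError(f"{path}: empty file, expected a header row")
        fields = [f.strip() for f in reader.fieldnames]
        missing = [c for c in _REQUIRED if c not in fields]
        if missing:
            raise CohortFormatError(f"{path}: missing required column(s) {missing}")
        has_logmar = "va_logmar" in fields
        has_decimal = "va_decimal" in fields
        if not (has_logmar or has_decimal):
            raise CohortFormatError(f"{path}: need a va_logmar or va_decimal column")
        if has_decimal and not has_logmar:
            logger.info("%s: converting decimal visual acuity to logMAR on ingest", path)
        has_vpep = "pep_v_deg" in fields

        records: list[ExamRecord] = []
        for rownum, row in enumerate(reader, start=2):
            sid = (row.get("subject_id") or "").strip()
            phase = (row.get("phase") or "").strip().lower()
            if not sid:
                raise CohortFormatError("empty subject_id", row=rownum)
            if phase not in ("pre", "post"):
                raise CohortFormatError(f"phase must be pre|post, got {phase!r}", row=rownum)
            if has_logmar:
                va_logmar = _parse_float(row["va_logmar"], "va_logmar", rownum)
            else:
                dec = _parse_float(row["va_decimal"], "va_decimal", rownum)
                va_logmar = decimal_to_logmar(dec)
            brbp_r = _parse_level(row["brbp_right"], "brbp_right", rownum)
            brbp_l = _parse_level(row["brbp_left"], "brbp_left", rownum)
            pep_h = _parse_float(row["pep_h_deg"], "pep_h_deg", rownum)
            pep_v = None
            if has_vpep and (row.get("pep_v_deg") or "").strip():
                pep_v = _parse_float(row["pep_v_deg"], "pep_v_deg", rownum)
            stereo_cell = (row.get("stereo_arcsec") or "").strip().lower()
            try:
                threshold = None if stereo_cell == "none" else int(stereo_cell)
                stereo = encode_stereoacuity(threshold)
            except (ValueError, DomainError):
                raise CohortFormatError(
                    f"stereo_arcsec must be 100|200|300|400|none, got {stereo_cell!r}",
                    row=rownum,
                )
            flags = []
            if brbp_r is None:
                flags.append("missing_brbp_right")
            if brbp_l is None:
                flags.append("missing_brbp_left")
            try:
                records.append(
                    ExamRecord.from_raw(
                        sid, phase,
                        va_logmar=va_logmar, brbp_right=brbp_r, brbp_left=brbp_l,
                        pep_h=pep_h, pep_v=pep_v, stereo_level=stereo.level,
                        flags=tuple(flags),
                    )
                )
            except DomainError as exc:
                raise CohortFormatError(str(exc), row=rownum)

    pair_cohort(records)  # validates pairing; result discarded here
    return records


def pair_cohort(records: Iterable[ExamRecord]) -> list[tuple[ExamRecord, ExamRecord]]:
    """Group records into (pre, post) pairs, one per subject, in file order."""
    by_subject: dict[str, dict[str, ExamRecord]] = {}
    for rec in records:
        phases = by_subject.setdefault(rec.subject_id, {})
        if rec.phase in phases:
            raise PairingError(f"subject {rec.subject_id!r} has duplicate {rec.phase!r} records")
        phases[rec.phase] = rec
    pairs = []
    for sid, phases in by_subject.items():
        if set(phases) != {"pre", "post"}:
            have = ", ".join(sorted(phases)) or "none"
            raise PairingError(f"subject {sid!r} lacks a pre/post pair (has: {have})")
        pairs.append((phases["pre"], phases["post"]))
    return pairs


def cohort_differences(records: Iterable[ExamRecord]):
    """Difference vectors for every paired subject, in cohort order."""
    return [compute_difference_vector(pre, post) for pre, post in pair_cohort(records)]


def write_cohort(records: Sequence[ExamRecord], path: str | Path) -> None:
    """Write records to cohort CSV (logMAR acuity, arcsec stereo)."""
    path = Path(path)
    has_vpep = any(r.pep.vertical is not None for r in records)
    header = ["subject_id", "phase", "va_logmar", "brbp_right", "brbp_left", "pep_h_deg"]
    if has_vpep:
        header.append("pep_v_deg")
    header.append("stereo_arcsec")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            arcsec = decode_stereoacuity(r.stereo)
            row = [
                r.subject_id,
                r.phase,
                repr(r.va.logmar),
                "" if r.brbp_right is None else r.brbp_right.level,
                "" if r.brbp_left is None else r.brbp_left.level,
                repr(r.pep.horizontal),
            ]
            if has_vpep:
                row.append("" if r.pep.vertical is None else repr(r.pep.vertical))
            row.append("none" if arcsec is None else arcsec)
            writer.writerow(row)


def load_validation_cohort(fill_missing: bool = True) -> list[ExamRecord]:
    """Load the packaged 8-subject validation cohort.

    With ``fill_missing=True`` (default) the single flagged-missing cell is
    filled (S1 pre right-eye BRBP -> level 8) so downstream difference
    scores are complete; with ``False`` the record keeps its missing flag.
    """
    with resources.as_file(
        resources.files("visioncouple.data").joinpath("validation_cohort.csv")
    ) as p:
        records = read_cohort(p)
    if not fill_missing:
        return records
    out = []
    for rec in records:
        if rec.subject_id == "S1" and rec.phase == "pre" and rec.brbp_right is None:
            rec = ExamRecord.from_raw(
                rec.subject_id, rec.phase,
                va_logmar=rec.va.logmar, brbp_right=8,
                brbp_left=rec.brbp_left.level if rec.brbp_left else None,
                pep_h=rec.pep.horizontal, pep_v=rec.pep.vertical,
                stereo_level=rec.stereo.level,
                flags=tuple(f for f in rec.flags if f != "missing_brbp_right") + ("filled_brbp_right",),
            )
        out.append(rec)
    return out
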