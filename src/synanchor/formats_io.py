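"""Readers and writers for the on-disk formats the anchoring pipeline touches.

All external formats use 1-based inclusive coordinates (BLAST / AGP
convention); everything internal to the package is 0-based half-open.  The
conversion happens here and nowhere else.  Writers emit UTF-8 with LF line
endings; readers tolerate CRLF.

Formats covered: wrapped FASTA, 12-column tabular pairwise alignments (the
"outfmt 6" dialect), AGP v2.1, and the three TSV tables the pipeline consumes
(radiation-hybrid marker map, differential-expression results, GO
annotations).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SequenceRecord",
    "AlignmentHit",
    "RHMarkerRecord",
    "AGPRecord",
    "DERecord",
    "GOAnnotationRecord",
    "parse_fasta",
    "write_fasta",
    "parse_alignment_tabular",
    "write_alignment_tabular",
    "parse_agp",
    "write_agp",
    "validate_agp_records",
    "parse_rh_map",
    "write_rh_map",
    "parse_de_table",
    "write_de_table",
    "parse_go_annotations",
    "write_go_annotations",
]


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


FASTA_ALPHABET = frozenset("ACGTNacgtn")
GO_ID_RE = re.compile(r"^GO:\d{7}$")
FASTA_WRAP = 60


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with its FASTA header."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"sequence id must be a non-empty token: {self.id!r}")
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular alignment output; the atomic homology evidence.

    Coordinates are kept 1-based inclusive exactly as read.  The subject
    strand is implicit: minus iff ``s_start > s_end`` (the tabular dialect has
    no strand column).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if self.e_value < 0:
            raise ValidationError("e_value must be non-negative")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError("percent_identity outside [0, 100]")

    @property
    def strand(self) -> str:
        """'+' or '-': minus iff subject coordinates are reversed."""
        return "-" if self.s_start > self.s_end else "+"

    @property
    def subject_midpoint(self) -> int:
        """Midpoint of the subject interval, 1-based (floor)."""
        return (self.s_start + self.s_end) // 2


@dataclass(frozen=True)
class RHMarkerRecord:
    """One radiation-hybrid marker: its linkage group and rank within it."""

    marker_id: str
    rh_group: str
    position_index: int

    def __post_init__(self) -> None:
        if self.position_index < 0:
            raise ValidationError("position_index must be >= 0")


@dataclass(frozen=True)
class AGPRecord:
    """One AGP v2.1 line: a sequence component (W) or a gap (N) tiling an object.

    Coordinates are 1-based inclusive as in the format.  For gaps,
    ``component_id_or_gaplen`` holds the gap length (as int) and the
    component coordinates/orientation are None.
    """

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # "W" or "N"
    component_id_or_gaplen: str | int
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None  # "+" or "-", W only
    gap_type: str | None = None  # "scaffold", N only

    def __post_init__(self) -> None:
        if self.component_type not in ("W", "N"):
            raise ValidationError(f"component_type must be W or N: {self.component_type!r}")
        span = self.object_end - self.object_beg + 1
        if span < 1:
            raise ValidationError("object_end < object_beg")
        if self.component_type == "W":
            if self.component_beg is None or self.component_end is None:
                raise ValidationError("W record requires component coordinates")
            if self.orientation not in ("+", "-"):
                raise ValidationError("W record requires orientation + or -")
            if self.component_end - self.component_beg + 1 != span:
                raise ValidationError(
                    f"object span {span} != component span for part {self.part_number}"
                )
        else:
            gap_len = int(self.component_id_or_gaplen)
            if gap_len != span:
                raise ValidationError(
                    f"gap length {gap_len} != object span {span} for part {self.part_number}"
                )


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression statistic.

    Positive ``log2_fold_change`` means higher in the condition the caller
    designates positive (see ``DEConfig.positive_direction_label``).  A
    missing adjusted p-value (``None``) is treated as not significant
    downstream, never imputed.
    """

    feature_id: str
    log2_fold_change: float
    p_value: float
    p_adjusted: float | None

    def __post_init__(self) -> None:
        if self.p_adjusted is not None and not 0.0 <= self.p_adjusted <= 1.0:
            raise ValidationError(
                f"padj for {self.feature_id!r} outside [0, 1]: {self.p_adjusted}"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value for {self.feature_id!r} outside [0, 1]")


@dataclass(frozen=True)
class GOAnnotationRecord:
    """GO identifiers annotated to one feature."""

    feature_id: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError(f"feature {self.feature_id!r} has no terms")
        for t in self.terms:
            if not GO_ID_RE.match(t):
                raise ValidationError(f"malformed GO identifier: {t!r}")


# ---------------------------------------------------------------------------
# FASTA


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.splitlines()


def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file, validating the nucleotide alphabet.

    Raises :class:`FormatError` (with the offending line number) on an empty
    file, a file not starting with '>', residues outside {A,C,G,T,N} (either
    case), or a header with no sequence.
    """
    lines = _read_lines(path)
    if not lines or not any(ln.strip() for ln in lines):
        raise FormatError(f"{path}: empty FASTA file")
    if not lines[0].startswith(">"):
        raise FormatError(f"{path}: line 1: FASTA must begin with '>'")

    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        assert header is not None
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: line {header_line}: record {header!r} has no sequence")
        name, _, desc = header.partition(" ")
        records.append(SequenceRecord(id=name, residues=seq, description=desc))

    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                flush()
            header = line[1:].strip()
            header_line = i
            chunks = []
            if not header:
                raise FormatError(f"{path}: line {i}: empty FASTA header")
        else:
            bad = set(line) - FASTA_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}: line {i}: residue(s) outside alphabet: {sorted(bad)}"
                )
            chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns so that parse(write(x)) == x."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), FASTA_WRAP):
                fh.write(rec.residues[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular alignments ("outfmt 6" dialect)

_HIT_FIELDS = 12


def parse_alignment_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse tab-separated 12-column alignment rows; '#'-comment lines skipped."""
    hits: list[AlignmentHit] = []
    for i, raw in enumerate(_read_lines(path), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != _HIT_FIELDS:
            raise FormatError(
                f"{path}: line {i}: expected {_HIT_FIELDS} tab-separated fields, got {len(parts)}"
            )
        try:
            hit = AlignmentHit(
                query_id=parts[0],
                subject_id=parts[1],
                percent_identity=float(parts[2]),
                alignment_length=int(parts[3]),
                mismatches=int(parts[4]),
                gap_opens=int(parts[5]),
                q_start=int(parts[6]),
                q_end=int(parts[7]),
                s_start=int(parts[8]),
                s_end=int(parts[9]),
                e_value=float(parts[10]),
                bit_score=float(parts[11]),
            )
        except ValueError as exc:  # includes ValidationError
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        hits.append(hit)
    return hits


def _fmt_float(x: float) -> str:
    """Format a float the way tabular alignment output does, losslessly for repr."""
    return repr(x) if x == x else "nan"


def write_alignment_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        _fmt_float(h.percent_identity),
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        _fmt_float(h.e_value),
                        _fmt_float(h.bit_score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1


def validate_agp_records(records: Sequence[AGPRecord]) -> None:
    """Check that records tile each object contiguously with consecutive parts."""
    by_object: dict[str, list[AGPRecord]] = {}
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    for obj, recs in by_object.items():
        expected_beg = 1
        for k, rec in enumerate(recs, start=1):
            if rec.part_number != k:
                raise ValidationError(
                    f"object {obj}: part_number {rec.part_number} at position {k}"
                )
            if rec.object_beg != expected_beg:
                raise ValidationError(
                    f"object {obj} part {k}: begins at {rec.object_beg}, expected {expected_beg}"
                )
            expected_beg = rec.object_end + 1


def parse_agp(path: str | Path) -> list[AGPRecord]:
    records: list[AGPRecord] = []
    for i, raw in enumerate(_read_lines(path), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise FormatError(f"{path}: line {i}: expected 9 fields, got {len(parts)}")
        try:
            ctype = parts[4]
            if ctype == "W":
                rec = AGPRecord(
                    object_id=parts[0],
                    object_beg=int(parts[1]),
                    object_end=int(parts[2]),
                    part_number=int(parts[3]),
                    component_type="W",
                    component_id_or_gaplen=parts[5],
                    component_beg=int(parts[6]),
                    component_end=int(parts[7]),
                    orientation=parts[8],
                )
            elif ctype == "N":
                rec = AGPRecord(
                    object_id=parts[0],
                    object_beg=int(parts[1]),
                    object_end=int(parts[2]),
                    part_number=int(parts[3]),
                    component_type="N",
                    component_id_or_gaplen=int(parts[5]),
                    gap_type=parts[6],
                )
            else:
                raise FormatError(
                    f"{path}: line {i}: unsupported component type {ctype!r}"
                )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        records.append(rec)
    validate_agp_records(records)
    return records


def write_agp(records: Sequence[AGPRecord], path: str | Path) -> None:
    """Write AGP v2.1; records are validated (tiling, part numbering) first."""
    validate_agp_records(records)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in records:
            if r.component_type == "W":
                cols = [
                    r.object_id,
                    str(r.object_beg),
                    str(r.object_end),
                    str(r.part_number),
                    "W",
                    str(r.component_id_or_gaplen),
                    str(r.component_beg),
                    str(r.component_end),
                    r.orientation or "+",
                ]
            else:
                cols = [
                    r.object_id,
                    str(r.object_beg),
                    str(r.object_end),
                    str(r.part_number),
                    "N",
                    str(int(r.component_id_or_gaplen)),
                    r.gap_type or "scaffold",
                    "yes",
                    "align_genus",
                ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# RH marker map


def parse_rh_map(
    path: str | Path, valid_groups: Iterable[str] | None = None
) -> list[RHMarkerRecord]:
    """Parse the 3-column marker map TSV (marker_id, group, rank), header-bearing.

    ``valid_groups``, when given, is the declared label set (e.g. SQ1..SQ24);
    a group outside it is a validation error, as is a duplicated marker id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["marker_id", "group", "rank"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    allowed = set(valid_groups) if valid_groups is not None else None
    seen: set[str] = set()
    records: list[RHMarkerRecord] = []
    for row in df.itertuples(index=False):
        marker, group, rank = row.marker_id, row.group, row.rank
        if marker in seen:
            raise ValidationError(f"{path}: duplicate marker id {marker!r}")
        seen.add(marker)
        if allowed is not None and group not in allowed:
            raise ValidationError(f"{path}: unknown RH group label {group!r}")
        records.append(
            RHMarkerRecord(marker_id=marker, rh_group=group, position_index=int(rank))
        )
    return records


def write_rh_map(records: Iterable[RHMarkerRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("marker_id\tgroup\trank\n")
        for r in records:
            fh.write(f"{r.marker_id}\t{r.rh_group}\t{r.position_index}\n")


# ---------------------------------------------------------------------------
# DE table

_NA_TOKENS = {"", "NA", "NaN", "nan", "na", "None"}


def parse_de_table(path: str | Path) -> list[DERecord]:
    """Parse a DE results TSV with columns feature, log2FC, pvalue, padj.

    An empty or "NA" padj cell is parsed as absent (treated as not
    significant downstream); a padj outside [0, 1] is a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["feature", "log2FC", "pvalue", "padj"]
    if list(df.columns[:4]) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    records: list[DERecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.feature in seen:
            raise ValidationError(f"{path}: duplicate feature id {row.feature!r}")
        seen.add(row.feature)
        padj_raw = "" if row.padj is None or (isinstance(row.padj, float) and math.isnan(row.padj)) else str(row.padj)
        padj = None if padj_raw.strip() in _NA_TOKENS else float(padj_raw)
        records.append(
            DERecord(
                feature_id=row.feature,
                log2_fold_change=float(row.log2FC),
                p_value=float(row.pvalue),
                p_adjusted=padj,
            )
        )
    return records


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature\tlog2FC\tpvalue\tpadj\n")
        for r in records:
            padj = "NA" if r.p_adjusted is None else repr(r.p_adjusted)
            fh.write(
                f"{r.feature_id}\t{repr(r.log2_fold_change)}\t{repr(r.p_value)}\t{padj}\n"
            )


# ---------------------------------------------------------------------------
# GO annotations


def parse_go_annotations(path: str | Path) -> list[GOAnnotationRecord]:
    """Parse the 2-column TSV feature_id <tab> semicolon-separated GO ids."""
    records: list[GOAnnotationRecord] = []
    lines = _read_lines(path)
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {i}: expected 2 fields, got {len(parts)}")
        feature, terms_raw = parts
        terms = frozenset(t.strip() for t in terms_raw.split(";") if t.strip())
        try:
            records.append(GOAnnotationRecord(feature_id=feature, terms=terms))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return records


def write_go_annotations(records: Iterable[GOAnnotationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            fh.write(f"{r.feature_id}\t{';'.join(sorted(r.terms))}\n")
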