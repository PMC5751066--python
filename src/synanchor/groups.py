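"""Build in silico chromosome groups from dual homology evidence.

Scaffolds supported by a consistent pair of evidence channels — an RH
linkage-group vote and a reference-chromosome assignment that the fixed
1-to-1 homology table pairs together — are grouped, sorted by their match
position on the reference, oriented by their best-hit strand, and
concatenated into named pseudo-chromosomes separated by N-gaps.  The module
also emits AGP, a placements table, a conflicts side-table and a circos-style
link file, and lifts coordinates between scaffold and group space.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .formats_io import AGPRecord, AlignmentHit, SequenceRecord, ValidationError
from .homology import ScaffoldEvidence, best_hit_per_query

__all__ = [
    "HomologyTable",
    "Placement",
    "InSilicoGroup",
    "GroupBuildResult",
    "reconcile_placement",
    "order_scaffolds",
    "concatenate_group",
    "lift_coordinate",
    "lift_coordinate_inverse",
    "map_transcripts_to_groups",
    "build_groups",
    "write_link_file",
]

DEFAULT_GAP_LENGTH = 100

PLACED_STATUSES = ("placed_dual", "placed_ref_only", "placed_rh_only")


class HomologyTable:
    """The fixed 1-to-1 correspondence between RH groups and reference chromosomes.

    Output groups are named ``prefix + <group number>`` where the number is
    taken from the RH group label (SQ12 -> SD12 with the default prefix).
    """

    def __init__(self, pairs: list[tuple[str, str]], prefix: str = "SD") -> None:
        groups = [g for g, _ in pairs]
        chroms = [c for _, c in pairs]
        if len(set(groups)) != len(pairs) or len(set(chroms)) != len(pairs):
            raise ValidationError("homology table must be a bijection")
        self.pairs = list(pairs)
        self.prefix = prefix
        self._by_group = dict(pairs)
        self._by_chrom = {c: g for g, c in pairs}

    @classmethod
    def default(cls, prefix: str = "SD") -> "HomologyTable":
        """The packaged 24-pair amberjack/yellowtail/medaka table."""
        from .datasets import homology_pairs

        return cls(homology_pairs(), prefix=prefix)

    @classmethod
    def from_tsv(cls, path, prefix: str = "SD") -> "HomologyTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(list(zip(df.iloc[:, 0], df.iloc[:, 1])), prefix=prefix)

    def __len__(self) -> int:
        return len(self.pairs)

    def chromosome_for(self, rh_group: str) -> str:
        try:
            return self._by_group[rh_group]
        except KeyError:
            raise ValidationError(f"unknown RH group label {rh_group!r}") from None

    def group_for(self, chromosome: str) -> str:
        try:
            return self._by_chrom[chromosome]
        except KeyError:
            raise ValidationError(f"unknown chromosome label {chromosome!r}") from None

    def lookup(self, label: str) -> str:
        """Partner of ``label`` on either side of the table."""
        if label in self._by_group:
            return self._by_group[label]
        if label in self._by_chrom:
            return self._by_chrom[label]
        raise ValidationError(f"label {label!r} absent from homology table")

    def output_name(self, rh_group: str) -> str:
        """Output group label for an RH group, e.g. SQ12 -> SD12."""
        self.chromosome_for(rh_group)  # domain check
        m = re.search(r"(\d+)$", rh_group)
        suffix = m.group(1) if m else rh_group
        return f"{self.prefix}{suffix}"

    def rh_group_for_output(self, output_group: str) -> str:
        for g, _ in self.pairs:
            if self.output_name(g) == output_group:
                return g
        raise ValidationError(f"unknown output group {output_group!r}")


@dataclass(frozen=True)
class Placement:
    """Where one scaffold ends up, and on what evidence."""

    scaffold_id: str
    status: str  # placed_dual | placed_ref_only | placed_rh_only | conflict | unplaced
    group: str | None = None
    order_key: float | None = None
    orientation: str = "+"
    scaffold_length: int = 0
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.status in ("conflict", "unplaced"):
            if self.group is not None or self.order_key is not None:
                raise ValidationError(f"{self.status} placement must carry no group")
        elif self.status in PLACED_STATUSES:
            if self.group is None:
                raise ValidationError("placed scaffold must carry a group")
        else:
            raise ValidationError(f"unknown placement status {self.status!r}")


@dataclass
class InSilicoGroup:
    """An ordered, oriented, gapped tiling of scaffolds on one pseudo-chromosome.

    ``placements`` holds (scaffold_id, offset, length, orientation) with
    0-based half-open offsets on the group sequence.
    """

    group_id: str
    placements: list[tuple[str, int, int, str]]
    gap_length: int
    total_length: int

    def __post_init__(self) -> None:
        offset = 0
        for i, (sid, off, length, orient) in enumerate(self.placements):
            if off != offset:
                raise ValidationError(
                    f"{self.group_id}: scaffold {sid} offset {off}, expected {offset}"
                )
            if orient not in ("+", "-"):
                raise ValidationError(f"bad orientation {orient!r}")
            offset = off + length + self.gap_length
        expected_total = sum(p[2] for p in self.placements) + self.gap_length * max(
            0, len(self.placements) - 1
        )
        if self.total_length != expected_total:
            raise ValidationError(
                f"{self.group_id}: total_length {self.total_length} != {expected_total}"
            )


def reconcile_placement(ev: ScaffoldEvidence, table: HomologyTable) -> Placement:
    """Resolve one scaffold's two evidence channels against the homology table.

    Dual, consistent evidence places the scaffold with its reference position
    as the ordering key; reference-only evidence places it via the inverse
    table lookup; RH-only evidence places it with its smallest supporting
    marker rank as a fallback key (such scaffolds sort after all
    reference-positioned ones); inconsistent evidence — including a tied RH
    vote — is a conflict, and no evidence leaves the scaffold unplaced.
    """
    rh_winner = ev.rh_winner()
    rh_tied = bool(ev.rh_votes) and rh_winner is None
    ref = ev.reference
    ref_known = ref is not None and ref.chromosome in table._by_chrom

    if rh_tied:
        return Placement(scaffold_id=ev.scaffold_id, status="conflict")
    if rh_winner is not None and ref_known:
        if table.chromosome_for(rh_winner) == ref.chromosome:
            return Placement(
                scaffold_id=ev.scaffold_id,
                status="placed_dual",
                group=table.output_name(rh_winner),
                order_key=float(ref.position),
                orientation=ref.strand,
                ambiguous=ref.ambiguous,
            )
        return Placement(scaffold_id=ev.scaffold_id, status="conflict")
    if ref_known:
        return Placement(
            scaffold_id=ev.scaffold_id,
            status="placed_ref_only",
            group=table.output_name(table.group_for(ref.chromosome)),
            order_key=float(ref.position),
            orientation=ref.strand,
            ambiguous=ref.ambiguous,
        )
    if rh_winner is not None:
        ranks = ev.supporting_marker_ranks.get(rh_winner, [])
        return Placement(
            scaffold_id=ev.scaffold_id,
            status="placed_rh_only",
            group=table.output_name(rh_winner),
            order_key=float(min(ranks)) if ranks else 0.0,
            orientation="+",
        )
    return Placement(scaffold_id=ev.scaffold_id, status="unplaced")


def order_scaffolds(placements: list[Placement]) -> list[Placement]:
    """Sort one group's placements: reference position first, marker-rank fallback last.

    Within each tier the key ascends; ties go to the longer scaffold, then
    the lexicographically smaller id, so the order is deterministic.
    """
    groups = {p.group for p in placements}
    if len(groups) > 1:
        raise ValidationError(f"order_scaffolds got mixed groups: {sorted(groups)}")
    for p in placements:
        if p.status not in PLACED_STATUSES:
            raise ValidationError(f"cannot order {p.status} scaffold {p.scaffold_id}")
    return sorted(
        placements,
        key=lambda p: (
            p.status == "placed_rh_only",  # rank-keyed scaffolds after positioned ones
            p.order_key,
            -p.scaffold_length,
            p.scaffold_id,
        ),
    )


def concatenate_group(
    ordered: list[Placement],
    sequences: dict[str, SequenceRecord],
    gap_length: int = DEFAULT_GAP_LENGTH,
    group_id: str | None = None,
) -> tuple[SequenceRecord, list[AGPRecord], InSilicoGroup]:
    """Join ordered scaffolds into one pseudo-chromosome with N-gap spacers.

    Minus-orientation scaffolds are reverse-complemented.  The AGP alternates
    W (scaffold) and N (gap) components in 1-based coordinates; the returned
    :class:`InSilicoGroup` uses 0-based offsets.
    """
    if gap_length < 0:
        raise ValidationError("gap_length must be >= 0")
    if not ordered:
        raise ValidationError("cannot concatenate an empty group")
    gid = group_id or ordered[0].group or "group"

    parts: list[str] = []
    agp: list[AGPRecord] = []
    tiling: list[tuple[str, int, int, str]] = []
    offset = 0
    part_number = 1
    for i, p in enumerate(ordered):
        rec = sequences.get(p.scaffold_id)
        if rec is None:
            raise ValidationError(f"no sequence for scaffold {p.scaffold_id!r}")
        seq = rec.residues
        if p.orientation == "-":
            seq = str(Seq(seq).reverse_complement())
        if i > 0 and gap_length > 0:
            parts.append("N" * gap_length)
            agp.append(
                AGPRecord(
                    object_id=gid,
                    object_beg=offset + 1,
                    object_end=offset + gap_length,
                    part_number=part_number,
                    component_type="N",
                    component_id_or_gaplen=gap_length,
                    gap_type="scaffold",
                )
            )
            part_number += 1
            offset += gap_length
        parts.append(seq)
        agp.append(
            AGPRecord(
                object_id=gid,
                object_beg=offset + 1,
                object_end=offset + len(seq),
                part_number=part_number,
                component_type="W",
                component_id_or_gaplen=p.scaffold_id,
                component_beg=1,
                component_end=len(seq),
                orientation=p.orientation,
            )
        )
        tiling.append((p.scaffold_id, offset, len(seq), p.orientation))
        part_number += 1
        offset += len(seq)

    group = InSilicoGroup(
        group_id=gid,
        placements=tiling,
        gap_length=gap_length,
        total_length=offset,
    )
    record = SequenceRecord(id=gid, residues="".join(parts))
    return record, agp, group


def lift_coordinate(
    group: InSilicoGroup, scaffold_id: str, position: int
) -> tuple[str, int]:
    """Map a 0-based scaffold position onto the group sequence."""
    for sid, offset, length, orient in group.placements:
        if sid == scaffold_id:
            if not 0 <= position < length:
                raise ValidationError(
                    f"position {position} outside scaffold {scaffold_id} (len {length})"
                )
            if orient == "+":
                return group.group_id, offset + position
            return group.group_id, offset + (length - 1 - position)
    raise ValidationError(f"scaffold {scaffold_id!r} not in group {group.group_id}")


def lift_coordinate_inverse(group: InSilicoGroup, position: int) -> tuple[str, int]:
    """Map a 0-based group position back to (scaffold, position); gaps are errors."""
    if not 0 <= position < group.total_length:
        raise ValidationError(
            f"position {position} outside group {group.group_id} (len {group.total_length})"
        )
    starts = [off for _, off, _, _ in group.placements]
    i = bisect_right(starts, position) - 1
    sid, offset, length, orient = group.placements[i]
    local = position - offset
    if local >= length:
        raise ValidationError(
            f"group position {position} falls in a gap of {group.group_id}"
        )
    if orient == "+":
        return sid, local
    return sid, length - 1 - local


def map_transcripts_to_groups(
    transcript_hits: list[AlignmentHit],
) -> tuple[dict[str, tuple[str, tuple[int, int]]], dict[str, int]]:
    """Assign each transcript to the group of its best surviving hit.

    Input hits must already have passed ``transcript_placement_filter``.
    Returns (transcript -> (group, 0-based half-open subject span)) and a
    per-group transcript count table.  Equal-score hits resolve by the
    best-hit tie-break (identity, then lexicographically smallest group
    label), so assignment is unique and deterministic.
    """
    best = best_hit_per_query(transcript_hits)
    assignment: dict[str, tuple[str, tuple[int, int]]] = {}
    counts: dict[str, int] = {}
    for tid, hit in best.items():
        lo, hi = sorted((hit.s_start, hit.s_end))
        assignment[tid] = (hit.subject_id, (lo - 1, hi))
        counts[hit.subject_id] = counts.get(hit.subject_id, 0) + 1
    return assignment, counts


@dataclass
class GroupBuildResult:
    """Everything the anchoring step produces."""

    groups: dict[str, InSilicoGroup]
    records: list[SequenceRecord]
    agp: list[AGPRecord]
    placements: list[Placement]

    @property
    def conflicts(self) -> list[Placement]:
        return [p for p in self.placements if p.status == "conflict"]

    @property
    def unplaced(self) -> list[Placement]:
        return [p for p in self.placements if p.status == "unplaced"]

    def placement_of(self, scaffold_id: str) -> Placement | None:
        for p in self.placements:
            if p.scaffold_id == scaffold_id:
                return p
        return None

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.placements:
            out[p.status] = out.get(p.status, 0) + 1
        return out


def build_groups(
    evidence: dict[str, ScaffoldEvidence],
    table: HomologyTable,
    sequences: dict[str, SequenceRecord],
    gap_length: int = DEFAULT_GAP_LENGTH,
    include_rh_only: bool = True,
) -> GroupBuildResult:
    """Reconcile, order and concatenate all scaffolds into in silico groups.

    Every scaffold in ``sequences`` receives exactly one placement record;
    scaffolds without evidence are unplaced, conflicting ones go to the
    conflicts side-table — nothing is silently dropped.  ``include_rh_only``
    controls whether marker-only scaffolds enter the concatenated groups.
    """
    placements: list[Placement] = []
    for sid in sorted(sequences):
        ev = evidence.get(sid)
        if ev is None:
            placements.append(Placement(scaffold_id=sid, status="unplaced"))
            continue
        p = reconcile_placement(ev, table)
        placements.append(
            Placement(
                scaffold_id=p.scaffold_id,
                status=p.status,
                group=p.group,
                order_key=p.order_key,
                orientation=p.orientation,
                scaffold_length=len(sequences[sid]),
                ambiguous=p.ambiguous,
            )
        )

    by_group: dict[str, list[Placement]] = {}
    for p in placements:
        if p.status in PLACED_STATUSES:
            if p.status == "placed_rh_only" and not include_rh_only:
                continue
            by_group.setdefault(p.group, []).append(p)

    groups: dict[str, InSilicoGroup] = {}
    records: list[SequenceRecord] = []
    agp: list[AGPRecord] = []
    for gid in sorted(by_group):
        ordered = order_scaffolds(by_group[gid])
        rec, grp_agp, grp = concatenate_group(
            ordered, sequences, gap_length=gap_length, group_id=gid
        )
        groups[gid] = grp
        records.append(rec)
        agp.extend(grp_agp)
    return GroupBuildResult(
        groups=groups, records=records, agp=agp, placements=placements
    )


def write_link_file(
    result: GroupBuildResult,
    evidence: dict[str, ScaffoldEvidence],
    path,
) -> None:
    """Emit circos-style links ``group start end chromosome start end``.

    One link per placed scaffold with a reference assignment: the scaffold's
    span on its group, joined to a point interval at its representative
    reference position (coordinates 0-based half-open, space-separated).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gid in sorted(result.groups):
            for sid, offset, length, _ in result.groups[gid].placements:
                ev = evidence.get(sid)
                if ev is None or ev.reference is None:
                    continue
                ref = ev.reference
                fh.write(
                    f"{gid} {offset} {offset + length} "
                    f"{ref.chromosome} {ref.position - 1} {ref.position}\n"
                )
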