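"""Per-scaffold homology evidence from raw alignment hits.

Two evidence channels feed the anchoring step: radiation-hybrid markers
best-hitting scaffolds (votes for an RH linkage group) and scaffolds
best-hitting a reference genome (a chromosome assignment with a
representative position).  Evidence strength is the alignment bit score —
monotone, additive and length-aware — never the e-value or identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import AlignmentHit, RHMarkerRecord, ValidationError

__all__ = [
    "EvidenceConfig",
    "ScaffoldEvidence",
    "ReferenceAssignment",
    "filter_hits_by_evalue",
    "best_hit_per_query",
    "marker_group_votes",
    "vote_reference_chromosome",
    "transcript_placement_filter",
    "collect_evidence",
]

#: A runner-up chromosome with at least this fraction of the winner's
#: bit-score mass marks the assignment as ambiguous.
AMBIGUITY_RATIO = 0.8


@dataclass(frozen=True)
class EvidenceConfig:
    """Filtering thresholds for the two evidence channels.

    ``max_marker_evalue`` is a strict upper bound (hits with e-value equal to
    it are removed); the transcript-placement bounds are inclusive, so the
    defaults demand exact 100% identity and a floating-point-zero e-value.
    """

    max_marker_evalue: float = 1e-10
    transcript_min_identity: float = 100.0
    transcript_max_evalue: float = 0.0
    ambiguity_ratio: float = AMBIGUITY_RATIO

    def __post_init__(self) -> None:
        if self.max_marker_evalue < 0 or self.transcript_max_evalue < 0:
            raise ValidationError("e-value thresholds must be non-negative")


@dataclass(frozen=True)
class ReferenceAssignment:
    """Winning reference chromosome for one scaffold, by summed bit score."""

    chromosome: str
    position: int  # representative subject coordinate (midpoint of best hit)
    strand: str  # strand of the single best hit on the winning chromosome
    score_mass: float
    ambiguous: bool = False


@dataclass
class ScaffoldEvidence:
    """Both evidence channels for one scaffold.

    ``rh_votes`` maps RH group label to summed bit-score mass from markers
    best-hitting this scaffold; the reference assignment may be absent.
    """

    scaffold_id: str
    rh_votes: dict[str, float] = field(default_factory=dict)
    reference: ReferenceAssignment | None = None
    supporting_marker_ranks: dict[str, list[int]] = field(default_factory=dict)

    def rh_winner(self) -> str | None:
        """Group with maximal vote mass; ``None`` if no votes or a tied top."""
        if not self.rh_votes:
            return None
        best = max(self.rh_votes.values())
        winners = [g for g, m in self.rh_votes.items() if m == best]
        return winners[0] if len(winners) == 1 else None


def filter_hits_by_evalue(
    hits: list[AlignmentHit], max_evalue: float
) -> list[AlignmentHit]:
    """Keep hits with e-value *strictly* below ``max_evalue``; order preserved."""
    if max_evalue < 0:
        raise ValidationError("max_evalue must be non-negative")
    return [h for h in hits if h.e_value < max_evalue]


def _hit_rank_key(h: AlignmentHit) -> tuple:
    # Primary: bit score, then identity; subject id lexicographic as the
    # stated tie-break; the coordinate tail makes the choice a pure function
    # of the hit set (independent of input order) even for duplicate hits.
    return (-h.bit_score, -h.percent_identity, h.subject_id, h.s_start, h.s_end, h.q_start, h.q_end)


def best_hit_per_query(hits: list[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Maximal-bit-score hit per query.

    Ties go to the higher percent identity, then the lexicographically
    smallest subject id; the result is identical for any permutation of the
    input.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank_key(h) < _hit_rank_key(cur):
            best[h.query_id] = h
    return best


def marker_group_votes(
    marker_best_hits: dict[str, AlignmentHit], rh_map: list[RHMarkerRecord]
) -> dict[str, dict[str, float]]:
    """Accumulate each marker's bit score onto its RH group, per scaffold hit.

    Returns scaffold_id -> {rh_group: summed bit-score mass}.  A marker not
    present in the RH map is a validation error.
    """
    by_marker = {m.marker_id: m for m in rh_map}
    votes: dict[str, dict[str, float]] = {}
    for marker_id, hit in marker_best_hits.items():
        rec = by_marker.get(marker_id)
        if rec is None:
            raise ValidationError(f"marker {marker_id!r} absent from the RH map")
        scaffold_votes = votes.setdefault(hit.subject_id, {})
        scaffold_votes[rec.rh_group] = scaffold_votes.get(rec.rh_group, 0.0) + hit.bit_score
    return votes


def vote_reference_chromosome(
    hits_by_scaffold: dict[str, list[AlignmentHit]],
    ambiguity_ratio: float = AMBIGUITY_RATIO,
) -> dict[str, ReferenceAssignment]:
    """Assign each scaffold the reference chromosome with maximal summed bit score.

    The representative position is the subject midpoint of the scaffold's
    single highest-scoring hit on the winning chromosome (robust to spurious
    secondary hits), and the strand is that hit's strand.  Mass ties go to
    the lexicographically smallest chromosome label.  A runner-up with
    >= ``ambiguity_ratio`` of the winner's mass flags the assignment
    ambiguous; nothing is discarded here.
    """
    out: dict[str, ReferenceAssignment] = {}
    for scaffold_id, hits in hits_by_scaffold.items():
        if not hits:
            continue
        mass: dict[str, float] = {}
        for h in hits:
            mass[h.subject_id] = mass.get(h.subject_id, 0.0) + h.bit_score
        winner = min(mass, key=lambda c: (-mass[c], c))
        best_hit = min(
            (h for h in hits if h.subject_id == winner), key=_hit_rank_key
        )
        runner_up = max(
            (m for c, m in mass.items() if c != winner), default=0.0
        )
        out[scaffold_id] = ReferenceAssignment(
            chromosome=winner,
            position=best_hit.subject_midpoint,
            strand=best_hit.strand,
            score_mass=mass[winner],
            ambiguous=runner_up >= ambiguity_ratio * mass[winner],
        )
    return out


def transcript_placement_filter(
    hits: list[AlignmentHit], cfg: EvidenceConfig | None = None
) -> list[AlignmentHit]:
    """Keep transcript hits meeting the placement bounds (inclusive).

    Defaults demand perfect identity and a zero e-value, the stringency used
    when re-mapping a reference transcriptome onto its own concatenated
    assembly.
    """
    cfg = cfg or EvidenceConfig()
    return [
        h
        for h in hits
        if h.percent_identity >= cfg.transcript_min_identity
        and h.e_value <= cfg.transcript_max_evalue
    ]


def collect_evidence(
    marker_hits: list[AlignmentHit],
    scaffold_hits: list[AlignmentHit],
    rh_map: list[RHMarkerRecord],
    cfg: EvidenceConfig | None = None,
) -> dict[str, ScaffoldEvidence]:
    """Run both evidence channels and merge them per scaffold.

    ``marker_hits`` are marker->scaffold alignments, ``scaffold_hits`` are
    scaffold->reference-genome alignments; both are e-value filtered at
    ``cfg.max_marker_evalue`` before best-hit reduction / voting.
    """
    cfg = cfg or EvidenceConfig()
    marker_best = best_hit_per_query(filter_hits_by_evalue(marker_hits, cfg.max_marker_evalue))
    votes = marker_group_votes(marker_best, rh_map)

    by_marker = {m.marker_id: m for m in rh_map}
    ranks: dict[str, dict[str, list[int]]] = {}
    for marker_id, hit in marker_best.items():
        rec = by_marker[marker_id]
        ranks.setdefault(hit.subject_id, {}).setdefault(rec.rh_group, []).append(
            rec.position_index
        )

    by_scaffold: dict[str, list[AlignmentHit]] = {}
    for h in filter_hits_by_evalue(scaffold_hits, cfg.max_marker_evalue):
        by_scaffold.setdefault(h.query_id, []).append(h)
    assignments = vote_reference_chromosome(by_scaffold, cfg.ambiguity_ratio)

    evidence: dict[str, ScaffoldEvidence] = {}
    for sid in sorted(set(votes) | set(assignments)):
        evidence[sid] = ScaffoldEvidence(
            scaffold_id=sid,
            rh_votes=votes.get(sid, {}),
            reference=assignments.get(sid),
            supporting_marker_ranks=ranks.get(sid, {}),
        )
    return evidence
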