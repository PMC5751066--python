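"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the study conditions at desk scale: two diverged
karyotypes with a conserved 1-to-1 chromosome homology (occasional
translocations and inversions), fragmentation of the study genome into
scaffolds, noisy tabular alignment hits, a radiation-hybrid marker panel per
group, negative-binomial count matrices for a 4-vs-4 design with a fraction
of direction-biased features, and GO annotations with spiked enriched terms.
Every generator is a pure function of its :class:`SimulationConfig` —
identical configs give bit-identical output.

Sequences are synthesized i.i.d. uniform over A/C/G/T: alignment hits are
simulated from the known gene coordinates, not computed by an aligner, so
sequence realism is unnecessary.  The companion DE table is produced by a
simple pooled-variance two-group t-test on log2(count+1) with BH adjustment
— a clearly labelled stand-in for a count-model fit, adequate for exercising
the filtering stage, and not a reimplementation of any published DE method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .expression import CountMatrix
from .formats_io import (
    AlignmentHit,
    DERecord,
    GOAnnotationRecord,
    RHMarkerRecord,
    SequenceRecord,
    ValidationError,
    write_alignment_tabular,
    write_de_table,
    write_fasta,
    write_go_annotations,
    write_rh_map,
)
from .groups import GroupBuildResult, HomologyTable, build_groups
from .homology import EvidenceConfig, collect_evidence

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ScaffoldTruth",
    "GenomePair",
    "AnchoringScenario",
    "simulate_genome_pair",
    "fragment_genome",
    "simulate_alignments",
    "simulate_rh_panel",
    "simulate_expression",
    "simulate_go_annotations",
    "simulate_anchoring_scenario",
    "run_anchoring",
    "group_accuracy",
    "order_concordance",
    "simulate_all",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for every generator; ``seed`` is mandatory.

    Defaults describe the desk-scale study conditions: 4 chromosomes of 50
    genes (gene lengths 300-800 bp, 500 bp intergap), fragmentation to a
    ~2 kb scaffold N50 (a couple of genes per scaffold, so scaffolds
    outnumber gene-bearing loci as in a short-read draft), 10 RH markers per
    group, and a 2000-feature expression panel with 5% true effects of
    |log2FC| = 4.
    """

    seed: int
    n_chromosomes: int = 4
    genes_per_chromosome: int = 50
    translocation_rate: float = 0.02
    inversion_rate: float = 0.1
    scaffold_n50_target: int = 2000
    false_hit_rate: float = 0.0
    markers_per_group: int = 10
    n_features_expr: int = 2000
    de_fraction: float = 0.05
    lfc_magnitude: float = 4.0
    nb_dispersion: float = 0.1
    n_go_terms: int = 100
    spiked_terms: int = 2
    spike_fold: float = 6.0
    go_baseline_prob: float = 0.05
    gene_length_range: tuple[int, int] = (300, 800)
    intergenic_length: int = 500
    flip_probability: float = 0.5

    def __post_init__(self) -> None:
        for name in ("translocation_rate", "inversion_rate", "false_hit_rate",
                     "de_fraction", "go_baseline_prob", "flip_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]: {v}")
        for name in ("n_chromosomes", "genes_per_chromosome", "scaffold_n50_target",
                     "markers_per_group", "n_features_expr", "n_go_terms"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one op; streams keep ops decoupled."""
        return np.random.default_rng([int(self.seed), stream])


# distinct RNG stream ids per generator
_S_GENOME, _S_FRAG, _S_ALIGN, _S_RH, _S_EXPR, _S_GO = range(6)


@dataclass(frozen=True)
class _Gene:
    gene_id: str
    length: int


@dataclass
class GenomePair:
    """Two gene orders related by translocation/inversion, plus coordinates.

    ``ref_order[chrom]`` is the list of gene ids along a reference
    chromosome; ``study_order[group]`` is the list of (gene_id, strand) along
    a study chromosome.  ``ref_span`` / ``study_span`` give each gene's
    0-based half-open coordinates on its chromosome, and ``study_sequences``
    holds the synthesized study chromosome sequences.
    """

    gene_lengths: dict[str, int]
    ref_order: dict[str, list[str]]
    study_order: dict[str, list[tuple[str, str]]]
    ref_span: dict[str, tuple[str, int, int]]
    study_span: dict[str, tuple[str, int, int, str]]
    study_sequences: dict[str, str]
    homology_pairs: list[tuple[str, str]]

    def homology_table(self, prefix: str = "SD") -> HomologyTable:
        return HomologyTable(self.homology_pairs, prefix=prefix)


def _layout(order: list[str], lengths: dict[str, int], intergap: int):
    """Place genes left to right with a fixed intergap; returns spans and total."""
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for gid in order:
        pos += intergap
        spans[gid] = (pos, pos + lengths[gid])
        pos += lengths[gid]
    return spans, pos + intergap


def simulate_genome_pair(cfg: SimulationConfig) -> GenomePair:
    """Build reference and study karyotypes with conserved 1-to-1 homology.

    Genes start in identical orders; each gene then translocates to a
    uniformly redrawn study chromosome with probability
    ``translocation_rate``, and each study chromosome suffers one random
    segment inversion with probability ``inversion_rate``.  The homology
    table (SQi <-> OLi) holds by construction.
    """
    rng = cfg.rng(_S_GENOME)
    lo, hi = cfg.gene_length_range
    n_chrom = cfg.n_chromosomes
    ref_chroms = [f"OL{i + 1}" for i in range(n_chrom)]
    study_groups = [f"SQ{i + 1}" for i in range(n_chrom)]

    genes: list[_Gene] = []
    ref_order: dict[str, list[str]] = {c: [] for c in ref_chroms}
    study_assign: dict[str, list[str]] = {g: [] for g in study_groups}
    k = 0
    for ci in range(n_chrom):
        for _ in range(cfg.genes_per_chromosome):
            gid = f"g{k:05d}"
            k += 1
            genes.append(_Gene(gid, int(rng.integers(lo, hi + 1))))
            ref_order[ref_chroms[ci]].append(gid)
            study_assign[study_groups[ci]].append(gid)

    # translocations: redraw the study chromosome, insert at a random slot
    for ci, group in enumerate(study_groups):
        for gid in list(study_assign[group]):
            if rng.random() < cfg.translocation_rate:
                target = study_groups[int(rng.integers(n_chrom))]
                if target != group:
                    study_assign[group].remove(gid)
                    slot = int(rng.integers(len(study_assign[target]) + 1))
                    study_assign[target].insert(slot, gid)

    # inversions: reverse one random segment, flipping strands
    study_order: dict[str, list[tuple[str, str]]] = {}
    for group in study_groups:
        order = [(gid, "+") for gid in study_assign[group]]
        if len(order) >= 2 and rng.random() < cfg.inversion_rate:
            i = int(rng.integers(len(order) - 1))
            j = int(rng.integers(i + 1, len(order)))
            seg = [(g, "-" if s == "+" else "+") for g, s in reversed(order[i : j + 1])]
            order = order[:i] + seg + order[j + 1 :]
        study_order[group] = order

    lengths = {g.gene_id: g.length for g in genes}
    ref_span: dict[str, tuple[str, int, int]] = {}
    for chrom in ref_chroms:
        spans, _ = _layout(ref_order[chrom], lengths, cfg.intergenic_length)
        for gid, (s, e) in spans.items():
            ref_span[gid] = (chrom, s, e)

    study_span: dict[str, tuple[str, int, int, str]] = {}
    study_sequences: dict[str, str] = {}
    for group in study_groups:
        order_ids = [gid for gid, _ in study_order[group]]
        spans, total = _layout(order_ids, lengths, cfg.intergenic_length)
        strand = dict(study_order[group])
        for gid, (s, e) in spans.items():
            study_span[gid] = (group, s, e, strand[gid])
        study_sequences[group] = "".join(rng.choice(_BASES, size=total))

    return GenomePair(
        gene_lengths=lengths,
        ref_order=ref_order,
        study_order=study_order,
        ref_span=ref_span,
        study_span=study_span,
        study_sequences=study_sequences,
        homology_pairs=list(zip(study_groups, ref_chroms)),
    )


@dataclass(frozen=True)
class ScaffoldTruth:
    """Ground truth for one scaffold: where it belongs and how it is oriented."""

    scaffold_id: str
    group: str  # study group label (SQ*)
    order_index: int  # rank along the study chromosome
    orientation: str  # '+' as laid out, '-' if the emitted sequence is flipped
    chrom_start: int  # 0-based start on the study chromosome
    chrom_end: int
    genes: tuple[str, ...]  # gene ids fully contained in the scaffold


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulators, keyed for recovery tests."""

    scaffolds: dict[str, ScaffoldTruth] = field(default_factory=dict)
    de_labels: dict[str, str | None] = field(default_factory=dict)
    spiked_terms: list[str] = field(default_factory=list)


def fragment_genome(
    pair: GenomePair, cfg: SimulationConfig
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Cut study chromosomes into scaffolds and record per-scaffold truth.

    Cut points fall in intergenic midpoints; per-scaffold target lengths are
    drawn uniformly from [1, 1.5] x ``scaffold_n50_target``, so a target at
    least the chromosome length yields one scaffold per chromosome.  Each
    scaffold is reverse-complemented with probability ``flip_probability``
    (recorded as orientation '-').  Concatenating truth-ordered,
    truth-oriented scaffolds reconstructs each chromosome exactly.
    """
    from Bio.Seq import Seq

    rng = cfg.rng(_S_FRAG)
    records: list[SequenceRecord] = []
    truth = SyntheticTruth()
    sid_counter = 0
    for group, _chrom in pair.homology_pairs:
        seq = pair.study_sequences[group]
        order = pair.study_order[group]
        spans = {gid: pair.study_span[gid] for gid, _ in order}
        # candidate cut points: midpoints of intergenic gaps between genes
        cuts: list[int] = []
        boundary_after: list[int] = []  # index of last gene before each cut
        for i in range(len(order) - 1):
            end_i = spans[order[i][0]][2]
            start_next = spans[order[i + 1][0]][1]
            cuts.append((end_i + start_next) // 2)
            boundary_after.append(i)

        chosen: list[int] = []
        target = float(rng.uniform(1.0, 1.5)) * cfg.scaffold_n50_target
        prev = 0
        for cut, _gi in zip(cuts, boundary_after):
            if cut - prev >= target:
                chosen.append(cut)
                prev = cut
                target = float(rng.uniform(1.0, 1.5)) * cfg.scaffold_n50_target
        starts = [0] + chosen
        ends = chosen + [len(seq)]

        order_ids = [gid for gid, _ in order]
        for oi, (s, e) in enumerate(zip(starts, ends)):
            sid = f"scaf{sid_counter:05d}"
            sid_counter += 1
            contained = tuple(
                gid for gid in order_ids if spans[gid][1] >= s and spans[gid][2] <= e
            )
            flipped = rng.random() < cfg.flip_probability
            segment = seq[s:e]
            if flipped:
                segment = str(Seq(segment).reverse_complement())
            records.append(SequenceRecord(id=sid, residues=segment))
            truth.scaffolds[sid] = ScaffoldTruth(
                scaffold_id=sid,
                group=group,
                order_index=oi,
                orientation="-" if flipped else "+",
                chrom_start=s,
                chrom_end=e,
                genes=contained,
            )
    return records, truth


def _gene_in_scaffold(
    pair: GenomePair, st: ScaffoldTruth, gid: str
) -> tuple[int, int, str]:
    """0-based half-open span and strand of a gene inside its (possibly
    flipped) scaffold sequence."""
    _, gs, ge, strand = pair.study_span[gid]
    s, e = gs - st.chrom_start, ge - st.chrom_start
    if st.orientation == "-":
        length = st.chrom_end - st.chrom_start
        s, e = length - e, length - s
        strand = "-" if strand == "+" else "+"
    return s, e, strand


def _mk_hit(
    query: str,
    subject: str,
    q_span: tuple[int, int],
    s_span: tuple[int, int],
    minus: bool,
    rng: np.random.Generator,
) -> AlignmentHit:
    """One simulated high-confidence hit (e-value well below 1e-12)."""
    qs, qe = q_span
    ss, se = s_span
    length = qe - qs
    if minus:
        s1, s2 = se, ss + 1  # 1-based reversed
    else:
        s1, s2 = ss + 1, se
    pident = float(rng.uniform(98.0, 100.0))
    evalue = float(10.0 ** -rng.uniform(20.0, 60.0))
    return AlignmentHit(
        query_id=query,
        subject_id=subject,
        percent_identity=round(pident, 2),
        alignment_length=length,
        mismatches=0,
        gap_opens=0,
        q_start=qs + 1,
        q_end=qe,
        s_start=s1,
        s_end=s2,
        e_value=evalue,
        bit_score=float(2 * length),
    )


def simulate_rh_panel(
    pair: GenomePair, cfg: SimulationConfig
) -> list[RHMarkerRecord]:
    """Sample ``markers_per_group`` marker genes per study group.

    Markers are genes drawn without replacement along each study chromosome;
    ranks follow the true gene order, so within a group they increase
    strictly along the chromosome.
    """
    rng = cfg.rng(_S_RH)
    records: list[RHMarkerRecord] = []
    for group, _ in pair.homology_pairs:
        order_ids = [gid for gid, _ in pair.study_order[group]]
        n = min(cfg.markers_per_group, len(order_ids))
        idx = sorted(rng.choice(len(order_ids), size=n, replace=False).tolist())
        for rank, i in enumerate(idx):
            records.append(
                RHMarkerRecord(
                    marker_id=f"mk_{order_ids[i]}",
                    rh_group=group,
                    position_index=rank,
                )
            )
    return records


def simulate_alignments(
    pair: GenomePair,
    truth: SyntheticTruth,
    rh_map: list[RHMarkerRecord],
    cfg: SimulationConfig,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Emit marker->scaffold and scaffold->reference hits from the truth.

    Every marker hits the scaffold containing its gene; every scaffold emits
    one hit per contained gene onto that gene's reference chromosome, with
    bit score proportional to the gene length and e-values far below the
    1e-10 filter.  With probability ``false_hit_rate`` a hit is redirected
    to a uniformly random subject and position (the true subject may be
    redrawn by chance).
    """
    rng = cfg.rng(_S_ALIGN)
    gene_to_scaffold = {
        gid: sid for sid, st in truth.scaffolds.items() for gid in st.genes
    }
    scaffold_ids = sorted(truth.scaffolds)
    scaffold_len = {
        sid: st.chrom_end - st.chrom_start for sid, st in truth.scaffolds.items()
    }
    ref_chroms = [c for _, c in pair.homology_pairs]
    ref_len = {
        c: _layout(pair.ref_order[c], pair.gene_lengths, cfg.intergenic_length)[1]
        for c in ref_chroms
    }

    marker_hits: list[AlignmentHit] = []
    for rec in rh_map:
        gid = rec.marker_id.removeprefix("mk_")
        sid = gene_to_scaffold.get(gid)
        if sid is None:
            continue  # marker gene split across a cut: no mappable target
        glen = pair.gene_lengths[gid]
        if rng.random() < cfg.false_hit_rate:
            subject = scaffold_ids[int(rng.integers(len(scaffold_ids)))]
            start = int(rng.integers(max(1, scaffold_len[subject] - glen + 1)))
            span = (start, min(start + glen, scaffold_len[subject]))
            marker_hits.append(_mk_hit(rec.marker_id, subject, (0, glen), span, False, rng))
        else:
            s, e, strand = _gene_in_scaffold(pair, truth.scaffolds[sid], gid)
            marker_hits.append(
                _mk_hit(rec.marker_id, sid, (0, glen), (s, e), strand == "-", rng)
            )

    scaffold_hits: list[AlignmentHit] = []
    for sid in scaffold_ids:
        st = truth.scaffolds[sid]
        for gid in st.genes:
            qs, qe, strand_in_scaf = _gene_in_scaffold(pair, st, gid)
            ref_chrom, rs, re_ = pair.ref_span[gid]
            if rng.random() < cfg.false_hit_rate:
                subject = ref_chroms[int(rng.integers(len(ref_chroms)))]
                glen = qe - qs
                start = int(rng.integers(max(1, ref_len[subject] - glen)))
                scaffold_hits.append(
                    _mk_hit(sid, subject, (qs, qe), (start, start + glen), False, rng)
                )
            else:
                scaffold_hits.append(
                    _mk_hit(sid, ref_chrom, (qs, qe), (rs, re_), strand_in_scaf == "-", rng)
                )
    return marker_hits, scaffold_hits


# ---------------------------------------------------------------------------
# expression and annotation


def simulate_expression(
    cfg: SimulationConfig, n_per_condition: int = 4
) -> tuple[CountMatrix, list[DERecord], dict[str, str | None]]:
    """Negative-binomial counts for an n-vs-n design with planted effects.

    Baseline means are log-normal (median ~100); a ``de_fraction`` of
    features receive a 2**(+-lfc_magnitude) fold change between the
    conditions, half in each direction, applied symmetrically (each
    condition shifted by half the effect) so the baseline stays the
    geometric mean.  Counts are NB with variance m + dispersion * m^2.
    The companion DE table comes from the documented stand-in test — a
    pooled-variance two-sample t on log2(count+1) with BH adjustment (the
    log transform makes the two groups' variances comparable, and pooling
    keeps the 6 degrees of freedom a 4-vs-4 design affords) — with log2FC
    estimated as the difference of mean log2 counts (positive = higher in
    condition A).
    """
    rng = cfg.rng(_S_EXPR)
    n = cfg.n_features_expr
    features = [f"t{i:05d}" for i in range(n)]
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n)

    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    labels: dict[str, str | None] = {f: None for f in features}
    mean_a = base.copy()
    mean_b = base.copy()
    half = 2.0 ** (cfg.lfc_magnitude / 2.0)
    for j, i in enumerate(sorted(de_idx.tolist())):
        if j % 2 == 0:
            mean_a[i], mean_b[i] = base[i] * half, base[i] / half
            labels[features[i]] = "up_in_a"
        else:
            mean_a[i], mean_b[i] = base[i] / half, base[i] * half
            labels[features[i]] = "up_in_b"

    def draw(means: np.ndarray) -> np.ndarray:
        m = np.repeat(means[:, None], n_per_condition, axis=1)
        if cfg.nb_dispersion <= 0:
            return rng.poisson(m)
        size = 1.0 / cfg.nb_dispersion
        p = size / (size + m)
        return rng.negative_binomial(size, p)

    counts = np.hstack([draw(mean_a), draw(mean_b)]).astype(np.int64)
    samples = [f"A{i + 1}" for i in range(n_per_condition)] + [
        f"B{i + 1}" for i in range(n_per_condition)
    ]
    conditions = ["A"] * n_per_condition + ["B"] * n_per_condition
    matrix = CountMatrix(
        features=features, samples=samples, conditions=conditions, counts=counts
    )

    log = matrix.log_transformed()
    a = log[:, :n_per_condition]
    b = log[:, n_per_condition:]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=True)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    from .enrichment import bh_fdr

    qvals = bh_fdr([float(p) for p in pvals])
    de_table = [
        DERecord(
            feature_id=f,
            log2_fold_change=float(l),
            p_value=float(p),
            p_adjusted=float(q),
        )
        for f, l, p, q in zip(features, lfc, pvals, qvals)
    ]
    return matrix, de_table, labels


def simulate_go_annotations(
    cfg: SimulationConfig, de_labels: dict[str, str | None]
) -> tuple[list[GOAnnotationRecord], list[str]]:
    """Bernoulli baseline annotations with spiked terms among true-DE features.

    Each (feature, term) pair is annotated with probability
    ``go_baseline_prob``; for the first ``spiked_terms`` terms the
    probability among true-DE features is multiplied by ``spike_fold``
    (capped at 1).  Features that end up with no terms are simply absent.
    """
    rng = cfg.rng(_S_GO)
    features = sorted(de_labels)
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    spiked = terms[: cfg.spiked_terms]
    p0 = cfg.go_baseline_prob
    p_spike = min(1.0, cfg.spike_fold * p0)

    records: list[GOAnnotationRecord] = []
    u = rng.random((len(features), len(terms)))
    for i, fid in enumerate(features):
        is_de = de_labels[fid] is not None
        assigned = []
        for j, term in enumerate(terms):
            p = p_spike if (is_de and term in spiked) else p0
            if u[i, j] < p:
                assigned.append(term)
        if assigned:
            records.append(GOAnnotationRecord(feature_id=fid, terms=frozenset(assigned)))
    return records, spiked


# ---------------------------------------------------------------------------
# scenario orchestration and recovery scoring


@dataclass
class AnchoringScenario:
    """Everything the anchoring pipeline consumes, plus its ground truth."""

    pair: GenomePair
    scaffolds: list[SequenceRecord]
    marker_hits: list[AlignmentHit]
    scaffold_hits: list[AlignmentHit]
    rh_map: list[RHMarkerRecord]
    table: HomologyTable
    truth: SyntheticTruth


def simulate_anchoring_scenario(cfg: SimulationConfig) -> AnchoringScenario:
    """Genome pair -> fragmentation -> marker panel -> alignment hits."""
    pair = simulate_genome_pair(cfg)
    scaffolds, truth = fragment_genome(pair, cfg)
    rh_map = simulate_rh_panel(pair, cfg)
    marker_hits, scaffold_hits = simulate_alignments(pair, truth, rh_map, cfg)
    return AnchoringScenario(
        pair=pair,
        scaffolds=scaffolds,
        marker_hits=marker_hits,
        scaffold_hits=scaffold_hits,
        rh_map=rh_map,
        table=pair.homology_table(),
        truth=truth,
    )


def run_anchoring(
    scenario: AnchoringScenario, cfg: EvidenceConfig | None = None
) -> GroupBuildResult:
    """Run evidence collection and group building on a simulated scenario."""
    evidence = collect_evidence(
        scenario.marker_hits, scenario.scaffold_hits, scenario.rh_map, cfg
    )
    sequences = {r.id: r for r in scenario.scaffolds}
    return build_groups(evidence, scenario.table, sequences)


def group_accuracy(result: GroupBuildResult, scenario: AnchoringScenario) -> float:
    """Fraction of gene-bearing scaffolds placed in their true group.

    Scaffolds containing no gene have no evidence and are excluded;
    conflicts and unplaced gene-bearing scaffolds count as wrong.
    """
    table = scenario.table
    total = correct = 0
    placement = {p.scaffold_id: p for p in result.placements}
    for sid, st in scenario.truth.scaffolds.items():
        if not st.genes:
            continue
        total += 1
        p = placement.get(sid)
        if p is not None and p.group == table.output_name(st.group):
            correct += 1
    if total == 0:
        raise ValidationError("no placeable scaffolds in scenario")
    return correct / total


def order_concordance(result: GroupBuildResult, scenario: AnchoringScenario) -> float:
    """Mean within-group Kendall tau of recovered vs true scaffold order.

    For each built group, scaffolds truly belonging to it are ranked by
    their recovered offsets and compared with their true order indices.
    Groups with fewer than two such scaffolds are skipped.
    """
    taus = []
    for gid, grp in result.groups.items():
        rh_group = scenario.table.rh_group_for_output(gid)
        recovered = [
            sid
            for sid, _, _, _ in grp.placements
            if scenario.truth.scaffolds.get(sid)
            and scenario.truth.scaffolds[sid].group == rh_group
        ]
        if len(recovered) < 2:
            continue
        true_idx = [scenario.truth.scaffolds[sid].order_index for sid in recovered]
        tau, _ = stats.kendalltau(range(len(recovered)), true_idx)
        taus.append(tau)
    if not taus:
        raise ValidationError("no group with >= 2 scaffolds to score")
    return float(np.mean(taus))


# ---------------------------------------------------------------------------
# file emission


def simulate_all(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus truth tables into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    scenario = simulate_anchoring_scenario(cfg)
    paths["scaffolds"] = out / "scaffolds.fasta"
    write_fasta(scenario.scaffolds, paths["scaffolds"])
    paths["marker_hits"] = out / "marker_hits.tsv"
    write_alignment_tabular(scenario.marker_hits, paths["marker_hits"])
    paths["ref_hits"] = out / "ref_hits.tsv"
    write_alignment_tabular(scenario.scaffold_hits, paths["ref_hits"])
    paths["rh_map"] = out / "rh_map.tsv"
    write_rh_map(scenario.rh_map, paths["rh_map"])
    paths["homology_table"] = out / "homology_table.tsv"
    with open(paths["homology_table"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rh_group\tref_chromosome\n")
        for g, c in scenario.table.pairs:
            fh.write(f"{g}\t{c}\n")

    matrix, de_table, labels = simulate_expression(cfg)
    paths["counts"] = out / "counts.tsv"
    df = matrix.to_frame()
    df.columns = [f"{s}:{c}" for s, c in zip(matrix.samples, matrix.conditions)]
    df.to_csv(paths["counts"], sep="\t")
    paths["de_table"] = out / "de_table.tsv"
    write_de_table(de_table, paths["de_table"])

    annotations, spiked = simulate_go_annotations(cfg, labels)
    paths["go_annotations"] = out / "go_annotations.tsv"
    write_go_annotations(annotations, paths["go_annotations"])

    paths["truth_scaffolds"] = out / "truth_scaffolds.tsv"
    with open(paths["truth_scaffolds"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("scaffold_id\tgroup\torder_index\torientation\tn_genes\n")
        for sid in sorted(scenario.truth.scaffolds):
            st = scenario.truth.scaffolds[sid]
            fh.write(
                f"{sid}\t{st.group}\t{st.order_index}\t{st.orientation}\t{len(st.genes)}\n"
            )
    paths["truth_de"] = out / "truth_de.tsv"
    with open(paths["truth_de"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature\tlabel\n")
        for fid in sorted(labels):
            fh.write(f"{fid}\t{labels[fid] or 'none'}\n")
    paths["truth_spiked_terms"] = out / "truth_spiked_terms.txt"
    paths["truth_spiked_terms"].write_text("\n".join(spiked) + "\n", encoding="utf-8")
    return paths
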