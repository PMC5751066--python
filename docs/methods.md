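# Methods

## The anchoring model

The pipeline assumes three genomes with conserved synteny: a fragmented
study assembly (scaffolds), a relative carrying an RH marker map organised
into linkage groups, and a chromosome-level reference whose chromosomes
stand in fixed 1-to-1 homology with those linkage groups. Under that
assumption a scaffold's true chromosome can be inferred from either
evidence channel alone, and the two channels cross-validate each other.

Evidence strength is the alignment **bit score** throughout — it is
monotone in alignment quality, additive over independent hits, and
length-aware, none of which holds for e-values or percent identity.
Concretely:

- *Marker channel.* Hits are filtered at e-value strictly below `1e-10`.
  Each marker is reduced to its best hit (maximal bit score, ties broken by
  higher identity, then lexicographically smallest subject, with the hit
  coordinates as a final tie-break so the choice is a pure function of the
  hit set). The marker's bit score is added to its RH group's vote mass on
  the hit scaffold. A scaffold's RH winner is the group with maximal mass;
  a tied maximum is treated as a conflict rather than resolved arbitrarily.
- *Reference channel.* Per scaffold, bit scores are summed per reference
  chromosome; the maximal sum wins (ties to the lexicographically smallest
  label). The representative position is the subject midpoint of the single
  highest-scoring hit on the winning chromosome — a weighted mean would be
  distorted by spurious secondary hits — and that hit's strand orients the
  scaffold. A runner-up chromosome reaching 80% of the winner's mass flags
  the assignment *ambiguous* (configurable ratio); flagged scaffolds are
  still placed, because discarding them would silently lose sequence.

Reconciliation against the homology table yields five disjoint outcomes:
`placed_dual`, `placed_ref_only`, `placed_rh_only`, `conflict`, `unplaced`.
Every input scaffold lands in exactly one. Conflicts go to a side table,
never into a group. Marker-only scaffolds are placed using their smallest
supporting marker rank as the ordering key and sort after all
reference-positioned scaffolds (the reference provides base-pair
resolution; marker ranks are ordinal only); a switch excludes them
entirely.

Groups are concatenated with 100-bp N gaps (a common AGP "scaffold" gap
convention; the value is recorded in the AGP, so it is fully reversible),
reverse-complementing minus-oriented scaffolds. Output groups are named by
prefixing the RH group number with `SD`. Coordinate lift-over between
scaffold and group space is exact and bijective outside gaps; positions
landing in gaps on the inverse lift are errors, not approximations.

Transcript placement onto the finished groups demands 100% identity and an
e-value of exactly 0 (both bounds inclusive, both configurable): re-mapping
a transcriptome onto its own assembly legitimately achieves perfect hits,
and the strict default keeps one transcript from seeding multiple groups.
Each transcript is assigned uniquely by the same best-hit policy.

### Coordinate conventions

External formats (tabular alignments, AGP) are 1-based inclusive; all
internal offsets are 0-based half-open. The conversion happens only in the
format layer. Minus strand on input is encoded by reversed subject
coordinates (the 12-column dialect has no strand column) and by an explicit
orientation field internally.

## Expression stage

DE model fitting is deliberately out of scope: the stage consumes a
per-feature table (log2FC, p, padj) from whatever count model produced it.
Significance requires padj present, `padj < 0.005` and `|log2FC| > 2`, both
strict, matching the operators of the thresholds as stated; a missing padj
is never imputed and never significant. Positive log2FC means higher in the
condition designated positive (explicit in `DEConfig`, so factor ordering
can never silently flip a contrast).

QC works on `log2(count+1)` — the simplest variance-compressing transform,
configurable in principle and stated here so distances are interpretable:

- *Distances*: Euclidean between transformed sample columns.
- *Outliers*: sample *i* is flagged iff its mean distance to the others
  exceeds the grand mean of those means by more than `k = 2` sample
  standard deviations. This deterministic rule stands in for an
  unparameterised dendrogram-cut inspection; it needs ≥ 3 samples.
- *PCA*: SVD of the centered transformed matrix; variance fractions are
  non-increasing and sum to 1; a constant matrix yields zero scores with
  uniform fractions rather than an error.

## Enrichment

The two-tailed Fisher exact p uses the probability-mass method: the sum of
hypergeometric probabilities, over all tables with the observed margins, no
larger than the observed table's. With fixed margins every mass is
`C(r1,a)·C(r2,c) / C(N,n1)`, so mass comparison reduces to integer
numerator comparison. The implementation therefore works in exact integer
arithmetic — floating-point pmf comparisons can flip the inclusion of
near-tied tables, which matters because mass ties are common in small
tables. Degenerate margins give p = 1. The doubling variant is deliberately
not offered as a default; the probability-mass method is what mainstream
exact-test implementations compute.

The contingency reference side excludes the test set (`reference \ test`),
keeping the four cells disjoint; a flag restores the inclusive variant.
Terms are tested as annotated, with no GO-graph ancestor propagation, and
only terms occurring in at least one test feature are tested. BH q-values
come from `statsmodels` (step-up, capped at 1, input order preserved);
results are returned at q strictly below the threshold with direction
`over`/`under` by rate comparison.

## What the simulators emulate — and what they do not

The generators produce the study conditions at desk scale, with defaults
chosen once:

| parameter | default | why |
| --- | --- | --- |
| `n_chromosomes` × `genes_per_chromosome` | 4 × 50 | enough structure for per-group statistics while keeping every test fast |
| gene length / intergap | U(300, 800) bp / 500 bp | compact gene-dense toy chromosomes (~50 kb) |
| `scaffold_n50_target` | 2000 bp | ~2 genes per scaffold, so scaffolds outnumber gene loci as in a short-read draft |
| `translocation_rate`, `inversion_rate` | 0.02, 0.1 | occasional rearrangements between karyotypes; the homology table stays bijective by construction |
| `markers_per_group` | 10 | a sparse marker panel: most scaffolds carry 0–1 markers, as with a real RH map |
| `false_hit_rate` | 0.0 | noise is opt-in per experiment |
| expression design | 4 vs 4, 2000 features | the smallest replicated design the QC and DE stages target |
| `de_fraction`, `lfc_magnitude` | 0.05, 4.0 | a minority of strong effects |
| `nb_dispersion` | 0.1 | typical biological overdispersion |
| `go_baseline_prob`, `spike_fold` | 0.05, 6 | sparse annotations; spiked terms 6-fold enriched among true-DE features |

Scaffold cut points fall at intergenic midpoints with per-fragment targets
drawn from U(1, 1.5) × N50 target, so a target of at least the chromosome
length yields exactly one scaffold and no gene is ever split (a real
assembler would split genes; hits from partial genes are not modelled).
Sequences are i.i.d. uniform A/C/G/T: alignments are *simulated from the
known coordinates*, not computed by an aligner, so repeat structure and
sequence divergence are unmodelled. Noise enters only through
`false_hit_rate` — uniform redirection of a hit to a random subject —
which is a cruder error model than real spurious alignments (these
correlate with repeats). Passing recovery tests therefore demonstrate the
*logic* of filtering, voting, reconciliation and ordering, not robustness
to real alignment pathology.

Planted expression effects apply the fold change symmetrically — each
condition shifted by half the effect around the baseline geometric mean —
which fixes the between-condition ratio at `2^lfc` while keeping both
conditions on the expressed range; a one-sided 2⁻⁴ shift would push
low-baseline features under the shot-noise floor where no 4-sample test
could recover them, conflating generator artefacts with method behaviour.

The companion DE table uses a pooled-variance two-sample t on
`log2(count+1)` with BH adjustment. Pooling, rather than Welch, is
deliberate: after the log transform the two groups' variances are
comparable, and Welch's Satterthwaite degrees of freedom collapse toward
~3 in the strong-effect/low-count regime, which throws away most of the
meagre power a 4-vs-4 design has. This stand-in is *not* a count-model
fit: it shares no information across features and will under-call
low-count features relative to shrinkage-based methods. Sensitivity
figures on simulated data (≈0.99 at dispersion 0.01, lower at 0.1)
characterise the stand-in under generator conditions, not any published
DE tool.

Every generator draws from a dedicated RNG stream derived from
`(seed, stream-id)`, so each op is a pure function of its config and the
ops stay decoupled: changing the expression panel cannot shift the
fragmentation, and identical configs are bit-identical.

## Numerical choices and degenerate inputs

- Strict `<` for the marker e-value filter; inclusive bounds for the
  transcript filter (an equality threshold admits equality).
- All sorting tie-breaks are total orders (length, then id; label
  lexicographic), so every output is permutation-invariant.
- `p_adjusted` outside [0,1], non-tiling AGP records, non-bijective
  homology tables, mixed-group ordering requests, missing sequences and
  in-gap inverse lifts are validation errors, not warnings.
- Fisher p is clipped to 1 after exact summation; BH caps at 1.
- Outlier detection refuses n < 3; distances refuse n < 2.

## Packaged study tables

The 24-row comparative-mapping fixture (per RH group: markers mapped,
homologous reference chromosome, transcripts mapped) and the study's
printed summary totals ship inside the package so the arithmetic
consistency checks recompute, rather than assert, their relationships. One
discrepancy in the source material is preserved deliberately: the per-group
marker counts sum to 467 while the running text reports 468; the fixture
records both and resolves neither. A small companion table records known
teleost sex-determining genes located on the groups (e.g. *dmY/dmrt1a* on
SD7, *gsdf* on SD17, *sox3Y* on SD18) with their gonad DE direction.

## Known limitations

- No rearrangement-aware ordering: inversions within a group are not
  detected, and translocated scaffolds resolve by vote mass, not by
  split placement.
- Gap sizes are a fixed convention, not estimated from read pairs.
- The simulator's alignment noise is uniform, not repeat-driven.
- Enrichment treats features as opaque ids; whether they are transcripts
  or genes is the caller's concern.
- The muscle-type contrast in studies of this design sometimes states its
  thresholds ambiguously (p vs padj, |lfc| > 1 vs > 2); the defaults here
  mirror the gonad contrast and both knobs are exposed in `DEConfig`.
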