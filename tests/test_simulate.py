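"""Determinism, boundary behaviour and statistical calibration of the simulators."""

import numpy as np
import pytest
from Bio.Seq import Seq

from synanchor.formats_io import parse_alignment_tabular, write_alignment_tabular
from synanchor.simulate import (
    SimulationConfig,
    fragment_genome,
    group_accuracy,
    order_concordance,
    run_anchoring,
    simulate_alignments,
    simulate_anchoring_scenario,
    simulate_expression,
    simulate_genome_pair,
    simulate_go_annotations,
    simulate_rh_panel,
)


def _cfg(**kw):
    base = dict(seed=123)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenomePair:
    def test_no_rearrangement_limit_preserves_order(self):
        pair = simulate_genome_pair(_cfg(translocation_rate=0.0, inversion_rate=0.0))
        for (sq, ol) in pair.homology_pairs:
            assert [g for g, _ in pair.study_order[sq]] == pair.ref_order[ol]
            assert all(s == "+" for _, s in pair.study_order[sq])

    def test_same_seed_reproducible(self):
        a = simulate_genome_pair(_cfg())
        b = simulate_genome_pair(_cfg())
        assert a.study_sequences == b.study_sequences
        assert a.study_order == b.study_order

    def test_full_translocation_keeps_bijective_homology(self):
        pair = simulate_genome_pair(_cfg(translocation_rate=1.0))
        groups = [g for g, _ in pair.homology_pairs]
        chroms = [c for _, c in pair.homology_pairs]
        assert len(set(groups)) == len(set(chroms)) == pair.homology_table().pairs.__len__()
        n_genes = sum(len(v) for v in pair.study_order.values())
        assert n_genes == 4 * 50  # genes conserved, only relocated

    def test_inversion_flips_strands(self):
        pair = simulate_genome_pair(_cfg(seed=7, inversion_rate=1.0, translocation_rate=0.0))
        flipped = sum(
            s == "-" for order in pair.study_order.values() for _, s in order
        )
        assert flipped > 0


class TestFragmentation:
    def test_huge_n50_gives_one_scaffold_per_chromosome(self):
        cfg = _cfg(scaffold_n50_target=10**9)
        pair = simulate_genome_pair(cfg)
        records, truth = fragment_genome(pair, cfg)
        assert len(records) == cfg.n_chromosomes

    def test_reassembly_reconstructs_chromosomes(self):
        cfg = _cfg()
        pair = simulate_genome_pair(cfg)
        records, truth = fragment_genome(pair, cfg)
        seqs = {r.id: r.residues for r in records}
        for group, _ in pair.homology_pairs:
            pieces = sorted(
                (st for st in truth.scaffolds.values() if st.group == group),
                key=lambda st: st.order_index,
            )
            rebuilt = "".join(
                str(Seq(seqs[st.scaffold_id]).reverse_complement())
                if st.orientation == "-"
                else seqs[st.scaffold_id]
                for st in pieces
            )
            assert rebuilt == pair.study_sequences[group]

    def test_same_seed_identical_fragmentation(self):
        cfg = _cfg()
        pair = simulate_genome_pair(cfg)
        r1, t1 = fragment_genome(pair, cfg)
        r2, t2 = fragment_genome(pair, cfg)
        assert r1 == r2
        assert t1.scaffolds == t2.scaffolds

    def test_every_scaffold_has_a_truth_entry(self):
        cfg = _cfg()
        pair = simulate_genome_pair(cfg)
        records, truth = fragment_genome(pair, cfg)
        assert {r.id for r in records} == set(truth.scaffolds)


class TestAlignments:
    def test_zero_noise_hits_consistent_with_truth(self):
        cfg = _cfg(false_hit_rate=0.0, translocation_rate=0.0, inversion_rate=0.0)
        sc = simulate_anchoring_scenario(cfg)
        chrom_of = dict(sc.pair.homology_pairs)
        for hit in sc.scaffold_hits:
            true_group = sc.truth.scaffolds[hit.query_id].group
            assert hit.subject_id == chrom_of[true_group]
        gene_scaffold = {
            g: sid for sid, st in sc.truth.scaffolds.items() for g in st.genes
        }
        for hit in sc.marker_hits:
            assert hit.subject_id == gene_scaffold[hit.query_id.removeprefix("mk_")]

    def test_full_redirection_truth_rate_near_uniform(self):
        # with every hit redirected, P(correct chromosome) = 1/n_chromosomes;
        # check the empirical fraction within binomial 95% bounds
        cfg = _cfg(false_hit_rate=1.0, translocation_rate=0.0, inversion_rate=0.0)
        sc = simulate_anchoring_scenario(cfg)
        chrom_of = dict(sc.pair.homology_pairs)
        n = len(sc.scaffold_hits)
        k = sum(
            hit.subject_id == chrom_of[sc.truth.scaffolds[hit.query_id].group]
            for hit in sc.scaffold_hits
        )
        p = 1.0 / cfg.n_chromosomes
        se = (p * (1 - p) / n) ** 0.5
        assert abs(k / n - p) < 1.96 * se + 1e-9

    def test_emitted_hits_roundtrip_through_parser(self, tmp_path):
        sc = simulate_anchoring_scenario(_cfg())
        p = tmp_path / "hits.tsv"
        write_alignment_tabular(sc.scaffold_hits, p)
        assert parse_alignment_tabular(p) == sc.scaffold_hits

    def test_hits_pass_the_marker_evalue_filter(self):
        sc = simulate_anchoring_scenario(_cfg())
        assert all(h.e_value < 1e-12 for h in sc.marker_hits + sc.scaffold_hits)


class TestRHPanel:
    def test_marker_count(self):
        cfg = _cfg()
        pair = simulate_genome_pair(cfg)
        panel = simulate_rh_panel(pair, cfg)
        assert len(panel) == cfg.markers_per_group * cfg.n_chromosomes

    def test_ranks_strictly_increase_along_chromosome(self):
        cfg = _cfg()
        pair = simulate_genome_pair(cfg)
        panel = simulate_rh_panel(pair, cfg)
        for group, _ in pair.homology_pairs:
            order = [g for g, _ in pair.study_order[group]]
            pos = {g: i for i, g in enumerate(order)}
            markers = [m for m in panel if m.rh_group == group]
            chrom_positions = [pos[m.marker_id.removeprefix("mk_")] for m in markers]
            ranks = [m.position_index for m in markers]
            assert ranks == sorted(ranks)
            assert chrom_positions == sorted(chrom_positions)

    def test_same_seed_identical_panel(self):
        cfg = _cfg()
        pair = simulate_genome_pair(cfg)
        assert simulate_rh_panel(pair, cfg) == simulate_rh_panel(pair, cfg)


class TestExpressionSimulator:
    def test_no_de_limit(self):
        _, _, labels = simulate_expression(_cfg(de_fraction=0.0))
        assert all(l is None for l in labels.values())

    def test_effect_size_near_configured_ratio(self):
        # near-zero dispersion, lfc 4: mean count ratio of up_in_a features
        # should be ~16x (law of large numbers over ~2000 features)
        cfg = _cfg(nb_dispersion=1e-4, lfc_magnitude=4.0)
        m, _, labels = simulate_expression(cfg)
        idx = {f: i for i, f in enumerate(m.features)}
        a = m.counts[:, :4].mean(axis=1)
        b = m.counts[:, 4:].mean(axis=1)
        ratios = [
            a[idx[f]] / max(b[idx[f]], 1e-9)
            for f, l in labels.items()
            if l == "up_in_a"
        ]
        geo = float(np.exp(np.mean(np.log(ratios))))
        assert abs(geo - 16.0) / 16.0 < 0.2

    def test_same_seed_identical_counts(self):
        m1, _, _ = simulate_expression(_cfg())
        m2, _, _ = simulate_expression(_cfg())
        assert np.array_equal(m1.counts, m2.counts)

    def test_de_table_covers_all_features(self):
        m, de, labels = simulate_expression(_cfg())
        assert len(de) == len(m.features) == len(labels)


class TestGOSimulator:
    def test_spike_fold_one_is_null(self):
        cfg = _cfg(spike_fold=1.0)
        _, _, labels = simulate_expression(cfg)
        ann, spiked = simulate_go_annotations(cfg, labels)
        # spiked list still names terms, but their assignment law is baseline
        de = {f for f, l in labels.items() if l}
        terms_by_feature = {r.feature_id: r.terms for r in ann}
        for term in spiked:
            rate_de = np.mean([term in terms_by_feature.get(f, ()) for f in de])
            assert abs(rate_de - cfg.go_baseline_prob) < 0.05

    def test_spiked_rate_matches_fold(self):
        cfg = _cfg()
        _, _, labels = simulate_expression(cfg)
        ann, spiked = simulate_go_annotations(cfg, labels)
        de = {f for f, l in labels.items() if l}
        terms_by_feature = {r.feature_id: r.terms for r in ann}
        expected = cfg.spike_fold * cfg.go_baseline_prob
        for term in spiked:
            rate = np.mean([term in terms_by_feature.get(f, ()) for f in de])
            se = (expected * (1 - expected) / len(de)) ** 0.5
            assert abs(rate - expected) < 3 * se + 1e-9

    def test_same_seed_identical_annotations(self):
        cfg = _cfg()
        _, _, labels = simulate_expression(cfg)
        a1, _ = simulate_go_annotations(cfg, labels)
        a2, _ = simulate_go_annotations(cfg, labels)
        assert a1 == a2


class TestEndToEndRecovery:
    def test_clean_conditions_recover_everything(self, clean_scenario, clean_result):
        assert group_accuracy(clean_result, clean_scenario) == 1.0
        assert order_concordance(clean_result, clean_scenario) == 1.0

    def test_noisy_hits_keep_high_accuracy(self):
        accs = []
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, translocation_rate=0.0, inversion_rate=0.0,
                false_hit_rate=0.05,
            )
            sc = simulate_anchoring_scenario(cfg)
            accs.append(group_accuracy(run_anchoring(sc), sc))
        assert float(np.mean(accs)) >= 0.95
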