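"""Synthetic-data generator: determinism, planted structure, noise models."""

import numpy as np
import pytest

from capture_atlas.core import CANONICAL_MOTIFS, motif_of
from capture_atlas.io import read_fasta, write_fasta
from capture_atlas.simulate import (
    SimulationConfig,
    simulate_genome_and_annotation,
    simulate_gwas_inputs,
    simulate_long_reads,
    simulate_short_read_junctions,
    thin_reads,
)


def small_config(**kw):
    base = dict(seed=11, n_genes=10, include_spikeins=False, depth=4000)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_same_outputs(self):
        cfg = small_config()
        a = simulate_genome_and_annotation(cfg)
        b = simulate_genome_and_annotation(cfg)
        assert a.sequences == b.sequences
        assert [t.chain for t in a.transcripts] == [t.chain for t in b.transcripts]
        ra, rb = simulate_long_reads(a), simulate_long_reads(b)
        assert [r.exons for r in ra.reads] == [r.exons for r in rb.reads]
        assert ra.sidecar.equals(rb.sidecar)
        ja, jb = simulate_short_read_junctions(a), simulate_short_read_junctions(b)
        assert ja == jb
        ga, gb = simulate_gwas_inputs(a), simulate_gwas_inputs(b)
        assert ga.snps.equals(gb.snps) and ga.cage_peaks == gb.cage_peaks


class TestGenomeAndAnnotation:
    def test_isoform_count_conservation(self):
        cfg = small_config(isoforms_per_gene=2, min_isoforms_per_gene=2)
        exp = simulate_genome_and_annotation(cfg)
        assert len(exp.transcripts) == 20  # 10 genes x 2 isoforms

    def test_all_motifs_canonical_when_fraction_zero(self, tmp_path):
        cfg = small_config(noncanonical_fraction=0.0, n_genes=20)
        exp = simulate_genome_and_annotation(cfg)
        write_fasta(exp.sequences, str(tmp_path / "g.fa"))
        genome = read_fasta(str(tmp_path / "g.fa"))
        for t in exp.transcripts:
            for d, a in t.chain.introns:
                assert motif_of(genome, t.chrom, d, a, t.strand) in CANONICAL_MOTIFS

    def test_spike_ladder_spans_four_orders(self, default_experiment):
        conc = default_experiment.spikeins["concentration"]
        assert np.log10(conc.max() / conc.min()) >= 4.0
        assert (conc > 0).all()

    def test_mix_design_counts(self, default_experiment):
        sp = default_experiment.spikeins
        assert len(sp) == 164
        assert int(sp["captured"].sum()) == 49
        assert sp["gene_id"].nunique() == 78
        assert sp.loc[sp["captured"], "gene_id"].nunique() == 25


class TestLongReads:
    def test_noise_free_reads_equal_truth(self):
        cfg = small_config(boundary_jitter_sd=0.0, truncation_prob=0.0)
        exp = simulate_genome_and_annotation(cfg)
        reads = simulate_long_reads(exp)
        chains = {t.id: t.chain.exons for t in exp.transcripts}
        src = dict(zip(reads.sidecar["read_id"], reads.sidecar["transcript_id"]))
        for r in reads.reads:
            assert r.exons == chains[src[r.id]]

    def test_read_count_conservation(self, default_reads):
        assert len(default_reads.reads) == len(default_reads.sidecar)

    def test_enrichment_one_is_neutral(self):
        cfg = small_config(capture_enrichment=1.0)
        exp = simulate_genome_and_annotation(cfg)
        assert all(
            exp.effective_enrichment(t.id) == 1.0 for t in exp.transcripts
        )

    def test_spike_read_share_matches_fraction_without_enrichment(self):
        cfg = SimulationConfig(seed=3, capture_enrichment=1.0, depth=40000)
        exp = simulate_genome_and_annotation(cfg)
        reads = simulate_long_reads(exp)
        share = reads.sidecar["transcript_id"].str.startswith("S").mean()
        # binomial sampling error around the configured 2% mass fraction
        assert share == pytest.approx(cfg.spike_fraction, abs=0.005)

    def test_error_counts_match_configured_rates(self):
        cfg = small_config(depth=20000)
        exp = simulate_genome_and_annotation(cfg)
        sc = simulate_long_reads(exp).sidecar
        n = sc["aligned_bases"].sum()
        mm = sc["mismatches"].sum() / n
        se = np.sqrt(cfg.mismatch_rate * (1 - cfg.mismatch_rate) / n)
        assert abs(mm - cfg.mismatch_rate) < 3 * se

    def test_jitter_bounded_by_wobble(self):
        cfg = small_config(boundary_jitter_sd=5.0, junction_wobble_max=6,
                           truncation_prob=0.0)
        exp = simulate_genome_and_annotation(cfg)
        reads = simulate_long_reads(exp)
        chains = {t.id: np.array(t.chain.exons) for t in exp.transcripts}
        src = dict(zip(reads.sidecar["read_id"], reads.sidecar["transcript_id"]))
        for r in reads.reads:
            delta = np.abs(np.array(r.exons) - chains[src[r.id]])
            assert delta.max() <= 6

    def test_thinning_subsets_reads(self, default_reads):
        thin = thin_reads(default_reads, 0.5, seed=1)
        full_ids = {r.id for r in default_reads.reads}
        assert {r.id for r in thin.reads} <= full_ids
        assert 0.4 < len(thin.reads) / len(full_ids) < 0.6


class TestShortReadJunctions:
    def test_junctions_unique_and_exact(self, default_experiment,
                                        default_junctions):
        keys = [(j.chrom, j.strand, j.donor, j.acceptor)
                for j in default_junctions]
        assert len(keys) == len(set(keys))
        truth = set(default_experiment.expressed_junctions())
        assert set(keys) == truth

    def test_unexpressed_transcripts_contribute_no_junctions(self):
        cfg = small_config()
        exp = simulate_genome_and_annotation(cfg)
        victim = exp.transcripts[0].id
        exp.expression[victim] = 0.0
        keys = {(j.chrom, j.strand, j.donor, j.acceptor)
                for j in simulate_short_read_junctions(exp)}
        only_victim = set()
        for t in exp.transcripts:
            for d, a in t.chain.introns:
                k = (t.chrom, t.strand, d, a)
                if t.id == victim:
                    only_victim.add(k)
        shared = {
            k for t in exp.transcripts if t.id != victim
            for k in [(t.chrom, t.strand, d, a) for d, a in t.chain.introns]
        }
        assert not (only_victim - shared) & keys


class TestGwasInputs:
    def test_cage_fraction_one_hits_every_tss(self):
        cfg = small_config(cage_fraction=1.0, cage_background_rate=0.0)
        exp = simulate_genome_and_annotation(cfg)
        g = simulate_gwas_inputs(exp)
        from capture_atlas.evidence import tss_evidence

        flags = tss_evidence(exp.transcripts, g.cage_peaks, 500, True)
        assert flags.all()

    def test_ld_partners_within_500kb(self, default_experiment):
        g = simulate_gwas_inputs(default_experiment)
        snp_pos = dict(zip(g.snps["rsid"], g.snps["pos"]))
        for row in g.ld.itertuples(index=False):
            assert abs(row.partner_pos - snp_pos[row.rsid]) <= 500_000
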