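"""Seven-criterion filtering, class codes, novelty, feature census."""

import numpy as np
import pytest

from capture_atlas.core import CANONICAL_MOTIFS, GenomicInterval, motif_of
from capture_atlas.filters import (
    CODE_PRECEDENCE,
    FilterParams,
    AnnotationIndex,
    apply_filters,
    classify,
    classify_transcripts,
    feature_census,
    novelty_by_block,
)
from helpers import SparseGenome, plant, seven_criterion_fixture, tx


REF = tx("REF", ((1000, 1200), (2000, 2200), (3000, 3200), (4000, 4200)))
ANNOTATION = [REF]


class TestClassify:
    @pytest.mark.parametrize(
        "exons,strand,expected",
        [
            # identical intron chain, different ends -> '='
            (((950, 1200), (2000, 2200), (3000, 3200), (4000, 4300)), "+", "="),
            # contiguous intron sub-chain within the reference span -> 'c'
            (((1050, 1200), (2000, 2200), (3000, 3100)), "+", "c"),
            # shares one junction but adds its own -> 'j'
            (((1000, 1200), (2000, 2250), (2600, 2800)), "+", "j"),
            # single exon reaching >= 10 bp into a reference intron -> 'e'
            (((1100, 1250),), "+", "e"),
            # same-strand exonic overlap without shared junctions -> 'o'
            (((1100, 1300), (1500, 1700)), "+", "o"),
            # fully inside a reference intron, same strand -> 'i'
            (((1300, 1400), (1500, 1600)), "+", "i"),
            # exonic overlap on the opposite strand only -> 'x'
            (((1100, 1300), (1500, 1700)), "-", "x"),
            # identical intron chain on the opposite strand -> 's'
            (((1000, 1200), (2000, 2200), (3000, 3200), (4000, 4200)), "-", "s"),
            # no overlap, within 2 kb downstream of the 3' end -> 'p'
            (((4500, 4700), (5000, 5100)), "+", "p"),
            # no overlap at all -> 'u'
            (((50000, 50200), (51000, 51200)), "+", "u"),
        ],
    )
    def test_code_assignment(self, exons, strand, expected):
        assert classify(tx("q", exons, strand), ANNOTATION) == expected

    def test_repeat_code_requires_mask(self):
        t = tx("q", ((50000, 50200), (51000, 51200)))
        mask = [GenomicInterval("chr1", 49000, 52000)]
        assert classify(t, ANNOTATION, repeat_mask=mask) == "r"
        assert classify(t, ANNOTATION, repeat_mask=None) == "u"

    def test_unstranded_transcript_rejected(self):
        with pytest.raises(ValueError):
            classify(tx("q", ((100, 300),), "."), ANNOTATION)

    def test_every_transcript_gets_exactly_one_code(self, rng):
        chroms_ok = 0
        for i in range(50):
            start = int(rng.integers(0, 6000))
            n = int(rng.integers(1, 4))
            exons, pos = [], start
            for _ in range(n):
                ln = int(rng.integers(50, 300))
                exons.append((pos, pos + ln))
                pos += ln + int(rng.integers(50, 500))
            strand = "+" if rng.random() < 0.5 else "-"
            code = classify(tx(f"q{i}", exons, strand), ANNOTATION)
            assert code in CODE_PRECEDENCE
            chroms_ok += 1
        assert chroms_ok == 50

    def test_novelty_mapping(self):
        cls = classify_transcripts(
            [
                tx("known", ((950, 1200), (2000, 2200), (3000, 3200), (4000, 4300))),
                tx("anti", ((1100, 1300), (1500, 1700)), "-"),
                tx("inter", ((50000, 50200), (51000, 51200))),
                tx("iso", ((1000, 1200), (2000, 2250), (2600, 2800))),
            ],
            ANNOTATION,
        )
        assert [c.novelty for c in cls] == [
            "known", "novel-antisense", "novel-intergenic", "novel-isoform",
        ]


class TestApplyFilters:
    def test_seven_criterion_census(self):
        transcripts, probes, genome, annotation = seven_criterion_fixture()
        survivors, counts = apply_filters(
            transcripts, probes, genome, annotation
        )
        assert [t.id for t in survivors] == ["T_clean"]
        assert list(counts.values()) == [1, 1, 1, 1, 1, 1, 1]

    def test_membership_independent_of_criterion_order(self):
        """Each fixture transcript violates exactly its own criterion of
        (i)-(vi), so survival cannot depend on the order they are applied."""
        transcripts, probes, genome, annotation = seven_criterion_fixture()
        params = FilterParams()
        index = AnnotationIndex(annotation)
        violations = {}
        for t in transcripts:
            v = []
            if not any(
                p.chrom == t.chrom and s < p.end and p.start < e
                for p in probes for s, e in t.chain.exons
            ):
                v.append("i")
            if t.chain.n_exons < params.min_exons:
                v.append("ii")
            if any(a - d > params.max_intron for d, a in t.chain.introns):
                v.append("iii")
            if any(
                motif_of(genome, t.chrom, d, a, t.strand) not in CANONICAL_MOTIFS
                for d, a in t.chain.introns
            ):
                v.append("iv")
            if classify(t, index) in params.excluded_codes:
                v.append("v")
            if t.length < params.min_length:
                v.append("vi")
            violations[t.id] = v
        expected = {
            "T_noprobe": ["i"], "T_2exon": ["ii"], "T_bigintron": ["iii"],
            "T_noncanon": ["iv"], "T_runon": ["v"], "T_short": ["vi"],
            "T_contained": [], "T_clean": [],
        }
        assert violations == expected

    def test_intron_of_exactly_one_megabase_retained(self):
        transcripts, probes, genome, annotation = seven_criterion_fixture()
        t = tx("T_mb", ((1000, 1200), (2000, 2200), (1002200, 1002500)))
        for d, a in t.chain.introns:
            plant(genome._planted, "chr1", d, a)
        assert t.chain.introns[1][1] - t.chain.introns[1][0] == 1_000_000
        survivors, _ = apply_filters([t], probes, genome, annotation)
        assert [s.id for s in survivors] == ["T_mb"]

    def test_length_of_exactly_200nt_retained(self):
        transcripts, probes, genome, annotation = seven_criterion_fixture()
        t = tx("T_200", ((9000, 9060), (9500, 9570), (10000, 10070)))
        for d, a in t.chain.introns:
            plant(genome._planted, "chr1", d, a)
        assert t.length == 200
        survivors, _ = apply_filters([t], probes, genome, annotation)
        assert [s.id for s in survivors] == ["T_200"]

    def test_redundancy_keeps_longer_then_smaller_id(self):
        transcripts, probes, genome, annotation = seven_criterion_fixture()
        a = tx("a_same", ((1000, 1200), (2000, 2200), (3000, 3200)))
        b = tx("b_same", ((1000, 1200), (2000, 2200), (3000, 3200)))
        survivors, counts = apply_filters([b, a], probes, genome, annotation)
        assert [t.id for t in survivors] == ["a_same"]
        assert counts["vii_redundant"] == 1

    def test_missing_chromosome_raises(self):
        transcripts, probes, genome, annotation = seven_criterion_fixture()
        ghost = tx("ghost", ((100, 300), (500, 700), (900, 1200)),
                   chrom="chrZ")
        probes2 = probes + [GenomicInterval("chrZ", 0, 2000)]
        with pytest.raises(KeyError):
            apply_filters([ghost], probes2, genome, annotation)


class TestFeatureCensus:
    def test_shared_introns_deduplicated(self):
        a = tx("a", ((100, 200), (300, 400), (500, 600)))
        b = tx("b", ((90, 200), (300, 400), (500, 610)))
        n, introns, internal = feature_census([a, b])
        assert (n, introns, internal) == (2, 2, 1)

    def test_three_exon_transcript_has_one_internal_exon(self):
        t = tx("a", ((100, 200), (300, 400), (500, 600)))
        assert feature_census([t])[2] == 1


class TestNoveltyByBlock:
    def _block(self, start, end, category="exonic-overlap", bid="b1"):
        from capture_atlas.blocks import HaplotypeBlock

        return HaplotypeBlock(
            bid, GenomicInterval("chr1", start, end), ["rs1"], [],
            category=category,
        )

    def test_block_with_novel_transcript_flagged(self):
        cls = classify_transcripts(
            [tx("inter", ((50000, 50200), (51000, 51200)))], ANNOTATION
        )
        df, summary = novelty_by_block(cls, [self._block(49000, 52000)])
        assert bool(df["has_novel"].iloc[0])
        assert summary["fraction_blocks_with_novel"] == 1.0

    def test_block_with_only_known_transcripts_not_flagged(self):
        cls = classify_transcripts(
            [tx("known", ((950, 1200), (2000, 2200), (3000, 3200), (4000, 4300)))],
            ANNOTATION,
        )
        df, _ = novelty_by_block(cls, [self._block(900, 4500)])
        assert not bool(df["has_novel"].iloc[0])

    def test_planted_novel_fraction_recovered(self):
        from capture_atlas.blocks import (
            build_blocks, categorize_blocks, snp_records_from_tables,
        )
        from capture_atlas.correct import (
            collapse, correct_chains, junctions_from_annotation,
        )
        from capture_atlas.simulate import (
            SimulationConfig,
            simulate_genome_and_annotation,
            simulate_gwas_inputs,
            simulate_long_reads,
            simulate_short_read_junctions,
        )

        cfg = SimulationConfig(
            seed=17, n_genes=40, min_isoforms_per_gene=2,
            novel_isoform_fraction=0.6, captured_gene_fraction=1.0,
            include_spikeins=False, depth=12000, n_intronic_blocks=0,
            n_intergenic_blocks=0,
        )
        exp = simulate_genome_and_annotation(cfg)
        reads = simulate_long_reads(exp)
        corrected, _ = correct_chains(
            reads.reads,
            junctions_from_annotation(exp.annotation),
            simulate_short_read_junctions(exp),
        )
        models = collapse(corrected)
        cls = classify_transcripts(models, exp.annotation)
        g = simulate_gwas_inputs(exp)
        blocks = build_blocks(snp_records_from_tables(g.snps, g.ld))
        categorize_blocks(blocks, exp.annotation)
        _, summary = novelty_by_block(cls, blocks)
        recovered = summary["fraction_blocks_with_novel"]
        # binomial CI around the planted rate of 0.6 over ~40 blocks
        ci = 1.96 * np.sqrt(0.6 * 0.4 / len(blocks))
        assert abs(recovered - 0.6) <= ci + 0.05
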