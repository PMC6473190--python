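"""Spike-in diagnostics: quantifier, dose-response, enrichment, LoD, CV,
coverage uniformity, assembly evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from capture_atlas.core import ExonChain, GenomicInterval
from capture_atlas.diagnostics import (
    assign_reads,
    coverage_uniformity,
    cv_per_isoform,
    enrichment_fold,
    error_rates,
    evaluate_assembly,
    fit_dose_response,
    limit_of_detection,
    on_target_rate,
    per_base_coverage,
    rpg10k,
    tpm_matrix,
)
from helpers import tx


def spike_table(rows):
    return pd.DataFrame(
        rows, columns=["isoform_id", "gene_id", "concentration", "captured"]
    )


class TestQuantifier:
    transcripts = [
        tx("long", ((100, 200), (300, 400), (500, 600))),
        tx("skip", ((100, 200), (500, 600))),
    ]

    def test_full_length_read_is_uniquely_assigned(self):
        read = ExonChain("r", "chr1", "+", ((120, 200), (300, 400), (500, 580)))
        df, n_un = assign_reads([read], self.transcripts)
        assert n_un == 0
        assert df["transcript_id"].tolist() == ["long"]

    def test_ambiguous_read_split_equally(self):
        # single-exon read inside the shared first exon
        read = ExonChain("r", "chr1", "+", ((120, 180),))
        df, _ = assign_reads([read], self.transcripts)
        assert sorted(df["transcript_id"]) == ["long", "skip"]
        assert (df["weight"] == 0.5).all()

    def test_incompatible_read_unassigned(self):
        read = ExonChain("r", "chr1", "+", ((120, 200), (320, 400)))
        df, n_un = assign_reads([read], self.transcripts)
        assert n_un == 1 and df.empty

    def test_tpm_sums_to_one_million(self):
        reads = {
            0: [ExonChain("r0", "chr1", "+", ((120, 200), (300, 400), (500, 580)))],
            1: [ExonChain("r1", "chr1", "+", ((120, 200), (500, 580)))],
        }
        tpm = tpm_matrix(reads, self.transcripts)
        assert np.allclose(tpm.sum(axis=0), 1e6)


class TestDoseResponse:
    def _tpm(self, values):
        return pd.DataFrame({0: values, 1: values},
                            index=[f"i{k}" for k in range(len(values))])

    def _spk(self, conc, captured=True):
        return spike_table(
            [(f"i{k}", f"g{k}", c, captured) for k, c in enumerate(conc)]
        )

    def test_proportional_tpm_gives_unit_slope(self):
        conc = [1.0, 10.0, 100.0, 1000.0]
        fit = fit_dose_response(self._tpm([10 * c for c in conc]),
                                self._spk(conc), "captured")
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_tpm_gives_zero_slope(self):
        conc = [1.0, 10.0, 100.0, 1000.0]
        fit = fit_dose_response(self._tpm([7.0] * 4), self._spk(conc),
                                "captured")
        assert fit.slope == pytest.approx(0.0)

    def test_undetected_isoforms_excluded_and_reported(self):
        conc = [1.0, 10.0, 100.0]
        fit = fit_dose_response(self._tpm([0.0, 10.0, 100.0]),
                                self._spk(conc), "captured")
        assert fit.n_points == 2 and fit.undetected == ["i0"]

    def test_single_detected_point_is_an_error(self):
        with pytest.raises(ValueError):
            fit_dose_response(self._tpm([0.0, 0.0, 5.0]),
                              self._spk([1.0, 10.0, 100.0]), "captured")


class TestEnrichment:
    def test_mean_of_point_ratios(self):
        # two shared points with ratios 200 and 250
        spk = spike_table(
            [("c1", "g1", 1.0, True), ("n1", "g2", 1.0, False),
             ("c2", "g3", 10.0, True), ("n2", "g4", 10.0, False)]
        )
        tpm = pd.DataFrame(
            {0: [200.0, 1.0, 2500.0, 10.0], 1: [200.0, 1.0, 2500.0, 10.0]},
            index=["c1", "n1", "c2", "n2"],
        )
        assert enrichment_fold(tpm, spk) == pytest.approx(225.0)

    def test_identical_domains_give_unity(self):
        spk = spike_table(
            [("c1", "g1", 1.0, True), ("n1", "g2", 1.0, False)]
        )
        tpm = pd.DataFrame({0: [5.0, 5.0], 1: [5.0, 5.0]}, index=["c1", "n1"])
        assert enrichment_fold(tpm, spk) == pytest.approx(1.0)

    def test_no_shared_point_is_an_error(self):
        spk = spike_table([("c1", "g1", 1.0, True), ("n1", "g2", 2.0, False)])
        tpm = pd.DataFrame({0: [5.0, 5.0], 1: [5.0, 5.0]}, index=["c1", "n1"])
        with pytest.raises(ValueError):
            enrichment_fold(tpm, spk)


class TestLoD:
    spk = spike_table(
        [("a", "g", 0.1, False), ("b", "g", 1.0, False), ("c", "g", 10.0, False)]
    )

    def test_single_sample_detection_not_eligible(self):
        tpm = pd.DataFrame(
            {0: [1.0, 2.0, 3.0], 1: [0.0, 2.0, 3.0]}, index=["a", "b", "c"]
        )
        lod, det = limit_of_detection(tpm, self.spk)
        assert lod == pytest.approx(1.0)
        assert not det.set_index("isoform_id")["detected"]["a"]

    def test_everything_detected_gives_ladder_minimum(self):
        tpm = pd.DataFrame(
            {0: [1.0, 2.0, 3.0], 1: [1.0, 2.0, 3.0]}, index=["a", "b", "c"]
        )
        assert limit_of_detection(tpm, self.spk)[0] == pytest.approx(0.1)

    def test_nothing_detected_returns_sentinel(self):
        tpm = pd.DataFrame({0: [0.0] * 3, 1: [0.0] * 3}, index=["a", "b", "c"])
        lod, _ = limit_of_detection(tpm, self.spk)
        assert lod is None


class TestSimpleMetrics:
    def test_cv_matches_hand_computation(self):
        tpm = pd.DataFrame([[8.0, 10.0, 12.0, 10.0]], index=["i"])
        assert cv_per_isoform(tpm)["i"] == pytest.approx(0.16329, abs=1e-4)

    def test_cv_scale_invariant(self, rng):
        tpm = pd.DataFrame(rng.uniform(1, 100, size=(5, 4)))
        assert np.allclose(cv_per_isoform(tpm), cv_per_isoform(tpm * 37.5))

    def test_cv_flagged_nan_for_zero_mean(self):
        tpm = pd.DataFrame([[0.0, 0.0]], index=["i"])
        assert np.isnan(cv_per_isoform(tpm)["i"])

    def test_rpg10k_arithmetic(self):
        out = rpg10k(pd.Series({"g": 25}), total_aligned=50_000)
        assert out["g"] == pytest.approx(5.0)
        with pytest.raises(ValueError):
            rpg10k(pd.Series({"g": 25}), 0)

    def test_on_target_rate(self):
        reads = [
            ExonChain("on", "chr1", "+", ((100, 200),)),
            ExonChain("off", "chr1", "+", ((5000, 5100),)),
            ExonChain("offchrom", "chr2", "+", ((100, 200),)),
        ]
        targets = [GenomicInterval("chr1", 150, 400)]
        assert on_target_rate(reads, targets) == pytest.approx(1 / 3)

    def test_error_rate_recovery_from_sidecar(self, default_reads,
                                              default_experiment):
        mm, ind = error_rates(default_reads.sidecar)
        cfg = default_experiment.config
        n = default_reads.sidecar["aligned_bases"].sum()
        assert abs(mm - cfg.mismatch_rate) < 3 * np.sqrt(
            cfg.mismatch_rate / n
        ) + 1e-9
        assert abs(ind - cfg.indel_rate) < 3 * np.sqrt(cfg.indel_rate / n)


class TestCoverageUniformity:
    def test_flat_coverage_has_zero_cv(self):
        reads = [ExonChain("r", "chr1", "+", ((0, 100),)) for _ in range(5)]
        cov = per_base_coverage(reads, GenomicInterval("chr1", 10, 60))
        assert cov.std() == 0

    def test_identical_platforms_give_p_one(self):
        cov = {f"e{i}": np.arange(1, 20 + i) for i in range(4)}
        _, t, p = coverage_uniformity({"ONT": cov, "Illumina": dict(cov)})
        assert (t, p) == (0.0, 1.0)

    def test_planted_difference_detected(self, rng):
        n_exons, length = 100, 60
        ont, ill = {}, {}
        for i in range(n_exons):
            base = rng.poisson(50, length) + 1
            ont[f"e{i}"] = base
            ill[f"e{i}"] = base * (1 + rng.uniform(0, 2, length))
        df, t, p = coverage_uniformity({"ONT": ont, "Illumina": ill})
        assert p < 0.01
        assert df["ONT"].median() < df["Illumina"].median()


class TestEvaluateAssembly:
    truth = [
        tx("t1", ((100, 200), (300, 400), (500, 600)), gene="gA"),
        tx("t2", ((1000, 1100), (1300, 1400)), gene="gB"),
    ]

    def test_perfect_prediction_scores_one(self):
        ev = evaluate_assembly([t.chain for t in self.truth], self.truth)
        assert (ev["sensitivity"] == 1.0).all()
        assert (ev["precision"] == 1.0).all()

    def test_empty_prediction_reports_zero_precision_flagged(self):
        ev = evaluate_assembly([], self.truth)
        assert (ev["sensitivity"] == 0.0).all()
        assert (ev["precision"] == 0.0).all()
        assert not ev["precision_defined"].any()

    def test_shifted_junctions_kill_intron_level_only(self):
        shifted = [
            ExonChain("p1", "chr1", "+", ((100, 201), (301, 400), (500, 600)))
        ]
        ev = evaluate_assembly(shifted, self.truth)
        assert ev.loc["intron", "sensitivity"] < 0.5
        assert ev.loc["base", "sensitivity"] > 0.4
        assert ev.loc["base", "precision"] > 0.99
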