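"""DETE/DEG calling, class attribution, chi-square composition test,
genomic-feature annotation."""

import math

import numpy as np
import pandas as pd
import pytest

from teescape.core import GeneModel, GenomicInterval, TeescapeError
from teescape.dete import (
    ClassBreakdown,
    SignificanceConfig,
    annotate_features,
    call_significant,
    class_breakdown,
    class_composition_test,
    classify_te_class,
    dete_loci_from_annotation,
)
from teescape.io import DEResultTable

from oracles import annotate_bruteforce


def _table(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "feature_kind", "base_mean",
                                     "log2fc", "pvalue", "padj"])
    return DEResultTable(condition_label="X", data=df)


class TestCallSignificant:
    def test_threshold_count(self):
        rows = [
            (f"t{i}:F:LINE", "te", 10, 1.0, p, p)
            for i, p in enumerate([0.01, 0.04, 0.06, 0.5])
        ]
        sig = call_significant(_table(rows))
        assert len(sig.dete_ids) == 2

    def test_nothing_significant_when_all_p_one(self):
        rows = [("g1", "gene", 1, 1.0, 1.0, 1.0), ("t:F:LTR", "te", 1, -1.0, 1.0, 1.0)]
        sig = call_significant(_table(rows))
        assert sig.counts()["degs"] == 0 and sig.counts()["detes"] == 0

    def test_zero_lfc_rows_counted_but_undirected(self):
        rows = [("g1", "gene", 1, 0.0, 0.001, 0.01)]
        sig = call_significant(_table(rows))
        assert sig.n_zero_lfc == 1
        assert sig.deg_ids == []

    def test_adjusted_mode_uses_padj(self):
        rows = [("g1", "gene", 1, 1.0, 0.001, 0.2), ("g2", "gene", 1, 1.0, 0.001, 0.05)]
        sig = call_significant(
            _table(rows), SignificanceConfig(use_adjusted=True, fdr_threshold=0.1)
        )
        assert sig.deg_ids == ["g2"]

    @pytest.mark.parametrize("a1, a2", [(0.01, 0.05), (0.001, 0.2), (0.05, 0.05)])
    def test_monotone_in_threshold(self, default_cohort, a1, a2):
        table = default_cohort.tables["NFD"]
        s1 = set(call_significant(table, SignificanceConfig(p_threshold=a1)).dete_ids)
        s2 = set(call_significant(table, SignificanceConfig(p_threshold=a2)).dete_ids)
        assert s1 <= s2

    def test_recovery_on_planted_cohort(self, default_cohort):
        """Recovered DETE count ~= power * planted + alpha * nulls."""
        cfg = default_cohort.config
        table = default_cohort.tables["VPR"]
        truth = default_cohort.truth
        n_planted = len(truth.true_dete_up["VPR"]) + len(truth.true_dete_down["VPR"])
        n_null = cfg.n_tes - n_planted
        expected = cfg.detection_power * n_planted + cfg.detection_alpha * n_null
        var = (
            n_planted * cfg.detection_power * (1 - cfg.detection_power)
            + n_null * cfg.detection_alpha * (1 - cfg.detection_alpha)
        )
        observed = call_significant(table).counts()["detes"]
        assert abs(observed - expected) <= 3 * math.sqrt(var)


class TestClassifyTEClass:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("LINE", "non-LTR"),
            ("SINE", "non-LTR"),
            ("LTR", "LTR"),
            ("DNA", "DNA"),
            ("DNA/hAT-Charlie", "DNA"),
            ("LINE?", "non-LTR"),
            ("Satellite", "other"),
            ("Simple_repeat", "other"),
            ("Unknown", "other"),
        ],
    )
    def test_mapping(self, raw, expected):
        assert classify_te_class(raw) == expected


class TestClassBreakdown:
    def test_share_arithmetic(self):
        rows = (
            [(f"a{i}:F:LTR", "te", 1, 1.0, 0.01, 0.01) for i in range(5)]
            + [(f"b{i}:F:LINE", "te", 1, 1.0, 0.01, 0.01) for i in range(3)]
            + [(f"c{i}:F:DNA", "te", 1, -1.0, 0.01, 0.01) for i in range(2)]
        )
        sig = call_significant(_table(rows))
        bd = class_breakdown(sig.detes)
        assert bd.counts == {"LTR": 5, "non-LTR": 3, "DNA": 2, "other": 0}
        assert bd.shares()["non-LTR"] == pytest.approx(0.30)
        assert bd.by_direction["down"]["DNA"] == 2

    def test_empty_breakdown_has_undefined_shares(self):
        bd = class_breakdown(_table([("g", "gene", 1, 1, 0.9, 0.9)]).tes.assign(direction="up"))
        assert bd.total == 0
        assert all(v is None for v in bd.shares().values())

    def test_breakdown_recovers_planted_mix(self):
        """Uniform perturbation over the universe yields the universe mix."""
        from teescape.simulate import SimulationConfig, generate_cohort

        mix = {"LTR": 0.5, "non-LTR": 0.3, "DNA": 0.2}
        cfg = SimulationConfig(
            seed=21, n_tes=1000, n_genes=300, immune_set_size=20,
            condition_class_props={},  # fall back to the universe mix
            te_class_mix=mix,
        )
        cohort = generate_cohort(cfg)
        sig = call_significant(cohort.tables["VPR"])
        bd = class_breakdown(sig.detes, cohort.te_features)
        n = bd.total
        for klass, frac in mix.items():
            sd = math.sqrt(n * frac * (1 - frac))
            assert abs(bd.counts[klass] - n * frac) <= 3 * sd


class TestClassCompositionTest:
    @staticmethod
    def _bd(ltr, nonltr, dna, other=0):
        counts = {"LTR": ltr, "non-LTR": nonltr, "DNA": dna, "other": other}
        return ClassBreakdown(counts=counts, by_direction={"up": counts, "down": {}})

    def test_perfect_fit(self):
        res = class_composition_test(self._bd(10, 10, 10), self._bd(7, 7, 7))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_at_two_degrees_of_freedom(self):
        # chi2 = 20 at df 2: survival p = exp(-chi2/2) = exp(-10)
        res = class_composition_test(self._bd(20, 10, 0), self._bd(10, 10, 10))
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 2
        assert res.p == pytest.approx(math.exp(-10), rel=1e-9)

    def test_all_zero_reference_rejected(self):
        with pytest.raises(TeescapeError):
            class_composition_test(self._bd(1, 1, 1), self._bd(0, 0, 0))

    def test_detects_planted_nonltr_excess(self, default_cohort):
        sig_v = call_significant(default_cohort.tables["VPR"])
        sig_w = call_significant(default_cohort.tables["WT"])
        bd_v = class_breakdown(sig_v.detes, default_cohort.te_features)
        bd_w = class_breakdown(sig_w.detes, default_cohort.te_features)
        res = class_composition_test(bd_v, bd_w)
        assert res.p < 0.01
        assert bd_v.shares()["non-LTR"] > bd_w.shares()["non-LTR"]


class TestAnnotateFeatures:
    def _gene(self, gid, chrom, start, end, strand="+"):
        body = GenomicInterval(chrom, start, end, strand)
        return GeneModel(gid, gid, body, start if strand == "+" else end)

    def test_precedence_intron_over_enhancer(self):
        gene = self._gene("g", "chr1", 10_000, 40_000)
        enh = [GenomicInterval("chr1", 20_000, 25_000)]
        loci = [("te1", GenomicInterval("chr1", 21_000, 22_000))]
        fb = annotate_features(loci, [gene], enh, promoter_window=1000)
        assert fb.counts["intron"] == 1

    def test_promoter_beats_everything(self):
        gene = self._gene("g", "chr1", 10_000, 40_000)
        enh = [GenomicInterval("chr1", 9_000, 11_000)]
        loci = [("te1", GenomicInterval("chr1", 9_500, 10_500))]
        fb = annotate_features(loci, [gene], enh, promoter_window=1000)
        assert fb.counts["promoter"] == 1

    def test_exons_take_precedence_over_intron_when_given(self):
        gene = self._gene("g", "chr1", 10_000, 40_000)
        exons = [GenomicInterval("chr1", 15_000, 16_000)]
        loci = [("te1", GenomicInterval("chr1", 15_200, 15_400))]
        fb = annotate_features(loci, [gene], [], promoter_window=1000, exons=exons)
        assert fb.counts["exon"] == 1

    def test_duplicate_loci_counted_once(self):
        iv = GenomicInterval("chr1", 500_000, 501_000)
        fb = annotate_features([("a", iv), ("b", iv)], [], [])
        assert fb.total == 1
        assert fb.counts["intergenic"] == 1

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(42)
        genes = [
            self._gene(f"g{i}", "chr1", s, s + int(rng.integers(5_000, 20_000)))
            for i, s in enumerate(sorted(rng.choice(2_000_000, 30, replace=False)))
        ]
        enh = [
            GenomicInterval("chr1", int(s), int(s) + 2_000)
            for s in rng.choice(2_000_000, 20, replace=False)
        ]
        loci = [
            (f"te{i}", GenomicInterval("chr1", int(s), int(s) + int(rng.integers(200, 3_000))))
            for i, s in enumerate(rng.choice(2_000_000, 100, replace=False))
        ]
        fb = annotate_features(loci, genes, enh, promoter_window=1000)
        expected = annotate_bruteforce(loci, genes, enh, promoter_window=1000)
        got = {iv.as_key(): label for _, iv, label in fb.assignments}
        assert got == expected

    def test_planted_locus_features_recovered(self, default_cohort):
        """Generator truth labels match the annotation stage exactly."""
        truth_by_key = {
            (r["chrom"], r["start"], r["end"]): r["label"]
            for r in default_cohort.truth.te_locus_feature
        }
        loci = dete_loci_from_annotation(
            [t.te_id for t in default_cohort.te_features], default_cohort.te_features
        )
        fb = annotate_features(
            loci, default_cohort.gene_models, default_cohort.enhancers,
            promoter_window=default_cohort.config.promoter_window,
        )
        mismatches = [
            (iv, label, truth_by_key[iv.as_key()])
            for _, iv, label in fb.assignments
            if truth_by_key[iv.as_key()] != label
        ]
        assert not mismatches
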