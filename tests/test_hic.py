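"""Hi-C proximity: FDR DETE selection, contact-anchored gene joins,
DEG intersection."""

import math

import numpy as np
import pandas as pd
import pytest

from teescape.core import ContactPair, GeneModel, GenomicInterval, TeescapeError
from teescape.dete import call_significant, dete_loci_from_annotation
from teescape.hic import (
    ProximityConfig,
    find_proximal_genes,
    intersect_with_degs,
    select_hic_detes,
)
from teescape.io import DEResultTable

from oracles import proximal_genes_bruteforce


def _de_table(te_pvals, gene_pvals=()):
    rows = [
        (f"te{i}:F:LINE", "te", 1.0, 1.0, p, np.nan) for i, p in enumerate(te_pvals)
    ] + [(f"g{i}", "gene", 1.0, 1.0, p, np.nan) for i, p in enumerate(gene_pvals)]
    df = pd.DataFrame(rows, columns=["feature_id", "feature_kind", "base_mean",
                                     "log2fc", "pvalue", "padj"])
    return DEResultTable(condition_label="VPR", data=df)


class TestSelectHicDetes:
    def test_hand_computed_bh_selection(self):
        """BH over {0.001, 0.002, 0.5, 0.9} gives {0.004, 0.004, 0.667, 0.9}."""
        table = _de_table([0.001, 0.002, 0.5, 0.9])
        selected = select_hic_detes(table, ProximityConfig(dete_fdr=0.1))
        assert selected == ["te0:F:LINE", "te1:F:LINE"]

    def test_all_null_pvalues_select_nothing(self):
        assert select_hic_detes(_de_table([1.0, 1.0, 1.0])) == []

    def test_monotone_in_fdr_cutoff(self):
        rng = np.random.default_rng(0)
        table = _de_table(np.concatenate([rng.random(50), rng.random(20) * 1e-3]))
        prev: set = set()
        for fdr in (0.01, 0.05, 0.1, 0.3):
            cur = set(select_hic_detes(table, ProximityConfig(dete_fdr=fdr)))
            assert prev <= cur
            prev = cur

    def test_no_te_rows_is_an_error(self):
        with pytest.raises(TeescapeError):
            select_hic_detes(_de_table([], gene_pvals=[0.5, 0.1]))


def _gene(gid, chrom, start, end):
    return GeneModel(gid, gid, GenomicInterval(chrom, start, end), start)


class TestFindProximalGenes:
    def _basic(self):
        dete_loci = [("te1", GenomicInterval("chr1", 101_000, 103_000))]
        contact = ContactPair(
            GenomicInterval("chr1", 100_000, 105_000),
            GenomicInterval("chr1", 300_000, 305_000),
        )
        return dete_loci, [contact]

    def test_gene_within_cutoff_included(self):
        dete_loci, contacts = self._basic()
        genes = [_gene("near", "chr1", 310_000, 320_000)]
        res = find_proximal_genes(dete_loci, contacts, genes, ProximityConfig(cell_type=None))
        assert res.dete_proximal_genes == {"near"}
        assert res.best_distance("near") == 5_000

    def test_gene_beyond_cutoff_excluded(self):
        dete_loci, contacts = self._basic()
        genes = [_gene("far", "chr1", 330_000, 340_000)]
        res = find_proximal_genes(dete_loci, contacts, genes, ProximityConfig(cell_type=None))
        assert res.dete_proximal_genes == set()

    def test_distal_rule_ignores_genes_at_the_dete_anchor(self):
        dete_loci, contacts = self._basic()
        genes = [_gene("self", "chr1", 106_000, 110_000)]
        distal = find_proximal_genes(
            dete_loci, contacts, genes, ProximityConfig(cell_type=None)
        )
        either = find_proximal_genes(
            dete_loci, contacts, genes,
            ProximityConfig(cell_type=None, anchor_rule="either_anchor"),
        )
        assert distal.dete_proximal_genes == set()
        assert either.dete_proximal_genes == {"self"}

    def test_chromosome_naming_mismatch_is_hard_error(self):
        dete_loci, contacts = self._basic()
        genes = [_gene("g", "1", 310_000, 320_000)]  # bare Ensembl-style name
        with pytest.raises(TeescapeError, match="chromosome"):
            find_proximal_genes(dete_loci, contacts, genes, ProximityConfig(cell_type=None))

    def test_cell_type_filter_applied(self):
        dete_loci, _ = self._basic()
        genes = [_gene("near", "chr1", 310_000, 320_000)]
        contacts = [
            ContactPair(
                GenomicInterval("chr1", 100_000, 105_000),
                GenomicInterval("chr1", 300_000, 305_000),
                cell_type=ct,
            )
            for ct in ("excitatory", "inhibitory")
        ]
        res = find_proximal_genes(dete_loci, contacts, genes, ProximityConfig())
        assert res.n_contacts_used == 1
        assert res.dete_proximal_genes == {"near"}

    @pytest.mark.parametrize("rule", ["distal_anchor", "either_anchor"])
    def test_matches_bruteforce_triple_loop(self, rule):
        rng = np.random.default_rng(11)
        genes = [
            _gene(f"g{i}", "chr1", s, s + int(rng.integers(2_000, 15_000)))
            for i, s in enumerate(sorted(rng.choice(3_000_000, 60, replace=False)))
        ]
        dete_loci = [
            (f"te{i}", GenomicInterval("chr1", int(s), int(s) + int(rng.integers(300, 4_000))))
            for i, s in enumerate(rng.choice(3_000_000, 40, replace=False))
        ]
        contacts = []
        for _ in range(200):
            a, b = (int(x) for x in rng.choice(3_000_000, 2))
            contacts.append(
                ContactPair(
                    GenomicInterval("chr1", a, a + 5_000),
                    GenomicInterval("chr1", b, b + 5_000),
                    cell_type=("excitatory" if rng.random() < 0.7 else "other"),
                )
            )
        cfg = ProximityConfig(anchor_rule=rule)
        res = find_proximal_genes(dete_loci, contacts, genes, cfg)
        expected = proximal_genes_bruteforce(
            dete_loci, contacts, genes, cfg.max_distance, rule, cfg.cell_type
        )
        assert res.dete_proximal_genes == set(expected)
        for gid, d in expected.items():
            assert res.best_distance(gid) == d

    def test_either_anchor_superset_of_distal(self, default_cohort):
        table = default_cohort.tables["VPR"]
        ids = select_hic_detes(table, ProximityConfig())
        loci = dete_loci_from_annotation(ids, default_cohort.te_features)
        distal = find_proximal_genes(
            loci, default_cohort.contacts, default_cohort.gene_models, ProximityConfig()
        )
        either = find_proximal_genes(
            loci, default_cohort.contacts, default_cohort.gene_models,
            ProximityConfig(anchor_rule="either_anchor"),
        )
        assert distal.dete_proximal_genes <= either.dete_proximal_genes

    def test_monotone_in_max_distance(self, default_cohort):
        table = default_cohort.tables["VPR"]
        ids = select_hic_detes(table, ProximityConfig())
        loci = dete_loci_from_annotation(ids, default_cohort.te_features)
        prev: set = set()
        for dist in (0, 5_000, 20_000, 50_000):
            cur = find_proximal_genes(
                loci, default_cohort.contacts, default_cohort.gene_models,
                ProximityConfig(max_distance=dist),
            ).dete_proximal_genes
            assert prev <= cur
            prev = cur


class TestIntersectWithDEGs:
    def _proximity(self, gene_ids):
        from teescape.hic import ProximityResult, SupportingContact

        contact = ContactPair(
            GenomicInterval("chr1", 0, 1_000), GenomicInterval("chr1", 5_000, 6_000)
        )
        supporting = {
            g: [SupportingContact("te", contact, 100.0, contact.anchor_b)]
            for g in gene_ids
        }
        return ProximityResult(set(gene_ids), supporting, ProximityConfig(), 1)

    def _degs(self, spec):
        rows = [
            {"feature_id": gid, "feature_kind": "gene", "base_mean": 1.0,
             "log2fc": lfc, "pvalue": 0.01, "padj": 0.05,
             "direction": "up" if lfc > 0 else "down"}
            for gid, lfc in spec
        ]
        return pd.DataFrame(rows)

    def test_fraction_down_arithmetic(self):
        prox = self._proximity(["a", "b", "c", "d"])
        degs = self._degs([("a", -1.0), ("b", -2.0), ("c", 1.0), ("x", -5.0)])
        inter = intersect_with_degs(prox, degs)
        assert inter.fraction_down == pytest.approx(2 / 3)
        assert set(inter.degs["gene_id"]) == {"a", "b", "c"}

    def test_empty_intersection_gives_undefined_fraction(self):
        inter = intersect_with_degs(self._proximity(["a"]), self._degs([("z", -1.0)]))
        assert inter.fraction_down is None

    def test_planted_down_fraction_recovered(self, default_cohort):
        cfg_sim = default_cohort.config
        table = default_cohort.tables["VPR"]
        ids = select_hic_detes(table, ProximityConfig())
        loci = dete_loci_from_annotation(ids, default_cohort.te_features)
        prox = find_proximal_genes(
            loci, default_cohort.contacts, default_cohort.gene_models, ProximityConfig()
        )
        sig = call_significant(table)
        inter = intersect_with_degs(prox, sig.degs)
        n = inter.counts()["up"] + inter.counts()["down"]
        sd = math.sqrt(cfg_sim.planted_down_frac * (1 - cfg_sim.planted_down_frac) / n)
        assert abs(inter.fraction_down - cfg_sim.planted_down_frac) <= 3 * sd
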