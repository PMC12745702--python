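"""Seed-deterministic synthetic cohorts with planted ground truth.

The generator emulates the downstream-facing shape of a TE-derepression
study: three graded perturbation conditions (WT-like, NFD-like, VPR-like
relative to a GFP control) with increasing numbers of upregulated TE
subfamilies, a LTR / non-LTR / DNA class mixture whose upregulated portion
shifts toward non-LTR elements in the stronger conditions, TE loci placed
in introns, distal-enhancer blocks, or intergenic space, Hi-C-style contact
pairs preferentially linking a planted immune gene set to upregulated TE
loci within cis-regulatory distance, and downregulation of those TE-proximal
immune genes.

Effects are planted directly on the summary statistics (log2 fold change and
p-value) that the downstream stages consume; count-level modeling and model
fitting are upstream of this pipeline. Null features carry uniform p-values
and Normal(0, noise_sd) log2 fold changes; perturbed TEs carry Beta(a, 1)
p-values with a chosen so that P(p < alpha) equals the configured detection
power, and |log2fc| from a shifted exponential with the configured mean.
Gene-level statistics arise from a latent-effect z-score model so that
p-values and fold changes stay mutually consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ConfigError,
    ContactPair,
    GeneModel,
    GeneSetCollection,
    GenomicInterval,
    TEFeature,
)
from .enrichment import bh_fdr
from .io import (
    DEResultTable,
    sha256_file,
    write_contacts,
    write_de_table,
    write_gene_models,
    write_gmt,
    write_intervals_bed,
    write_json,
    write_te_annotation,
)

CANONICAL = ("LTR", "non-LTR", "DNA")

#: RepeatMasker-style (family, class) labels drawn per collapsed class.
RAW_LABELS = {
    "LTR": (("ERVK", "LTR"), ("ERVL", "LTR"), ("ERV1", "LTR")),
    "non-LTR": (("L1", "LINE"), ("B2", "SINE"), ("Alu", "SINE")),
    "DNA": (("hAT-Charlie", "DNA"), ("TcMar-Tigger", "DNA")),
}

IMMUNE_SET_NAME = "leukocyte activation involved in immune response"


@dataclass(frozen=True)
class ConditionEffect:
    """Per-condition TE perturbation: fractions of the TE universe pushed up
    and down, and the mean |log2fc| of perturbed features."""

    frac_te_up: float
    frac_te_down: float
    mean_abs_log2fc: float

    def __post_init__(self):
        if not (0 <= self.frac_te_up <= 1 and 0 <= self.frac_te_down <= 1):
            raise ConfigError("TE fractions must lie in [0, 1]")
        if self.frac_te_up + self.frac_te_down > 1:
            raise ConfigError("frac_te_up + frac_te_down must not exceed 1")
        if self.mean_abs_log2fc <= 0:
            raise ConfigError("mean_abs_log2fc must be positive")


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    The defaults mirror the graded three-condition structure the pipeline is
    designed for: perturbed-TE fractions 0.04 / 0.17 / 0.34 of a 1,500-
    subfamily universe (about 60 / 255 / 510 planted DETEs), a class mixture
    of half LTR / 30% non-LTR / 20% DNA with the upregulated portion shifting
    toward non-LTR in the stronger conditions (13% -> 26% -> 33%), and 71%
    of the planted TE-proximal immune genes downregulated.
    """

    seed: int = 0
    n_genes: int = 2000
    n_tes: int = 1500
    te_class_mix: dict = field(
        default_factory=lambda: {"LTR": 0.5, "non-LTR": 0.3, "DNA": 0.2}
    )
    condition_effect_sizes: dict = field(
        default_factory=lambda: {
            "WT": ConditionEffect(0.04, 0.01, 1.5),
            "NFD": ConditionEffect(0.17, 0.01, 2.0),
            "VPR": ConditionEffect(0.34, 0.02, 2.5),
        }
    )
    # Class proportions of the *planted upregulated* TE draw, per condition.
    # Chosen by inverting the null-false-positive dilution so that the
    # REALIZED class mixture of called DETEs (planted hits at the detection
    # power plus ~alpha of the nulls, which arrive at the universe mix)
    # reproduces the graded non-LTR expansion across conditions
    # (~0.20 / 0.26 / 0.33 realized non-LTR share); see docs/methods.md.
    condition_class_props: dict = field(
        default_factory=lambda: {
            "WT": {"LTR": 0.70, "non-LTR": 0.05, "DNA": 0.25},
            "NFD": {"LTR": 0.553, "non-LTR": 0.247, "DNA": 0.20},
            "VPR": {"LTR": 0.50, "non-LTR": 0.335, "DNA": 0.165},
        }
    )
    # shared latent gene program scaled per condition (drives RRHO concordance)
    gene_program_frac: float = 0.15
    program_effect_sd: float = 1.2
    condition_gene_scale: dict = field(
        default_factory=lambda: {"WT": 0.15, "NFD": 0.6, "VPR": 1.0}
    )
    # Latent downshift applied to every immune gene, scaled per condition:
    # with noise_sd 0.3 the implied z-shifts are -0.75 / -3 / -5 for the
    # WT / NFD / VPR scales, i.e. non-significant, moderate-but-significant,
    # and strongest immune downregulation respectively.
    immune_set_size: int = 100
    immune_mild_effect: float = 1.5
    planted_proximal_frac: float = 0.7
    planted_down_frac: float = 0.71
    noise_sd: float = 0.3
    n_contacts_background: int = 300
    genome: tuple = (("chr1", 50_000_000), ("chr2", 50_000_000))
    te_feature_mix: dict = field(
        default_factory=lambda: {
            "intron": 0.45,
            "distal_enhancer": 0.35,
            "intergenic": 0.20,
        }
    )
    detection_power: float = 0.9
    detection_alpha: float = 0.05
    lfc_shift: float = 0.5
    promoter_window: int = 1000
    hic_condition: str = "VPR"
    contact_anchor_width: int = 5000
    cell_type_mix: dict = field(
        default_factory=lambda: {
            "excitatory": 0.6,
            "inhibitory": 0.25,
            "astrocyte": 0.15,
        }
    )
    n_decoy_sets: int = 20
    reference_label: str = "GFP"

    def validate(self) -> None:
        if self.n_genes < 10 or self.n_tes < 4:
            raise ConfigError("n_genes/n_tes too small to build a cohort")
        if abs(sum(self.te_class_mix.values()) - 1) > 1e-9:
            raise ConfigError("te_class_mix must sum to 1")
        if set(self.te_class_mix) != set(CANONICAL):
            raise ConfigError(f"te_class_mix must cover exactly {CANONICAL}")
        for frac in (self.planted_proximal_frac, self.planted_down_frac,
                     self.gene_program_frac):
            if not (0 <= frac <= 1):
                raise ConfigError("fractions must lie in [0, 1]")
        if self.immune_set_size > self.n_genes:
            raise ConfigError("immune_set_size exceeds n_genes")
        if self.hic_condition not in self.condition_effect_sizes:
            raise ConfigError(
                f"hic_condition {self.hic_condition!r} has no effect sizes"
            )
        for label, eff in self.condition_effect_sizes.items():
            if not isinstance(eff, ConditionEffect):
                raise ConfigError(f"effect sizes for {label} must be ConditionEffect")
        if not (0 < self.detection_alpha < 1 and 0 < self.detection_power < 1):
            raise ConfigError("detection power/alpha must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.n_contacts_background < 0:
            raise ConfigError("n_contacts_background must be >= 0")

    @property
    def beta_a(self) -> float:
        """Beta(a, 1) shape with P(p < alpha) = power: a = ln(power)/ln(alpha)."""
        return math.log(self.detection_power) / math.log(self.detection_alpha)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        raw = dict(raw)
        if "condition_effect_sizes" in raw:
            raw["condition_effect_sizes"] = {
                k: v if isinstance(v, ConditionEffect) else ConditionEffect(**v)
                for k, v in raw["condition_effect_sizes"].items()
            }
        if "genome" in raw:
            raw["genome"] = tuple((c, int(n)) for c, n in raw["genome"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted truth for recovery-based testing."""

    true_dete_up: dict  # condition -> list of te ids
    true_dete_down: dict
    te_class: dict  # te id -> collapsed class
    te_locus_feature: list  # dicts: te_id, chrom, start, end, label
    immune_genes: list
    program_genes: list
    planted_proximal_genes: list
    planted_down_genes: list
    planted_up_genes: list

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, raw: Mapping) -> "GroundTruth":
        return cls(**raw)


@dataclass
class Cohort:
    config: SimulationConfig
    tables: dict  # condition label -> DEResultTable
    te_features: list
    gene_models: list
    enhancers: list
    contacts: list
    gene_sets: GeneSetCollection
    truth: GroundTruth


# ---------------------------------------------------------------------------
# genome layout


def _layout_genome(cfg: SimulationConfig, rng: np.random.Generator):
    """Place non-overlapping genes along the chromosomes, carve enhancer
    blocks into half of the intergenic gaps, and remember placement windows
    for intronic / enhancer / deep-intergenic TE loci."""
    genes: list[GeneModel] = []
    enhancers: list[GenomicInterval] = []
    intron_windows: list[tuple[str, int, int]] = []
    intergenic_windows: list[tuple[str, int, int]] = []

    chrom_idx = 0
    chrom, clen = cfg.genome[chrom_idx]
    cursor = 20_000
    for i in range(cfg.n_genes):
        glen = int(rng.integers(8_000, 30_000))
        gap = int(rng.integers(8_000, 25_000))
        if cursor + glen + gap + 20_000 > clen:
            chrom_idx += 1
            if chrom_idx >= len(cfg.genome):
                raise ConfigError(
                    f"genome too small for {cfg.n_genes} genes; "
                    f"placed {len(genes)} before running out"
                )
            chrom, clen = cfg.genome[chrom_idx]
            cursor = 20_000
        strand = "+" if rng.random() < 0.5 else "-"
        body = GenomicInterval(chrom, cursor, cursor + glen, strand)
        tss = body.start if strand == "+" else body.end
        gid = f"G{i:05d}"
        genes.append(GeneModel(gid, gid, body, tss))
        # intron placement window: body minus the promoter-side margin
        w = cfg.promoter_window
        if strand == "+":
            win = (chrom, body.start + w, body.end)
        else:
            win = (chrom, body.start, body.end - w)
        if win[2] - win[1] > 1_000:
            intron_windows.append(win)
        # gap after the gene: enhancer block or deep intergenic slot
        gap_start, gap_end = body.end + 2_000, body.end + gap - 2_000
        if gap_end - gap_start > 2_000:
            if rng.random() < 0.5:
                ew = int(rng.integers(1_500, 4_000))
                if gap_end - gap_start > ew:
                    es = int(rng.integers(gap_start, gap_end - ew))
                    enhancers.append(GenomicInterval(chrom, es, es + ew))
            else:
                intergenic_windows.append((chrom, gap_start, gap_end))
        cursor = body.end + gap
    return genes, enhancers, intron_windows, intergenic_windows


def _place_te_loci(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    classes: np.ndarray,
    enhancers: list,
    intron_windows: list,
    intergenic_windows: list,
):
    """Assign each TE subfamily 1-2 loci inside intron / enhancer /
    intergenic containers according to the feature mix."""
    feat_labels = list(cfg.te_feature_mix)
    feat_probs = np.array([cfg.te_feature_mix[f] for f in feat_labels], dtype=float)
    feat_probs = feat_probs / feat_probs.sum()

    te_features: list[TEFeature] = []
    locus_truth: list[dict] = []
    raw_cycle: dict[str, int] = {}
    for i, klass in enumerate(classes):
        options = RAW_LABELS[klass]
        j = raw_cycle.get(klass, 0)
        family, raw_class = options[j % len(options)]
        raw_cycle[klass] = j + 1
        name = f"TE{i:04d}"
        n_loci = 2 if rng.random() < 0.15 else 1
        loci = []
        for _ in range(n_loci):
            label = feat_labels[int(rng.choice(len(feat_labels), p=feat_probs))]
            te_len = int(rng.integers(300, 6_000))
            if label == "intron" and intron_windows:
                chrom, ws, we = intron_windows[int(rng.integers(len(intron_windows)))]
            elif label == "distal_enhancer" and enhancers:
                e = enhancers[int(rng.integers(len(enhancers)))]
                chrom, ws, we = e.chrom, e.start, e.end
            elif intergenic_windows:
                label = "intergenic"
                chrom, ws, we = intergenic_windows[int(rng.integers(len(intergenic_windows)))]
            else:
                continue
            te_len = min(te_len, we - ws)
            if te_len < 50:
                te_len = we - ws
            start = int(rng.integers(ws, we - te_len)) if we - ws > te_len else ws
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, start, start + te_len, strand)
            loci.append(iv)
            locus_truth.append(
                {
                    "te_id": f"{name}:{family}:{raw_class}",
                    "chrom": chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "label": label,
                }
            )
        te_features.append(
            TEFeature(te_name=name, te_family=family, te_class_raw=raw_class,
                      loci=tuple(loci))
        )
    return te_features, locus_truth


# ---------------------------------------------------------------------------
# statistics


def _sample_alt_stats(
    rng: np.random.Generator, n: int, mean_abs_lfc: float, shift: float, beta_a: float
):
    """(p, |lfc|) for perturbed features: Beta(a,1) p-values (via inverse
    CDF of a uniform draw) and shifted-exponential |log2fc|."""
    p = rng.random(n) ** (1.0 / beta_a)
    p = np.clip(p, 1e-300, 1.0)
    scale = max(mean_abs_lfc - shift, 1e-6)
    lfc = shift + rng.exponential(scale, size=n)
    return p, lfc


def _allocate_up_by_class(
    n_up: int, props: Mapping[str, float], available: Mapping[str, np.ndarray]
) -> dict:
    """Integer per-class allocation of the upregulated draw (largest
    remainder), capped by availability with spill to the other classes."""
    raw = {c: n_up * props.get(c, 0.0) for c in CANONICAL}
    alloc = {c: int(math.floor(raw[c])) for c in CANONICAL}
    remainders = sorted(CANONICAL, key=lambda c: raw[c] - alloc[c], reverse=True)
    short = n_up - sum(alloc.values())
    for c in remainders[:short]:
        alloc[c] += 1
    # cap by availability and spill
    for _ in range(3):
        overflow = 0
        for c in CANONICAL:
            avail = len(available[c])
            if alloc[c] > avail:
                overflow += alloc[c] - avail
                alloc[c] = avail
        if overflow == 0:
            break
        for c in sorted(CANONICAL, key=lambda c: len(available[c]) - alloc[c], reverse=True):
            room = len(available[c]) - alloc[c]
            take = min(room, overflow)
            alloc[c] += take
            overflow -= take
            if overflow == 0:
                break
        if overflow:
            break
    return alloc


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort with planted ground truth.

    One RNG seeded from ``config.seed`` drives every draw in a fixed order,
    so identical configs yield byte-identical fixture bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- genome, genes, enhancers, TE loci
    genes, enhancers, intron_win, interg_win = _layout_genome(config, rng)
    class_labels = np.array(CANONICAL)
    class_probs = np.array([config.te_class_mix[c] for c in CANONICAL])
    classes = class_labels[
        rng.choice(len(CANONICAL), size=config.n_tes, p=class_probs)
    ]
    te_features, locus_truth = _place_te_loci(
        config, rng, classes, enhancers, intron_win, interg_win
    )
    te_ids = np.array([te.te_id for te in te_features])
    gene_ids = np.array([g.gene_id for g in genes])

    # --- gene universe structure
    n_genes = config.n_genes
    n_program = int(round(config.gene_program_frac * n_genes))
    perm_genes = rng.permutation(n_genes)
    program_idx = perm_genes[:n_program]
    non_program = perm_genes[n_program:]
    if config.immune_set_size > len(non_program):
        raise ConfigError(
            "immune_set_size exceeds the genes left outside the latent program"
        )
    immune_idx = non_program[: config.immune_set_size]

    latent = np.zeros(n_genes)
    latent[program_idx] = rng.normal(0.0, config.program_effect_sd, size=n_program)
    latent[immune_idx] -= config.immune_mild_effect

    # --- planted TE-proximal immune genes (Hi-C condition)
    n_planted = int(round(config.planted_proximal_frac * config.immune_set_size))
    planted_idx = rng.permutation(immune_idx)[:n_planted] if n_planted else np.array([], int)
    n_down = int(round(config.planted_down_frac * n_planted))
    planted_down_idx = planted_idx[:n_down]
    planted_up_idx = planted_idx[n_down:]

    # --- per-condition TE perturbation sets (nested across conditions)
    class_perm = {
        c: rng.permutation(np.flatnonzero(classes == c)) for c in CANONICAL
    }
    global_perm = rng.permutation(config.n_tes)
    te_truth_up: dict[str, list[str]] = {}
    te_truth_down: dict[str, list[str]] = {}
    condition_up_idx: dict[str, np.ndarray] = {}
    condition_down_idx: dict[str, np.ndarray] = {}
    for label, eff in config.condition_effect_sizes.items():
        n_up = int(round(eff.frac_te_up * config.n_tes))
        props = config.condition_class_props.get(
            label, {c: config.te_class_mix[c] for c in CANONICAL}
        )
        alloc = _allocate_up_by_class(n_up, props, class_perm)
        up_idx = np.concatenate(
            [class_perm[c][: alloc[c]] for c in CANONICAL]
        ) if n_up else np.array([], int)
        up_set = set(up_idx.tolist())
        n_dn = int(round(eff.frac_te_down * config.n_tes))
        down_idx = np.array(
            [i for i in global_perm if i not in up_set][:n_dn], dtype=int
        )
        condition_up_idx[label] = np.sort(up_idx)
        condition_down_idx[label] = np.sort(down_idx)
        te_truth_up[label] = sorted(te_ids[condition_up_idx[label]].tolist())
        te_truth_down[label] = sorted(te_ids[condition_down_idx[label]].tolist())

    # --- per-condition DE tables
    tables: dict[str, DEResultTable] = {}
    beta_a = config.beta_a
    for label, eff in config.condition_effect_sizes.items():
        scale = config.condition_gene_scale.get(label, 1.0)
        z = scale * latent / config.noise_sd + rng.normal(0.0, 1.0, size=n_genes)
        gene_lfc = z * config.noise_sd
        gene_p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)

        if label == config.hic_condition and n_planted:
            for idx_arr, sign in ((planted_down_idx, -1.0), (planted_up_idx, 1.0)):
                if idx_arr.size:
                    p_alt, lfc_alt = _sample_alt_stats(
                        rng, idx_arr.size, eff.mean_abs_log2fc,
                        config.lfc_shift, beta_a,
                    )
                    gene_p[idx_arr] = p_alt
                    gene_lfc[idx_arr] = sign * lfc_alt

        te_p = 1.0 - rng.random(config.n_tes)  # uniform on (0, 1]
        te_lfc = rng.normal(0.0, config.noise_sd, size=config.n_tes)
        for idx_arr, sign in (
            (condition_up_idx[label], 1.0),
            (condition_down_idx[label], -1.0),
        ):
            if idx_arr.size:
                p_alt, lfc_alt = _sample_alt_stats(
                    rng, idx_arr.size, eff.mean_abs_log2fc, config.lfc_shift, beta_a
                )
                te_p[idx_arr] = p_alt
                te_lfc[idx_arr] = sign * lfc_alt

        base_mean = np.concatenate(
            [rng.lognormal(5.0, 1.5, size=n_genes), rng.lognormal(3.0, 1.5, size=config.n_tes)]
        )
        df = pd.DataFrame(
            {
                "feature_id": np.concatenate([gene_ids, te_ids]),
                "feature_kind": ["gene"] * n_genes + ["te"] * config.n_tes,
                "base_mean": base_mean,
                "log2fc": np.concatenate([gene_lfc, te_lfc]),
                "pvalue": np.concatenate([gene_p, te_p]),
            }
        )
        df["padj"] = bh_fdr(df["pvalue"].to_numpy())
        tables[label] = DEResultTable(
            condition_label=label,
            reference_label=config.reference_label,
            data=df,
        )

    # --- contacts
    contacts: list[ContactPair] = []
    w = config.contact_anchor_width
    chrom_names = [c for c, _ in config.genome]
    chrom_len = dict(config.genome)
    hic_up = condition_up_idx[config.hic_condition]
    eligible = [i for i in hic_up if te_features[i].loci]
    if n_planted and not eligible:
        if config.condition_effect_sizes[config.hic_condition].frac_te_up > 0:
            raise ConfigError(
                "planted proximal genes requested but no upregulated TE in "
                f"{config.hic_condition} carries a genomic locus"
            )
        planted_idx = np.array([], int)
        planted_down_idx = np.array([], int)
        planted_up_idx = np.array([], int)
        n_planted = 0
    for gi in planted_idx:
        g = genes[gi]
        te = te_features[eligible[int(rng.integers(len(eligible)))]]
        locus = te.loci[int(rng.integers(len(te.loci)))]
        mid = (locus.start + locus.end) // 2
        ls = max(0, min(mid - w // 2, chrom_len[locus.chrom] - w))
        te_anchor = GenomicInterval(locus.chrom, ls, ls + w)
        gap = int(rng.integers(0, 12_001))
        upstream = rng.random() < 0.5
        if upstream and g.body.start - gap - w >= 0:
            ga = GenomicInterval(g.body.chrom, g.body.start - gap - w, g.body.start - gap)
        else:
            gs = min(g.body.end + gap, chrom_len[g.body.chrom] - w)
            ga = GenomicInterval(g.body.chrom, gs, gs + w)
        contacts.append(ContactPair(te_anchor, ga, cell_type="excitatory"))

    ct_labels = list(config.cell_type_mix)
    ct_probs = np.array([config.cell_type_mix[c] for c in ct_labels], dtype=float)
    ct_probs = ct_probs / ct_probs.sum()
    lens = np.array([chrom_len[c] for c in chrom_names], dtype=float)
    for _ in range(config.n_contacts_background):
        anchors = []
        for _ in range(2):
            ci = int(rng.choice(len(chrom_names), p=lens / lens.sum()))
            pos = int(rng.integers(0, chrom_len[chrom_names[ci]] - w))
            anchors.append(GenomicInterval(chrom_names[ci], pos, pos + w))
        ct = ct_labels[int(rng.choice(len(ct_labels), p=ct_probs))]
        contacts.append(ContactPair(anchors[0], anchors[1], cell_type=ct))

    # --- gene sets
    sets: dict[str, frozenset[str]] = {
        IMMUNE_SET_NAME: frozenset(gene_ids[immune_idx].tolist())
    }
    for k in range(config.n_decoy_sets):
        size = int(rng.integers(10, 150))
        members = rng.choice(n_genes, size=size, replace=False)
        sets[f"random_set_{k:02d}"] = frozenset(gene_ids[members].tolist())

    truth = GroundTruth(
        true_dete_up=te_truth_up,
        true_dete_down=te_truth_down,
        te_class={te.te_id: k for te, k in zip(te_features, classes)},
        te_locus_feature=locus_truth,
        immune_genes=sorted(gene_ids[immune_idx].tolist()),
        program_genes=sorted(gene_ids[program_idx].tolist()),
        planted_proximal_genes=sorted(gene_ids[planted_idx].tolist()),
        planted_down_genes=sorted(gene_ids[planted_down_idx].tolist()),
        planted_up_genes=sorted(gene_ids[planted_up_idx].tolist()),
    )
    return Cohort(
        config=config,
        tables=tables,
        te_features=te_features,
        gene_models=genes,
        enhancers=enhancers,
        contacts=contacts,
        gene_sets=GeneSetCollection(sets=sets),
        truth=truth,
    )


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fully-null configuration: no TE perturbation, no gene program, no
    immune downshift, no planted proximal genes."""
    base = dict(
        seed=seed,
        condition_effect_sizes={
            "WT": ConditionEffect(0.0, 0.0, 1.0),
            "NFD": ConditionEffect(0.0, 0.0, 1.0),
            "VPR": ConditionEffect(0.0, 0.0, 1.0),
        },
        gene_program_frac=0.0,
        immune_mild_effect=0.0,
        planted_proximal_frac=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(
    cohort: Cohort, out_dir: str | Path, force: bool = False
) -> dict:
    """Write the cohort as standard-format files plus ground-truth JSON and
    a manifest of file hashes; refuses to overwrite an existing non-empty
    directory unless ``force``."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} exists and is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    files: dict[str, str] = {}
    for label, table in cohort.tables.items():
        path = out / f"de_{label}.tsv"
        write_de_table(table, path)
        files[path.name] = sha256_file(path)
    paths = {
        "te_loci.bed": lambda p: write_te_annotation(cohort.te_features, p),
        "genes.gtf": lambda p: write_gene_models(cohort.gene_models, p),
        "enhancers.bed": lambda p: write_intervals_bed(cohort.enhancers, p, "enh"),
        "contacts.bedpe": lambda p: write_contacts(cohort.contacts, p),
        "gene_sets.gmt": lambda p: write_gmt(cohort.gene_sets, p),
        "ground_truth.json": lambda p: write_json(cohort.truth.to_json(), p),
    }
    for name, writer in paths.items():
        path = out / name
        writer(path)
        files[name] = sha256_file(path)

    manifest = {
        "seed": cohort.config.seed,
        "n_genes": cohort.config.n_genes,
        "n_tes": cohort.config.n_tes,
        "conditions": sorted(cohort.tables),
        "n_contacts": len(cohort.contacts),
        "n_gene_sets": len(cohort.gene_sets),
        "files": files,
    }
    write_json(manifest, out / "manifest.json")
    return manifest
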