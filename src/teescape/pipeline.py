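"""End-to-end orchestration: dete -> rrho -> enrichment -> proximity ->
resampling, from a single validated config, with a run manifest and a
combined Markdown + JSON report.

Every stage writes its outputs under its own subdirectory of ``out_dir`` so
each can be re-run or audited in isolation; the manifest records input
hashes, per-stage row counts and seeds, and is written in a 'running' state
before the first stage so a failed run still leaves the completed stages'
provenance intact.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ConfigError, TeescapeError
from .dete import (
    SignificanceConfig,
    annotate_features,
    call_significant,
    class_breakdown,
    class_composition_test,
    dete_loci_from_annotation,
)
from .enrichment import EnrichmentConfig, enrichment_frame, gsea, ora_frame
from .hic import ProximityConfig, find_proximal_genes, intersect_with_degs, select_hic_detes
from .io import (
    read_contacts,
    read_de_table,
    read_gene_models,
    read_gmt,
    read_intervals_bed,
    read_te_annotation,
    sha256_file,
    write_json,
)
from .resampling import ResamplingConfig, resample_enrichment, summarize_resampling
from .rrho import rank_features, rrho_map, rrho_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    de_tables: dict  # condition label -> path
    te_annotation: str
    genes: str
    contacts: str
    gene_sets: str
    out_dir: str
    enhancers: str | None = None
    reference_condition: str = "WT"
    hic_condition: str = "VPR"
    reference_label: str = "GFP"
    promoter_window: int = 1000
    rrho_step: int | None = None
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (
            ("significance", SignificanceConfig),
            ("enrichment", EnrichmentConfig),
            ("proximity", ProximityConfig),
            ("resampling", ResamplingConfig),
        ):
            if key in raw and isinstance(raw[key], Mapping):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        missing = []
        paths = dict(self.de_tables)
        paths.update(
            {
                "te_annotation": self.te_annotation,
                "genes": self.genes,
                "contacts": self.contacts,
                "gene_sets": self.gene_sets,
            }
        )
        if self.enhancers:
            paths["enhancers"] = self.enhancers
        for name, p in paths.items():
            if not Path(p).is_file():
                missing.append(f"{name}: {p}")
        if missing:
            raise ConfigError("missing input files:\n  " + "\n  ".join(missing))
        if self.reference_condition not in self.de_tables:
            raise ConfigError(
                f"reference condition {self.reference_condition!r} has no DE table"
            )
        if self.hic_condition not in self.de_tables:
            raise ConfigError(
                f"hic condition {self.hic_condition!r} has no DE table"
            )

    def input_hashes(self) -> dict:
        out = {f"de_{k}": sha256_file(v) for k, v in self.de_tables.items()}
        for name in ("te_annotation", "genes", "contacts", "gene_sets", "enhancers"):
            p = getattr(self, name)
            if p:
                out[name] = sha256_file(p)
        return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the finalized run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "status": "running",
        "config": _config_snapshot(config),
        "inputs": config.input_hashes(),
        "stages": {},
        "seeds": {
            "gsea": config.enrichment.rng_seed,
            "resampling": config.resampling.rng_seed,
        },
    }
    write_json(manifest, out / "manifest.json")

    tables = {
        label: read_de_table(path, label, reference_label=config.reference_label)
        for label, path in config.de_tables.items()
    }
    te_annotation = read_te_annotation(config.te_annotation)
    genes = read_gene_models(config.genes)
    enhancers = read_intervals_bed(config.enhancers) if config.enhancers else []
    gene_sets = read_gmt(config.gene_sets)
    contacts = read_contacts(config.contacts)

    report: dict = {}
    try:
        report["dete"] = _stage_dete(
            config, out / "dete", tables, te_annotation, genes, enhancers
        )
        manifest["stages"]["dete"] = report["dete"]["counts"]
        write_json(manifest, out / "manifest.json")

        report["rrho"] = _stage_rrho(config, out / "rrho", tables)
        manifest["stages"]["rrho"] = {
            k: v["concordance"] for k, v in report["rrho"].items()
        }
        write_json(manifest, out / "manifest.json")

        report["enrichment"] = _stage_enrichment(config, out / "enrichment", tables, gene_sets)
        manifest["stages"]["enrichment"] = {
            k: v["n_significant"] for k, v in report["enrichment"].items()
        }
        write_json(manifest, out / "manifest.json")

        report["proximity"] = _stage_proximity(
            config, out / "proximity", tables, te_annotation, genes, contacts
        )
        manifest["stages"]["proximity"] = {
            "n_proximal_genes": report["proximity"]["n_proximal_genes"],
            "n_proximal_degs": report["proximity"]["n_proximal_degs"],
        }
        write_json(manifest, out / "manifest.json")

        report["resampling"] = _stage_resampling(
            config, out / "resampling", tables, gene_sets, report["proximity"]
        )
        manifest["stages"]["resampling"] = {
            "percentile": report["resampling"]["percentile"]
        }
    finally:
        manifest["status"] = (
            "complete" if len(manifest["stages"]) == 5 else "partial"
        )
        write_json(manifest, out / "manifest.json")

    public = {
        stage: {k: v for k, v in res.items() if not k.startswith("_")}
        if isinstance(res, dict)
        else res
        for stage, res in report.items()
    }
    write_json(public, out / "report.json")
    (out / "report.md").write_text(make_report(public))
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    return snap


def _stage_dete(config, stage_dir, tables, te_annotation, genes, enhancers) -> dict:
    stage_dir.mkdir(parents=True, exist_ok=True)
    counts, breakdowns, chi2 = {}, {}, {}
    called = {}
    for label, table in tables.items():
        sig = call_significant(table, config.significance)
        called[label] = sig
        counts[label] = sig.counts()
        pd.concat([sig.degs, sig.detes]).to_csv(
            stage_dir / f"significant_{label}.tsv", sep="\t", index=False
        )
        bd = class_breakdown(sig.detes, te_annotation)
        breakdowns[label] = bd
        bd.to_frame().to_csv(
            stage_dir / f"class_breakdown_{label}.tsv", sep="\t", index=False
        )
        loci = dete_loci_from_annotation(sig.dete_ids, te_annotation)
        fb = annotate_features(
            loci, genes, enhancers, promoter_window=config.promoter_window
        )
        fb.to_frame().to_csv(
            stage_dir / f"feature_breakdown_{label}.tsv", sep="\t", index=False
        )
        counts[label]["dete_loci"] = fb.total

    ref = config.reference_condition
    chi2_out = {}
    for label in tables:
        if label == ref:
            continue
        try:
            res = class_composition_test(breakdowns[label], breakdowns[ref])
            chi2_out[label] = {
                "chi2": res.chi2, "df": res.df, "p": res.p, "vs": ref
            }
        except TeescapeError as exc:
            chi2_out[label] = {"error": str(exc), "vs": ref}
    write_json(chi2_out, stage_dir / "chi2.json")
    return {
        "counts": counts,
        "chi2": chi2_out,
        "breakdowns": {
            k: v.to_frame().to_dict("records") for k, v in breakdowns.items()
        },
        "_called": called,
    }


def _stage_rrho(config, stage_dir, tables) -> dict:
    stage_dir.mkdir(parents=True, exist_ok=True)
    ranked = {label: rank_features(t) for label, t in tables.items()}
    out = {}
    labels = sorted(tables)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            rmap = rrho_map(ranked[a], ranked[b], step=config.rrho_step)
            summ = rrho_summary(rmap)
            key = f"{a}_vs_{b}"
            rmap.to_frame().to_csv(stage_dir / f"map_{key}.tsv", sep="\t")
            out[key] = {
                "concordance": summ.concordance,
                "max_coupregulation": summ.max_coupregulation,
                "max_codownregulation": summ.max_codownregulation,
                "bonferroni_neglog10": summ.bonferroni_alpha_neglog10,
            }
    write_json(out, stage_dir / "summary.json")
    return out


def _stage_enrichment(config, stage_dir, tables, gene_sets) -> dict:
    stage_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for label, table in tables.items():
        ranked = rank_features(table)
        results = gsea(ranked, gene_sets, config.enrichment)
        df = enrichment_frame(results)
        df.to_csv(stage_dir / f"gsea_{label}.tsv", sep="\t", index=False)
        cutoff = config.enrichment.fdr_cutoff
        out[label] = {
            "n_terms": len(df),
            "n_significant": int((df["fdr"] < cutoff).sum()) if len(df) else 0,
            "n_significant_fdr05": int((df["fdr"] < 0.05).sum()) if len(df) else 0,
            "top": df.head(10).to_dict("records") if len(df) else [],
        }
    write_json(out, stage_dir / "summary.json")
    return out


def _stage_proximity(config, stage_dir, tables, te_annotation, genes, contacts) -> dict:
    stage_dir.mkdir(parents=True, exist_ok=True)
    table = tables[config.hic_condition]
    dete_ids = select_hic_detes(table, config.proximity)
    loci = dete_loci_from_annotation(dete_ids, te_annotation)
    result = find_proximal_genes(loci, contacts, genes, config.proximity)
    result.to_frame().to_csv(stage_dir / "proximal_genes.tsv", sep="\t", index=False)

    sig = call_significant(table, config.significance)
    inter = intersect_with_degs(result, sig.degs)
    inter.degs.to_csv(stage_dir / "proximal_degs.tsv", sep="\t", index=False)
    summary = {
        "hic_condition": config.hic_condition,
        "n_fdr_detes": len(dete_ids),
        "n_dete_loci": len(loci),
        "n_contacts_used": result.n_contacts_used,
        "n_proximal_genes": len(result.dete_proximal_genes),
        "n_proximal_degs": len(inter.degs),
        "fraction_down": inter.fraction_down,
        **inter.counts(),
    }
    write_json(summary, stage_dir / "summary.json")
    summary["_proximal_genes"] = sorted(result.dete_proximal_genes)
    summary["_proximal_deg_ids"] = inter.degs["gene_id"].tolist()
    return summary


def _stage_resampling(config, stage_dir, tables, gene_sets, proximity_summary) -> dict:
    stage_dir.mkdir(parents=True, exist_ok=True)
    pool = proximity_summary["_proximal_genes"]
    observed = proximity_summary["_proximal_deg_ids"]
    table = tables[config.hic_condition]
    universe = table.genes["feature_id"].tolist()
    rcfg = config.resampling
    target_name = rcfg.target_set_name
    if not target_name:
        raise ConfigError("resampling.target_set_name must name a gene set")
    if target_name not in gene_sets:
        raise ConfigError(f"target set {target_name!r} not in the GMT collection")
    if not observed:
        return {"skipped": "no proximal DEGs", "percentile": None}
    result = resample_enrichment(
        pool=pool,
        observed_subset=observed,
        target_set=gene_sets[target_name],
        universe=universe,
        cfg=rcfg,
    )
    row = summarize_resampling(result)
    write_json(row, stage_dir / "summary.json")
    pd.DataFrame({"null_p": result.null_ps}).to_csv(
        stage_dir / "null_distribution.tsv", sep="\t", index=False
    )
    return row


def make_report(report: dict) -> str:
    """Render the combined stage results as Markdown; stages absent from the
    input are marked not-computed rather than omitted."""
    lines = ["# TE-escape pipeline report", ""]

    lines.append("## Differential expression (DEGs / DETEs)")
    dete = report.get("dete")
    if dete:
        lines.append("")
        lines.append("| condition | DEGs | up | down | DETEs | up | down | loci |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for label, c in sorted(dete["counts"].items()):
            lines.append(
                f"| {label} | {c['degs']} | {c['degs_up']} | {c['degs_down']} "
                f"| {c['detes']} | {c['detes_up']} | {c['detes_down']} "
                f"| {c.get('dete_loci', '-')} |"
            )
        lines.append("")
        for label, res in sorted(dete["chi2"].items()):
            if "error" in res:
                lines.append(
                    f"- class composition {label} vs {res['vs']}: {res['error']}"
                )
            else:
                lines.append(
                    f"- class composition {label} vs {res['vs']}: "
                    f"chi2 = {res['chi2']:.2f}, df = {res['df']}, p = {res['p']:.3g}"
                )
    else:
        lines.append("*not computed*")
    lines.append("")

    lines.append("## RRHO concordance")
    rrho_res = report.get("rrho")
    if rrho_res:
        ordering = sorted(
            rrho_res.items(), key=lambda kv: kv[1]["concordance"], reverse=True
        )
        for key, v in ordering:
            lines.append(
                f"- {key}: concordance = {v['concordance']:.2f} "
                f"(max co-up {v['max_coupregulation']:.1f}, "
                f"max co-down {v['max_codownregulation']:.1f})"
            )
    else:
        lines.append("*not computed*")
    lines.append("")

    lines.append("## Gene-set enrichment (GSEA)")
    enr = report.get("enrichment")
    if enr:
        for label, v in sorted(enr.items()):
            lines.append(
                f"- {label}: {v['n_significant']} significant terms "
                f"(of {v['n_terms']}) at the configured FDR; "
                f"{v['n_significant_fdr05']} at FDR < 0.05"
            )
    else:
        lines.append("*not computed*")
    lines.append("")

    lines.append("## Hi-C proximity")
    prox = report.get("proximity")
    if prox:
        frac = prox.get("fraction_down")
        frac_str = f"{100 * frac:.0f}%" if frac is not None else "undefined"
        lines.append(
            f"- {prox['n_fdr_detes']} FDR-surviving DETEs with "
            f"{prox['n_dete_loci']} loci; {prox['n_proximal_genes']} "
            f"DETE-proximal genes; {prox['n_proximal_degs']} proximal DEGs "
            f"({frac_str} downregulated)"
        )
    else:
        lines.append("*not computed*")
    lines.append("")

    lines.append("## Resampling empirical null")
    res = report.get("resampling")
    if res and res.get("percentile") is not None:
        lines.append(
            f"- target set {res['target_set']!r}: observed p = "
            f"{res['observed_p']:.3g}, percentile = {res['percentile']:.2f} "
            f"of {res['n_subsets']} random subsets of size {res['subset_size']}"
        )
    elif res:
        lines.append(f"- skipped: {res.get('skipped', 'unavailable')}")
    else:
        lines.append("*not computed*")
    lines.append("")
    return "\n".join(lines)
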