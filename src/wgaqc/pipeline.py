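"""End-to-end pipeline: simulate -> classify -> screen -> score -> associate.

Each stage writes its TSV outputs before the next stage reads anything, so
any stage can be re-run from cached upstream files; the bundle ends with a
machine-readable JSON of headline numbers. Deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from . import burden as burden_mod
from . import chimera as chimera_mod
from . import concordance as conc
from . import context as ctx
from . import enrichment as enrich_mod
from . import genome, variants
from .simulate import (
    CHIMERA_ARTIFACT,
    HP_ARTIFACT,
    TRUE_VARIANT,
    SimConfig,
    select_association_samples,
    simulate_cohort,
)

log = logging.getLogger("wgaqc")

SUMMARY_SCHEMA_VERSION = 1

DEFAULT_FILTER_TIERS = {"TS99": 0.99, "TS95": 0.95, "TS90": 0.90}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    filter_tiers: dict = field(default_factory=lambda: dict(DEFAULT_FILTER_TIERS))
    af_max: float = 0.05
    strict_enrichment: bool = False
    chimera_window: int = 10_000
    chimera_min_identity: float = 1.0
    bootstrap_reps: int = 1000

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        return cls(sim=sim, **d)


def annotate_consequences(
    alleles: Sequence[variants.VariantAllele],
    genes: Sequence[genome.GeneModel],
    ref: genome.ReferenceSequence,
) -> dict[tuple, str]:
    """Coding consequence per allele key (noncoding outside all genes)."""
    lookup = burden_mod._GeneLookup(genes)
    gene_by_id = {g.gene_id: g for g in genes}
    out: dict[tuple, str] = {}
    for a in alleles:
        gid = lookup.gene_at(a.contig, a.pos - 1)
        if gid is None:
            out[a.key] = "noncoding"
        else:
            out[a.key] = genome.classify_consequence(a, gene_by_id[gid], ref)
    return out


def enrichment_sensitivity(
    results: Sequence[enrich_mod.EnrichmentResult], ledger: pd.DataFrame
) -> dict:
    """Artifact recovery of the Fisher screen against the truth ledger."""
    origin = {
        (r.contig, r.pos, r.ref, r.alt): r.origin for r in ledger.itertuples()
    }
    n_art = n_art_called = n_enriched = n_enriched_art = 0
    for r in results:
        o = origin.get(r.key)
        if o in (HP_ARTIFACT, CHIMERA_ARTIFACT):
            n_art += 1
            n_art_called += int(r.enriched)
        if r.enriched:
            n_enriched += 1
            n_enriched_art += int(o in (HP_ARTIFACT, CHIMERA_ARTIFACT))
    return {
        "n_artifact_indels": n_art,
        "sensitivity": n_art_called / n_art if n_art else float("nan"),
        "n_enriched": n_enriched,
        "precision": n_enriched_art / n_enriched if n_enriched else float("nan"),
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a simulated cohort; write the report bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim

    log.info("simulating cohort (seed=%d)", cfg.seed)
    sim = simulate_cohort(cfg)
    genome.write_fasta(out / "reference.fa", [sim.ref])
    genome.write_gene_bed(out / "genes.bed", sim.genes)
    variants.write_vcf(out / "cohort.vcf", sim.alleles, sim.samples,
                       {sim.ref.name: len(sim.ref)})
    variants.write_meta(out / "meta.tsv", sim.meta)
    sim.ledger.to_csv(out / "ledger.tsv", sep="\t", index=False)

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": cfg.seed,
        "n_samples": len(sim.samples),
        "n_alleles": len(sim.alleles),
    }
    wga_mask = sim.wga_mask
    n_wga = int(wga_mask.sum())
    n_dna = len(sim.samples) - n_wga

    # --- indel taxonomy -----------------------------------------------------
    log.info("classifying indel contexts")
    contexts = ctx.classify_all(
        [a for a in sim.alleles if a.is_indel], sim.ref
    )

    # --- enrichment ---------------------------------------------------------
    if n_wga == 0:
        log.warning("no WGA samples: enrichment stage skipped")
        enr_results, enriched_flags = [], {}
        summary["enrichment"] = {"skipped": "no WGA samples"}
    else:
        log.info("Fisher enrichment screen (%d WGA / %d DNA)", n_wga, n_dna)
        enr_results = enrich_mod.call_enriched(
            sim.alleles, wga_mask, strict=config.strict_enrichment
        )
        enriched_flags = {r.key: r.enriched for r in enr_results}
        enrich_mod.results_to_frame(enr_results).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        summary["enrichment"] = {
            "singleton_threshold": enrich_mod.singleton_threshold(n_wga, n_dna),
            **enrichment_sensitivity(enr_results, sim.ledger),
        }

    ctx.contexts_to_frame(list(contexts.values()), enriched_flags).to_csv(
        out / "indel_contexts.tsv", sep="\t", index=False
    )
    if enriched_flags:
        ordered = list(contexts.values())
        tax = ctx.taxonomy_summary(
            ordered, [enriched_flags.get(c.key, False) for c in ordered]
        )
        tax.drop(columns="size_histogram").to_csv(out / "taxonomy.tsv", sep="\t")
        summary["taxonomy"] = {
            g: {k: float(v) for k, v in row.items() if k != "size_histogram"}
            for g, row in tax.iterrows()
        }

    # --- chimera origin search ----------------------------------------------
    log.info("chimera origin search")
    large = [a for a in sim.alleles if a.is_indel and a.indel_len >= 15]
    hits = [
        chimera_mod.find_origin(
            a, sim.ref, window=config.chimera_window,
            min_identity=config.chimera_min_identity,
        )
        for a in large
    ]
    chimera_mod.hits_to_frame(hits).to_csv(out / "chimera_hits.tsv", sep="\t", index=False)
    if hits:
        dist = chimera_mod.origin_distance_summary(hits, enriched_flags or None)
        dist.to_csv(out / "chimera_summary.tsv", sep="\t")
        summary["chimera"] = {
            s: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for s, row in dist.iterrows()
        }

    # --- replicate concordance ----------------------------------------------
    pairs = conc.pairs_from_meta(sim.meta)
    if pairs:
        log.info("replicate concordance over %d pairs", len(pairs))
        ptable = conc.pairwise_discordance(
            pairs, sim.alleles, sim.samples, contexts=contexts
        )
        ptable.to_csv(out / "concordance.tsv", sep="\t", index=False)
        medians = conc.summarize_by_pair_type(ptable)
        medians.to_csv(out / "concordance_medians.tsv", sep="\t")
        summary["discordance_median"] = {
            pt: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for pt, row in medians.iterrows()
        }

    # --- burden + ANOVA ------------------------------------------------------
    log.info("LOF burden and variance decomposition")
    consequences = annotate_consequences(sim.alleles, sim.genes, sim.ref)
    table = burden_mod.build_burden(
        sim.alleles, sim.samples, consequences, genes=sim.genes,
        contexts=contexts, af_max=config.af_max, per_gene=True,
    )
    table.per_sample.to_csv(out / "burden.tsv", sep="\t")
    summary["burden"] = {}
    for col in ("lof_indel", "lof_snv"):
        vals = table.per_sample[col]
        med = {
            "median_wga": float(vals[wga_mask].median()) if n_wga else None,
            "median_dna": float(vals[~wga_mask].median()),
        }
        if n_wga >= 2:
            med["wga_mean_ci"] = burden_mod.bootstrap_ci(
                vals[wga_mask], reps=config.bootstrap_reps, seed=cfg.seed
            )
        summary["burden"][col] = med
    if n_wga and n_dna:
        summary["anova"] = {}
        for col in ("lof_indel", "lof_snv"):
            try:
                dec = burden_mod.anova_decomposition(table.per_sample[col], sim.meta)
            except ValueError as exc:
                log.warning("ANOVA for %s skipped: %s", col, exc)
                summary["anova"][col] = {"skipped": str(exc)}
                continue
            dec.table.to_csv(out / f"anova_{col}.tsv", sep="\t")
            summary["anova"][col] = {
                "top_factor": dec.top_factor,
                "pct_var_wga": dec.pct_var("wga"),
            }

    # --- filtered association across tiers -----------------------------------
    log.info("association testing across filter tiers")
    truth_qs = [
        a.qs
        for a, o in zip(sim.alleles, sim.ledger["origin"])
        if o == TRUE_VARIANT
    ]
    assoc_samples = select_association_samples(sim.meta)
    sample_pos = {s: i for i, s in enumerate(sim.samples)}
    results_by_tier: dict[str, list] = {}
    tier_summaries = {}
    groups_tested = [cfg.confounded_group] + [
        g for g in cfg.groups if g != cfg.confounded_group
    ][:1]
    for tier, stringency in sorted(
        config.filter_tiers.items(), key=lambda kv: -kv[1]
    ):
        kept = variants.apply_quality_filter(sim.alleles, stringency, truth_qs)
        tier_table = burden_mod.build_burden(
            kept, sim.samples, consequences, genes=sim.genes,
            contexts=contexts, af_max=config.af_max, per_gene=True,
        )
        gene_burden = (
            tier_table.per_gene.loc[assoc_samples]
            if tier_table.per_gene is not None and not tier_table.per_gene.empty
            else pd.DataFrame(index=pd.Index(assoc_samples, name="sample_id"))
        )
        results: list = []
        for group in groups_tested:
            results.extend(
                assoc.one_vs_rest_test(gene_burden, sim.meta, group)
            )
        results_by_tier[tier] = results
        assoc.results_to_frame(results).to_csv(
            out / f"association_{tier}.tsv", sep="\t", index=False
        )
        tier_summaries[tier] = {
            "stringency": stringency,
            "n_kept_alleles": len(kept),
            "median_lof_indel_burden": float(
                tier_table.per_sample["lof_indel"].median()
            ),
        }
    report = assoc.inflation_report(results_by_tier, n_groups=len(cfg.groups))
    for tier, rep in report.items():
        rep["qq"].to_csv(out / f"qq_{tier}.tsv", sep="\t", index=False)
        tier_summaries[tier].update(
            {
                "bonferroni_cutoff": rep["cutoff"],
                "n_tested_genes": rep["n_tested_genes"],
                "n_significant": rep["n_significant"],
            }
        )
    summary["association"] = tier_summaries

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2, sort_keys=True)
    log.info("report bundle written to %s", out)
    return summary


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else round(float(obj), 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
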