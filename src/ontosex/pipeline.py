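"""End-to-end orchestration: screen, cluster, enrich, codon, phylo, report.

``run_all`` is a pure function of (inputs, config, seed): rerunning the
same configuration produces byte-identical report tables.  Every
threshold lives in :class:`RunConfig`, which is serialised verbatim
into the output manifest for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ontosex import __version__, clustering, codon_usage, diffexpr, enrichment, phylogenomics
from ontosex.core_io import (
    FEMALE,
    LARVAL_STAGES,
    MALE,
    STAGES,
    BiasProfile,
    read_annotation_map,
    read_cds_fasta,
    read_expression_matrix,
    read_fly_bias,
    read_orthology_table,
    write_bias_profiles,
)

log = logging.getLogger("ontosex")

STAGE_GROUPS: dict[str, tuple[str, ...]] = {
    "larvae": LARVAL_STAGES,
    "pupae": ("P",),
    "adult": ("A",),
}


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    expression: str
    cds: str
    orthology: str
    annotations: str
    fly_bias: str
    outdir: str
    seed: int = 0
    alpha: float = 0.05
    bias_threshold: float = 0.8
    recovery_threshold: float = 0.6
    min_replicate_fraction: float = 0.66
    tiers: tuple[float, float] = (0.8, 1.6)
    k: int = 11
    qt_diameter: float = 1.0
    min_codons: int = 50
    enrichment_alpha: float = 0.001
    decile: float = 0.1

    def __post_init__(self) -> None:
        for name in ("alpha", "bias_threshold", "recovery_threshold",
                     "min_replicate_fraction", "enrichment_alpha", "decile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "tiers" in raw:
            raw["tiers"] = tuple(raw["tiers"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tiers"] = list(self.tiers)
        return d


def report_percentages(counts: list[tuple[str, int, int]], decimals: int = 1) -> pd.DataFrame:
    """Format labelled (k, n) pairs as percentages, one decimal by default
    (half away from zero); rows with n = 0 are reported missing."""
    rows = []
    for label, k, n in counts:
        pct = diffexpr.percentage(k, n, decimals) if n > 0 else np.nan
        rows.append({"label": label, "k": k, "n": n, "percent": pct})
    return pd.DataFrame(rows)


def _stage_group_calls(profiles: list[BiasProfile]) -> dict[str, dict[str, set[str]]]:
    """Per stage group: total / male / female gene sets.

    Total = genes with a determined call at >= 1 stage of the group;
    male/female = called that sex at >= 1 stage of the group.
    """
    out: dict[str, dict[str, set[str]]] = {}
    for group, stages in STAGE_GROUPS.items():
        total, male, female = set(), set(), set()
        for p in profiles:
            calls = [p.call.get(s) for s in stages]
            if any(c and c != "undetermined" for c in calls):
                total.add(p.gene)
            if MALE in calls:
                male.add(p.gene)
            if FEMALE in calls:
                female.add(p.gene)
        out[group] = {"total": total, "male": male, "female": female}
    return out


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the report bundle.

    Returns the mapping of report names to file paths; any stage failure
    aborts with the stage name while preserving partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage = "setup"
    try:
        # ---------------- diffexpr ----------------
        stage = "diffexpr"
        matrix = read_expression_matrix(config.expression)
        screen = diffexpr.screen_genes(
            matrix, config.alpha, config.min_replicate_fraction, config.recovery_threshold
        )
        admitted = {r.gene for r in screen if r.admitted}
        log.info("screen: %d of %d genes admitted", len(admitted), len(matrix.genes))
        profiles = diffexpr.build_bias_profiles(matrix, admitted, config.bias_threshold)

        paths["bias_profiles"] = outdir / "bias_profiles.tsv"
        write_bias_profiles(profiles, paths["bias_profiles"])

        summary = diffexpr.stage_summary(profiles, config.tiers)
        paths["stage_summary"] = outdir / "stage_summary.tsv"
        summary.to_csv(paths["stage_summary"], sep="\t", na_rep="NA", index=False)

        venn = diffexpr.maintained_bias(profiles)
        venn_rows = [
            {"pools": "+".join(sorted(k)), "n_genes": len(v),
             "genes": ",".join(sorted(v))}
            for k, v in sorted(venn.items(), key=lambda kv: "+".join(sorted(kv[0])))
        ]
        paths["venn"] = outdir / "venn.tsv"
        pd.DataFrame(venn_rows).to_csv(paths["venn"], sep="\t", index=False)

        paths["mean_vs_sd"] = outdir / "mean_vs_sd.tsv"
        diffexpr.variance_profile(profiles).to_csv(
            paths["mean_vs_sd"], sep="\t", na_rep="NA", index=False
        )

        # ---------------- clustering ----------------
        stage = "clustering"
        eligible = clustering.eligible_profiles(profiles)
        k = min(config.k, max(1, len(eligible)))
        result = clustering.kmeans_cluster(eligible, k, seed=config.seed)
        clustering.assign_groups(result.clusters, config.bias_threshold)
        member_rows = [
            {"gene": g, "cluster": c.id, "group": c.group}
            for c in result.clusters
            for g in sorted(c.members)
        ]
        paths["clusters"] = outdir / "clusters.tsv"
        pd.DataFrame(member_rows).to_csv(paths["clusters"], sep="\t", index=False)
        centroid_rows = [
            {"cluster": c.id, "group": c.group,
             **{s: c.centroid[i] for i, s in enumerate(STAGES)}}
            for c in result.clusters
        ]
        paths["centroids"] = outdir / "centroids.tsv"
        pd.DataFrame(centroid_rows).to_csv(
            paths["centroids"], sep="\t", na_rep="NA", index=False, float_format="%.6g"
        )

        # ---------------- enrichment ----------------
        stage = "enrichment"
        ann = read_annotation_map(config.annotations)
        enr_rows = []
        for c in result.clusters:
            for r in enrichment.enrich_cluster(
                set(c.members), admitted, ann, config.enrichment_alpha
            ):
                enr_rows.append(
                    {"cluster": c.id, "term": r.term, "k": r.k, "n": r.n,
                     "K": r.K, "N": r.N, "p_raw": r.p_raw, "p_adj": r.p_adj,
                     "enriched": r.enriched}
                )
        paths["enrichment"] = outdir / "enrichment.tsv"
        pd.DataFrame(
            enr_rows, columns=["cluster", "term", "k", "n", "K", "N",
                               "p_raw", "p_adj", "enriched"]
        ).to_csv(paths["enrichment"], sep="\t", index=False, float_format="%.6g")

        # ---------------- codon usage ----------------
        stage = "codon_usage"
        records = codon_usage.select_longest_transcripts(read_cds_fasta(config.cds))
        stats_rows = []
        counts_by_gene = {}
        enc_by_gene = {}
        for rec in records:
            verdict = codon_usage.qc_cds(rec)
            row = {"gene": rec.gene, "qc_pass": verdict.passed,
                   "reasons": ";".join(verdict.reasons), "length": rec.length,
                   "enc": np.nan, "fop": np.nan}
            if verdict.passed:
                cc = codon_usage.count_codons(rec)
                counts_by_gene[rec.gene] = cc
                enc_by_gene[rec.gene] = codon_usage.enc(cc, config.min_codons)
                row["enc"] = enc_by_gene[rec.gene]
            stats_rows.append(row)
        optimal = codon_usage.determine_optimal_codons(
            [(counts_by_gene[g], e) for g, e in enc_by_gene.items()],
            decile=config.decile,
        )
        for row in stats_rows:
            g = row["gene"]
            if g in counts_by_gene:
                row["fop"] = codon_usage.fop(counts_by_gene[g], optimal, config.min_codons)
        stats_df = pd.DataFrame(stats_rows).sort_values("gene")
        paths["codon_stats"] = outdir / "codon_stats.tsv"
        stats_df.to_csv(paths["codon_stats"], sep="\t", na_rep="NA", index=False,
                        float_format="%.6g")

        group_calls = _stage_group_calls(profiles)
        class_rows = []
        for group, sets in group_calls.items():
            stat = stats_df.set_index("gene")
            ref = stat.loc[stat.index.intersection(sorted(sets["total"]))]
            ref = ref[ref["qc_pass"] & ref["enc"].notna()]
            for cls in ("total", "male", "female"):
                sel = stat.loc[stat.index.intersection(sorted(sets[cls]))]
                sel = sel[sel["qc_pass"] & sel["enc"].notna()]
                row = {"stage_group": group, "class": cls, "n": len(sel),
                       "mean_length": sel["length"].mean(),
                       "mean_enc": sel["enc"].mean(),
                       "mean_fop": sel["fop"].mean(),
                       "ks_p_enc": np.nan, "ks_p_fop": np.nan}
                if cls != "total" and len(sel) >= 5 and len(ref) >= 5:
                    _, row["ks_p_enc"] = codon_usage.ks_compare(sel["enc"], ref["enc"])
                    _, row["ks_p_fop"] = codon_usage.ks_compare(
                        sel["fop"].dropna(), ref["fop"].dropna()
                    )
                class_rows.append(row)
        paths["codon_classes"] = outdir / "codon_classes.tsv"
        pd.DataFrame(class_rows).to_csv(paths["codon_classes"], sep="\t",
                                        na_rep="NA", index=False, float_format="%.6g")

        # ---------------- phylogenomics ----------------
        stage = "phylogenomics"
        orth = read_orthology_table(config.orthology)
        orth_genes = {r.gene for r in orth}
        tests = []
        for group, sets in group_calls.items():
            background = sets["total"] & orth_genes
            for cls in ("male", "female"):
                gene_set = sets[cls] & orth_genes
                if not gene_set or not background:
                    continue
                for comparison in phylogenomics.COMPARISONS:
                    tests.append((f"{group}_{cls}", gene_set, background, comparison))
        m = len(tests)
        ortho_rows = []
        for label, gene_set, background, comparison in tests:
            r = phylogenomics.ortho_enrichment_test(
                gene_set, background, orth, comparison, label=label, family_size=m
            )
            ortho_rows.append(dataclasses.asdict(r))
        paths["orthology_tests"] = outdir / "orthology_tests.tsv"
        pd.DataFrame(ortho_rows).to_csv(paths["orthology_tests"], sep="\t",
                                        index=False, float_format="%.6g")

        fly = read_fly_bias(config.fly_bias)
        calls, cons_summary = phylogenomics.cross_species_conservation(profiles, orth, fly)
        paths["conservation"] = outdir / "conservation.tsv"
        pd.DataFrame(
            [{"gene": c.gene, "category": c.category} for c in calls]
        ).sort_values("gene").to_csv(paths["conservation"], sep="\t", index=False)
        cons_rows = [
            {"an_class": cls, **{k: v for k, v in d.items()}}
            for cls, d in cons_summary.items()
        ]
        paths["conservation_summary"] = outdir / "conservation_summary.tsv"
        pd.DataFrame(cons_rows).to_csv(paths["conservation_summary"], sep="\t",
                                       na_rep="NA", index=False)

        # ---------------- manifest ----------------
        stage = "manifest"
        cfg = config.to_dict()
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": cfg,
            "config_sha256": cfg_hash,
            "n_genes_input": len(matrix.genes),
            "n_genes_admitted": len(admitted),
            "n_profiles_clustered": len(eligible),
            "reports": {k: str(v.name) for k, v in paths.items()},
        }
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return paths
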