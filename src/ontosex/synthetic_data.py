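"""Seeded generators for every input the pipeline consumes.

Each generator plants a known ground truth and returns it alongside the
data, so every downstream operation can be scored without additional
information.  Defaults echo the study landscape the pipeline targets:
three replicates at five stages, a sex-biased fraction rising from
about 1% at the first larval stage (male-dominated) to about 28.5% in
adults (female-dominated), replicate noise of 0.3 log2 units, and
planted effect sizes drawn uniformly from [0.9, 3.0] log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ontosex.core_io import (
    FEMALE,
    MALE,
    STAGES,
    UNBIASED,
    AnnotationMap,
    CdsRecord,
    ExpressionMatrix,
    OrthologyRecord,
    write_annotation_map,
    write_cds_fasta,
    write_expression_matrix,
    write_fly_bias,
    write_orthology_table,
)
from ontosex.codon_usage import FAMILIES, SINGLE_CODON_AA

#: per-stage sex-biased fraction defaults (rising through ontogeny)
DEFAULT_BIASED_FRACTION = {"L1": 0.01, "L2-3": 0.015, "L4": 0.02, "P": 0.03, "A": 0.285}
#: fraction of biased genes that are male-biased (male-dominated early,
#: female-dominated at the adult stage)
DEFAULT_MALE_SHARE = {"L1": 0.85, "L2-3": 0.85, "L4": 0.85, "P": 0.60, "A": 0.36}


@dataclass
class ExpressionSimSpec:
    """Design of a synthetic replicated log-ratio experiment."""

    n_genes: int = 5000
    replicate_count: int = 3
    biased_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIASED_FRACTION)
    )
    male_share: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MALE_SHARE))
    effect_low: float = 0.9
    effect_high: float = 3.0
    noise_sd: float = 0.3
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for s, f in self.biased_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"biased fraction for {s} outside [0,1]")


def gen_expression(spec: ExpressionSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a gene x (stage, replicate) matrix with planted bias calls.

    Per gene and stage the latent mean is 0 (unbiased) or +/-effect;
    replicates add Normal(0, noise_sd); entries go missing independently
    at ``missing_rate``.  The truth table records the planted call and
    effect for every gene x stage.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    n, S, R = spec.n_genes, len(STAGES), spec.replicate_count

    means = np.zeros((n, S))
    truth_call = np.full((n, S), UNBIASED, dtype=object)
    for j, s in enumerate(STAGES):
        biased = rng.random(n) < spec.biased_fraction.get(s, 0.0)
        male = rng.random(n) < spec.male_share.get(s, 0.5)
        effect = rng.uniform(spec.effect_low, spec.effect_high, n)
        sign = np.where(male, 1.0, -1.0)
        means[:, j] = np.where(biased, sign * effect, 0.0)
        truth_call[biased & male, j] = MALE
        truth_call[biased & ~male, j] = FEMALE

    values = means[:, :, None] + rng.normal(0.0, spec.noise_sd, (n, S, R))
    if spec.missing_rate > 0:
        values[rng.random((n, S, R)) < spec.missing_rate] = np.nan

    columns = pd.MultiIndex.from_tuples(
        [(s, r + 1) for s in STAGES for r in range(R)], names=["stage", "replicate"]
    )
    frame = pd.DataFrame(
        values.reshape(n, S * R), index=pd.Index(genes, name="gene"), columns=columns
    )
    truth = pd.DataFrame(truth_call, index=genes, columns=list(STAGES))
    truth_effect = pd.DataFrame(means, index=genes, columns=[f"effect_{s}" for s in STAGES])
    truth = pd.concat([truth, truth_effect], axis=1)
    return ExpressionMatrix(frame), truth


# ---------------------------------------------------------------------------
# Coding sequences
# ---------------------------------------------------------------------------

_AA_LIST = sorted(FAMILIES)  # 20 amino acids


@dataclass
class CdsSimSpec:
    """Design of a synthetic CDS collection with tunable codon bias.

    ``beta`` tilts synonymous codon choice toward one designated codon
    per amino acid (weight exp(beta) against 1 for the others); beta = 0
    gives uniform synonymous usage.  Scalar beta applies to all genes;
    a sequence gives one value per gene.
    """

    n_genes: int = 200
    beta: float | list[float] = 0.0
    length_low: int = 150
    length_high: int = 450
    seed: int = 0


def _designate_codons(rng: np.random.Generator) -> dict[str, str]:
    return {
        aa: codons[rng.integers(len(codons))]
        for aa, codons in FAMILIES.items()
        if aa not in SINGLE_CODON_AA
    }


def gen_cds(
    spec: CdsSimSpec, designated: dict[str, str] | None = None
) -> tuple[list[CdsRecord], dict]:
    """Generate QC-clean CDS records with beta-tilted synonymous usage.

    Sequences start with ATG, end with TAA, contain no internal stops
    and draw amino acids uniformly.  Returns records plus a truth dict
    with the per-gene beta values and the designated codon per amino
    acid.
    """
    rng = np.random.default_rng(spec.seed)
    if designated is None:
        designated = _designate_codons(rng)
    betas = (
        np.full(spec.n_genes, float(spec.beta))
        if np.isscalar(spec.beta)
        else np.asarray(spec.beta, dtype=float)
    )
    if betas.shape != (spec.n_genes,):
        raise ValueError("beta must be scalar or one value per gene")

    lengths = rng.integers(spec.length_low, spec.length_high + 1, spec.n_genes)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    aa_idx = rng.integers(0, len(_AA_LIST), total)
    gene_of_pos = np.repeat(np.arange(spec.n_genes), lengths)

    codon_at = np.empty(total, dtype=object)
    for ai, aa in enumerate(_AA_LIST):
        pos = np.flatnonzero(aa_idx == ai)
        if pos.size == 0:
            continue
        codons = FAMILIES[aa]
        if len(codons) == 1:
            codon_at[pos] = codons[0]
            continue
        w = np.ones((pos.size, len(codons)))
        d = codons.index(designated[aa])
        w[:, d] = np.exp(betas[gene_of_pos[pos]])
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random(pos.size)
        choice = (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1)
        codon_at[pos] = np.array(codons, dtype=object)[choice]

    records = []
    for g in range(spec.n_genes):
        body = "".join(codon_at[offsets[g] : offsets[g + 1]])
        records.append(
            CdsRecord(gene=f"G{g:05d}", transcript=f"T{g:05d}", sequence="ATG" + body + "TAA")
        )
    truth = {"beta": betas, "designated": dict(designated)}
    return records, truth


# ---------------------------------------------------------------------------
# Orthology, annotations, comparator bias
# ---------------------------------------------------------------------------


def gen_orthology(
    n_genes: int,
    unique_fraction_ae: float = 0.2,
    unique_fraction_dm: float = 0.25,
    one2one_fraction: float = 0.5,
    enriched_set: set[str] | None = None,
    multiplier: float = 1.0,
    seed: int = 0,
    genes: list[str] | None = None,
) -> tuple[list[OrthologyRecord], pd.DataFrame]:
    """Bernoulli orthologue presence per comparator with optional planting.

    Genes in ``enriched_set`` have their uniqueness probabilities
    multiplied by ``multiplier`` (an error if that leaves [0,1]).  A
    stated subfraction of genes with a comparator orthologue receive a
    one-to-one partner identifier.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:05d}" for i in range(n_genes)]
    records = []
    rows = []
    for i, g in enumerate(genes):
        p_ae, p_dm = unique_fraction_ae, unique_fraction_dm
        if enriched_set and g in enriched_set:
            p_ae, p_dm = p_ae * multiplier, p_dm * multiplier
            if not (0 <= p_ae <= 1 and 0 <= p_dm <= 1):
                raise ValueError("multiplier pushes a uniqueness fraction outside [0,1]")
        unique_ae = rng.random() < p_ae
        unique_dm = rng.random() < p_dm
        one2one = None
        if not unique_dm and rng.random() < one2one_fraction:
            one2one = f"FBgn{i:05d}"
        records.append(
            OrthologyRecord(
                gene=g, has_orth_ae=not unique_ae, has_orth_dm=not unique_dm,
                one2one_dm=one2one,
            )
        )
        rows.append({"gene": g, "unique_ae": unique_ae, "unique_dm": unique_dm})
    return records, pd.DataFrame(rows).set_index("gene")


def gen_annotations(
    genes: list[str],
    n_terms: int = 50,
    base_rate: float = 0.02,
    planted: list[tuple[set[str], str, float]] | None = None,
    namespace: str = "GO",
    seed: int = 0,
) -> tuple[AnnotationMap, list[tuple[set[str], str, float]]]:
    """Bernoulli term membership with optional planted cluster enrichment.

    ``planted`` triples (cluster gene set, term, fold) boost the term's
    membership probability by ``fold`` within the cluster (fold >= 1).
    """
    rng = np.random.default_rng(seed)
    planted = planted or []
    for _, _, fold in planted:
        if fold < 1:
            raise ValueError("planted folds must be >= 1")
    terms = [f"{namespace}:{t:07d}" for t in range(n_terms)]
    boost: dict[str, dict[str, float]] = {}
    for cluster, term, fold in planted:
        for g in cluster:
            boost.setdefault(g, {})[term] = fold
    mapping: dict[str, set[str]] = {}
    for g in genes:
        for t in terms:
            p = min(1.0, base_rate * boost.get(g, {}).get(t, 1.0))
            if rng.random() < p:
                mapping.setdefault(g, set()).add(t)
    return AnnotationMap({g: frozenset(v) for g, v in mapping.items()}, namespace), planted


#: cross-species concordance defaults for the comparator bias table:
#: probability that the comparator partner of a focal male-/female-/un-
#: biased gene is male-biased, female-biased or unbiased.
DEFAULT_FLY_CONCORDANCE = {
    MALE: {MALE: 0.15, FEMALE: 0.03},
    FEMALE: {MALE: 0.03, FEMALE: 0.38},
    UNBIASED: {MALE: 0.10, FEMALE: 0.10},
}


def gen_fly_bias(
    adult_calls: dict[str, str],
    orth: list[OrthologyRecord],
    concordance: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Comparator-species bias classes for every one-to-one partner.

    The partner's class is drawn conditional on the focal gene's planted
    adult call using the concordance probabilities (remainder mass goes
    to unbiased).
    """
    rng = np.random.default_rng(seed)
    conc = concordance or DEFAULT_FLY_CONCORDANCE
    table: dict[str, str] = {}
    rows = []
    for rec in orth:
        if not rec.one2one_dm:
            continue
        focal = adult_calls.get(rec.gene, UNBIASED)
        probs = conc.get(focal, conc[UNBIASED])
        u = rng.random()
        if u < probs.get(MALE, 0.0):
            cls = MALE
        elif u < probs.get(MALE, 0.0) + probs.get(FEMALE, 0.0):
            cls = FEMALE
        else:
            cls = UNBIASED
        table[rec.one2one_dm] = cls
        rows.append({"gene": rec.gene, "partner": rec.one2one_dm, "fly_bias": cls})
    return table, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full input bundle
# ---------------------------------------------------------------------------


def simulate_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 5000,
    expression_spec: ExpressionSimSpec | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic input bundle plus truth tables.

    Emits expression.tsv, cds.fasta, orthology.tsv, annotations.tsv,
    fly_bias.tsv and the matching truth tables; returns the path map.
    Derived sub-seeds keep each generator independently reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss]

    spec = expression_spec or ExpressionSimSpec(n_genes=n_genes, seed=sub[0])
    matrix, truth_expr = gen_expression(spec)
    genes = matrix.genes

    # two codon-bias classes so optimal-codon inference has signal
    betas = np.where(np.arange(len(genes)) % 2 == 0, 1.5, 0.2)
    cds, truth_cds = gen_cds(
        CdsSimSpec(n_genes=len(genes), beta=list(betas), seed=sub[1])
    )
    for rec, g in zip(cds, genes):
        rec.gene = g
        rec.transcript = g + ".t1"

    orth, truth_orth = gen_orthology(len(genes), seed=sub[2], genes=genes)
    ann, _ = gen_annotations(genes, seed=sub[3])
    adult_calls = {g: truth_expr.loc[g, "A"] for g in genes}
    fly, truth_fly = gen_fly_bias(adult_calls, orth, seed=sub[4])

    paths = {
        "expression": outdir / "expression.tsv",
        "cds": outdir / "cds.fasta",
        "orthology": outdir / "orthology.tsv",
        "annotations": outdir / "annotations.tsv",
        "fly_bias": outdir / "fly_bias.tsv",
        "truth_expression": outdir / "truth_expression.tsv",
        "truth_orthology": outdir / "truth_orthology.tsv",
        "truth_fly": outdir / "truth_fly.tsv",
    }
    write_expression_matrix(matrix, paths["expression"])
    write_cds_fasta(cds, paths["cds"])
    write_orthology_table(orth, paths["orthology"])
    write_annotation_map(ann, paths["annotations"])
    write_fly_bias(fly, paths["fly_bias"])
    truth_expr.to_csv(paths["truth_expression"], sep="\t", index_label="gene")
    truth_orth.to_csv(paths["truth_orthology"], sep="\t")
    truth_fly.to_csv(paths["truth_fly"], sep="\t", index=False)
    return paths
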