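"""Domain types and tab-separated / FASTA readers and writers.

All tabular formats are UTF-8, tab-separated, with a mandatory header
row.  Missing values are written as ``NA`` and parsed from empty cells
or ``NA`` — never as 0, because 0 is a meaningful log-ratio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class StageLabel(str, enum.Enum):
    """The five sampled developmental stages, in ontogenetic order."""

    L1 = "L1"
    L2_3 = "L2-3"
    L4 = "L4"
    P = "P"
    A = "A"

    @property
    def index(self) -> int:
        return _STAGE_ORDER[self.value]

    def __lt__(self, other: "StageLabel") -> bool:  # type: ignore[override]
        if not isinstance(other, StageLabel):
            return NotImplemented
        return self.index < other.index


#: Canonical stage order used for all 5-vectors.
STAGES: tuple[str, ...] = ("L1", "L2-3", "L4", "P", "A")
_STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}

#: Larval stages pooled for the ontogeny Venn partition.
LARVAL_STAGES: tuple[str, ...] = ("L1", "L2-3", "L4")

#: Bias-call vocabulary.
MALE, FEMALE, UNBIASED, UNDETERMINED = "male", "female", "unbiased", "undetermined"


class DataError(ValueError):
    """Raised on malformed or invariant-violating input data."""


@dataclass
class ExpressionMatrix:
    """Gene x (stage, replicate) log2(male/female) ratio matrix.

    ``data`` has one row per gene (unique string index) and a two-level
    column MultiIndex ``(stage, replicate)`` with replicates numbered
    from 1.  Missing values are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate gene identifier: {dup!r}")
        if any(not isinstance(g, str) or not g for g in idx):
            raise DataError("gene identifiers must be nonempty strings")
        stages = self.data.columns.get_level_values(0)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise DataError(f"unknown stage label(s): {sorted(unknown)}")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise DataError("non-finite (infinite) expression value present")
        # enforce canonical stage order
        order = sorted(self.data.columns, key=lambda c: (_STAGE_ORDER[c[0]], c[1]))
        self.data = self.data.loc[:, order].astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def stages(self) -> list[str]:
        seen = dict.fromkeys(self.data.columns.get_level_values(0))
        return list(seen)

    def replicate_count(self, stage: str) -> int:
        return int((self.data.columns.get_level_values(0) == stage).sum())

    def stage_values(self, gene: str, stage: str) -> np.ndarray:
        """Replicate values (with NaN) for one gene at one stage."""
        return self.data.loc[gene, stage].to_numpy(dtype=float)


@dataclass
class BiasProfile:
    """Per-gene stage means and categorical sex-bias calls.

    ``mean_ratio[stage]`` is the mean of non-missing replicates (NaN if
    none); ``call[stage]`` is one of male / female / unbiased /
    undetermined, undetermined exactly where the mean is missing.
    """

    gene: str
    mean_ratio: dict[str, float]
    call: dict[str, str]

    def biased_stages(self) -> list[str]:
        return [s for s in STAGES if self.call.get(s) in (MALE, FEMALE)]

    @property
    def is_biased(self) -> bool:
        return bool(self.biased_stages())

    def vector(self) -> np.ndarray:
        return np.array([self.mean_ratio.get(s, np.nan) for s in STAGES], dtype=float)


@dataclass
class CdsRecord:
    """One coding sequence: gene, transcript, uppercase nucleotides."""

    gene: str
    transcript: str
    sequence: str
    alphabet_ok: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class OrthologyRecord:
    """Orthologue presence in two comparator genomes for one gene."""

    gene: str
    has_orth_ae: bool
    has_orth_dm: bool
    one2one_dm: str | None = None

    def __post_init__(self) -> None:
        if self.one2one_dm is not None and not self.has_orth_dm:
            raise DataError(
                f"gene {self.gene!r}: one-to-one partner given but has_orth_dm is false"
            )


@dataclass
class AnnotationMap:
    """Gene -> set of term identifiers within one namespace (GO or domain)."""

    mapping: dict[str, frozenset[str]]
    namespace: str = "GO"

    def __post_init__(self) -> None:
        for g, terms in self.mapping.items():
            if any(not t for t in terms):
                raise DataError(f"gene {g!r} carries an empty term identifier")
            self.mapping[g] = frozenset(terms)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def annotated_genes(self) -> set[str]:
        return {g for g, t in self.mapping.items() if t}


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, gene_col: str = "gene") -> ExpressionMatrix:
    """Read a tab-separated gene x stage_replicate ratio table.

    Columns other than ``gene_col`` must be named ``<stage>_<replicate>``
    (e.g. ``L2-3_1``).  Empty cells and ``NA`` parse as missing; any
    other non-numeric cell is a hard error naming its row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if gene_col not in df.columns:
        raise DataError(f"missing gene column {gene_col!r}")
    genes = df[gene_col].tolist()
    dup = pd.Series(genes)[pd.Series(genes).duplicated()]
    if not dup.empty:
        raise DataError(f"duplicate gene identifier: {dup.iloc[0]!r}")

    columns: list[tuple[str, int]] = []
    for col in df.columns:
        if col == gene_col:
            continue
        stage, _, rep = col.rpartition("_")
        if stage not in _STAGE_ORDER or not rep.isdigit():
            raise DataError(f"unknown stage/replicate column {col!r}")
        columns.append((stage, int(rep)))

    values = np.full((len(genes), len(columns)), np.nan)
    data_cols = [c for c in df.columns if c != gene_col]
    for j, col in enumerate(data_cols):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in ("", "NA"):
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataError(
                    f"non-numeric value {cell!r} at gene {genes[i]!r}, column {col!r}"
                ) from None

    frame = pd.DataFrame(
        values, index=pd.Index(genes, name="gene"),
        columns=pd.MultiIndex.from_tuples(columns, names=["stage", "replicate"]),
    )
    return ExpressionMatrix(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    flat = matrix.data.copy()
    flat.columns = [f"{s}_{r}" for s, r in flat.columns]
    flat.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


# ---------------------------------------------------------------------------
# CDS FASTA I/O
# ---------------------------------------------------------------------------

_CDS_ALPHABET = set("ACGT")
_PARSE_ALPHABET = set("ACGTUN")


def read_cds_fasta(path: str | Path, delimiter: str = "|") -> list[CdsRecord]:
    """Read coding sequences; headers are ``gene<delimiter>transcript``.

    Sequences are uppercased and U is mapped to T.  An entry containing
    characters outside {A,C,G,T,N} after mapping is retained but flagged
    ``alphabet_ok=False`` (quality control fails it later); an empty
    sequence is a hard error.
    """
    records: list[CdsRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise DataError(f"empty sequence for FASTA entry {rec.id!r}")
        if not set(seq) <= _PARSE_ALPHABET:
            bad = sorted(set(seq) - _PARSE_ALPHABET)
            raise DataError(f"illegal character(s) {bad} in FASTA entry {rec.id!r}")
        gene, _, transcript = rec.id.partition(delimiter)
        if not transcript:
            transcript = gene
        records.append(
            CdsRecord(gene=gene, transcript=transcript, sequence=seq,
                      alphabet_ok=set(seq) <= _CDS_ALPHABET)
        )
    return records


def write_cds_fasta(records: list[CdsRecord], path: str | Path,
                    delimiter: str = "|") -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"{r.gene}{delimiter}{r.transcript}",
                  description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Orthology / annotation / comparator-bias tables
# ---------------------------------------------------------------------------

_BOOL = {"0": False, "1": True, "true": True, "false": False}


def _parse_bool(cell: str, context: str) -> bool:
    try:
        return _BOOL[cell.strip().lower()]
    except KeyError:
        raise DataError(f"malformed boolean {cell!r} in {context}") from None


def read_orthology_table(path: str | Path) -> list[OrthologyRecord]:
    """Read columns gene / has_orth_ae / has_orth_dm / one2one_dm ('.' = none)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "has_orth_ae", "has_orth_dm", "one2one_dm"}
    if not required <= set(df.columns):
        raise DataError(f"orthology table must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        partner = row.one2one_dm.strip()
        records.append(
            OrthologyRecord(
                gene=row.gene,
                has_orth_ae=_parse_bool(row.has_orth_ae, f"gene {row.gene!r}"),
                has_orth_dm=_parse_bool(row.has_orth_dm, f"gene {row.gene!r}"),
                one2one_dm=None if partner in (".", "", "NA") else partner,
            )
        )
    return records


def write_orthology_table(records: list[OrthologyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "has_orth_ae": [int(r.has_orth_ae) for r in records],
            "has_orth_dm": [int(r.has_orth_dm) for r in records],
            "one2one_dm": [r.one2one_dm or "." for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_map(path: str | Path, namespace: str = "GO") -> AnnotationMap:
    """Read a long-format gene/term table (one pair per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene", "term"} <= set(df.columns):
        raise DataError("annotation table must have columns ['gene', 'term']")
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        if not row.term:
            raise DataError(f"empty term identifier for gene {row.gene!r}")
        mapping.setdefault(row.gene, set()).add(row.term)
    return AnnotationMap({g: frozenset(t) for g, t in mapping.items()}, namespace)


def write_annotation_map(ann: AnnotationMap, path: str | Path) -> None:
    rows = [(g, t) for g in sorted(ann.mapping) for t in sorted(ann.mapping[g])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


_FLY_CLASSES = {MALE, FEMALE, UNBIASED}


def read_fly_bias(path: str | Path) -> dict[str, str]:
    """Read the comparator-species sex-bias table: gene -> bias class."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene", "bias"} <= set(df.columns):
        raise DataError("comparator bias table must have columns ['gene', 'bias']")
    table: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.bias not in _FLY_CLASSES:
            raise DataError(f"unknown bias class {row.bias!r} for gene {row.gene!r}")
        if row.gene in table:
            raise DataError(f"duplicate comparator gene {row.gene!r}")
        table[row.gene] = row.bias
    return table


def write_fly_bias(table: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(table.items()), columns=["gene", "bias"]).to_csv(
        path, sep="\t", index=False
    )


def write_bias_profiles(profiles: list[BiasProfile], path: str | Path) -> None:
    """Emit gene, five mean ratios and five calls, tab-separated."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"gene": p.gene}
        for s in STAGES:
            row[f"ratio_{s}"] = p.mean_ratio.get(s, np.nan)
            row[f"call_{s}"] = p.call.get(s, UNDETERMINED)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", na_rep="NA", index=False)


def read_bias_profiles(path: str | Path) -> list[BiasProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    profiles = []
    for row in df.to_dict("records"):
        mean_ratio = {}
        call = {}
        for s in STAGES:
            cell = row[f"ratio_{s}"].strip()
            mean_ratio[s] = np.nan if cell in ("", "NA") else float(cell)
            call[s] = row[f"call_{s}"]
        profiles.append(BiasProfile(row["gene"], mean_ratio, call))
    return profiles
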