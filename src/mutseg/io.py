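"""Readers, writers and filtering rules for cohort tables.

Three tables make up a cohort: a somatic mutation table (MAF or a minimal
TSV dialect), a normalized expression matrix (genes x samples) and a
clinical table with disease-free-survival time and event flag.  All
positions are 1-based inclusive, matching the MAF convention.  Readers
accept plain or gzip-compressed TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "MutationRecord",
    "ExpressionMatrix",
    "ClinicalRecord",
    "Cohort",
    "CohortFormatError",
    "read_mutations",
    "write_mutations",
    "filter_mutations",
    "single_mutation_patients",
    "read_expression",
    "read_clinical",
    "write_clinical",
    "harmonize",
]


class CohortFormatError(ValueError):
    """Raised for malformed cohort input files."""


class VariantClass(str, Enum):
    silent = "silent"
    missense = "missense"
    nonsense = "nonsense"
    frameshift_ins = "frameshift_ins"
    frameshift_del = "frameshift_del"
    inframe_indel = "inframe_indel"
    splice = "splice"
    rna = "rna"
    other = "other"


#: MAF Variant_Classification values -> internal enum.  Anything absent from
#: this map is retained as ``other`` (never silently dropped): removing
#: silent/RNA calls is an explicit, separate filtering step.
MAF_CLASS_MAP: dict[str, VariantClass] = {
    "Silent": VariantClass.silent,
    "Missense_Mutation": VariantClass.missense,
    "Nonsense_Mutation": VariantClass.nonsense,
    "Frame_Shift_Ins": VariantClass.frameshift_ins,
    "Frame_Shift_Del": VariantClass.frameshift_del,
    "In_Frame_Ins": VariantClass.inframe_indel,
    "In_Frame_Del": VariantClass.inframe_indel,
    "Splice_Site": VariantClass.splice,
    "Splice_Region": VariantClass.splice,
    "RNA": VariantClass.rna,
}

_MAF_CLASS_INV = {
    VariantClass.silent: "Silent",
    VariantClass.missense: "Missense_Mutation",
    VariantClass.nonsense: "Nonsense_Mutation",
    VariantClass.frameshift_ins: "Frame_Shift_Ins",
    VariantClass.frameshift_del: "Frame_Shift_Del",
    VariantClass.inframe_indel: "In_Frame_Ins",
    VariantClass.splice: "Splice_Site",
    VariantClass.rna: "RNA",
    VariantClass.other: "Other",
}

_MAF_COLUMNS = [
    "Hugo_Symbol",
    "Variant_Classification",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
]

_SIMPLE_COLUMNS = [
    "sample_id",
    "gene",
    "genomic_position",
    "variant_class",
    "ref_allele",
    "alt_allele",
]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call.

    ``cdna_position`` is 1-based on the spliced transcript with position 1
    at the A of the start codon (so "cDNA:1006insG" means an insertion
    after coding position 1006).
    """

    sample_id: str
    gene: str
    genomic_position: int
    variant_class: VariantClass
    ref_allele: str
    alt_allele: str
    cdna_position: int | None = None
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.genomic_position < 1:
            raise ValueError(
                f"genomic_position must be >= 1, got {self.genomic_position}"
            )
        if self.ref_allele == "-" and self.alt_allele == "-":
            raise ValueError("ref and alt alleles may not both be '-'")
        if not isinstance(self.variant_class, VariantClass):
            object.__setattr__(
                self, "variant_class", VariantClass(self.variant_class)
            )


@dataclass
class ClinicalRecord:
    """Disease-free survival record: time in months, event = recurrence."""

    sample_id: str
    dfs_time: float
    dfs_event: bool

    def __post_init__(self) -> None:
        if self.dfs_time < 0:
            raise ValueError(f"dfs_time must be >= 0, got {self.dfs_time}")


class ExpressionMatrix:
    """Normalized expression, genes x samples, backed by a DataFrame.

    Values are unitless normalized abundances (e.g. RSEM); the analysis
    only ever uses them through a rank transform, so any monotone
    normalization is acceptable.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise CohortFormatError("duplicate gene ids in expression matrix")
        if values.columns.has_duplicates:
            raise CohortFormatError("duplicate sample ids in expression matrix")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise CohortFormatError("expression values must be finite")
        if (arr < 0).any():
            raise CohortFormatError("expression values must be >= 0")
        self._df = values

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def gene_values(self, gene: str, samples: Sequence[str]) -> np.ndarray:
        return self._df.loc[gene, list(samples)].to_numpy(dtype=float)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self._df.loc[:, list(samples)])

    def __contains__(self, gene: str) -> bool:
        return gene in self._df.index

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class Cohort:
    mutations: list[MutationRecord]
    expression: ExpressionMatrix
    clinical: list[ClinicalRecord] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def _parse_int(value, row: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError) as exc:
        raise CohortFormatError(
            f"row {row}: unparseable {column} value {value!r}"
        ) from exc


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return str(value)


def read_mutations(path: str | Path, dialect: str = "maf") -> list[MutationRecord]:
    """Read a mutation table.

    ``dialect`` is ``"maf"`` (TCGA MAF column names) or ``"simple_tsv"``
    (internal column names; the format the synthetic module writes).
    Unknown variant classifications map to ``other`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    records: list[MutationRecord] = []
    if dialect == "maf":
        _require_columns(df, _MAF_COLUMNS, path)
        for idx, row in enumerate(df.itertuples(index=False)):
            raw_class = getattr(row, "Variant_Classification")
            vclass = MAF_CLASS_MAP.get(raw_class)
            if vclass is None:
                log.warning(
                    "row %d: unknown Variant_Classification %r mapped to 'other'",
                    idx, raw_class,
                )
                vclass = VariantClass.other
            records.append(
                MutationRecord(
                    sample_id=str(getattr(row, "Tumor_Sample_Barcode")),
                    gene=str(getattr(row, "Hugo_Symbol")),
                    genomic_position=_parse_int(
                        getattr(row, "Start_Position"), idx, "Start_Position"
                    ),
                    variant_class=vclass,
                    ref_allele=str(getattr(row, "Reference_Allele")),
                    alt_allele=str(getattr(row, "Tumor_Seq_Allele2")),
                    cdna_position=_opt_int(getattr(row, "cDNA_Position", None)),
                    protein_change=_opt_str(getattr(row, "HGVSp_Short", None)),
                )
            )
    elif dialect == "simple_tsv":
        _require_columns(df, _SIMPLE_COLUMNS, path)
        for idx, row in enumerate(df.itertuples(index=False)):
            raw_class = getattr(row, "variant_class")
            try:
                vclass = VariantClass(raw_class)
            except ValueError:
                log.warning(
                    "row %d: unknown variant_class %r mapped to 'other'",
                    idx, raw_class,
                )
                vclass = VariantClass.other
            records.append(
                MutationRecord(
                    sample_id=str(getattr(row, "sample_id")),
                    gene=str(getattr(row, "gene")),
                    genomic_position=_parse_int(
                        getattr(row, "genomic_position"), idx, "genomic_position"
                    ),
                    variant_class=vclass,
                    ref_allele=str(getattr(row, "ref_allele")),
                    alt_allele=str(getattr(row, "alt_allele")),
                    cdna_position=_opt_int(getattr(row, "cdna_position", None)),
                    protein_change=_opt_str(getattr(row, "protein_change", None)),
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return records


def write_mutations(
    records: Sequence[MutationRecord], path: str | Path, dialect: str = "maf"
) -> None:
    """Write records to TSV in either dialect (inverse of :func:`read_mutations`).

    The MAF dialect carries ``cDNA_Position`` as an extra column so a
    round trip preserves all fields.
    """
    rows = []
    if dialect == "maf":
        for r in records:
            rows.append(
                {
                    "Hugo_Symbol": r.gene,
                    "Variant_Classification": _MAF_CLASS_INV[r.variant_class],
                    "Start_Position": r.genomic_position,
                    "Reference_Allele": r.ref_allele,
                    "Tumor_Seq_Allele2": r.alt_allele,
                    "Tumor_Sample_Barcode": r.sample_id,
                    "HGVSp_Short": r.protein_change or "",
                    "cDNA_Position": "" if r.cdna_position is None else r.cdna_position,
                }
            )
        cols = _MAF_COLUMNS + ["HGVSp_Short", "cDNA_Position"]
    elif dialect == "simple_tsv":
        for r in records:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "gene": r.gene,
                    "genomic_position": r.genomic_position,
                    "variant_class": r.variant_class.value,
                    "ref_allele": r.ref_allele,
                    "alt_allele": r.alt_allele,
                    "cdna_position": "" if r.cdna_position is None else r.cdna_position,
                    "protein_change": r.protein_change or "",
                }
            )
        cols = _SIMPLE_COLUMNS + ["cdna_position", "protein_change"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def filter_mutations(
    records: Sequence[MutationRecord],
    drop: set[VariantClass] | frozenset[VariantClass] = frozenset({VariantClass.silent}),
) -> list[MutationRecord]:
    """Remove variant classes excluded from the analysis, preserving order.

    Default drops silent calls; METABRIC-style cohorts additionally drop
    the noncoding "RNA" class.
    """
    drop = {VariantClass(d) for d in drop}
    return [r for r in records if r.variant_class not in drop]


def single_mutation_patients(
    records: Sequence[MutationRecord], gene: str
) -> dict[str, MutationRecord]:
    """Samples carrying exactly one retained mutation in ``gene``.

    Samples with two or more mutations in the gene are excluded entirely.
    Returns an empty mapping (with a log message) if the gene is absent.
    """
    per_sample: dict[str, list[MutationRecord]] = {}
    for r in records:
        if r.gene == gene:
            per_sample.setdefault(r.sample_id, []).append(r)
    if not per_sample:
        log.info("gene %s absent from mutation records", gene)
        return {}
    return {s: muts[0] for s, muts in per_sample.items() if len(muts) == 1}


def truncate_barcode(sample_id: str, length: int | None) -> str:
    return sample_id if length is None else sample_id[:length]


def harmonize(cohort: Cohort, barcode_length: int | None = 15) -> Cohort:
    """Intersect mutation/clinical sample ids with the expression matrix.

    TCGA mutation barcodes are longer than expression sample ids; the
    configurable prefix truncation (default: first 15 characters, the
    TCGA sample-level barcode) is applied to mutation and clinical ids
    before matching.  Raises if no sample overlaps.
    """
    expr_samples = set(cohort.expression.samples)
    mutations = []
    dropped_mut = 0
    for r in cohort.mutations:
        sid = truncate_barcode(r.sample_id, barcode_length)
        if sid in expr_samples:
            mutations.append(replace(r, sample_id=sid) if sid != r.sample_id else r)
        else:
            dropped_mut += 1
    clinical = []
    dropped_clin = 0
    for c in cohort.clinical:
        sid = truncate_barcode(c.sample_id, barcode_length)
        if sid in expr_samples:
            clinical.append(ClinicalRecord(sid, c.dfs_time, c.dfs_event))
        else:
            dropped_clin += 1
    if cohort.mutations and not mutations:
        raise CohortFormatError(
            "no mutation sample ids overlap the expression matrix after harmonization"
        )
    if dropped_mut or dropped_clin:
        log.info(
            "harmonize: dropped %d mutation and %d clinical records without "
            "expression data", dropped_mut, dropped_clin,
        )
    return Cohort(mutations=mutations, expression=cohort.expression, clinical=clinical)


def read_expression(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix.from_tsv(path)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "dfs_months", "dfs_event"], path)
    return [
        ClinicalRecord(
            sample_id=str(row.sample_id),
            dfs_time=float(row.dfs_months),
            dfs_event=bool(int(row.dfs_event)),
        )
        for row in df.itertuples(index=False)
    ]


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in records],
            "dfs_months": [c.dfs_time for c in records],
            "dfs_event": [int(c.dfs_event) for c in records],
        }
    ).to_csv(path, sep="\t", index=False)
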