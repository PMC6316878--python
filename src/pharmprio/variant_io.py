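"""Readers, writers and summaries for genotype, clinical and evidence tables.

Genotype calls are coded per (variant, sample) as

* ``0`` — common homozygote,
* ``1`` — heterozygote,
* ``2`` — rare homozygote,
* ``-1`` — missing (``NA`` in TSV, ``./.`` in VCF).

Codes coming straight off a VCF count non-reference alleles; use
:func:`orient_to_common` to flip sites where the non-reference allele is the
*major* allele in the analyzed cohort, so that downstream genotype groups are
always (common hom, het, rare hom).

Two on-disk dialects are supported:

* VCF 4.x, GT subfield only (via :mod:`pysam`); multi-allelic sites are
  rejected.
* A TSV matrix: variants as rows, samples as columns, first column
  ``variant_id``, cells in ``{0, 1, 2, NA}``.

Clinical and evidence tables are plain TSV with documented mandatory columns
(:data:`CLINICAL_COLUMNS`, :data:`EVIDENCE_COLUMNS`); unknown columns are
preserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from . import __version__

MISSING = -1
GENOTYPE_CODES = frozenset({0, 1, 2, MISSING})

GENOMIC_CLASSES = (
    "exonic",
    "intronic",
    "splicing",
    "UTR3",
    "UTR5",
    "upstream",
    "downstream",
    "intergenic",
    "ncRNA",
    "other",
)

EXONIC_CLASSES = (
    "synonymous SNV",
    "non-synonymous SNV",
    "stopgain",
    "stoploss",
    "frameshift insertion",
    "frameshift deletion",
    "non-frameshift insertion",
    "non-frameshift deletion",
    "unknown",
)

THERAPY_ARMS = ("neoadjuvant", "adjuvant", "hormonal_only", "none")
RESPONSE_VALUES = ("responder", "non-responder")
SUBTYPES = ("luminal A", "luminal B", "HER2", "triple negative")

CLINICAL_COLUMNS = (
    "sample_id",
    "arm",
    "response",
    "dfs_months",
    "dfs_event",
    "stage",
    "grade",
    "er",
    "pr",
    "her2",
    "subtype",
    "lost_to_followup",
)

#: Mandatory evidence columns; per-tool calls use "." (or empty) for missing.
EVIDENCE_COLUMNS = (
    "variant_id",
    "variant_class",
    "pharmgkb",
    "clinvar",
    "cancer_related",
    "mutation_assessor",
    "sift_score",
    "lrt_pred",
    "provean_pred",
    "cadd_phred",
    "dbscsnv_ada",
    "maxentscan_ref",
    "maxentscan_alt",
    "regulome_category",
    "pines_p",
    "iw_score",
    "mirna_site",
)


class ParseError(ValueError):
    """Malformed input row; message carries the 1-based line number."""


class SchemaError(ValueError):
    """Missing mandatory column or violated table invariant."""


class DuplicateIdError(ValueError):
    """Duplicate variant or sample identifier."""


class UnsupportedVariantError(ValueError):
    """Variant cannot be represented (e.g. multi-allelic site)."""


@dataclass
class GenotypeMatrix:
    """Variants x samples matrix of diploid genotype codes.

    ``calls`` is an int8 array of shape ``(len(variant_ids), len(sample_ids))``
    with values in ``{0, 1, 2, -1}``.
    """

    variant_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.sample_ids = list(self.sample_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise DuplicateIdError("duplicate variant ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdError("duplicate sample ids")
        if self.calls.shape != (len(self.variant_ids), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variant_ids)} variants x {len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.calls[bad])}")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id: {variant_id}") from None

    def row(self, variant_id: str) -> np.ndarray:
        """Calls for one variant, ordered as ``sample_ids``."""
        return self.calls[self.variant_index(variant_id)]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(self.variant_ids, sample_ids, self.calls[:, idx])

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(variant_ids, self.sample_ids, self.calls[idx, :])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.variant_ids, columns=self.sample_ids)


def nonref_allele_frequency(calls: np.ndarray) -> float:
    """Non-reference allele frequency over non-missing calls (NaN if none)."""
    calls = np.asarray(calls)
    informative = calls[calls != MISSING]
    if informative.size == 0:
        return float("nan")
    return float(informative.sum() / (2 * informative.size))


def orient_to_common(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Flip codes at sites where the non-reference allele is the major allele.

    Returns the oriented matrix and the list of flipped variant ids.  After
    orientation code 0 is always the *common* homozygote in this cohort, which
    is the grouping every downstream test assumes.  Orientation should be fixed
    once on the full cohort before any subsetting.
    """
    calls = matrix.calls.copy()
    flipped: list[str] = []
    for i, vid in enumerate(matrix.variant_ids):
        af = nonref_allele_frequency(calls[i])
        if np.isfinite(af) and af > 0.5:
            row = calls[i]
            mask = row != MISSING
            row[mask] = 2 - row[mask]
            flipped.append(vid)
    return GenotypeMatrix(matrix.variant_ids, matrix.sample_ids, calls), flipped


# ---------------------------------------------------------------------------
# genotype matrix I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    ``format`` is ``"tsv"`` (matrix dialect) or ``"vcf"`` (GT subfield only;
    both ``/`` and ``|`` separators accepted; multi-allelic sites rejected).
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty genotype matrix")
    header = lines[0].rstrip("\n").split("\t")
    if not header or header[0] != "variant_id":
        raise SchemaError(f"{path}: first column must be 'variant_id'")
    sample_ids = header[1:]
    variant_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        variant_ids.append(fields[0])
        row = []
        for val in fields[1:]:
            val = val.strip()
            if val in ("NA", "", "."):
                row.append(MISSING)
            elif val in ("0", "1", "2"):
                row.append(int(val))
            else:
                raise ParseError(f"{path}: line {lineno}: invalid genotype code {val!r}")
        rows.append(row)
    if len(set(variant_ids)) != len(variant_ids):
        dups = sorted({v for v in variant_ids if variant_ids.count(v) > 1})
        raise DuplicateIdError(f"{path}: duplicate variant ids: {dups}")
    return GenotypeMatrix(variant_ids, sample_ids, np.array(rows, dtype=np.int8))


def _read_genotypes_vcf(path: str) -> GenotypeMatrix:
    vcf = pysam.VariantFile(path)
    sample_ids = list(vcf.header.samples)
    variant_ids: list[str] = []
    rows: list[list[int]] = []
    for rec in vcf:
        vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0] if rec.alts else '.'}"
        if rec.alts is not None and len(rec.alts) > 1:
            raise UnsupportedVariantError(f"multi-allelic site not supported: {vid}")
        row = []
        for s in sample_ids:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                row.append(MISSING)
            else:
                row.append(int(sum(1 for a in gt if a != 0)))
        variant_ids.append(vid)
        rows.append(row)
    vcf.close()
    if len(set(variant_ids)) != len(variant_ids):
        raise DuplicateIdError(f"{path}: duplicate variant ids")
    return GenotypeMatrix(variant_ids, sample_ids, np.array(rows, dtype=np.int8))


def _header_comment(seed: int | None) -> str:
    tail = f" seed={seed}" if seed is not None else ""
    return f"# pharmprio {__version__}{tail}\n"


def write_genotypes(
    matrix: GenotypeMatrix, path: str, format: str = "tsv", seed: int | None = None
) -> None:
    """Write a genotype matrix; the inverse of :func:`read_genotypes`."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(_header_comment(seed))
            fh.write("variant_id\t" + "\t".join(matrix.sample_ids) + "\n")
            for vid, row in zip(matrix.variant_ids, matrix.calls):
                cells = ["NA" if g == MISSING else str(int(g)) for g in row]
                fh.write(vid + "\t" + "\t".join(cells) + "\n")
    elif format == "vcf":
        _write_genotypes_vcf(matrix, path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_genotypes_vcf(matrix: GenotypeMatrix, path: str) -> None:
    # Minimal synthetic VCF: placeholder chrom/pos/alleles, GT only.
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source=pharmprio-{__version__}\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("##contig=<ID=1>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids)
        + "\n"
    )
    for i, (vid, row) in enumerate(zip(matrix.variant_ids, matrix.calls), start=1):
        gts = "\t".join(_VCF_GT[int(g)] for g in row)
        buf.write(f"1\t{i}\t{vid}\tA\tG\t.\t.\t.\tGT\t{gts}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# variant records and class summaries
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """Annotation for one variant; ``rs_id is None`` marks a novel variant."""

    id: str
    gene: str = ""
    rs_id: str | None = None
    genomic_class: str = "other"
    exonic_class: str | None = None
    allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.genomic_class not in GENOMIC_CLASSES:
            self.genomic_class = "other"
        if self.exonic_class is not None and self.genomic_class != "exonic":
            raise ValueError(
                f"{self.id}: exonic class set but genomic class is {self.genomic_class!r}"
            )
        if self.allele_freq is not None and not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError(f"{self.id}: allele_freq {self.allele_freq} outside [0,1]")

    @property
    def novel(self) -> bool:
        return self.rs_id is None


@dataclass
class ClassSummary:
    """Per-class counts and one-decimal percentages of a variant set."""

    level: str
    total: int
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.counts),
                "count": list(self.counts.values()),
                "percentage": [self.percentages[c] for c in self.counts],
            }
        )


def summarize_classes(records: list[VariantRecord], level: str = "genomic") -> ClassSummary:
    """Count variants per functional class with percentages to one decimal.

    ``level="genomic"`` tabulates ``genomic_class`` over all records;
    ``level="exonic"`` tabulates ``exonic_class`` over exonic records only
    (the exonic total is the percentage denominator).
    """
    if level == "genomic":
        labels = [r.genomic_class for r in records]
    elif level == "exonic":
        labels = [
            r.exonic_class or "unknown" for r in records if r.genomic_class == "exonic"
        ]
    else:
        raise ValueError(f"unknown summary level: {level!r}")
    total = len(labels)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    counts = dict(sorted(counts.items()))
    percentages = {
        c: round(100.0 * n / total, 1) if total else 0.0 for c, n in counts.items()
    }
    return ClassSummary(level=level, total=total, counts=counts, percentages=percentages)


@dataclass
class NovelCounts:
    n_novel: int
    n_total: int
    fraction: float
    per_group: dict[str, int] = field(default_factory=dict)
    per_group_per_gene: dict[str, float] = field(default_factory=dict)


def count_novel(
    records: list[VariantRecord],
    gene_groups: dict[str, str] | None = None,
    genes_per_group: dict[str, int] | None = None,
) -> NovelCounts:
    """Count novel records (no rs id), overall and optionally per gene group.

    ``gene_groups`` maps gene symbol -> group name; ``genes_per_group`` gives
    the number of genes in each group, used to normalize per-group counts to
    novel variants per gene.
    """
    novel = [r for r in records if r.novel]
    per_group: dict[str, int] = {}
    if gene_groups:
        for r in novel:
            grp = gene_groups.get(r.gene)
            if grp is not None:
                per_group[grp] = per_group.get(grp, 0) + 1
    per_gene: dict[str, float] = {}
    if genes_per_group:
        for grp, n in per_group.items():
            denom = genes_per_group.get(grp, 0)
            if denom > 0:
                per_gene[grp] = n / denom
    frac = len(novel) / len(records) if records else 0.0
    return NovelCounts(len(novel), len(records), frac, per_group, per_gene)


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """Per-sample outcomes and covariates, schema-validated.

    Invariants: ``response`` is set only for neoadjuvant samples; DFS fields
    are absent iff the sample is lost to follow-up.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"clinical table missing columns: {missing_cols}")
        if df["sample_id"].duplicated().any():
            raise DuplicateIdError("duplicate sample ids in clinical table")
        bad_arm = ~df["arm"].isin(THERAPY_ARMS)
        if bad_arm.any():
            raise SchemaError(f"invalid therapy arm values: {df.loc[bad_arm, 'arm'].unique()}")
        has_resp = df["response"].notna() & (df["response"] != "")
        bad_resp_val = has_resp & ~df["response"].isin(RESPONSE_VALUES)
        if bad_resp_val.any():
            raise SchemaError(
                f"invalid response values: {df.loc[bad_resp_val, 'response'].unique()}"
            )
        misplaced = has_resp & (df["arm"] != "neoadjuvant")
        if misplaced.any():
            ids = df.loc[misplaced, "sample_id"].tolist()
            raise SchemaError(f"response set for non-neoadjuvant samples: {ids}")
        lost = df["lost_to_followup"].astype(bool)
        has_dfs = df["dfs_months"].notna()
        if (lost & has_dfs).any():
            raise SchemaError("dfs_months present for samples lost to follow-up")
        if (~lost & ~has_dfs).any():
            raise SchemaError("dfs_months absent for samples not lost to follow-up")
        if (df.loc[has_dfs, "dfs_months"] < 0).any():
            raise SchemaError("negative dfs_months")

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def neoadjuvant_with_response(self) -> pd.DataFrame:
        df = self.data
        mask = (df["arm"] == "neoadjuvant") & df["response"].isin(RESPONSE_VALUES)
        return df.loc[mask]

    def with_followup(self) -> pd.DataFrame:
        return self.data.loc[~self.data["lost_to_followup"].astype(bool)]


def read_clinical(path: str) -> ClinicalTable:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"sample_id": str, "response": str, "subtype": str},
        keep_default_na=True,
    )
    if "response" in df.columns:
        df["response"] = df["response"].where(df["response"].notna(), None)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        table.data.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evidence table
# ---------------------------------------------------------------------------

def read_evidence(path: str) -> pd.DataFrame:
    """Read the per-variant evidence TSV; "." cells become NaN/missing."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."], dtype={"variant_id": str})
    missing_cols = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"evidence table missing columns: {missing_cols}")
    if df["variant_id"].duplicated().any():
        raise DuplicateIdError("duplicate variant ids in evidence table")
    return df


def write_evidence(df: pd.DataFrame, path: str, seed: int | None = None) -> None:
    missing_cols = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"evidence table missing columns: {missing_cols}")
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# generic report writer
# ---------------------------------------------------------------------------

def write_report(df: pd.DataFrame, path: str, seed: int | None = None) -> None:
    """Write a results table as TSV (or JSON if ``path`` ends in .json).

    Numeric columns keep full precision (repr round-trip).
    """
    if path.endswith(".json"):
        df.to_json(path, orient="records", indent=2, double_precision=15)
        return
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index=False, float_format=None)


def read_report(path: str) -> pd.DataFrame:
    if path.endswith(".json"):
        return pd.read_json(path, orient="records")
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
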