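"""Readers and writers for the on-disk formats the tool consumes and produces.

Genotypes arrive as a PLINK 1 BED/BIM/FAM triplet (SNP-major, 2-bit encoded);
expression, covariates, gene annotations and results are plain TSV. The
in-memory data model defined here (:class:`GenotypeMatrix`,
:class:`ExpressionMatrix`, :class:`CovariateMatrix`, :class:`GeneAnnotation`)
is shared by every downstream module.

Dosage dialect: a dosage counts copies of the BIM *allele1* (the A1 allele,
conventionally the minor allele in PLINK 1.9 output). Orientation does not
affect any statistic computed downstream because genotype columns are
standardized per split, but it is fixed here for reproducibility.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "CovariateMatrix",
    "GeneAnnotation",
    "read_plink",
    "write_plink",
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 magic + SNP-major flag

# 2-bit PLINK codes, little-endian within a byte:
#   00 -> homozygous A1 (dosage 2), 01 -> missing (NaN),
#   10 -> heterozygous (dosage 1), 11 -> homozygous A2 (dosage 0)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """Raised when an input file is structurally invalid."""


def _build_decode_table() -> np.ndarray:
    table = np.empty((256, 4), dtype=np.float64)
    for byte in range(256):
        for k in range(4):
            table[byte, k] = _CODE_TO_DOSAGE[(byte >> (2 * k)) & 0b11]
    return table


_DECODE = _build_decode_table()


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with per-variant metadata.

    ``dosages`` holds allele counts in {0, 1, 2}; missing calls are NaN and
    are summarized by :meth:`missing_counts` (variant QC removes any column
    with a missing call, so downstream code may assume a complete matrix).
    ``variants`` is a DataFrame with columns ``id, chrom, pos, a1, a2``.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if m != len(self.variants):
            raise ValueError("variant table length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_counts(self) -> np.ndarray:
        """Number of missing calls per variant."""
        return np.isnan(self.dosages).sum(axis=0)

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[idx].reset_index(drop=True)
            if idx.dtype == bool or idx.dtype.kind in "iu"
            else self.variants.loc[idx].reset_index(drop=True),
        )

    def subset_samples(self, row_index) -> "GenotypeMatrix":
        idx = np.asarray(row_index)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            sample_ids=self.sample_ids[idx],
            variants=self.variants,
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of expression measurements."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    def gene_vector(self, gene_id: str) -> np.ndarray:
        rows = np.flatnonzero(self.gene_ids == gene_id)
        if len(rows) != 1:
            raise KeyError(f"gene {gene_id!r} not found")
        return self.values[rows[0]]


@dataclass
class CovariateMatrix:
    """Sample x covariate matrix; an intercept is implicit downstream."""

    values: np.ndarray
    sample_ids: np.ndarray
    covariate_names: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.covariate_names = np.asarray(self.covariate_names, dtype=object)
        if self.values.shape != (len(self.sample_ids), len(self.covariate_names)):
            raise ValueError("values shape does not match sample/covariate names")


@dataclass(frozen=True)
class GeneAnnotation:
    """Transcribed-region coordinates for one gene (1-based, inclusive).

    ``tss``/``tes`` are canonicalized so that tss <= tes; the symmetric
    flanking window used downstream makes strand irrelevant.
    """

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.tss > self.tes:
            lo, hi = self.tes, self.tss
            object.__setattr__(self, "tss", lo)
            object.__setattr__(self, "tes", hi)

    @staticmethod
    def canonical(gene_id, chrom, tss, tes, strand=None) -> "GeneAnnotation":
        lo, hi = (int(tss), int(tes)) if tss <= tes else (int(tes), int(tss))
        return GeneAnnotation(str(gene_id), str(chrom), lo, hi, strand)


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM
# ---------------------------------------------------------------------------

def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK 1 binary triplet ``prefix``.bed/.bim/.fam.

    Samples are ordered as in the .fam file, variants as in the .bim file.
    Dosages count copies of the BIM allele1; missing calls decode to NaN.
    """
    prefix = os.fspath(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"missing PLINK file: {prefix + ext}")

    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    sample_ids = fam["iid"].to_numpy(dtype=object)
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )

    n, m = len(sample_ids), len(variants)
    bytes_per_variant = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise FormatError(
                f"{prefix}.bed: bad magic bytes {magic!r} (expected SNP-major PLINK 1 BED)"
            )
        packed = np.frombuffer(fh.read(), dtype=np.uint8)
    if packed.size != m * bytes_per_variant:
        raise FormatError(
            f"{prefix}.bed: expected {m * bytes_per_variant} data bytes, found {packed.size}"
        )
    decoded = _DECODE[packed.reshape(m, bytes_per_variant)]  # (m, bpv, 4)
    dosages = decoded.reshape(m, bytes_per_variant * 4)[:, :n].T.copy()
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, variants=variants)


def write_plink(prefix: str | os.PathLike, G: GenotypeMatrix) -> None:
    """Write ``G`` as a PLINK 1 BED/BIM/FAM triplet (inverse of read_plink)."""
    prefix = os.fspath(prefix)
    n, m = G.dosages.shape

    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": "0",
            "mother": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": G.variants["chrom"],
            "id": G.variants["id"],
            "cm": 0,
            "pos": G.variants["pos"],
            "a1": G.variants["a1"],
            "a2": G.variants["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    # dosage -> 2-bit code
    codes = np.full(G.dosages.shape, 0b01, dtype=np.uint8)  # missing
    codes[G.dosages == 2] = 0b00
    codes[G.dosages == 1] = 0b10
    codes[G.dosages == 0] = 0b11

    bytes_per_variant = (n + 3) // 4
    # trailing pad bits of the final byte are zero, as PLINK writes them;
    # they are ignored on read because decoding slices to n samples
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(m, bytes_per_variant, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# TSV formats
# ---------------------------------------------------------------------------

def _read_numeric_tsv(path: str | os.PathLike, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate {kind} ids {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise FormatError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    return df


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (first column = gene ids)."""
    df = _read_numeric_tsv(path, "gene")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        gene_ids=df.index.to_numpy(dtype=object),
        sample_ids=df.columns.to_numpy(dtype=object),
    )


def write_expression(path: str | os.PathLike, expr: ExpressionMatrix) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_covariates(path: str | os.PathLike) -> CovariateMatrix:
    """Read a samples x covariates TSV (first column = sample ids)."""
    df = _read_numeric_tsv(path, "sample")
    return CovariateMatrix(
        values=df.to_numpy(dtype=np.float64),
        sample_ids=df.index.to_numpy(dtype=object),
        covariate_names=df.columns.to_numpy(dtype=object),
    )


def write_covariates(path: str | os.PathLike, cov: CovariateMatrix) -> None:
    df = pd.DataFrame(cov.values, index=cov.sample_ids, columns=cov.covariate_names)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation(path: str | os.PathLike) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV with columns gene_id, chrom, tss, tes[, strand].

    Coordinates are 1-based inclusive. TSS/TES are swapped if reversed so
    the stored interval always satisfies tss <= tes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "tes"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation must have columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids in annotation")
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand", None)
        out[row.gene_id] = GeneAnnotation.canonical(
            row.gene_id, row.chrom, int(row.tss), int(row.tes), strand
        )
    return out


def write_annotation(path: str | os.PathLike, annots: list[GeneAnnotation]) -> None:
    pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annots],
            "chrom": [a.chrom for a in annots],
            "tss": [a.tss for a in annots],
            "tes": [a.tes for a in annots],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return genes


RESULT_COLUMNS = [
    "gene_id",
    "n_train",
    "n_test",
    "delta_loss",
    "t_boot",
    "df",
    "p_boot",
    "t_cond",
    "p_cond",
    "n_snps_selected_a",
    "n_snps_selected_b",
    "status",
]


def write_results(path: str | os.PathLike, results: list) -> None:
    """Write per-gene test results as a TSV with a fixed column order.

    ``results`` is a non-empty list of objects exposing the RESULT_COLUMNS
    fields (see boottest.GeneTestResult). Floats are serialized with full
    precision so a read-back round-trips to 1e-12.
    """
    if not results:
        raise ValueError("results must be non-empty")
    rows = {col: [getattr(r, col) for r in results] for col in RESULT_COLUMNS}
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "status": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    return df
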