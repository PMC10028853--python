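"""Variant-level quality control on dosage data.

Filters applied (each an independent per-variant predicate):

* autosomal chromosome code (1-22),
* standard single-character allele codes (A/C/G/T),
* no missing calls,
* exact Hardy-Weinberg mid-p >= threshold (default 1e-6),
* minor allele frequency >= threshold (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io_formats import GenotypeMatrix

__all__ = [
    "GenotypeCounts",
    "minor_allele_frequency",
    "hwe_midp",
    "genotype_counts",
    "apply_variant_qc",
    "QCReport",
]

_AUTOSOMES = {str(c) for c in range(1, 23)}
_STANDARD_ALLELES = {"A", "C", "G", "T"}

# report categories, in the order the filters are conventionally described
_FILTERS = ("non_autosomal", "allele_code", "missing", "hwe", "maf")


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts at a biallelic site."""

    n_hom_a1: int
    n_het: int
    n_hom_a2: int

    def __post_init__(self) -> None:
        if min(self.n_hom_a1, self.n_het, self.n_hom_a2) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total == 0:
            raise ValueError("at least one genotype required")

    @property
    def total(self) -> int:
        return self.n_hom_a1 + self.n_het + self.n_hom_a2


def minor_allele_frequency(column: np.ndarray) -> float:
    """Minor allele frequency of a dosage vector: min(f, 1 - f), f = mean/2."""
    column = np.asarray(column, dtype=np.float64)
    if column.size == 0:
        raise ValueError("empty dosage vector")
    f = np.nanmean(column) / 2.0
    return float(min(f, 1.0 - f))


def genotype_counts(column: np.ndarray) -> GenotypeCounts:
    """Tabulate a dosage column (ignoring NaN) into genotype counts."""
    column = np.asarray(column, dtype=np.float64)
    obs = column[~np.isnan(column)]
    return GenotypeCounts(
        n_hom_a1=int(np.sum(obs == 2)),
        n_het=int(np.sum(obs == 1)),
        n_hom_a2=int(np.sum(obs == 0)),
    )


def _het_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count.

    Given ``n`` diploid individuals carrying ``n_minor`` copies of the minor
    allele, the heterozygote count h ranges over values with the same parity
    as n_minor, with

        P(h) = n! * n_minor! * n_major! * 2^h
               / [ ((n_minor-h)/2)! * h! * ((n_major-h)/2)! * (2n)! ]

    Returns (support, log-probabilities).
    """
    n_major = 2 * n - n_minor
    h_max = min(n_minor, n_major)
    support = np.arange(n_minor % 2, h_max + 1, 2)
    logp = (
        support * np.log(2.0)
        + gammaln(n + 1)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln((n_minor - support) / 2 + 1)
        - gammaln(support + 1)
        - gammaln((n_major - support) / 2 + 1)
        - gammaln(2 * n + 1)
    )
    # renormalize in log space to absorb rounding
    m = logp.max()
    logp -= m + np.log(np.exp(logp - m).sum())
    return support, logp


def hwe_midp(counts: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg test mid-p value.

    The two-sided exact p-value sums the probabilities of all heterozygote
    counts (conditional on the observed allele counts) that are no more
    probable than the observed one; the mid-p adjustment subtracts half the
    observed table's probability.
    """
    n = counts.total
    n_a1 = 2 * counts.n_hom_a1 + counts.n_het
    n_minor = min(n_a1, 2 * n - n_a1)
    support, logp = _het_log_probs(n, n_minor)
    probs = np.exp(logp)
    obs_idx = np.flatnonzero(support == counts.n_het)
    if obs_idx.size != 1:  # parity mismatch cannot happen for valid counts
        raise ValueError("inconsistent genotype counts")
    p_obs = probs[obs_idx[0]]
    p_two = probs[probs <= p_obs * (1 + 1e-12)].sum()
    midp = p_two - 0.5 * p_obs
    return float(min(max(midp, np.nextafter(0, 1)), 1.0))


@dataclass
class QCReport:
    """Per-filter removal counts plus totals."""

    removed: dict
    n_input: int
    n_kept: int

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [{"filter": k, "n_removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "kept", "n_removed": self.n_kept})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_variant_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply all variant filters to ``G`` and return the surviving matrix.

    The filters are independent predicates, so their order cannot change the
    surviving set; removal counts are reported sequentially in the order
    listed in the module docstring (each variant counted once, at the first
    filter that rejects it).
    """
    if not (0 <= maf_min <= 1 and 0 <= hwe_p_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")

    m = G.n_variants
    chrom = G.variants["chrom"].to_numpy(dtype=object)
    a1 = G.variants["a1"].to_numpy(dtype=object)
    a2 = G.variants["a2"].to_numpy(dtype=object)

    autosomal = np.array([str(c) in _AUTOSOMES for c in chrom])
    good_alleles = np.array(
        [str(x) in _STANDARD_ALLELES and str(y) in _STANDARD_ALLELES for x, y in zip(a1, a2)]
    )
    complete = G.missing_counts() == 0

    maf_ok = np.zeros(m, dtype=bool)
    hwe_ok = np.zeros(m, dtype=bool)
    for j in range(m):
        col = G.dosages[:, j]
        maf_ok[j] = minor_allele_frequency(col) >= maf_min
        hwe_ok[j] = hwe_midp(genotype_counts(col)) >= hwe_p_min

    predicates = {
        "non_autosomal": autosomal,
        "allele_code": good_alleles,
        "missing": complete,
        "hwe": hwe_ok,
        "maf": maf_ok,
    }
    keep = np.ones(m, dtype=bool)
    removed = {}
    surviving = np.ones(m, dtype=bool)
    for name in _FILTERS:
        ok = predicates[name]
        removed[name] = int(np.sum(surviving & ~ok))
        surviving &= ok
        keep &= ok

    report = QCReport(removed=removed, n_input=m, n_kept=int(keep.sum()))
    if not keep.any():
        raise ValueError(f"all {m} variants removed by QC: {removed}")
    return G.subset_variants(keep), report
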