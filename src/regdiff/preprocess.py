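"""Per-gene data preparation: sample splits, cis-window extraction,
covariate residualization, monomorphic pruning and standardization.

Two equally sized training sets and a disjoint test set are formed once per
run; for every gene, the dosages inside the gene's flanking window and the
expression vector are then adjusted *independently within each split* so
that no statistic leaks between training and test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypeMatrix, GeneAnnotation

__all__ = [
    "SplitAssignment",
    "AdjustedGeneData",
    "UntestableGeneError",
    "make_splits",
    "cis_window",
    "extract_cis",
    "residualize",
    "standardize_and_prune",
]

MEAN_TOL = 1e-10
VAR_TOL = 1e-8


class UntestableGeneError(ValueError):
    """Raised when a gene cannot be tested (no cis variants, constant expression)."""


@dataclass
class SplitAssignment:
    """Index sets for the two training splits and the test split.

    Invariants (checked by :meth:`validate`): the test set is disjoint from
    both training sets; the training sets have equal cardinality; the
    training sets may overlap each other only when ``allow_overlap`` is set.
    """

    idx_a: np.ndarray
    idx_b: np.ndarray
    idx_t: np.ndarray
    allow_overlap: bool = field(default=False)

    def __post_init__(self) -> None:
        self.idx_a = np.asarray(self.idx_a, dtype=np.intp)
        self.idx_b = np.asarray(self.idx_b, dtype=np.intp)
        self.idx_t = np.asarray(self.idx_t, dtype=np.intp)
        self.validate()

    def validate(self) -> None:
        a, b, t = set(self.idx_a.tolist()), set(self.idx_b.tolist()), set(self.idx_t.tolist())
        if len(a) != len(self.idx_a) or len(b) != len(self.idx_b) or len(t) != len(self.idx_t):
            raise ValueError("split index sets contain duplicates")
        if len(self.idx_a) != len(self.idx_b):
            raise ValueError(
                f"training sets must have equal size (got {len(self.idx_a)} and {len(self.idx_b)})"
            )
        if t & (a | b):
            raise ValueError("test set overlaps a training set")
        if (a & b) and not self.allow_overlap:
            raise ValueError("training sets overlap but overlap was not configured")

    @property
    def n_train(self) -> int:
        return len(self.idx_a)

    @property
    def n_test(self) -> int:
        return len(self.idx_t)


def make_splits(
    sample_ids,
    mode: str = "auto",
    seed: int = 0,
    overlap_fraction: float = 0.0,
    min_test_fraction: float = 0.25,
    n_train: int | None = None,
    n_test: int | None = None,
    custom: tuple | None = None,
) -> SplitAssignment:
    """Partition samples into training sets A/B and a test set.

    ``auto`` maximizes the (equal) training-set sizes subject to reserving at
    least ``min_test_fraction`` of the samples for testing; ``thirds`` forms
    three equal disjoint subsets (the negative-control design); ``custom``
    validates user-provided index sets. ``overlap_fraction`` makes the two
    training sets share that fraction of their members (1.0 means A == B);
    the test set always stays disjoint. Explicit ``n_train``/``n_test``
    override the automatic sizing. Deterministic given ``seed``.
    """
    n = len(sample_ids)
    if mode == "custom":
        if custom is None:
            raise ValueError("custom mode requires explicit index sets")
        idx_a, idx_b, idx_t = custom
        return SplitAssignment(idx_a, idx_b, idx_t, allow_overlap=overlap_fraction > 0)
    if n < 9:
        raise ValueError("at least 9 samples are required to form splits")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)

    if mode == "thirds":
        if overlap_fraction != 0.0:
            raise ValueError("thirds mode is disjoint by construction")
        k = n // 3
        return SplitAssignment(perm[:k], perm[k : 2 * k], perm[2 * k : 3 * k])
    if mode != "auto":
        raise ValueError(f"unknown split mode {mode!r}")

    if n_train is not None:
        m = int(n_train)
    else:
        reserve = int(np.ceil(n * min_test_fraction)) if n_test is None else int(n_test)
        # m training members per side, sharing s = round(f*m): distinct
        # training samples used = 2m - s <= n - reserve
        m = int((n - reserve) / (2.0 - overlap_fraction))
    s = int(round(overlap_fraction * m))
    distinct = 2 * m - s
    if n_test is not None:
        t_size = int(n_test)
    else:
        t_size = n - distinct
    if distinct + t_size > n or m < 1 or t_size < 1:
        raise ValueError("requested split sizes exceed available samples")

    shared = perm[:s]
    idx_a = np.concatenate([shared, perm[s : s + (m - s)]])
    idx_b = np.concatenate([shared, perm[s + (m - s) : distinct]])
    idx_t = perm[distinct : distinct + t_size]
    return SplitAssignment(idx_a, idx_b, idx_t, allow_overlap=overlap_fraction > 0)


def cis_window(gene: GeneAnnotation, window_bp: int = 500_000) -> tuple[str, int, int]:
    """Flanking window around the transcribed region, 1-based inclusive.

    Extends ``window_bp`` upstream of the TSS and downstream of the TES,
    clipped at position 1.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    if gene.tss > gene.tes:
        raise ValueError(f"gene {gene.gene_id}: tss > tes after canonicalization")
    return gene.chrom, max(1, gene.tss - window_bp), gene.tes + window_bp


def extract_cis(G: GenotypeMatrix, interval: tuple[str, int, int]) -> GenotypeMatrix:
    """Columns of ``G`` whose position lies within the closed interval."""
    chrom, start, end = interval
    pos = G.variants["pos"].to_numpy()
    on_chrom = G.variants["chrom"].to_numpy(dtype=object) == str(chrom)
    mask = on_chrom & (pos >= start) & (pos <= end)
    return G.subset_variants(mask)


def residualize(values: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of each column of ``values`` on [1, C].

    ``C`` is a samples x covariates array (or None/empty for intercept-only
    adjustment, i.e. column centering). Rank-deficient covariate sets are
    handled by projecting onto the column space (dependent directions carry
    no extra information); a warning is emitted.
    """
    values = np.asarray(values, dtype=np.float64)
    squeeze = values.ndim == 1
    V = values[:, None] if squeeze else values
    n = V.shape[0]
    if C is None or (hasattr(C, "size") and np.asarray(C).size == 0):
        D = np.ones((n, 1))
    else:
        C = np.asarray(C, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows do not align with value rows")
        # drop constant covariates (the explicit intercept covers them)
        keep = C.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance covariate(s)", stacklevel=2
            )
        D = np.column_stack([np.ones(n), C[:, keep]])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            warnings.warn("covariate matrix is rank deficient; projecting onto its span",
                          stacklevel=2)
    coef, *_ = np.linalg.lstsq(D, V, rcond=None)
    resid = V - D @ coef
    return resid[:, 0] if squeeze else resid


def _standardize(M: np.ndarray) -> np.ndarray:
    """Scale columns to mean 0, sample variance 1 (ddof=1)."""
    M = M - M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    return M / sd


@dataclass
class AdjustedGeneData:
    """Residualized, standardized per-split genotype and expression data."""

    x_a: np.ndarray
    y_a: np.ndarray
    x_b: np.ndarray
    y_b: np.ndarray
    x_t: np.ndarray
    y_t: np.ndarray
    variant_ids: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


def standardize_and_prune(
    raw_x: dict[str, np.ndarray],
    raw_y: dict[str, np.ndarray],
    covars: dict[str, np.ndarray | None],
    variant_ids,
) -> AdjustedGeneData:
    """Residualize, prune and standardize per-split data for one gene.

    ``raw_x``/``raw_y``/``covars`` map split labels 'A', 'B', 'T' to raw
    dosage matrices, raw expression vectors and covariate matrices. A
    variant monomorphic (zero dosage variance) in *any* split is removed
    from *all* splits so both models see identical features; the same
    harmonization is applied to columns whose post-residualization variance
    collapses. Raises :class:`UntestableGeneError` when no variants survive
    or expression is constant within a split.
    """
    variant_ids = np.asarray(variant_ids, dtype=object)
    splits = ("A", "B", "T")
    if variant_ids.size == 0:
        raise UntestableGeneError("no cis variants")
    for s in splits:
        y = np.asarray(raw_y[s], dtype=np.float64)
        if np.std(y) == 0:
            raise UntestableGeneError(f"expression constant within split {s}")

    keep = np.ones(variant_ids.size, dtype=bool)
    for s in splits:
        keep &= np.asarray(raw_x[s]).std(axis=0) > 0
    if not keep.any():
        raise UntestableGeneError("all cis variants monomorphic in some split")

    adj_x, adj_y = {}, {}
    for s in splits:
        rx = residualize(np.asarray(raw_x[s], dtype=np.float64)[:, keep], covars[s])
        ry = residualize(np.asarray(raw_y[s], dtype=np.float64), covars[s])
        if np.std(ry, ddof=1) == 0:
            raise UntestableGeneError(f"expression constant after adjustment in split {s}")
        adj_x[s], adj_y[s] = rx, ry

    # residualization can collapse a column that had raw variance
    fine = np.ones(int(keep.sum()), dtype=bool)
    for s in splits:
        fine &= adj_x[s].std(axis=0, ddof=1) > 1e-12
    if not fine.any():
        raise UntestableGeneError("all cis variants degenerate after adjustment")

    out_x = {s: _standardize(adj_x[s][:, fine]) for s in splits}
    out_y = {s: _standardize(adj_y[s][:, None])[:, 0] for s in splits}
    return AdjustedGeneData(
        x_a=out_x["A"],
        y_a=out_y["A"],
        x_b=out_x["B"],
        y_b=out_y["B"],
        x_t=out_x["T"],
        y_t=out_y["T"],
        variant_ids=variant_ids[keep][fine],
    )
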