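"""Synthetic genotype/expression cohorts with known regulatory structure.

Dosages are Binomial(2, maf) per variant (optionally with block LD via
haplotype copying); expression is a sparse linear genetic signal plus
independent Gaussian noise whose variance is set from a target proportion
of genetically explained variance. ``make_scenario`` writes a complete,
immediately runnable input set (PLINK triplet, per-context expression TSVs,
covariates, annotation, gene list) together with a truth table that labels
every gene null or differential for downstream power scoring.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    CovariateMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    write_annotation,
    write_covariates,
    write_expression,
    write_plink,
)

__all__ = ["SimTruth", "sim_genotypes", "sim_expression", "make_scenario"]

# genomic layout: one gene per 3 Mb block so +/-500 kb windows never overlap
_GENE_SPACING = 3_000_000
_GENE_LENGTH = 10_000


@dataclass
class SimTruth:
    """Ground-truth record for one simulated gene."""

    gene_id: str
    kind: str
    maf: list
    beta_a: list
    beta_b: list
    noise_var_a: float
    noise_var_b: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        maf = np.asarray(self.maf, dtype=float)
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.noise_var_a <= 0 or self.noise_var_b <= 0:
            raise ValueError("noise variances must be positive")


def sim_genotypes(
    n: int,
    p: int,
    maf,
    seed=0,
    ld: float = 0.0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    pos_step: int = 100,
    id_prefix: str = "snp",
) -> GenotypeMatrix:
    """Simulate an n x p dosage matrix.

    ``maf`` is a scalar or length-p vector of minor allele frequencies in
    (0, 0.5]. ``ld`` in [0, 1) induces local correlation by haplotype
    copying: each haplotype allele copies its left neighbour with
    probability ``ld`` and is drawn fresh otherwise.
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (p,)).copy()
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if not 0.0 <= ld < 1.0:
        raise ValueError("ld must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    if ld == 0.0:
        dosages = rng.binomial(2, maf, size=(n, p)).astype(np.float64)
    else:
        hap = np.empty((2, n, p), dtype=np.int8)
        hap[:, :, 0] = rng.random((2, n)) < maf[0]
        for j in range(1, p):
            fresh = rng.random((2, n)) < maf[j]
            copy = rng.random((2, n)) < ld
            hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
        dosages = hap.sum(axis=0).astype(np.float64)

    variants = pd.DataFrame(
        {
            "id": [f"{id_prefix}_{j}" for j in range(p)],
            "chrom": chrom,
            "pos": start_pos + pos_step * np.arange(p, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )
    sample_ids = np.array([f"ind{i:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, variants=variants)


def sim_expression(G: GenotypeMatrix, beta: np.ndarray, noise_var: float, seed=0) -> np.ndarray:
    """Expression vector ``y = G beta + Normal(0, noise_var)``."""
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape != (G.n_variants,):
        raise ValueError("beta must align with the genotype columns")
    if noise_var <= 0:
        raise ValueError("noise_var must be positive")
    rng = np.random.default_rng(seed)
    return G.dosages @ beta + rng.normal(0.0, np.sqrt(noise_var), size=G.n_samples)


def _sparse_effects(rng, p, n_causal, effect_size, forbidden=()):
    """Random sparse effect vector avoiding the ``forbidden`` index set."""
    candidates = np.setdiff1d(np.arange(p), np.asarray(forbidden, dtype=int))
    idx = rng.choice(candidates, size=n_causal, replace=False)
    beta = np.zeros(p)
    beta[idx] = effect_size * rng.choice([-1.0, 1.0], size=n_causal)
    return beta, np.sort(idx)


def _noise_for_h2(G_block, beta, h2):
    genetic = G_block @ beta
    var_g = float(np.var(genetic))
    if var_g == 0:
        return 1.0
    return var_g * (1.0 - h2) / h2


def make_scenario(
    out_dir: str | os.PathLike,
    kind: str,
    n: int = 300,
    p: int = 50,
    n_genes: int = 10,
    n_causal: int = 5,
    effect_size: float = 0.5,
    heritability: float = 0.2,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    causal_overlap: float = 0.0,
    overlap_fraction: float = 0.0,
    ld: float = 0.0,
    n_covariates: int = 2,
    seed: int = 0,
) -> dict:
    """Write a complete synthetic input set under ``out_dir``.

    ``kind='null'`` gives every gene identical effect vectors in both
    contexts and a *single* shared expression measurement (the
    one-cohort negative-control design); ``kind='differential'`` draws
    per-context effect vectors whose causal sets share a ``causal_overlap``
    fraction (0 = disjoint) and independent context noise. Genes occupy
    disjoint 3 Mb blocks so their flanking windows never collide.

    Returns a dict of file paths plus the truth table.
    """
    if kind not in ("null", "differential"):
        raise ValueError(f"unknown scenario kind {kind!r}")
    if n_causal > p:
        raise ValueError("n_causal cannot exceed p")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)

    blocks = []
    annots = []
    truths = []
    expr_a = np.empty((n_genes, n))
    expr_b = np.empty((n_genes, n))
    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]

    # covariates contribute to expression so residualization is exercised
    covar = rng.normal(size=(n, n_covariates))
    gamma = rng.normal(scale=0.3, size=n_covariates)

    sample_ids = None
    for g, gene_id in enumerate(gene_ids):
        tss = 1_000_000 + g * _GENE_SPACING
        maf = rng.uniform(maf_low, maf_high, size=p)
        G = sim_genotypes(
            n,
            p,
            maf,
            seed=rng.integers(2**63),
            ld=ld,
            chrom="1",
            start_pos=tss - p * 100 // 2,
            pos_step=100,
            id_prefix=f"g{g}snp",
        )
        sample_ids = G.sample_ids
        annots.append(GeneAnnotation.canonical(gene_id, "1", tss, tss + _GENE_LENGTH))

        if kind == "null":
            beta_a, _ = _sparse_effects(rng, p, n_causal, effect_size)
            beta_b = beta_a
            noise_a = noise_b = _noise_for_h2(G.dosages, beta_a, heritability)
            ya = G.dosages @ beta_a + rng.normal(0, np.sqrt(noise_a), n)
            yb = ya  # one cohort, one measurement
        else:
            n_shared = int(round(causal_overlap * n_causal))
            beta_a, idx_a = _sparse_effects(rng, p, n_causal, effect_size)
            shared = rng.choice(idx_a, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
            forbidden = np.setdiff1d(idx_a, shared)
            beta_b, _ = _sparse_effects(rng, p, n_causal - n_shared, effect_size, forbidden=np.concatenate([forbidden, shared]))
            beta_b[shared] = beta_a[shared]
            noise_a = _noise_for_h2(G.dosages, beta_a, heritability)
            noise_b = _noise_for_h2(G.dosages, beta_b, heritability)
            ya = G.dosages @ beta_a + rng.normal(0, np.sqrt(noise_a), n)
            yb = G.dosages @ beta_b + rng.normal(0, np.sqrt(noise_b), n)

        expr_a[g] = ya + covar @ gamma
        expr_b[g] = yb + covar @ gamma
        blocks.append(G)
        truths.append(
            SimTruth(
                gene_id=gene_id,
                kind=kind,
                maf=maf.tolist(),
                beta_a=beta_a.tolist(),
                beta_b=beta_b.tolist(),
                noise_var_a=float(noise_a),
                noise_var_b=float(noise_b),
                n_samples=n,
                seed=seed,
            )
        )

    genotypes = GenotypeMatrix(
        dosages=np.hstack([G.dosages for G in blocks]),
        sample_ids=sample_ids,
        variants=pd.concat([G.variants for G in blocks], ignore_index=True),
    )

    paths = {
        "bfile": os.path.join(out_dir, "geno"),
        "expr_a": os.path.join(out_dir, "expr_a.tsv"),
        "expr_b": os.path.join(out_dir, "expr_b.tsv"),
        "covar": os.path.join(out_dir, "covar.tsv"),
        "annot": os.path.join(out_dir, "annot.tsv"),
        "genes": os.path.join(out_dir, "genes.txt"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "meta": os.path.join(out_dir, "meta.json"),
    }
    write_plink(paths["bfile"], genotypes)
    write_expression(
        paths["expr_a"],
        ExpressionMatrix(values=expr_a, gene_ids=np.array(gene_ids, dtype=object), sample_ids=sample_ids),
    )
    write_expression(
        paths["expr_b"],
        ExpressionMatrix(values=expr_b, gene_ids=np.array(gene_ids, dtype=object), sample_ids=sample_ids),
    )
    write_covariates(
        paths["covar"],
        CovariateMatrix(
            values=covar,
            sample_ids=sample_ids,
            covariate_names=np.array([f"cov{i}" for i in range(n_covariates)], dtype=object),
        ),
    )
    write_annotation(paths["annot"], annots)
    with open(paths["genes"], "w") as fh:
        fh.write("\n".join(gene_ids) + "\n")

    truth_df = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in truths],
            "kind": [t.kind for t in truths],
            "causal_ids_a": [
                ";".join(str(j) for j in np.flatnonzero(t.beta_a)) for t in truths
            ],
            "causal_ids_b": [
                ";".join(str(j) for j in np.flatnonzero(t.beta_b)) for t in truths
            ],
            "effect_size": effect_size,
            "noise_var_a": [t.noise_var_a for t in truths],
            "noise_var_b": [t.noise_var_b for t in truths],
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["meta"], "w") as fh:
        json.dump(
            {
                "kind": kind,
                "n": n,
                "p": p,
                "n_genes": n_genes,
                "n_causal": n_causal,
                "effect_size": effect_size,
                "heritability": heritability,
                "causal_overlap": causal_overlap,
                "overlap_fraction": overlap_fraction,
                "ld": ld,
                "seed": seed,
            },
            fh,
            indent=1,
        )
    paths["truth_table"] = truth_df
    return paths
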