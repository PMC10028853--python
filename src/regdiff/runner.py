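"""Per-gene orchestration, CLI, multiple-testing correction and calibration
diagnostics."""

from __future__ import annotations

import hashlib
import logging
import os
import time
import warnings
from dataclasses import dataclass

import click
import numpy as np
import pandas as pd
from scipy import stats

from . import boottest, io_formats, preprocess, qc_variants, simulate

__all__ = [
    "RunConfig",
    "run",
    "bonferroni",
    "genomic_lambda",
    "qq_data",
    "gene_seed",
    "cli",
]

log = logging.getLogger("regdiff")


@dataclass
class RunConfig:
    bfile: str
    expr_a: str
    expr_b: str
    annot: str
    genes: str
    out_dir: str
    covar: str | None = None
    test_context: str = "A"  # which context's measured expression forms y on the test set
    window_bp: int = 500_000
    boot_k: int = 50
    alpha_mix: float = 0.5
    n_folds: int = 5
    lambda_grid_size: int = 100
    seed: int = 0
    split_mode: str = "auto"
    overlap: float = 0.0
    min_test_fraction: float = 0.25
    n_train: int | None = None
    n_test: int | None = None
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    skip_qc: bool = False
    # rerun the CV penalty search inside every bootstrap replicate (the
    # faithful procedure; conservative under the null) or refit replicates
    # at the full-sample penalties
    reselect_lambda: bool = True

    def validate(self) -> None:
        for name in ("expr_a", "expr_b", "annot", "genes"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name}: {path} does not exist")
        for ext in (".bed", ".bim", ".fam"):
            if not os.path.exists(self.bfile + ext):
                raise FileNotFoundError(f"bfile: {self.bfile + ext} does not exist")
        if self.covar is not None and not os.path.exists(self.covar):
            raise FileNotFoundError(f"covar: {self.covar} does not exist")
        if self.test_context not in ("A", "B"):
            raise ValueError("test_context must be 'A' or 'B'")
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must lie in [0, 1]")
        if self.boot_k < 2:
            raise ValueError("boot_k must be at least 2")


def gene_seed(master_seed: int, gene_id: str) -> np.random.SeedSequence:
    """Stable per-gene random stream, independent of gene-list order."""
    digest = hashlib.sha256(f"{master_seed}:{gene_id}".encode()).digest()
    return np.random.SeedSequence(int.from_bytes(digest[:8], "big"))


def _intersect_samples(G, expr_a, expr_b, covar):
    """Sample ids present in every table, ordered as in the genotype file."""
    available = set(expr_a.sample_ids) & set(expr_b.sample_ids)
    if covar is not None:
        available &= set(covar.sample_ids)
    keep = [i for i, s in enumerate(G.sample_ids) if s in available]
    dropped = G.n_samples - len(keep)
    if dropped:
        log.info("dropped %d genotyped samples absent from expression/covariates", dropped)
    return np.asarray(keep, dtype=np.intp)


def _column_lookup(sample_ids, ordered):
    index = {s: i for i, s in enumerate(sample_ids)}
    return np.array([index[s] for s in ordered], dtype=np.intp)


def run(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline and write the per-gene results table."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    G = io_formats.read_plink(config.bfile)
    if not config.skip_qc:
        G, qc_report = qc_variants.apply_variant_qc(G, config.maf_min, config.hwe_p_min)
        qc_report.to_tsv(os.path.join(config.out_dir, "variant_qc.tsv"))
    expr_a = io_formats.read_expression(config.expr_a)
    expr_b = io_formats.read_expression(config.expr_b)
    covar = io_formats.read_covariates(config.covar) if config.covar else None
    annots = io_formats.read_annotation(config.annot)
    genes = io_formats.read_gene_list(config.genes)

    rows = _intersect_samples(G, expr_a, expr_b, covar)
    G = G.subset_samples(rows)
    ordered = G.sample_ids
    col_a = _column_lookup(expr_a.sample_ids, ordered)
    col_b = _column_lookup(expr_b.sample_ids, ordered)
    cov_vals = None
    if covar is not None:
        cov_vals = covar.values[_column_lookup(covar.sample_ids, ordered)]

    split = preprocess.make_splits(
        ordered,
        mode=config.split_mode,
        seed=config.seed,
        overlap_fraction=config.overlap,
        min_test_fraction=config.min_test_fraction,
        n_train=config.n_train,
        n_test=config.n_test,
    )
    if split.n_train < 100:
        warnings.warn(
            f"training sets have only {split.n_train} samples; test statistics "
            "are unstable below 100 training samples",
            stacklevel=2,
        )
        log.warning("unstable: n_train=%d < 100", split.n_train)
    expr_t = expr_a if config.test_context == "A" else expr_b
    col_t = col_a if config.test_context == "A" else col_b

    results = []
    for gene_id in genes:
        t0 = time.perf_counter()
        try:
            result = _test_one_gene(
                gene_id, G, expr_a, expr_b, expr_t, col_a, col_b, col_t,
                cov_vals, split, annots, config,
            )
        except preprocess.UntestableGeneError as exc:
            result = boottest.GeneTestResult.untestable(
                gene_id, split.n_train, split.n_test, reason="untestable"
            )
            log.info("gene %s untestable: %s", gene_id, exc)
        except Exception:  # noqa: BLE001 — a failing gene must not kill the run
            result = boottest.GeneTestResult.untestable(
                gene_id, split.n_train, split.n_test, reason="error"
            )
            log.exception("gene %s failed", gene_id)
        results.append(result)
        log.info(
            "gene=%s status=%s p_boot=%s p_cond=%s sel_a=%s sel_b=%s elapsed=%.2fs",
            gene_id, result.status, result.p_boot, result.p_cond,
            result.n_snps_selected_a, result.n_snps_selected_b,
            time.perf_counter() - t0,
        )

    out_path = os.path.join(config.out_dir, "results.tsv")
    io_formats.write_results(out_path, results)
    df = io_formats.read_results(out_path)
    n_ok = int((df["status"] == "ok").sum())
    log.info("tested %d/%d genes; results written to %s", n_ok, len(genes), out_path)
    return df


def _test_one_gene(gene_id, G, expr_a, expr_b, expr_t, col_a, col_b, col_t,
                   cov_vals, split, annots, config):
    if gene_id not in annots:
        raise preprocess.UntestableGeneError("gene missing from annotation")
    interval = preprocess.cis_window(annots[gene_id], config.window_bp)
    cis = preprocess.extract_cis(G, interval)
    if cis.n_variants == 0:
        raise preprocess.UntestableGeneError("no cis variants in window")

    y_a_all = expr_a.gene_vector(gene_id)[col_a]
    y_b_all = expr_b.gene_vector(gene_id)[col_b]
    y_t_all = expr_t.gene_vector(gene_id)[col_t]

    ia, ib, it = split.idx_a, split.idx_b, split.idx_t
    raw_x = {"A": cis.dosages[ia], "B": cis.dosages[ib], "T": cis.dosages[it]}
    raw_y = {"A": y_a_all[ia], "B": y_b_all[ib], "T": y_t_all[it]}
    covars = {
        "A": cov_vals[ia] if cov_vals is not None else None,
        "B": cov_vals[ib] if cov_vals is not None else None,
        "T": cov_vals[it] if cov_vals is not None else None,
    }
    adjusted = preprocess.standardize_and_prune(
        raw_x, raw_y, covars, cis.variants["id"].to_numpy(dtype=object)
    )
    return boottest.test_gene(
        adjusted,
        gene_id=gene_id,
        K=config.boot_k,
        seed=gene_seed(config.seed, gene_id),
        alpha=config.alpha_mix,
        n_folds=config.n_folds,
        lambda_grid_size=config.lambda_grid_size,
        reselect_lambda=config.reselect_lambda,
    )


# ---------------------------------------------------------------------------
# Multiple testing and calibration diagnostics
# ---------------------------------------------------------------------------

def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Family-wise flags at threshold alpha / m, m = number of finite p-values."""
    p = np.asarray(p_values, dtype=np.float64)
    finite = np.isfinite(p)
    m = int(finite.sum())
    if m < 1:
        raise ValueError("no finite p-values")
    threshold = alpha / m
    flags = np.zeros(p.shape, dtype=bool)
    flags[finite] = p[finite] <= threshold
    return flags, threshold


_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.45494


def genomic_lambda(p_values) -> float:
    """Genomic-control inflation factor from the median p-value.

    Converts the median p to a 1-df chi-square quantile and divides by the
    null median 0.45494; 1 indicates calibration, >1 inflation.
    """
    p = np.asarray(p_values, dtype=np.float64)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    return float(stats.chi2.isf(np.median(p), df=1) / _CHI2_MEDIAN)


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10(p) with a pointwise 95% null band.

    Expected quantiles are (i - 0.5) / n for ranks i = 1..n; the band comes
    from the Beta(i, n - i + 1) distribution of uniform order statistics.
    """
    p = np.asarray(p_values, dtype=np.float64)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    n = p.size
    observed = np.sort(p)
    ranks = np.arange(1, n + 1)
    expected = (ranks - 0.5) / n
    lower = stats.beta.ppf(0.025, ranks, n - ranks + 1)
    upper = stats.beta.ppf(0.975, ranks, n - ranks + 1)
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "expected_neglog10": -np.log10(expected),
                "observed_neglog10": -np.log10(observed),
                "band_lower_neglog10": -np.log10(upper),
                "band_upper_neglog10": -np.log10(lower),
            }
        )


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Enable per-gene log lines.")
def cli(verbose: bool) -> None:
    """Test genes for context-specific cis-genetic regulation."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(levelname)s %(message)s",
    )


@cli.command("run")
@click.option("--bfile", required=True, help="PLINK BED/BIM/FAM prefix.")
@click.option("--expr-a", required=True, type=click.Path(exists=True))
@click.option("--expr-b", required=True, type=click.Path(exists=True))
@click.option("--covar", default=None, type=click.Path(exists=True))
@click.option("--annot", required=True, type=click.Path(exists=True))
@click.option("--genes", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--test-context", type=click.Choice(["A", "B"]), required=True,
              help="Context whose measured expression forms the test response.")
@click.option("--window-bp", default=500_000, show_default=True)
@click.option("--boot-k", default=50, show_default=True)
@click.option("--alpha-mix", default=0.5, show_default=True)
@click.option("--folds", "n_folds", default=5, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--split", "split_mode", type=click.Choice(["auto", "thirds"]), default="auto",
              show_default=True)
@click.option("--overlap", default=0.0, show_default=True,
              help="Fraction of training samples shared between the two training sets.")
@click.option("--maf-min", default=0.01, show_default=True)
@click.option("--hwe-p", "hwe_p_min", default=1e-6, show_default=True)
@click.option("--freeze-lambda", "freeze_lambda", is_flag=True, default=False,
              help="Refit bootstrap replicates at the full-sample penalties "
                   "instead of rerunning CV inside each replicate.")
def cli_run(freeze_lambda: bool, **kwargs) -> None:
    """Run the full per-gene testing pipeline."""
    config = RunConfig(reselect_lambda=not freeze_lambda, **kwargs)
    df = run(config)
    click.echo(f"tested {int((df['status'] == 'ok').sum())}/{len(df)} genes")


@cli.command("simulate")
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--kind", type=click.Choice(["null", "differential"]), default="null",
              show_default=True)
@click.option("--n", default=300, show_default=True)
@click.option("--p", default=50, show_default=True)
@click.option("--genes", "n_genes", default=10, show_default=True)
@click.option("--n-causal", default=5, show_default=True)
@click.option("--effect-size", default=0.5, show_default=True)
@click.option("--heritability", default=0.2, show_default=True)
@click.option("--seed", default=0, show_default=True)
def cli_simulate(**kwargs) -> None:
    """Generate a runnable synthetic input set."""
    paths = simulate.make_scenario(**kwargs)
    click.echo(f"wrote scenario to {os.path.dirname(paths['expr_a'])}")


@cli.command("diagnose")
@click.option("--results", "results_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--alpha", default=0.05, show_default=True)
def cli_diagnose(results_path: str, out_dir: str, alpha: float) -> None:
    """Genomic-control lambda, QQ table and Bonferroni flags for a results TSV."""
    os.makedirs(out_dir, exist_ok=True)
    df = io_formats.read_results(results_path)
    ok = df[df["status"] == "ok"]
    for label, col in (("boot", "p_boot"), ("cond", "p_cond")):
        p = ok[col].to_numpy()
        lam = genomic_lambda(p)
        qq = qq_data(p)
        qq.to_csv(os.path.join(out_dir, f"qq_{label}.tsv"), sep="\t", index=False)
        flags, threshold = bonferroni(p, alpha)
        click.echo(
            f"{label}: lambda={lam:.4f} significant={int(flags.sum())}/{len(p)} "
            f"threshold={threshold:.3g}"
        )
        with open(os.path.join(out_dir, f"lambda_{label}.txt"), "w") as fh:
            fh.write(f"{lam:.6f}\n")
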