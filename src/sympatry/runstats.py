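"""Cross-run statistics: run summaries, PCA, Ward clustering, arm comparison.

A batch experiment runs many independent epochs per mating treatment
("arm"): random versus m-trait mating.  Each run is reduced to a summary —
the within-run mean and standard deviation of the m phenotype, the
alpha-locus heterozygote deviance, and the variance fraction captured by
the first two principal components of the standardized 4-d phenotype table.
Arms are compared on their vectors of within-run mean m with a two-tailed
Mann-Whitney U test (a shift test, deliberately, rather than a general
distribution test).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA

from .popgen import DEFAULT_EPSILON, HWResult, call_allele_classes, heterozygote_deviance

__all__ = [
    "RunSummary",
    "BatchComparison",
    "summarize_run",
    "summarize_snapshot",
    "pca_first_two_variance",
    "ward_tree",
    "mann_whitney_two_tailed",
    "compare_arms",
    "mean_m_histogram",
]

PHENOTYPE_COLUMNS = ("alpha", "delta", "rho", "m")


@dataclass
class RunSummary:
    """One epoch reduced to the cross-run reporting quantities."""

    run_id: int
    mode: str
    final_n: int
    mean_m: float
    sd_m: float
    alpha_hw: HWResult
    pca_var2: float                 # % variance in the first two PCs
    tree: np.ndarray | None = None  # Ward linkage matrix
    status: str = "ok"


@dataclass
class BatchComparison:
    n_random: int
    n_mtrait: int
    random_mean: float
    random_sd: float
    mtrait_mean: float
    mtrait_sd: float
    u_statistic: float
    p_value: float


def _standardize(table: np.ndarray) -> np.ndarray:
    """Z-score columns, dropping zero-variance ones (e.g. m before it varies)."""
    x = np.asarray(table, dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all phenotype columns are constant")
    return (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]


def pca_first_two_variance(phenotype_table: np.ndarray, standardize: bool = True) -> float:
    """Percent of total variance captured by the first two principal components.

    Computed on the per-column standardized table by default; data of rank
    <= 2 (a line or plane in phenotype space) give exactly 100%.
    """
    x = np.asarray(phenotype_table, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 individuals for a PCA")
    x = _standardize(x) if standardize else x - x.mean(axis=0)
    if x.shape[1] <= 2:
        return 100.0
    pca = PCA(n_components=None).fit(x)
    return float(pca.explained_variance_ratio_[:2].sum() * 100.0)


def ward_tree(phenotype_table: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Ward-linkage agglomerative tree over (standardized) phenotypes.

    Returns the scipy linkage matrix ((n-1) x 4); deterministic given the
    input row order, with scipy's lowest-index tie rule.
    """
    x = np.asarray(phenotype_table, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 individuals to cluster")
    if standardize:
        x = _standardize(x)
    return linkage(x, method="ward")


def mann_whitney_two_tailed(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test (shift alternative).

    Exact null distribution when the combined sample size is at most 20
    (full permutation enumeration when ties are present), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    small = a.size + b.size <= 20
    if small:
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = stats.PermutationMethod() if has_ties else "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def summarize_snapshot(
    snapshot: pd.DataFrame,
    run_id: int = 0,
    mode: str = "unknown",
    status: str = "ok",
    keep_tree: bool = False,
) -> RunSummary:
    """Reduce a final per-individual snapshot table to a RunSummary."""
    if len(snapshot) == 0:
        raise ValueError("snapshot is empty")
    m = snapshot["m"].to_numpy(dtype=float)
    geno = snapshot[["alpha1", "alpha2"]].to_numpy(dtype=float)
    classing = call_allele_classes(geno.ravel(), DEFAULT_EPSILON["alpha"], "alpha")
    hw = heterozygote_deviance(geno, classing)
    phen = snapshot[list(PHENOTYPE_COLUMNS)].to_numpy(dtype=float)
    try:
        pca_var2 = pca_first_two_variance(phen)
    except ValueError:
        pca_var2 = float("nan")
    tree = None
    if keep_tree and len(snapshot) >= 2:
        try:
            tree = ward_tree(phen)
        except ValueError:
            tree = None
    return RunSummary(
        run_id=run_id,
        mode=mode,
        final_n=len(snapshot),
        mean_m=float(m.mean()),
        sd_m=float(m.std(ddof=1)) if m.size > 1 else 0.0,
        alpha_hw=hw,
        pca_var2=pca_var2,
        tree=tree,
        status=status,
    )


def summarize_run(result, keep_tree: bool = False) -> RunSummary:
    """RunSummary from an epoch result (see ``epoch.run_epoch``)."""
    if result.final_snapshot is None:
        raise ValueError("epoch produced no snapshot (immediate extinction)")
    return summarize_snapshot(
        result.final_snapshot,
        run_id=result.config.seed,
        mode=result.config.mode,
        status=result.status,
        keep_tree=keep_tree,
    )


def compare_arms(
    random_summaries: list[RunSummary], mtrait_summaries: list[RunSummary]
) -> BatchComparison:
    """Mann-Whitney comparison of within-run mean m between the two arms."""
    if len(random_summaries) < 2 or len(mtrait_summaries) < 2:
        raise ValueError("need at least 2 runs per arm")
    rand_m = np.array([s.mean_m for s in random_summaries])
    mt_m = np.array([s.mean_m for s in mtrait_summaries])
    u, p = mann_whitney_two_tailed(rand_m, mt_m)
    return BatchComparison(
        n_random=len(rand_m),
        n_mtrait=len(mt_m),
        random_mean=float(rand_m.mean()),
        random_sd=float(rand_m.std(ddof=1)),
        mtrait_mean=float(mt_m.mean()),
        mtrait_sd=float(mt_m.std(ddof=1)),
        u_statistic=u,
        p_value=p,
    )


def mean_m_histogram(summaries: list[RunSummary]) -> tuple[np.ndarray, np.ndarray]:
    """Counts of within-run mean m binned into 0.1-wide bins over [0, 1]."""
    means = np.array([s.mean_m for s in summaries])
    edges = np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(np.clip(means, 0.0, 1.0), bins=edges)
    return counts, edges


def write_arm_report(summaries: list[RunSummary], path: str | Path) -> None:
    """Table-2-style per-run report, sorted on mean m."""
    rows = sorted(
        (
            {
                "run": s.run_id,
                "mode": s.mode,
                "N": s.final_n,
                "mean_m": s.mean_m,
                "sd_m": s.sd_m,
                "alpha_deviance": "" if s.alpha_hw.deviance is None else s.alpha_hw.deviance,
                "pca_var2": s.pca_var2,
                "status": s.status,
            }
            for s in summaries
        ),
        key=lambda r: r["mean_m"],
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
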