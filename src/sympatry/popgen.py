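"""Hardy-Weinberg analysis of continuous-allele snapshots.

Alleles in this model are continuous values, so before any Hardy-Weinberg
bookkeeping they are discretized into allele classes by single-linkage
clustering on the real line: sort the 2N observed values and cut wherever
the gap between neighbors exceeds a tolerance epsilon.  Mutation keeps
within-lineage values tightly grouped, so distinct evolved alleles appear as
well-separated clusters.  The departure statistic is the heterozygote
deviance (H_obs - H_exp)/H_exp with H_exp = 1 - sum(p_i^2), negative under
a heterozygote deficit — the signature of assortative mating / inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AlleleClassing",
    "HWResult",
    "DEFAULT_EPSILON",
    "call_allele_classes",
    "allele_frequencies",
    "heterozygote_deviance",
    "locus_report",
    "write_locus_report",
]

#: Default merge tolerance per locus: 5% of the founder allele range.
DEFAULT_EPSILON: dict[str, float] = {
    "alpha": 0.075,  # founders span [0, 1.5]
    "delta": 0.100,  # founders span [0, 2]
    "rho": 0.050,    # founders span [0, 1]
    "m": 0.050,      # m alleles live in [0, 1]
}

#: With this many or more called classes the locus is reported as having
#: insufficient structure for a meaningful deviance (convention: >= 5).
MAX_CLASSES = 5


@dataclass
class AlleleClassing:
    """Discretization of one locus's continuous allele values."""

    locus: str
    epsilon: float
    boundaries: np.ndarray  # ascending cut points between classes
    centers: np.ndarray     # mean allele value per class

    @property
    def n_classes(self) -> int:
        return len(self.centers)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Class index for each allele value."""
        return np.searchsorted(self.boundaries, np.asarray(values, dtype=float))


@dataclass
class HWResult:
    locus: str
    n_classes: int
    h_obs: float
    h_exp: float
    deviance: float | None
    status: str  # "ok" | "undefined"
    reason: str | None = None


def call_allele_classes(
    allele_values: np.ndarray, epsilon: float, locus: str = ""
) -> AlleleClassing:
    """Single-linkage 1-D clustering: cut the sorted values at gaps > epsilon."""
    values = np.sort(np.asarray(allele_values, dtype=float).ravel())
    if values.size == 0:
        raise ValueError("need at least one allele value")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    gaps = np.diff(values)
    cut_after = np.flatnonzero(gaps > epsilon)
    boundaries = (values[cut_after] + values[cut_after + 1]) / 2.0
    segments = np.split(values, cut_after + 1)
    centers = np.array([seg.mean() for seg in segments])
    return AlleleClassing(locus=locus, epsilon=epsilon, boundaries=boundaries, centers=centers)


def allele_frequencies(
    genotypes: np.ndarray, classing: AlleleClassing
) -> np.ndarray:
    """Class frequencies p_i over the 2N allele observations (sum to 1)."""
    geno = np.asarray(genotypes, dtype=float).reshape(-1, 2)
    labels = classing.assign(geno.ravel())
    counts = np.bincount(labels, minlength=classing.n_classes)
    return counts / counts.sum()


def heterozygote_deviance(
    genotypes: np.ndarray, classing: AlleleClassing, max_classes: int = MAX_CLASSES
) -> HWResult:
    """Hardy-Weinberg heterozygote deviance (H_obs - H_exp)/H_exp at one locus.

    H_obs is the fraction of individuals whose two alleles fall in different
    classes; H_exp = 1 - sum(p_i^2) is the multi-allelic expected
    heterozygosity.  Undefined when the locus is monomorphic (H_exp = 0) or
    when ``max_classes`` or more classes were called (insufficient structure
    to identify discrete alleles).
    """
    geno = np.asarray(genotypes, dtype=float).reshape(-1, 2)
    if geno.shape[0] < 1:
        raise ValueError("need at least one diploid genotype")
    labels = classing.assign(geno.ravel()).reshape(-1, 2)
    h_obs = float(np.mean(labels[:, 0] != labels[:, 1]))
    p = allele_frequencies(geno, classing)
    h_exp = float(1.0 - (p ** 2).sum())
    if classing.n_classes >= max_classes:
        return HWResult(classing.locus, classing.n_classes, h_obs, h_exp,
                        None, "undefined", "too-many-alleles")
    if h_exp == 0.0:
        return HWResult(classing.locus, classing.n_classes, h_obs, h_exp,
                        None, "undefined", "monomorphic")
    deviance = (h_obs - h_exp) / h_exp
    return HWResult(classing.locus, classing.n_classes, h_obs, h_exp,
                    float(deviance), "ok")


def locus_report(
    snapshot: pd.DataFrame, epsilon: dict[str, float] | None = None
) -> list[HWResult]:
    """Per-locus Hardy-Weinberg analysis of a 14-column snapshot table."""
    eps = dict(DEFAULT_EPSILON)
    if epsilon:
        eps.update(epsilon)
    results = []
    for locus in ("alpha", "delta", "rho", "m"):
        geno = snapshot[[f"{locus}1", f"{locus}2"]].to_numpy(dtype=float)
        classing = call_allele_classes(geno.ravel(), eps[locus], locus)
        results.append(heterozygote_deviance(geno, classing))
    return results


def write_locus_report(results: list[HWResult], path: str | Path) -> None:
    """Tab-delimited per-locus report (locus, n_classes, H_obs, H_exp, deviance, status)."""
    rows = [
        {
            "locus": r.locus,
            "n_classes": r.n_classes,
            "H_obs": r.h_obs,
            "H_exp": r.h_exp,
            "deviance": "" if r.deviance is None else r.deviance,
            "status": r.status if r.reason is None else f"{r.status}({r.reason})",
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
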