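"""Per-cohort tumor-vs-normal statistics and miRNA-mRNA anticorrelation.

For each gene in each expression cohort the pipeline reports the block
of statistics that makes up one cohort's columns of a ranked-target
table: a permutation p-value for the tumor/normal difference, its
Benjamini-Hochberg FDR across the gene set, the log2 fold change
(difference of mean log2 expression), and the Pearson correlation of
the gene's mRNA with the query miRNA across matched samples (samples
measured on both assays), with its t-based p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "GeneCohortStats",
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "permutation_de_test",
    "bh_fdr",
    "mirna_mrna_correlation",
    "cohort_gene_stats",
]

#: smallest p-value ever reported; combined p-values are floored here
#: too so that downstream log-transforms never see 0.
P_FLOOR = 1e-300

_TIE_TOL = 1e-12


class InsufficientDataError(ValueError):
    """Fewer samples than a statistic needs."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested on a zero-variance vector."""


@dataclass
class Cohort:
    """One study's expression data.

    Parameters
    ----------
    name : cohort label used in output column prefixes.
    mirna : log2 expression of the query miRNA per sample, or None for
        cohorts without a miRNA assay (correlation columns stay absent).
    mrna : genes x samples matrix of log2 expression.
    sample_class : sample id -> "tumor" | "normal".
    matched : sample ids carrying both the miRNA and the mRNA assay;
        Pearson correlations are computed on this subset only.
    """

    name: str
    mirna: pd.Series | None
    mrna: pd.DataFrame
    sample_class: pd.Series
    matched: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.sample_class = pd.Series(self.sample_class)
        bad = set(self.sample_class.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")
        missing = [s for s in self.mrna.columns if s not in self.sample_class.index]
        if missing:
            raise ValueError(f"samples without a class label: {missing[:5]}")
        classes = self.sample_class.loc[list(self.mrna.columns)]
        if (classes == "tumor").sum() < 2 or (classes == "normal").sum() < 2:
            raise InsufficientDataError(
                f"cohort {self.name!r} needs >=2 tumor and >=2 normal samples"
            )
        self.matched = frozenset(self.matched)
        for s in self.matched:
            if s not in self.mrna.columns:
                raise ValueError(f"matched sample {s!r} missing from mRNA matrix")
            if self.mirna is not None and s not in self.mirna.index:
                raise ValueError(f"matched sample {s!r} missing from miRNA vector")

    @property
    def tumor_samples(self) -> list[str]:
        cls = self.sample_class
        return [s for s in self.mrna.columns if cls[s] == "tumor"]

    @property
    def normal_samples(self) -> list[str]:
        cls = self.sample_class
        return [s for s in self.mrna.columns if cls[s] == "normal"]


@dataclass
class GeneCohortStats:
    """One gene's statistics block in one cohort."""

    gene_id: str
    cohort: str
    p_tn: float
    fdr: float
    log2fold: float
    r: float | None = None
    p_r: float | None = None
    n_matched: int = 0


def permutation_de_test(
    tumor_values: Sequence[float],
    normal_values: Sequence[float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    exhaustive_limit: int = 20_000,
) -> tuple[float, float]:
    """Two-sided permutation test on the difference of group means.

    If the number of distinct tumor-label assignments C(n, n_tumor) is
    at most ``exhaustive_limit`` the permutation distribution is
    enumerated exactly and p is the exact tail fraction.  Otherwise
    ``n_perm`` seeded random reassignments are drawn and the add-one
    estimate p = (b + 1) / (B + 1) is used, which is never 0.

    Returns ``(p, log2fold)`` with log2fold = mean(tumor) - mean(normal).
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size < 2 or n.size < 2:
        raise InsufficientDataError("need >=2 samples per group")
    if not (np.isfinite(t).all() and np.isfinite(n).all()):
        raise ValueError("non-finite expression values")
    obs = t.mean() - n.mean()
    pooled = np.concatenate([t, n])
    if np.ptp(pooled) == 0:  # constant data: p = 1 by convention
        return 1.0, float(obs)
    n1, ntot = t.size, pooled.size
    total = math.comb(ntot, n1)
    thresh = abs(obs) - _TIE_TOL
    if total <= exhaustive_limit:
        grand = pooled.sum()
        hits = 0
        for idx in combinations(range(ntot), n1):
            s1 = pooled[list(idx)].sum()
            d = s1 / n1 - (grand - s1) / (ntot - n1)
            if abs(d) >= thresh:
                hits += 1
        return hits / total, float(obs)
    rng = np.random.default_rng(seed)
    mat = np.tile(pooled, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    d = mat[:, :n1].mean(axis=1) - mat[:, n1:].mean(axis=1)
    b = int((np.abs(d) >= thresh).sum())
    return (b + 1) / (n_perm + 1), float(obs)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mirna_mrna_correlation(
    mirna_values: Sequence[float],
    mrna_values: Sequence[float],
    min_matched: int = 5,
) -> tuple[float | None, float | None]:
    """Pearson r between miRNA and mRNA over matched samples.

    The two-sided p-value comes from t = r * sqrt(n-2) / sqrt(1-r^2)
    on n-2 degrees of freedom.  With fewer than ``min_matched`` pairs
    both values are absent (None).  |r| = 1 yields the numerical floor
    rather than p = 0.
    """
    x = np.asarray(mirna_values, dtype=float)
    y = np.asarray(mrna_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("miRNA and mRNA vectors must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < min_matched:
        return None, None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a correlation input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        return r, P_FLOOR
    tstat = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(tstat), df=n - 2)
    return r, float(max(p, P_FLOOR))


def cohort_gene_stats(
    cohort: Cohort,
    gene_ids: Iterable[str] | None = None,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    min_matched: int = 5,
    exhaustive_limit: int = 20_000,
) -> list[GeneCohortStats]:
    """Full statistics block for every requested gene in one cohort.

    Runs the permutation test per gene (each gene gets an independent
    child seed of ``seed``), adjusts the p-values by Benjamini-Hochberg
    across the requested gene set, and computes the miRNA-mRNA Pearson
    correlation on the matched samples when the cohort carries a miRNA
    assay and at least ``min_matched`` matched samples.

    Genes with missing values in any sample are dropped with a warning.
    """
    genes = list(gene_ids) if gene_ids is not None else list(cohort.mrna.index)
    unknown = [g for g in genes if g not in cohort.mrna.index]
    if unknown:
        raise KeyError(f"genes absent from cohort {cohort.name!r}: {unknown[:5]}")
    usable: list[str] = []
    for g in genes:
        if np.isfinite(cohort.mrna.loc[g].to_numpy(dtype=float)).all():
            usable.append(g)
        else:
            logger.warning(
                "cohort %s: gene %s dropped (missing values)", cohort.name, g
            )
    tumor = cohort.tumor_samples
    normal = cohort.normal_samples
    matched = sorted(cohort.matched) if cohort.mirna is not None else []
    mir = (
        cohort.mirna.loc[matched].to_numpy(dtype=float) if matched else np.empty(0)
    )

    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = root.spawn(len(usable))

    p_tn = np.empty(len(usable))
    folds = np.empty(len(usable))
    for i, g in enumerate(usable):
        row = cohort.mrna.loc[g]
        p_tn[i], folds[i] = permutation_de_test(
            row[tumor].to_numpy(dtype=float),
            row[normal].to_numpy(dtype=float),
            n_perm=n_perm,
            seed=children[i],
            exhaustive_limit=exhaustive_limit,
        )
    fdr = bh_fdr(p_tn)

    out: list[GeneCohortStats] = []
    for i, g in enumerate(usable):
        r = p_r = None
        n_m = 0
        if matched:
            y = cohort.mrna.loc[g, matched].to_numpy(dtype=float)
            keep = np.isfinite(mir) & np.isfinite(y)
            n_m = int(keep.sum())
            try:
                r, p_r = mirna_mrna_correlation(
                    mir[keep], y[keep], min_matched=min_matched
                )
            except UndefinedCorrelationError as exc:
                raise UndefinedCorrelationError(
                    f"cohort {cohort.name!r}, gene {g!r}: {exc}"
                ) from exc
        out.append(
            GeneCohortStats(
                gene_id=g,
                cohort=cohort.name,
                p_tn=float(p_tn[i]),
                fdr=float(fdr[i]),
                log2fold=float(folds[i]),
                r=r,
                p_r=p_r,
                n_matched=n_m if r is not None else n_m,
            )
        )
    return out


def stats_frame(stats: Iterable[GeneCohortStats]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of per-gene stats blocks."""
    rows = [
        {
            "gene_id": s.gene_id,
            "cohort": s.cohort,
            "p_value_TN": s.p_tn,
            "FDR": s.fdr,
            "log2fold_TN": s.log2fold,
            "r_pearson": s.r,
            "p_value_pearson": s.p_r,
            "n_matched": s.n_matched,
        }
        for s in stats
    ]
    return pd.DataFrame(rows)
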