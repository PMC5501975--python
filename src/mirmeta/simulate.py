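"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* expression cohorts in which the query miRNA is shifted up in tumors
  (an oncomiR) and a handful of *planted targets* are coupled to it
  with a negative slope, hence downregulated in tumors and
  anticorrelated with the miRNA across matched samples;
* *decoy* genes that satisfy only part of the target signature —
  tumor-downshifted but uncoupled ("decoy_down"), or miRNA-coupled but
  with no net tumor shift ("decoy_corr") — so the composite filter
  (deregulated AND anticorrelated AND predicted) is exercised
  non-trivially;
* 3'-UTR sequences with seed-match sites planted at recorded
  coordinates;
* dose-response series following the median-effect model, and
  Loewe-additive drug combinations whose true combination index is 1.

Expression is generated directly on the log2 scale with Gaussian,
homoscedastic noise.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import expit, logit

from . import seeds as seedmod
from .cohort_stats import Cohort
from .median_effect import DoseResponseSeries, MedianEffectFit, dose_for_effect

__all__ = [
    "CohortSimConfig",
    "SimTruth",
    "simulate_cohorts",
    "simulate_utrs",
    "simulate_dose_response",
    "simulate_additive_combination",
]


class SimConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of one simulated expression cohort.

    All expression quantities are in log2 units.  ``target_slope`` is
    the expected change in target log2-mRNA per unit log2-miRNA
    (negative for repression); ``mirna_tumor_shift`` the tumor-vs-normal
    miRNA shift (positive for an oncomiR).  ``n_matched`` samples carry
    both the miRNA and the mRNA assay; with ``matched_mode="tumor"``
    (default) they are a subset of the tumor samples, with "pooled"
    the first ``n_matched`` tumor and first ``n_matched`` normal
    samples are matched.
    """

    name: str = "cohort"
    n_genes: int = 500
    n_planted_targets: int = 5
    n_tumor: int = 30
    n_normal: int = 30
    n_matched: int = 20
    mirna_tumor_shift: float = 2.0
    target_slope: float = -1.0
    noise_sd: float = 1.0
    frac_decoy_down: float = 0.05
    frac_decoy_corr: float = 0.05
    seed: int = 0
    mirna_baseline: float = 8.0
    gene_baseline_mean: float = 6.0
    gene_baseline_sd: float = 1.0
    matched_mode: str = "tumor"

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_tumor <= 0 or self.n_normal <= 0:
            raise SimConfigError("n_genes, n_tumor, n_normal must be positive")
        if not (0 <= self.n_planted_targets <= self.n_genes):
            raise SimConfigError("n_planted_targets must lie in [0, n_genes]")
        if not (0 <= self.n_matched <= min(self.n_tumor, self.n_normal)):
            raise SimConfigError("n_matched must lie in [0, min(n_tumor, n_normal)]")
        if self.noise_sd <= 0:
            raise SimConfigError("noise_sd must be positive")
        for f in (self.frac_decoy_down, self.frac_decoy_corr):
            if not (0.0 <= f <= 1.0):
                raise SimConfigError("decoy fractions must lie in [0, 1]")
        if self.matched_mode not in ("tumor", "pooled"):
            raise SimConfigError("matched_mode must be 'tumor' or 'pooled'")


@dataclass
class SimTruth:
    """Ground truth written by :func:`simulate_cohorts`.

    The three gene classes are pairwise disjoint.  ``slopes`` and
    ``shifts`` give each non-background gene's true miRNA-coupling
    slope and tumor shift (log2 units).
    """

    planted_target_ids: set[str] = field(default_factory=set)
    decoy_down_ids: set[str] = field(default_factory=set)
    decoy_corr_ids: set[str] = field(default_factory=set)
    slopes: dict[str, float] = field(default_factory=dict)
    shifts: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_target_ids": sorted(self.planted_target_ids),
            "decoy_down_ids": sorted(self.decoy_down_ids),
            "decoy_corr_ids": sorted(self.decoy_corr_ids),
            "slopes": dict(sorted(self.slopes.items())),
            "shifts": dict(sorted(self.shifts.items())),
        }


def _gene_ids(n: int, prefix: str = "") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}G{i + 1:0{width}d}" for i in range(n)]


def _assign_truth(
    cfg: CohortSimConfig, gene_ids: list[str], rng: np.random.Generator
) -> SimTruth:
    n_bg_pool = cfg.n_genes - cfg.n_planted_targets
    n_down = round(cfg.frac_decoy_down * n_bg_pool)
    n_corr = round(cfg.frac_decoy_corr * n_bg_pool)
    if n_down + n_corr > n_bg_pool:
        raise SimConfigError("decoy fractions exceed the non-target pool")
    order = rng.permutation(cfg.n_genes)
    planted = [gene_ids[i] for i in order[: cfg.n_planted_targets]]
    rest = order[cfg.n_planted_targets :]
    down = [gene_ids[i] for i in rest[:n_down]]
    corr = [gene_ids[i] for i in rest[n_down : n_down + n_corr]]
    truth = SimTruth(
        planted_target_ids=set(planted),
        decoy_down_ids=set(down),
        decoy_corr_ids=set(corr),
    )
    shift = cfg.target_slope * cfg.mirna_tumor_shift
    for g in planted:
        truth.slopes[g] = cfg.target_slope
        truth.shifts[g] = shift
    for g in down:
        truth.slopes[g] = 0.0
        truth.shifts[g] = shift
    for g in corr:
        truth.slopes[g] = cfg.target_slope
        truth.shifts[g] = 0.0
    return truth


def _simulate_one(
    cfg: CohortSimConfig, gene_ids: list[str], truth: SimTruth,
    rng: np.random.Generator,
) -> Cohort:
    tumor = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    normal = [f"N{i + 1:03d}" for i in range(cfg.n_normal)]
    samples = tumor + normal
    is_tumor = np.array([1.0] * cfg.n_tumor + [0.0] * cfg.n_normal)

    mirna = (
        cfg.mirna_baseline
        + cfg.mirna_tumor_shift * is_tumor
        + rng.normal(0.0, cfg.noise_sd, len(samples))
    )
    mirna_centered = mirna - cfg.mirna_baseline
    mirna_residual = mirna_centered - cfg.mirna_tumor_shift * is_tumor

    baselines = rng.normal(cfg.gene_baseline_mean, cfg.gene_baseline_sd, cfg.n_genes)
    x = np.empty((cfg.n_genes, len(samples)))
    shift = cfg.target_slope * cfg.mirna_tumor_shift
    for gi, g in enumerate(gene_ids):
        noise = rng.normal(0.0, cfg.noise_sd, len(samples))
        if g in truth.planted_target_ids:
            x[gi] = baselines[gi] + cfg.target_slope * mirna_centered + noise
        elif g in truth.decoy_down_ids:
            x[gi] = baselines[gi] + shift * is_tumor + noise
        elif g in truth.decoy_corr_ids:
            x[gi] = baselines[gi] + cfg.target_slope * mirna_residual + noise
        else:
            x[gi] = baselines[gi] + noise

    if cfg.matched_mode == "tumor":
        matched = tumor[: cfg.n_matched]
    else:
        matched = tumor[: cfg.n_matched] + normal[: cfg.n_matched]
    return Cohort(
        name=cfg.name,
        mirna=pd.Series(mirna, index=samples),
        mrna=pd.DataFrame(x, index=gene_ids, columns=samples),
        sample_class=pd.Series(
            ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal, index=samples
        ),
        matched=frozenset(matched),
    )


def simulate_cohorts(
    configs: list[CohortSimConfig], shared_truth: bool = True
) -> tuple[list[Cohort], SimTruth]:
    """Generate one or more expression cohorts with known ground truth.

    With ``shared_truth`` (the default, and the multi-cohort study
    setting) all configs must agree on ``n_genes``; gene identities and
    the planted/decoy class assignment are drawn once, from the first
    config's seed, and reused in every cohort.  Without it each cohort
    gets its own gene universe (ids prefixed with the cohort name) and
    its own truth draw; the returned truth is the union, which stays
    pairwise disjoint because of the prefixes.
    """
    if not configs:
        raise SimConfigError("need at least one cohort config")
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise SimConfigError("cohort names must be unique")
    if shared_truth:
        if len({c.n_genes for c in configs}) != 1:
            raise SimConfigError("shared_truth requires equal n_genes")
        gene_ids = _gene_ids(configs[0].n_genes)
        truth = _assign_truth(
            configs[0], gene_ids, np.random.default_rng([configs[0].seed, 0])
        )
        cohorts = [
            _simulate_one(cfg, gene_ids, truth, np.random.default_rng([cfg.seed, 1]))
            for cfg in configs
        ]
        return cohorts, truth
    union = SimTruth()
    cohorts = []
    for cfg in configs:
        gene_ids = _gene_ids(cfg.n_genes, prefix=f"{cfg.name}:")
        t = _assign_truth(cfg, gene_ids, np.random.default_rng([cfg.seed, 0]))
        cohorts.append(
            _simulate_one(cfg, gene_ids, t, np.random.default_rng([cfg.seed, 1]))
        )
        union.planted_target_ids |= t.planted_target_ids
        union.decoy_down_ids |= t.decoy_down_ids
        union.decoy_corr_ids |= t.decoy_corr_ids
        union.slopes.update(t.slopes)
        union.shifts.update(t.shifts)
    return cohorts, union


def simulate_utrs(
    gene_ids: list[str],
    mirna_sequence: str,
    site_plan: dict[str, list[str]],
    length: int = 200,
    gc_fraction: float = 0.5,
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[list[SeqRecord], dict[str, list[dict]]]:
    """Random 3'-UTRs with seed sites planted at recorded positions.

    Background composition is i.i.d. with the requested GC fraction.
    For genes with a non-empty plan the sequence is rejection-sampled
    until no *unplanned* site of equal-or-higher stringency than the
    loosest planted type exists outside the planted intervals, so the
    recorded truth is exactly the set of such sites.  Genes with an
    empty plan are pure background (spontaneous sites are left alone —
    they are part of the null the scanner is calibrated against).

    Returns Biopython SeqRecords and per-gene truth entries
    ``{"site_type", "start", "end"}`` (1-based inclusive).
    """
    if not (0.0 <= gc_fraction <= 1.0):
        raise SimConfigError("gc_fraction must lie in [0, 1]")
    site_seqs = {}
    for types in site_plan.values():
        for t in types:
            if t not in seedmod.SITE_TYPES:
                raise SimConfigError(f"unknown site type {t!r}")
            site_seqs[t] = seedmod.site_sequence(mirna_sequence, t)
    longest = max((len(s) for s in site_seqs.values()), default=0)
    if longest and length < longest + 2:
        raise SimConfigError(
            f"length {length} too short for a {longest}-nt site (need >= {longest + 2})"
        )
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = np.array(list("ACGT"))
    rank = {t: i for i, t in enumerate(seedmod.SITE_TYPES)}

    records: list[SeqRecord] = []
    truth: dict[str, list[dict]] = {}
    for gene in gene_ids:
        plan = list(site_plan.get(gene, []))
        planned_seqs = [site_seqs[t] for t in plan]
        if sum(len(s) for s in planned_seqs) > length:
            raise SimConfigError(f"sites for {gene!r} do not fit in length {length}")
        for attempt in range(max_tries):
            seq = "".join(rng.choice(bases, size=length, p=probs))
            intervals: list[tuple[int, int, str]] = []  # 0-based [start, end)
            ok = True
            for t, sseq in zip(plan, planned_seqs):
                placed = False
                positions = rng.permutation(length - len(sseq) + 1)
                for pos in positions:
                    if all(
                        pos + len(sseq) <= a or pos >= b for a, b, _ in intervals
                    ):
                        seq = seq[:pos] + sseq + seq[pos + len(sseq) :]
                        intervals.append((int(pos), int(pos) + len(sseq), t))
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if ok and plan:
                # no unplanned site at or above the loosest planted stringency
                loosest = max(rank[t] for t in plan)
                check_types = [t for t in seedmod.SITE_TYPES if rank[t] <= loosest]
                found = seedmod.find_seed_sites(
                    seq, mirna_sequence, site_types=check_types
                )
                for s in found:
                    inside = any(
                        s.start - 1 >= a and s.end <= b for a, b, _ in intervals
                    )
                    if not inside:
                        ok = False
                        break
            if ok:
                break
        else:
            raise SimConfigError(
                f"could not place sites for {gene!r} in {max_tries} tries"
            )
        records.append(SeqRecord(Seq(seq), id=gene, description=""))
        truth[gene] = [
            {"site_type": t, "start": a + 1, "end": b}
            for a, b, t in sorted(intervals)
        ]
    return records, truth


def _check_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise SimConfigError(f"{name} must be positive")


def simulate_dose_response(
    m: float,
    Dm: float,
    doses: list[float] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug: str = "drug",
) -> DoseResponseSeries:
    """Median-effect dose-response fa(D) = D^m / (D^m + Dm^m).

    Noise of sd ``noise_sd`` is added on the logit scale (so fa stays
    strictly inside (0, 1)); with ``noise_sd=0`` the series is exact.
    """
    _check_positive("m", m)
    _check_positive("Dm", Dm)
    if noise_sd < 0:
        raise SimConfigError("noise_sd must be non-negative")
    d = np.asarray(doses, dtype=float)
    if d.size == 0 or np.any(d <= 0):
        raise SimConfigError("doses must be positive and non-empty")
    fa = d**m / (d**m + Dm**m)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = expit(logit(fa) + rng.normal(0.0, noise_sd, fa.shape))
    return DoseResponseSeries(drugs=(drug,), doses=d, fa=fa, design="single")


def simulate_additive_combination(
    fit1_params: tuple[float, float] | MedianEffectFit,
    fit2_params: tuple[float, float] | MedianEffectFit,
    fa_grid: list[float] | np.ndarray,
    ratio: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    drugs: tuple[str, str] = ("drug1", "drug2"),
) -> DoseResponseSeries:
    """Loewe-additive combination series with true combination index 1.

    For each target fraction affected the component doses (d1, d2) with
    d2/d1 = ``ratio`` are placed on the additivity line
    d1/Dx1(fa) + d2/Dx2(fa) = 1, i.e. d1 = 1 / (1/Dx1 + ratio/Dx2).
    Observed fa is the target fa plus logit-scale noise.
    """

    def as_fit(params, label):
        if isinstance(params, MedianEffectFit):
            return params
        m, dm = params
        _check_positive("m", m)
        _check_positive("Dm", dm)
        return MedianEffectFit(drug=label, m=m, Dm=dm, r_linearity=1.0, n_points_used=0)

    fit1 = as_fit(fit1_params, drugs[0])
    fit2 = as_fit(fit2_params, drugs[1])
    _check_positive("ratio", ratio)
    fa = np.asarray(fa_grid, dtype=float)
    if fa.size == 0:
        raise SimConfigError("fa_grid must be non-empty")
    if np.any(fa <= 0) or np.any(fa >= 1):
        raise SimConfigError("fa_grid values must lie strictly in (0, 1)")
    if noise_sd < 0:
        raise SimConfigError("noise_sd must be non-negative")
    d1 = np.empty(fa.size)
    d2 = np.empty(fa.size)
    for i, f in enumerate(fa):
        dx1 = dose_for_effect(fit1, float(f))
        dx2 = dose_for_effect(fit2, float(f))
        d1[i] = 1.0 / (1.0 / dx1 + ratio / dx2)
        d2[i] = ratio * d1[i]
    observed = fa.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        observed = expit(logit(fa) + rng.normal(0.0, noise_sd, fa.shape))
    return DoseResponseSeries(
        drugs=drugs,
        doses=np.column_stack([d1, d2]),
        fa=observed,
        design="constant_ratio",
    )
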