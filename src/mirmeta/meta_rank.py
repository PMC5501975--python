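"""Cross-cohort evidence combination and target ranking.

Per-cohort correlation p-values are made one-sided in the expected
(anticorrelation) direction and combined across cohorts with Fisher's
method (-2 * sum(ln p) on chi-square with 2k df) and Stouffer's method
(summed normal quantiles).  Candidate targets must additionally clear
three filters before being ranked:

* consensus: predicted by at least ``min_votes`` of the six scanner modes,
* deregulation: FDR <= ``fdr_max`` with the expected fold-change sign in
  every cohort,
* anticorrelation: the expected correlation sign in every cohort where a
  correlation is available.

Genes passing all filters are sorted by the Fisher-combined correlation
p-value (Stouffer combined p, then gene id, as tie-breaks; the primary
key is configurable) and assigned ranks 1..k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .cohort_stats import P_FLOOR, GeneCohortStats
from .seeds import ConsensusPrediction

logger = logging.getLogger(__name__)

__all__ = [
    "RankedTarget",
    "fisher_combine",
    "stouffer_combine",
    "to_one_sided",
    "prioritize_targets",
    "ranking_auroc",
]


def ranking_auroc(targets: Sequence["RankedTarget"], positive_ids: set[str]) -> float:
    """Area under the ROC curve of the Fisher-combined ranking.

    Genes are scored by their Fisher-combined correlation p-value
    (smaller = more target-like; genes without correlation data score
    1).  AUROC is computed as the normalized Mann-Whitney U statistic
    of positives vs the rest, i.e. the probability that a random true
    target outranks a random non-target, with ties counted half.
    """
    scores = np.array(
        [
            -(t.combined_p_fisher if t.combined_p_fisher is not None else 1.0)
            for t in targets
        ]
    )
    labels = np.array([t.gene_id in positive_ids for t in targets])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative gene")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: X2 = -2*sum(ln p) ~ chi2(2k).

    For a single p-value the transform is the identity.  The result is
    floored at 1e-300, never 0: a printed combined p of exactly 0 is an
    underflow artefact, not a probability.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(max(sps.chi2.sf(x2, df=2 * p.size), P_FLOOR))


def stouffer_combine(
    p_values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Stouffer's Z combination of one-sided p-values.

    z_i = Phi^-1(1 - p_i); Z = sum(w_i z_i) / sqrt(sum(w_i^2));
    result = 1 - Phi(Z), floored at 1e-300.  Inputs must be strictly
    inside (0, 1): callers holding boundary values must floor/ceiling
    them first (see :func:`to_one_sided`).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p >= 1):
        raise ValueError(
            "one-sided p-values must lie strictly in (0, 1); "
            "pre-floor/ceiling boundary values"
        )
    if weights is None:
        w = np.ones(p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w <= 0):
            raise ValueError("weights must be positive, one per p-value")
    z = sps.norm.isf(p)
    big_z = float((w * z).sum() / math.sqrt(float((w * w).sum())))
    return float(max(sps.norm.sf(big_z), P_FLOOR))


def to_one_sided(
    p_two_sided: float, effect_sign: int, expected_sign: int
) -> float:
    """Directional (one-sided) p-value from a two-sided one.

    p/2 when the observed effect has the expected sign, 1 - p/2
    otherwise; a zero effect maps to 0.5.  Clipped inside
    (1e-300, 1 - 1e-16) so Stouffer's quantile transform stays finite.
    """
    if not (0.0 < p_two_sided <= 1.0):
        raise ValueError("two-sided p must lie in (0, 1]")
    if expected_sign not in (-1, 1):
        raise ValueError("expected_sign must be -1 or +1")
    if effect_sign == 0:
        return 0.5
    if effect_sign not in (-1, 1):
        raise ValueError("effect_sign must be -1, 0 or +1")
    p = p_two_sided / 2.0 if effect_sign == expected_sign else 1.0 - p_two_sided / 2.0
    return min(max(p, P_FLOOR), 1.0 - 1e-16)


@dataclass
class RankedTarget:
    """One gene's combined evidence, filter flags and final rank."""

    gene_id: str
    votes: int
    stats: dict[str, GeneCohortStats]
    combined_p_fisher: float | None
    combined_p_stouffer: float | None
    combined_p_tn_fisher: float | None
    passes_votes: bool
    passes_deregulation: bool
    passes_anticorrelation: bool
    rank: int | None = None
    note: str = ""


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def prioritize_targets(
    stats: Iterable[GeneCohortStats],
    consensus: Mapping[str, ConsensusPrediction | int],
    min_votes: int = 5,
    fdr_max: float = 0.1,
    expected_fold_sign: int = -1,
    expected_r_sign: int = -1,
    primary: str = "fisher",
) -> tuple[list[RankedTarget], dict[str, str]]:
    """Assemble the ranked target table from per-cohort statistics.

    Parameters
    ----------
    stats : per-gene, per-cohort statistics blocks (all cohorts pooled).
    consensus : gene -> ConsensusPrediction (or a bare vote count).
    min_votes, fdr_max, expected_fold_sign, expected_r_sign : the three
        filter thresholds; defaults reproduce "predicted by at least
        five programs, downregulated in every data set, anticorrelated
        with the miRNA".
    primary : "fisher" or "stouffer"; which combined p sorts first.

    Returns the full per-gene report (every gene retained, ranked or
    not) plus a mapping of excluded gene -> reason for genes dropped
    before evaluation (missing cohorts, no consensus entry).
    """
    if primary not in ("fisher", "stouffer"):
        raise ValueError("primary must be 'fisher' or 'stouffer'")
    by_gene: dict[str, dict[str, GeneCohortStats]] = {}
    cohort_names: set[str] = set()
    for s in stats:
        by_gene.setdefault(s.gene_id, {})[s.cohort] = s
        cohort_names.add(s.cohort)

    excluded: dict[str, str] = {}
    results: list[RankedTarget] = []
    for gene, blocks in sorted(by_gene.items()):
        missing = cohort_names - set(blocks)
        if missing:
            reason = f"missing cohorts: {sorted(missing)}"
            logger.info("gene %s excluded: %s", gene, reason)
            excluded[gene] = reason
            continue
        cons = consensus.get(gene)
        votes = cons.votes if isinstance(cons, ConsensusPrediction) else cons
        if votes is None:
            excluded[gene] = "no consensus prediction"
            continue

        passes_votes = votes >= min_votes
        passes_dereg = all(
            b.fdr <= fdr_max and _sign(b.log2fold) == expected_fold_sign
            for b in blocks.values()
        )
        corr_blocks = [b for b in blocks.values() if b.r is not None]
        passes_anti = all(_sign(b.r) == expected_r_sign for b in corr_blocks)

        note = ""
        fisher_p = stouffer_p = None
        if corr_blocks:
            one_sided = [
                to_one_sided(b.p_r, _sign(b.r), expected_r_sign)
                for b in corr_blocks
            ]
            fisher_p = fisher_combine(one_sided)
            stouffer_p = stouffer_combine(one_sided)
        else:
            note = "no cohort with correlation data"
        tn_fisher = fisher_combine([b.p_tn for b in blocks.values()])
        results.append(
            RankedTarget(
                gene_id=gene,
                votes=int(votes),
                stats=blocks,
                combined_p_fisher=fisher_p,
                combined_p_stouffer=stouffer_p,
                combined_p_tn_fisher=tn_fisher,
                passes_votes=passes_votes,
                passes_deregulation=passes_dereg,
                passes_anticorrelation=passes_anti,
                note=note,
            )
        )

    def sort_key(t: RankedTarget) -> tuple[float, float, str]:
        a = t.combined_p_fisher if primary == "fisher" else t.combined_p_stouffer
        b = t.combined_p_stouffer if primary == "fisher" else t.combined_p_fisher
        return (a, b, t.gene_id)

    rankable = [
        t
        for t in results
        if t.passes_votes
        and t.passes_deregulation
        and t.passes_anticorrelation
        and t.combined_p_fisher is not None
    ]
    rankable.sort(key=sort_key)
    for i, t in enumerate(rankable, start=1):
        t.rank = i
    results.sort(
        key=lambda t: (t.rank is None, t.rank if t.rank is not None else 0, t.gene_id)
    )
    return results, excluded
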