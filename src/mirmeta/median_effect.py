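"""Chou-Talalay median-effect fitting and combination-index analysis.

The median-effect equation fa/fu = (D/Dm)^m relates the fraction of
cells affected (fa, with fu = 1 - fa) to dose D through the median
effect dose Dm (here the 50% cytotoxic concentration, CC50) and the
sigmoidicity coefficient m.  Taking logs linearizes it:

    log10(fa / (1 - fa)) = m * log10(D) - m * log10(Dm)

so (m, Dm) come from ordinary least squares on the log-transformed
points (the classical procedure of the CompuSyn program); the
correlation coefficient of that line, r_linearity, measures conformity
to the model.

For a two-drug combination at doses (d1, d2) producing fraction
affected fa, the combination index in the mutually-exclusive (Loewe)
form is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa)

where Dxi(fa) = Dm_i * (fa/(1-fa))^(1/m_i) is the dose of drug i alone
producing fa.  CI < 1 indicates synergy, CI = 1 additivity, CI > 1
antagonism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseSeries",
    "MedianEffectFit",
    "CombinationIndexResult",
    "fit_median_effect",
    "dose_for_effect",
    "combination_index",
    "ci_curve",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class DoseResponseSeries:
    """Dose / fraction-affected data for one drug or a combination.

    ``doses`` has shape (n,) for a single agent or (n, 2) for a
    combination (one column per component drug).  ``design`` is one of
    "single", "constant_ratio", "non_constant_ratio".
    """

    drugs: tuple[str, ...]
    doses: np.ndarray
    fa: np.ndarray
    design: str = "single"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.design not in ("single", "constant_ratio", "non_constant_ratio"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "single":
            if self.doses.ndim != 1:
                raise ValueError("single-agent series needs a 1-d dose vector")
        else:
            if self.doses.ndim != 2 or self.doses.shape[1] != 2:
                raise ValueError("combination series needs (n, 2) dose array")
        if len(self.fa) != len(self.doses):
            raise ValueError("doses and fa must have equal length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(self.fa < 0) or np.any(self.fa > 1):
            raise ValueError("fraction affected must lie in [0, 1]")


@dataclass
class MedianEffectFit:
    """Fitted median-effect parameters for one agent.

    ``dm_se`` is the standard error of Dm propagated from the linear
    fit by the delta method (it is a standard error of the fit, not a
    replicate standard deviation).
    """

    drug: str
    m: float
    Dm: float
    r_linearity: float
    n_points_used: int
    dm_se: float | None = None

    def fa_at(self, dose: float | np.ndarray) -> float | np.ndarray:
        """Fraction affected predicted at ``dose``."""
        d = np.asarray(dose, dtype=float)
        out = 1.0 / (1.0 + (self.Dm / d) ** self.m)
        return float(out) if np.isscalar(dose) else out


def fit_median_effect(
    series: DoseResponseSeries | None = None,
    doses: Sequence[float] | None = None,
    fa: Sequence[float] | None = None,
    drug: str = "",
) -> MedianEffectFit:
    """Least-squares median-effect fit on the log-linearized model.

    Points with fa exactly 0 or 1 have no defined logit and are
    excluded with a warning; at least 2 interior points are required.
    """
    if series is not None:
        if series.design != "single":
            raise ValueError("fit_median_effect needs a single-agent series")
        d = series.doses
        f = series.fa
        drug = drug or series.drugs[0]
    else:
        d = np.asarray(doses, dtype=float)
        f = np.asarray(fa, dtype=float)
    keep = (f > 0.0) & (f < 1.0)
    if keep.sum() < len(f):
        logger.warning(
            "%d dose-response points at fa=0 or fa=1 excluded from the fit",
            int(len(f) - keep.sum()),
        )
    d, f = d[keep], f[keep]
    if d.size < 2:
        raise InsufficientDataError("need >=2 points with 0 < fa < 1")
    x = np.log10(d)
    y = np.log10(f / (1.0 - f))
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all doses equal")
    n = x.size
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    m = float(((x - xbar) * (y - y.mean())).sum() / sxx)
    b = float(y.mean() - m * xbar)
    if m == 0:
        raise ValueError("flat dose-response: slope m = 0, Dm undefined")
    resid = y - (m * x + b)
    syy = float(((y - y.mean()) ** 2).sum())
    r_lin = 1.0 if syy == 0 else float(np.sign(m) * math.sqrt(max(0.0, 1.0 - float((resid**2).sum()) / syy)))
    dm = 10.0 ** (-b / m)
    dm_se = None
    if n > 2:
        s2 = float((resid**2).sum()) / (n - 2)
        var_m = s2 / sxx
        var_b = s2 * (1.0 / n + xbar**2 / sxx)
        cov_mb = -xbar * s2 / sxx
        # delta method on log10(Dm) = -b/m
        g_b = -1.0 / m
        g_m = b / m**2
        var_log = g_b**2 * var_b + g_m**2 * var_m + 2 * g_b * g_m * cov_mb
        if var_log > 0:
            dm_se = math.log(10.0) * dm * math.sqrt(var_log)
    return MedianEffectFit(
        drug=drug,
        m=m,
        Dm=dm,
        r_linearity=r_lin,
        n_points_used=int(n),
        dm_se=dm_se,
    )


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing fraction affected ``fa``: Dm * (fa/(1-fa))^(1/m)."""
    if not (0.0 < fa < 1.0):
        raise ValueError("fa must lie strictly in (0, 1)")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


@dataclass
class CombinationIndexResult:
    """Combination index at one observed (d1, d2, fa) point."""

    fa: float
    d1: float
    d2: float
    Dx1: float
    Dx2: float
    ci: float


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    d1: float,
    d2: float,
    fa_observed: float,
    exclusive: bool = True,
) -> CombinationIndexResult:
    """Combination index of one combination point.

    The mutually-exclusive (Loewe) form d1/Dx1 + d2/Dx2 is the default;
    ``exclusive=False`` adds the non-exclusive interaction term
    d1*d2/(Dx1*Dx2).
    """
    if not (0.0 < fa_observed < 1.0):
        raise ValueError("fa_observed must lie strictly in (0, 1)")
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise ValueError("component doses must be >=0 and not both zero")
    dx1 = dose_for_effect(fit1, fa_observed)
    dx2 = dose_for_effect(fit2, fa_observed)
    ci = d1 / dx1 + d2 / dx2
    if not exclusive:
        ci += (d1 * d2) / (dx1 * dx2)
    return CombinationIndexResult(
        fa=float(fa_observed), d1=float(d1), d2=float(d2), Dx1=dx1, Dx2=dx2, ci=float(ci)
    )


def ci_curve(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    combo_series: DoseResponseSeries,
    exclusive: bool = True,
) -> list[CombinationIndexResult]:
    """CI at every usable combination point, sorted by fraction affected.

    Points with fa outside the open interval (0, 1) are skipped with a
    warning.  Summarize with the median of the returned ``ci`` values.
    """
    if combo_series.design == "single":
        raise ValueError("ci_curve needs a combination series")
    usable = [
        (float(f), float(d[0]), float(d[1]))
        for d, f in zip(combo_series.doses, combo_series.fa)
        if 0.0 < f < 1.0
    ]
    skipped = len(combo_series.fa) - len(usable)
    if skipped:
        logger.warning("%d combination points at fa=0 or fa=1 skipped", skipped)
    if not usable:
        raise InsufficientDataError("no combination point with 0 < fa < 1")
    usable.sort(key=lambda t: t[0])
    return [
        combination_index(fit1, fit2, d1, d2, f, exclusive=exclusive)
        for f, d1, d2 in usable
    ]
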