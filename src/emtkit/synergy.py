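"""Median-effect (Chou-Talalay) analysis of inhibitor combinations.

Single-agent potency is summarized by linearizing the median-effect
equation fa/fu = (D/Dm)^m: ordinary least squares of log10(fa/(1-fa)) on
log10(D) gives the sigmoidicity m (slope) and the median-effect dose
Dm = 10^(-intercept/m).  For a combination point (dA, dB) with affected
fraction fa, the combination index for mutually exclusive agents is

    CI = dA / DxA + dB / DxB,   Dx_i = Dm_i * (fa/(1-fa))^(1/m_i),

with CI < 1 synergy, ~1 additivity, > 1 antagonism.  The mutually
nonexclusive variant (an extra cross-term) is available behind a switch but
is not the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConfigError, InputError

__all__ = [
    "MedianEffectFit",
    "CombinationPoint",
    "fit_median_effect",
    "combination_index",
    "classify_interaction",
    "analyze_combination",
    "DEFAULT_CI_THRESHOLDS",
]

logger = logging.getLogger(__name__)

DEFAULT_CI_THRESHOLDS = (0.9, 1.1)
DEFAULT_FA_EPS = 0.01


@dataclass
class MedianEffectFit:
    """Single-agent median-effect line: slope m, median-effect dose Dm (uM).

    Only affected fractions strictly inside (eps, 1-eps) enter the fit;
    ``n_points_used + n_excluded`` equals the input size.  ``monotone`` is
    False when the fitted slope is non-positive.
    """

    m: float
    dm: float
    r2: float
    n_points_used: int
    n_excluded: int
    monotone: bool = True

    def dx(self, fa: float) -> float:
        """Dose of this agent alone producing affected fraction fa."""
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


def fit_median_effect(doses, fa, eps: float = DEFAULT_FA_EPS
                      ) -> MedianEffectFit:
    """OLS fit of the median-effect line from a single-agent dose series."""
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    if d.shape != f.shape:
        raise InputError("doses and fa must have equal length")
    if not (0.0 < eps < 0.5):
        raise ConfigError("eps must lie in (0, 0.5)")
    usable = np.isfinite(d) & np.isfinite(f) & (d > 0) \
        & (f > eps) & (f < 1.0 - eps)
    n_excluded = int(d.size - usable.sum())
    if usable.sum() < 3:
        raise InputError(
            f"need >=3 usable points with fa in ({eps}, {1 - eps}); "
            f"got {int(usable.sum())}")
    x = np.log10(d[usable])
    y = np.log10(f[usable] / (1.0 - f[usable]))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    monotone = slope > 0
    if not monotone:
        logger.warning("non-monotone median-effect fit: m = %.4g", slope)
        dm = math.nan
    else:
        dm = 10.0 ** (-intercept / slope)
    return MedianEffectFit(m=float(slope), dm=float(dm), r2=r2,
                           n_points_used=int(usable.sum()),
                           n_excluded=n_excluded, monotone=monotone)


@dataclass
class CombinationPoint:
    """CI at one (dA, dB) combination point."""

    dose_a: float
    dose_b: float
    fa: float
    dx_a: float
    dx_b: float
    ci: float
    classification: str


def classify_interaction(ci: float,
                         thresholds: tuple = DEFAULT_CI_THRESHOLDS) -> str:
    """Label a combination index: CI < low synergistic, CI > high
    antagonistic, additive in between."""
    low, high = thresholds
    if not (0.0 < low < high):
        raise ConfigError("need 0 < low < high CI thresholds")
    if ci < low:
        return "synergistic"
    if ci > high:
        return "antagonistic"
    return "additive"


def combination_index(point, fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                      thresholds: tuple = DEFAULT_CI_THRESHOLDS,
                      mutually_exclusive: bool = True) -> CombinationPoint:
    """Chou-Talalay CI for one combination point ``(dA, dB, fa)``.

    Requires fa strictly inside (0, 1) and positive-slope single-agent
    fits.  With ``mutually_exclusive=False`` the deprecated
    mutually-nonexclusive form adds the cross-term
    (dA*dB)/(DxA*DxB).
    """
    dose_a, dose_b, fa = (float(x) for x in point)
    if not (0.0 < fa < 1.0):
        raise InputError(f"fa must lie strictly in (0, 1), got {fa}")
    for name, fit in (("A", fit_a), ("B", fit_b)):
        if not fit.monotone or not math.isfinite(fit.dm):
            raise InputError(f"median-effect fit for drug {name} is not "
                             "usable (non-positive slope)")
    dx_a, dx_b = fit_a.dx(fa), fit_b.dx(fa)
    ci = dose_a / dx_a + dose_b / dx_b
    if not mutually_exclusive:
        ci += (dose_a * dose_b) / (dx_a * dx_b)
    return CombinationPoint(dose_a=dose_a, dose_b=dose_b, fa=fa, dx_a=dx_a,
                            dx_b=dx_b, ci=float(ci),
                            classification=classify_interaction(ci, thresholds))


def analyze_combination(combo: pd.DataFrame, fit_a: MedianEffectFit,
                        fit_b: MedianEffectFit,
                        thresholds: tuple = DEFAULT_CI_THRESHOLDS,
                        mutually_exclusive: bool = True,
                        fa_eps: float = 1e-6) -> pd.DataFrame:
    """CI per combination row (columns dose_a_uM, dose_b_uM, fa).

    Points with fa at 0 or 1 (within ``fa_eps``) are skipped with a log
    entry; negative fa values are clamped to ``fa_eps`` with a warning.
    """
    rows = []
    n_skipped = 0
    for rec in combo.itertuples(index=False):
        fa = float(rec.fa)
        if fa < 0.0:
            logger.warning("negative affected fraction %.4g clamped", fa)
            fa = fa_eps
        if fa <= fa_eps or fa >= 1.0 - fa_eps:
            n_skipped += 1
            continue
        pt = combination_index((rec.dose_a_uM, rec.dose_b_uM, fa),
                               fit_a, fit_b, thresholds, mutually_exclusive)
        rows.append({"dose_a_uM": pt.dose_a, "dose_b_uM": pt.dose_b,
                     "fa": pt.fa, "dx_a_uM": pt.dx_a, "dx_b_uM": pt.dx_b,
                     "ci": pt.ci, "classification": pt.classification})
    if n_skipped:
        logger.info("skipped %d combination points with fa at 0 or 1",
                    n_skipped)
    return pd.DataFrame(rows, columns=["dose_a_uM", "dose_b_uM", "fa",
                                       "dx_a_uM", "dx_b_uM", "ci",
                                       "classification"])
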