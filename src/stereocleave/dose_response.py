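"""Four-parameter log-logistic knockdown fits and absolute IC50.

The model is f(x) = c + (d - c) / (1 + (x/e)^b) with the upper asymptote d
fixed at 100% (the untreated mRNA level).  ``e`` is the inflection
concentration (relative EC50); the *absolute* IC50 — the concentration at
which the fitted response equals 50% of control — is solved in closed form
and is the potency measure used for compound comparison.  Confidence
intervals come from a residual bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .synthetic_data import four_pl

__all__ = [
    "FourPLFit",
    "PotencyRatio",
    "IC50UnattainableError",
    "fit_4pl",
    "absolute_ic50",
    "potency_ratio",
]


class IC50UnattainableError(ValueError):
    """The fitted curve never reaches 50% of control (lower asymptote >= 50)."""


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters; d is fixed at 100% by construction.

    A non-converged or degenerate (no dose effect) fit is flagged, never
    silent; its parameter values are best-effort and must not be consumed
    downstream.
    """

    b: float
    c: float
    e: float
    residual_variance: float
    converged: bool
    d: float = 100.0
    n_obs: int = 0

    def predict(self, x):
        return four_pl(x, self.b, self.c, self.d, self.e)


def _fit_objective(theta, logx, y):
    b, c, loge = theta
    return c + (100.0 - c) / (1.0 + np.exp(b * (logx - loge))) - y


def fit_4pl(concentrations: Sequence[float], responses: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit with d fixed at 100%.

    Deterministic given the data: initialization is b = 1, c = min response,
    e = geometric median concentration, with an analytic restart at -b; the
    lower of the two local optima is returned.  Note (x/e)^b = exp(b (ln x -
    ln e)), so the optimisation runs in log-concentration space, which makes
    the fit exactly scale-equivariant.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if (x <= 0).any():
        raise ValueError("concentrations must be > 0")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct positive concentrations")
    logx = np.log(x)

    degenerate = float(np.ptp(y)) < 1e-9
    b0, c0, loge0 = 1.0, float(y.min()), float(np.median(logx))
    best = None
    for b_init in (b0, -b0):
        sol = least_squares(
            _fit_objective, (b_init, c0, loge0), args=(logx, y),
            method="lm", xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    b, c, loge = best.x
    n = len(y)
    dof = max(n - 3, 1)
    resid_var = 2.0 * best.cost / dof
    converged = bool(best.success) and not degenerate and c < 100.0
    return FourPLFit(
        b=float(b), c=float(c), e=float(math.exp(loge)),
        residual_variance=float(resid_var), converged=converged, n_obs=n,
    )


def absolute_ic50(fit: FourPLFit) -> float:
    """Concentration achieving a response of 50% of control, in closed form:
    x = e * ((100 - c)/(50 - c) - 1)^(1/b)."""
    if not fit.converged:
        raise ValueError("absolute IC50 of a non-converged fit")
    if fit.c >= 50.0:
        raise IC50UnattainableError(
            f"lower asymptote c = {fit.c:.3g} >= 50%: 50% knockdown unattainable"
        )
    return fit.e * ((100.0 - fit.c) / (50.0 - fit.c) - 1.0) ** (1.0 / fit.b)


@dataclass(frozen=True)
class PotencyRatio:
    ratio: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    n_failed: int = 0


def potency_ratio(
    fit_a: FourPLFit,
    fit_b: FourPLFit,
    data_a: tuple[Sequence[float], Sequence[float]] | None = None,
    data_b: tuple[Sequence[float], Sequence[float]] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> PotencyRatio:
    """Absolute-IC50 ratio IC50_a / IC50_b with a percentile bootstrap CI.

    The CI (when both data sets are supplied) is a residual bootstrap:
    residuals of each fit are resampled with replacement onto the fitted
    curve, both curves are refitted, and the 2.5/97.5 percentiles of the
    resampled ratios are reported.  Bootstrap replicates whose refit fails
    or cannot reach 50% are dropped and counted.
    """
    ratio = absolute_ic50(fit_a) / absolute_ic50(fit_b)
    if data_a is None or data_b is None:
        return PotencyRatio(ratio)
    rng = np.random.default_rng(seed)
    sets = []
    for fit, (conc, resp) in ((fit_a, data_a), (fit_b, data_b)):
        x = np.asarray(conc, dtype=float)
        y = np.asarray(resp, dtype=float)
        fitted = fit.predict(x)
        sets.append((x, fitted, y - fitted))
    ratios = []
    failed = 0
    for _ in range(n_boot):
        ic50s = []
        try:
            for x, fitted, resid in sets:
                y_star = fitted + rng.choice(resid, size=len(resid), replace=True)
                ic50s.append(absolute_ic50(fit_4pl(x, y_star)))
        except (ValueError, IC50UnattainableError):
            failed += 1
            continue
        ratios.append(ic50s[0] / ic50s[1])
    if not ratios:
        return PotencyRatio(ratio, n_boot=n_boot, n_failed=failed)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return PotencyRatio(ratio, float(lo), float(hi), n_boot=n_boot, n_failed=failed)
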