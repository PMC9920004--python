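"""Power-law allometry fits, population summaries, growth curves, crossovers.

The allometric law ``y = alpha * x**beta`` relates two leaf traits; it is
fitted per progeny and per density either by ordinary least squares on the
log-log scale or by nonlinear least squares on the original scale (seeded
from the log-log fit).  Goodness of fit (R²) is always reported on the
original measurement scale.

Population mean growth over weeks is summarised by a logistic curve
``K / (1 + b * exp(-r t))``; the week at which the high- and low-density
mean curves intersect (the density crossover) is found by bracketed
root-finding on their difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import LongitudinalTraitSet, TraitPair


@dataclass
class AllometryFit:
    alpha: float
    beta: float
    r_squared: float
    n_points: int
    method: str
    degenerate: bool = False  # SST == 0 (constant response)


def _r_squared_original_scale(x, y, alpha, beta):
    yhat = alpha * np.power(x, beta)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    if sst == 0.0:
        return 1.0, True
    return 1.0 - sse / sst, False


def fit_power_law(x: np.ndarray, y: np.ndarray, method: str = "loglog-ols") -> AllometryFit:
    """Least-squares fit of y = alpha * x**beta.

    ``loglog-ols`` regresses log y on log x and back-transforms;
    ``nonlinear-ls`` refines that start by least squares on the original
    scale.  Both require strictly positive data and at least 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired finite points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0.0:
        raise ValueError("x has zero variance; beta is unidentifiable")
    if np.ptp(ly) == 0.0:
        # constant response: beta = 0, alpha = the constant
        alpha, beta = float(y[0]), 0.0
    else:
        beta, la = np.polyfit(lx, ly, 1)
        alpha = float(np.exp(la))
        beta = float(beta)
    if method == "nonlinear-ls":
        popt, _ = optimize.curve_fit(
            lambda xx, a, b: a * np.power(xx, b), x, y, p0=[alpha, beta], maxfev=10000
        )
        alpha, beta = float(popt[0]), float(popt[1])
    elif method != "loglog-ols":
        raise ValueError(f"unknown method {method!r}")
    r2, degenerate = _r_squared_original_scale(x, y, alpha, beta)
    return AllometryFit(
        alpha=alpha, beta=beta, r_squared=r2, n_points=int(x.size), method=method,
        degenerate=degenerate,
    )


def progeny_fits(
    traits: LongitudinalTraitSet,
    pair: TraitPair,
    method: str = "nonlinear-ls",
    min_points: int = 3,
) -> dict[str, list[AllometryFit | None]]:
    """Per-progeny allometry fits for each density.

    Progenies with fewer than ``min_points`` complete weeks in a density get
    ``None`` there (the power law is not identifiable from < 3 points).
    """
    out: dict[str, list[AllometryFit | None]] = {}
    for d in traits.densities:
        xs = traits.trait_matrix(d, pair.predictor)
        ys = traits.trait_matrix(d, pair.response)
        fits: list[AllometryFit | None] = []
        for i in range(traits.n_progeny):
            ok = np.isfinite(xs[i]) & np.isfinite(ys[i]) & (xs[i] > 0) & (ys[i] > 0)
            if ok.sum() < min_points:
                fits.append(None)
                continue
            fits.append(fit_power_law(xs[i][ok], ys[i][ok], method=method))
        out[d] = fits
    return out


def population_fit_summary(
    traits: LongitudinalTraitSet,
    pair: TraitPair,
    r2_threshold: float,
    method: str = "nonlinear-ls",
) -> dict[str, dict]:
    """Fraction of progenies whose allometry R² exceeds a threshold, per density.

    Mirrors the population goodness-of-fit screen used to decide which trait
    pairs carry a strong enough power law to map (weak pairs are dropped).
    """
    fits = progeny_fits(traits, pair, method=method)
    summary = {}
    for d, dfits in fits.items():
        r2 = np.array([f.r_squared for f in dfits if f is not None])
        if r2.size == 0:
            raise ValueError(f"no progeny could be fitted under density {d!r}")
        summary[d] = {
            "fraction_above": float(np.mean(r2 > r2_threshold)),
            "r_squared": r2,
            "n_fitted": int(r2.size),
        }
    return summary


@dataclass
class GrowthCurveFit:
    """Logistic fit K / (1 + b exp(-r t)) to a mean trajectory."""

    K: float
    r: float
    t0: float  # inflection week: b = exp(r * t0)
    residual_sd: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.K / (1.0 + np.exp(-self.r * (t - self.t0)))


def logistic(t, K, r, t0):
    return K / (1.0 + np.exp(-r * (t - t0)))


def fit_logistic(times: np.ndarray, values: np.ndarray) -> GrowthCurveFit:
    """Least-squares logistic fit to one trajectory (>= 4 points)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    times, values = times[ok], values[ok]
    if times.size < 4:
        raise ValueError("logistic fit needs >= 4 timepoints")
    slope = np.polyfit(times, values, 1)[0]
    if slope <= 0:
        raise ValueError("trajectory is not increasing; logistic growth fit refused")
    p0 = [float(values.max()) * 1.05, 1.0, float(np.median(times))]
    try:
        popt, _ = optimize.curve_fit(
            logistic, times, values, p0=p0,
            bounds=([1e-9, 1e-9, times.min() - 20.0], [np.inf, np.inf, times.max() + 20.0]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - optimizer pathologies
        raise RuntimeError(f"logistic fit did not converge: {err}") from err
    resid = values - logistic(times, *popt)
    return GrowthCurveFit(
        K=float(popt[0]), r=float(popt[1]), t0=float(popt[2]),
        residual_sd=float(np.std(resid)),
    )


def fit_mean_growth_curve(
    traits: LongitudinalTraitSet, trait: str, density: str
) -> GrowthCurveFit:
    """Logistic fit to the progeny-mean trajectory of one trait/density."""
    vals = traits.trait_matrix(density, trait)
    mean = np.nanmean(vals, axis=0)
    return fit_logistic(traits.times[density], mean)


@dataclass
class CrossoverResult:
    time: float | None
    multiple_roots: bool = False
    degenerate: bool = False  # curves identical over the bracket


def crossover_time(
    fit_high: GrowthCurveFit,
    fit_low: GrowthCurveFit,
    bracket: tuple[float, float],
    n_grid: int = 512,
) -> CrossoverResult:
    """Week at which the two density mean curves intersect.

    Scans the bracket on a fine grid for sign changes of
    ``fit_high(t) - fit_low(t)`` and solves each by Brent's method; returns
    the earliest root, flagging multiplicity.  ``time=None`` when the curves
    do not cross in the bracket (or coincide everywhere on it).
    """
    lo, hi = bracket
    grid = np.linspace(lo, hi, n_grid)
    diff = fit_high(grid) - fit_low(grid)
    if np.allclose(diff, 0.0, atol=1e-12):
        return CrossoverResult(time=None, degenerate=True)
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], diff[:-1], diff[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(optimize.brentq(lambda t: fit_high(t) - fit_low(t), a, b)))
    if diff[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        return CrossoverResult(time=None)
    return CrossoverResult(time=roots[0], multiple_roots=len(roots) > 1)
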