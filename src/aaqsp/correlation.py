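"""Hill-model correlation of predicted PGE2 decrease with pain relief.

Pairs the predicted decrease in PGE2 concentration (drug-free minus
drug-treated, over the 6-h window) with placebo-corrected mean pain-relief
scores and fits the sigmoidal Hill equation

    y = a * x**b / (c**b + x**b)

by multi-start nonlinear least squares.  95% confidence intervals come from
a seeded parametric bootstrap; model selection against simpler alternatives
(linear through the origin, Emax without exponent) is by AIC with R2 and
RMSE reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy.optimize import least_squares

__all__ = [
    "PkpdPair",
    "HillFit",
    "FitFailure",
    "evaluate_hill",
    "fit_hill",
    "compare_models",
    "pairs_from_profiles",
]


class FitFailure(RuntimeError):
    """Raised when no start converges; carries the best residual seen."""


@dataclass
class PkpdPair:
    """Paired (PGE2 decrease, placebo-corrected pain relief) observations."""

    x: np.ndarray
    y: np.ndarray
    dose_label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("paired lengths differ")
        if np.any(self.x < 0):
            raise ValueError("x (PGE2 decrease) must be >= 0 for fitting")


class HillFit(BaseModel):
    a: float = Field(gt=0)
    b: float = Field(gt=0)
    c: float = Field(gt=0)
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    ci_c: tuple[float, float]
    r_squared: float
    aic: float
    rmse: float
    model_label: str = "hill"
    n_boot: int = 0

    def predict(self, x) -> np.ndarray:
        return evaluate_hill((self.a, self.b, self.c), x)


def evaluate_hill(params: Sequence[float], x) -> np.ndarray:
    """y = a*x^b / (c^b + x^b), defined for x >= 0 (0 at x = 0)."""
    a, b, c = params
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        xb = np.power(x, b)
        out = a * xb / (np.power(c, b) + xb)
    return np.where(x == 0, 0.0, out)


def _quality(y: np.ndarray, yhat: np.ndarray, k_params: int) -> tuple[float, float, float]:
    resid = y - yhat
    n = len(y)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    # Gaussian log-likelihood AIC with sigma profiled out
    aic = n * np.log(max(sse / n, 1e-300)) + 2 * (k_params + 1)
    rmse = float(np.sqrt(sse / n))
    return r2, aic, rmse


def _fit_once(x, y, p0, bounds) -> Optional[tuple[np.ndarray, float]]:
    try:
        sol = least_squares(
            lambda p: evaluate_hill(p, x) - y, p0, bounds=bounds,
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
    except ValueError:
        return None
    if not sol.success:
        return None
    return sol.x, float(np.sum(sol.fun**2))


def _multi_start(x, y, n_starts: int, rng: np.random.Generator):
    x_pos = x[x > 0]
    y_max = max(float(np.max(y)), 1e-12)
    x_med = float(np.median(x_pos)) if len(x_pos) else 1.0
    x_hi = float(np.max(x)) if np.max(x) > 0 else 1.0
    bounds = (
        np.array([1e-9, 1e-3, 1e-9]),
        np.array([10 * y_max + 1.0, 50.0, 100 * x_hi + 1.0]),
    )
    starts = [np.array([y_max, 1.0, x_med]), np.array([y_max, 4.0, x_med])]
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    y_max * rng.uniform(0.5, 2.0),
                    rng.uniform(0.5, 10.0),
                    x_med * rng.uniform(0.2, 5.0),
                ]
            )
        )
    best = None
    for p0 in starts[:n_starts]:
        res = _fit_once(x, y, np.clip(p0, bounds[0], bounds[1]), bounds)
        if res is not None and (best is None or res[1] < best[1]):
            best = res
    return best, bounds


def fit_hill(
    pairs: PkpdPair | Sequence[PkpdPair],
    n_starts: int = 8,
    seed: int = 0,
    n_boot: int = 1000,
    ci_level: float = 0.95,
) -> HillFit:
    """Multi-start nonlinear least-squares Hill fit with bootstrap CIs.

    Requires at least 5 pairs with non-constant x.  The parametric bootstrap
    resamples y from the fitted curve plus Gaussian noise at the residual
    standard deviation, refits, and takes percentile intervals.  Raises
    :class:`FitFailure` if no start converges or the response carries no
    signal (constant y).
    """
    if isinstance(pairs, PkpdPair):
        x, y = pairs.x, pairs.y
    else:
        x = np.concatenate([p.x for p in pairs])
        y = np.concatenate([p.y for p in pairs])
    if len(x) < 5:
        raise ValueError("need at least 5 pairs to fit the Hill model")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; Hill model unidentifiable")
    if np.ptp(y) == 0:
        raise FitFailure(
            "constant response: Hill parameters unidentifiable (best residual 0)"
        )
    rng = np.random.default_rng(seed)
    best, bounds = _multi_start(x, y, n_starts, rng)
    if best is None:
        raise FitFailure("no start converged")
    p_hat, sse = best
    yhat = evaluate_hill(p_hat, x)
    r2, aic, rmse = _quality(y, yhat, 3)
    dof = max(len(x) - 3, 1)
    sigma = float(np.sqrt(sse / dof))
    boots = np.empty((0, 3))
    if n_boot > 0:
        samples = []
        for _ in range(n_boot):
            y_star = yhat + rng.normal(0.0, sigma, size=len(x))
            res = _fit_once(x, y_star, p_hat, bounds)
            if res is not None:
                samples.append(res[0])
        if samples:
            boots = np.vstack(samples)
    alpha = (1.0 - ci_level) / 2.0
    if len(boots):
        lo = np.quantile(boots, alpha, axis=0)
        hi = np.quantile(boots, 1.0 - alpha, axis=0)
        # percentile intervals may narrowly miss the point estimate on
        # heavily skewed resamples; widen to contain it by construction
        lo = np.minimum(lo, p_hat)
        hi = np.maximum(hi, p_hat)
    else:
        lo = hi = p_hat
    return HillFit(
        a=p_hat[0], b=p_hat[1], c=p_hat[2],
        ci_a=(float(lo[0]), float(hi[0])),
        ci_b=(float(lo[1]), float(hi[1])),
        ci_c=(float(lo[2]), float(hi[2])),
        r_squared=r2, aic=aic, rmse=rmse, n_boot=len(boots),
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _fit_linear(x, y):
    # y = m*x through the origin (the response is zero without drug)
    m = float(np.sum(x * y) / np.sum(x * x))
    return {"m": m}, m * x


def _fit_emax(x, y):
    # Emax without exponent: y = a*x/(c + x)
    def resid(p):
        return p[0] * x / (p[1] + x) - y

    y_max = max(float(np.max(y)), 1e-12)
    x_med = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    sol = least_squares(resid, [y_max, x_med], bounds=([1e-9, 1e-9], [np.inf, np.inf]))
    if not sol.success:
        raise FitFailure("Emax fit failed")
    return {"a": float(sol.x[0]), "c": float(sol.x[1])}, sol.x[0] * x / (sol.x[1] + x)


def compare_models(
    pairs: PkpdPair | Sequence[PkpdPair],
    candidates: Sequence[str] = ("hill", "emax", "linear"),
    seed: int = 0,
) -> list[dict]:
    """Fit each candidate and rank by AIC (R2 and RMSE reported alongside).

    Failed fits are marked, not fatal.  Candidate names: ``hill``, ``emax``
    (hyperbolic, no exponent), ``linear`` (through the origin).
    """
    if isinstance(pairs, PkpdPair):
        x, y = pairs.x, pairs.y
    else:
        x = np.concatenate([p.x for p in pairs])
        y = np.concatenate([p.y for p in pairs])
    rows = []
    for name in candidates:
        try:
            if name == "hill":
                fit = fit_hill(PkpdPair(x, y), seed=seed, n_boot=0)
                params = {"a": fit.a, "b": fit.b, "c": fit.c}
                yhat = fit.predict(x)
                k = 3
            elif name == "emax":
                params, yhat = _fit_emax(x, y)
                k = 2
            elif name == "linear":
                params, yhat = _fit_linear(x, y)
                k = 1
            else:
                raise ValueError(f"unknown candidate {name!r}")
            r2, aic, rmse = _quality(y, yhat, k)
            rows.append(
                {"model": name, "params": params, "r_squared": r2,
                 "aic": aic, "rmse": rmse, "failed": False}
            )
        except (FitFailure, ValueError) as exc:
            rows.append(
                {"model": name, "params": None, "r_squared": None,
                 "aic": float("inf"), "rmse": None, "failed": True,
                 "error": str(exc)}
            )
    rows.sort(key=lambda r: r["aic"])
    for rank, r in enumerate(rows, start=1):
        r["rank"] = rank
    return rows


# ---------------------------------------------------------------------------
# pairing helper
# ---------------------------------------------------------------------------

def pairs_from_profiles(
    control, treated, pain_relief: Callable[[float], float],
    times_min: Sequence[float], dose_label: str = "",
) -> PkpdPair:
    """Build (PGE2 decrease, pain relief) pairs at matched times from paired
    network runs; ``pain_relief`` maps time (min) to the placebo-corrected
    mean score."""
    x = []
    y = []
    for t in times_min:
        from .network import PGE2

        x.append(max(control.at(PGE2, t) - treated.at(PGE2, t), 0.0))
        y.append(pain_relief(t))
    return PkpdPair(np.asarray(x), np.asarray(y), dose_label)
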