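"""Temporal trend models for first-record rate series.

Five candidate families describe how a first-record rate ``y`` changes
with time ``x`` (years since a configurable origin):

========== ===========================================  ==
family     closed form                                  k
========== ===========================================  ==
linear     ``y = a + b*x``                              2
exponential``y = a * exp(b*x)``                         2
saturating ``y = a * (1 - exp(-b*x))``                  2
sigmoidal  ``y = a * x**b / (x**b + c**b)``             3
weibull    ``y = a*(b/c)*(x/c)**(b-1)*exp(-(x/c)**b)``  3
========== ===========================================  ==

The Weibull family is a scaled Weibull density and is the only
hump-shaped candidate; it captures rates that rise and then decline
(the pattern shown by mammals and fishes).  Each family is fitted by
least squares with multi-start Nelder--Mead, and the winning family is
the one with the smallest AIC, computed under Gaussian errors as
``n*ln(SSE/n) + 2*(k+1)`` (the ``+1`` counts the error variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "FAMILIES",
    "FAMILY_ORDER",
    "DomainError",
    "FitResult",
    "ModelSelection",
    "evaluate_family",
    "aic_gaussian",
    "fit_family",
    "fit_xy",
    "select_model",
    "minimize_multistart",
]

FAMILY_ORDER: tuple[str, ...] = (
    "linear",
    "exponential",
    "saturating",
    "sigmoidal",
    "weibull",
)

#: family -> number of free parameters k
FAMILIES: dict[str, int] = {
    "linear": 2,
    "exponential": 2,
    "saturating": 2,
    "sigmoidal": 3,
    "weibull": 3,
}

#: families whose x-domain is restricted to x > 0
_POSITIVE_X = frozenset({"sigmoidal", "weibull"})


class DomainError(ValueError):
    """An x value lies outside a family's domain."""


def _check_domain(family: str, x: np.ndarray) -> None:
    if family in _POSITIVE_X and np.any(x <= 0):
        bad = float(np.asarray(x)[np.asarray(x) <= 0][0])
        raise DomainError(f"family '{family}' requires x > 0, got x={bad}")


def evaluate_family(family: str, theta, x) -> np.ndarray:
    """Evaluate a trend family pointwise.

    Parameters
    ----------
    family : one of ``FAMILY_ORDER``
    theta : parameter vector ``(a, b)`` or ``(a, b, c)``
    x : time values (years since origin); must be > 0 for the
        sigmoidal and weibull families.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"unknown trend family '{family}'")
    if len(theta) != FAMILIES[family]:
        raise ValueError(
            f"family '{family}' takes {FAMILIES[family]} parameters, "
            f"got {len(theta)}"
        )
    _check_domain(family, x)
    if family == "linear":
        a, b = theta
        return a + b * x
    if family == "exponential":
        a, b = theta
        return a * np.exp(b * x)
    if family == "saturating":
        a, b = theta
        return a * (1.0 - np.exp(-b * x))
    if family == "sigmoidal":
        a, b, c = theta
        xb = np.power(x, b)
        return a * xb / (xb + np.power(c, b))
    # weibull: scaled density with shape b and scale c
    a, b, c = theta
    z = x / c
    return a * (b / c) * np.power(z, b - 1.0) * np.exp(-np.power(z, b))


def aic_gaussian(sse: float, n: int, k: int) -> float:
    """AIC for a least-squares fit under i.i.d. Gaussian errors.

    ``n*ln(SSE/n) + 2*(k+1)``; the error variance counts as one
    estimated parameter.  A perfect fit (SSE -> 0) gives -inf, which
    correctly dominates model selection.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mse = sse / n
    if mse <= 0.0:
        return -np.inf
    return n * float(np.log(mse)) + 2.0 * (k + 1)


# ---------------------------------------------------------------------------
# internal parameterization: positivity-constrained parameters are fitted on
# a log scale so Nelder--Mead stays unconstrained
# ---------------------------------------------------------------------------

#: parameters fitted on a log scale: amplitudes of the nonlinear
#: families (first-record rates are non-negative) and rate/shape/scale
#: constants that must stay positive.  The linear family keeps both
#: parameters free so fits may go negative for pathological data.
_LOG_PARAMS: dict[str, tuple[int, ...]] = {
    "linear": (),
    "exponential": (0,),
    "saturating": (0, 1),
    "sigmoidal": (0, 2),
    "weibull": (0, 1, 2),
}

#: soft box on the internal (log) scale: coordinates beyond this are
#: astronomically degenerate (e.g. amplitude e^50); a quadratic penalty
#: past it gives otherwise-flat ridges a slope so the simplex converges
_SOFT_BOUND = 50.0


def _to_internal(family: str, theta: np.ndarray) -> np.ndarray:
    z = np.array(theta, dtype=float)
    for i in _LOG_PARAMS[family]:
        z[i] = np.log(z[i])
    return z


def _from_internal(family: str, z: np.ndarray) -> np.ndarray:
    theta = np.array(z, dtype=float)
    for i in _LOG_PARAMS[family]:
        theta[i] = np.exp(np.clip(theta[i], -700, 700))
    return theta


def _heuristic_start(family: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Data-driven initial parameters (natural scale)."""
    ymax = float(np.max(y)) if y.size else 1.0
    if ymax <= 0:
        ymax = 1.0
    xspan = float(np.ptp(x)) or 1.0
    if family == "linear":
        b, a = np.polyfit(x, y, 1)
        return np.array([a, b])
    if family == "exponential":
        ypos = np.clip(y, ymax * 1e-6, None)
        b, loga = np.polyfit(x, np.log(ypos), 1)
        return np.array([np.exp(loga), b])
    if family == "saturating":
        half = np.searchsorted(np.maximum.accumulate(y), ymax / 2.0)
        x_half = float(x[min(half, len(x) - 1)])
        b = np.log(2.0) / max(x_half, 1e-6)
        return np.array([ymax * 1.05, b])
    if family == "sigmoidal":
        half = np.searchsorted(np.maximum.accumulate(y), ymax / 2.0)
        c = float(x[min(half, len(x) - 1)])
        return np.array([ymax * 1.05, 4.0, max(c, 1e-3)])
    # weibull: put the mode at the empirical peak
    x_peak = float(x[int(np.argmax(y))])
    b0, c0 = 2.0, max(x_peak, 1e-3)
    peak_val = float(evaluate_family("weibull", (1.0, b0, c0), [max(x_peak, 1e-6)])[0])
    a0 = ymax / peak_val if peak_val > 0 else ymax
    return np.array([a0, b0, c0])


def _make_objective(family: str, x: np.ndarray, y: np.ndarray):
    """SSE objective on the internal (log-transformed) parameter scale.

    Exponents are clipped so Nelder--Mead never sees overflow plateaus,
    which would stall the simplex.
    """

    # coordinates on a log/exponent scale, where |z| > _SOFT_BOUND is
    # astronomically degenerate; the linear family's raw intercept and
    # slope are never penalized
    bounded = np.arange(0 if family == "linear" else FAMILIES[family])

    def _sse(pred: np.ndarray, z: np.ndarray) -> float:
        r = y - pred
        s = float(r @ r)
        if not np.isfinite(s):
            return np.inf
        if bounded.size:
            excess = np.abs(z[bounded]) - _SOFT_BOUND
            if np.any(excess > 0):
                s += float(np.sum(np.clip(excess, 0.0, None) ** 2))
        return s

    def _exp(v):
        return np.exp(np.clip(v, -700.0, 700.0))

    if family == "linear":

        def objective(z):
            return _sse(z[0] + z[1] * x, z)

    elif family == "exponential":

        def objective(z):  # z = (log a, b)
            return _sse(_exp(z[0] + z[1] * x), z)

    elif family == "saturating":

        def objective(z):  # z = (log a, log b)
            return _sse(_exp(z[0]) * (1.0 - _exp(-_exp(z[1]) * x)), z)

    elif family == "sigmoidal":
        logx = np.log(x)

        def objective(z):  # z = (log a, b, log c)
            xb = _exp(z[1] * logx)
            cb = _exp(z[1] * z[2])
            return _sse(_exp(z[0]) * xb / (xb + cb), z)

    elif family == "weibull":
        logx = np.log(x)

        def objective(z):  # z = (log a, log b, log c)
            b = _exp(z[1])
            logz = logx - z[2]
            zb = _exp(b * logz)
            pred = b * _exp(z[0] + (b - 1.0) * logz - z[2] - zb)
            return _sse(pred, z)

    else:
        raise ValueError(f"unknown trend family '{family}'")

    return objective


def minimize_multistart(
    objective,
    starts,
    *,
    maxiter: int = 5000,
    tol: float = 1e-8,
):
    """Run Nelder--Mead from several starting points, keep the best.

    Returns ``(best_theta, best_fval, any_converged, n_runs)``.  Shared by
    the trend fits and the Michaelis--Menten fit.
    """
    best_theta = None
    best_fval = np.inf
    converged = False
    n_runs = 0
    for z0 in starts:
        z0 = np.asarray(z0, dtype=float)
        if not np.all(np.isfinite(z0)):
            continue
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            res = minimize(
            objective,
            z0,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": tol,
                "fatol": tol,
            },
        )
        n_runs += 1
        if np.isfinite(res.fun) and res.fun < best_fval:
            best_fval = float(res.fun)
            best_theta = np.asarray(res.x, dtype=float)
            converged = converged or bool(res.success)
    return best_theta, best_fval, converged, n_runs


@dataclass
class FitResult:
    """Outcome of fitting one family to one rate series."""

    family: str
    theta: np.ndarray
    sse: float
    n: int
    k: int
    aic: float
    fitted: np.ndarray
    converged: bool
    n_restarts: int

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "theta": [float(t) for t in self.theta],
            "sse": float(self.sse),
            "n": self.n,
            "k": self.k,
            "aic": float(self.aic),
            "converged": self.converged,
            "n_restarts": self.n_restarts,
        }


@dataclass
class ModelSelection:
    """All five fits plus the AIC winner."""

    fits: dict[str, FitResult]
    winner: str
    delta_aic: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "winner": self.winner,
            "delta_aic": {f: float(d) for f, d in self.delta_aic.items()},
            "fits": {f: r.to_dict() for f, r in self.fits.items()},
        }


def fit_xy(
    x,
    y,
    family: str,
    *,
    n_restarts: int = 20,
    rng: np.random.Generator | None = None,
    maxiter: int = 5000,
    tol: float = 1e-8,
) -> FitResult:
    """Least-squares fit of one family to (x, y) by multi-start Nelder--Mead.

    One start is the data-driven heuristic; the remaining
    ``n_restarts - 1`` perturb it randomly.  Requires at least k+2
    points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = FAMILIES[family]
    if len(x) < k + 2:
        raise ValueError(
            f"need at least {k + 2} points to fit '{family}', got {len(x)}"
        )
    _check_domain(family, x)
    if rng is None:
        rng = np.random.default_rng(0)

    objective = _make_objective(family, x, y)

    z_heur = _to_internal(family, _heuristic_start(family, x, y))
    starts = [z_heur]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(z_heur + rng.normal(0.0, 0.5, size=z_heur.shape) * (
            np.abs(z_heur) + 1.0
        ))
    z_best, sse, converged, n_runs = minimize_multistart(
        objective, starts, maxiter=maxiter, tol=tol
    )
    if z_best is None:
        theta = _heuristic_start(family, x, y)
        return FitResult(
            family=family,
            theta=theta,
            sse=np.inf,
            n=len(x),
            k=k,
            aic=np.inf,
            fitted=np.full_like(x, np.nan),
            converged=False,
            n_restarts=n_runs,
        )
    theta = _from_internal(family, z_best)
    fitted = evaluate_family(family, theta, x)
    return FitResult(
        family=family,
        theta=theta,
        sse=sse,
        n=len(x),
        k=k,
        aic=aic_gaussian(sse, len(x), k),
        fitted=fitted,
        converged=converged,
        n_restarts=n_runs,
    )


def _series_xy(series, origin_year: int):
    """x/y arrays from a RateSeries; x = bin start year - origin."""
    x = np.asarray(series.bin_start_years, dtype=float) - origin_year
    y = np.asarray(series.counts, dtype=float)
    return x, y


def fit_family(
    series,
    family: str,
    *,
    origin_year: int = 1499,
    n_restarts: int = 20,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit one family to a binned rate series.

    Time is measured as ``bin start year - origin_year``; the default
    origin 1499 makes x >= 1 on an analysis span starting 1500, keeping
    the sigmoidal and Weibull families inside their domain.
    """
    x, y = _series_xy(series, origin_year)
    return fit_xy(x, y, family, n_restarts=n_restarts, rng=rng)


def select_model(
    series_or_x,
    y=None,
    *,
    origin_year: int = 1499,
    n_restarts: int = 20,
    rng: np.random.Generator | None = None,
) -> ModelSelection:
    """Fit all five families and pick the smallest-AIC winner.

    Accepts either a RateSeries (with ``origin_year``) or raw x/y
    arrays.  Ties are broken toward fewer parameters, then the fixed
    family order.  Raises if fewer than two families converge.
    """
    if y is None:
        x, yv = _series_xy(series_or_x, origin_year)
    else:
        x = np.asarray(series_or_x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    fits = {
        fam: fit_xy(x, yv, fam, n_restarts=n_restarts, rng=rng)
        for fam in FAMILY_ORDER
    }
    n_ok = sum(r.converged and np.isfinite(r.sse) for r in fits.values())
    if n_ok < 2:
        raise RuntimeError(
            f"model selection needs >= 2 converged fits, got {n_ok}"
        )
    ranked = sorted(
        fits.values(),
        key=lambda r: (r.aic, r.k, FAMILY_ORDER.index(r.family)),
    )
    winner = ranked[0].family
    best_aic = ranked[0].aic
    delta = {
        fam: (r.aic - best_aic) if np.isfinite(r.aic) else np.inf
        for fam, r in fits.items()
    }
    if not np.isfinite(best_aic):  # perfect fit: delta 0 for winner only
        delta = {
            fam: 0.0 if fam == winner else np.inf for fam in fits
        }
    return ModelSelection(fits=fits, winner=winner, delta_aic=delta)
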