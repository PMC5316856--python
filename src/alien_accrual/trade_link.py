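"""Coupling first-record rates to the value of imported commodities.

The relationship between annual import value M and the first-record
rate R is assumed to saturate at large import values and is modelled by
a Michaelis--Menten curve

    R = Rmax * M / (K + M),

where Rmax is the asymptotic rate and K the import value at which the
rate reaches half its asymptote.  The fit minimizes squared error by
multi-start Nelder--Mead (sharing the optimizer used for the trend
families) and reports goodness of fit as the Pearson correlation
between observed and fitted rates.  Import values may optionally be
deflated by a consumer price index; non-deflated values are the
default, trading inflation bias for a longer usable time span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records_pipeline import RateSeries
from .synth_data import TradeSeries
from .trend_models import minimize_multistart

__all__ = [
    "MMFit",
    "deflate",
    "aggregate_total",
    "align",
    "fit_michaelis_menten",
    "michaelis_menten",
    "read_trade_table",
]

logger = logging.getLogger(__name__)


@dataclass
class MMFit:
    """Fitted Michaelis--Menten relationship between imports and rates."""

    rmax: float
    k: float
    sse: float
    fitted: np.ndarray
    pearson_r: float
    converged: bool
    degenerate: bool = False

    def predict(self, m) -> np.ndarray:
        return michaelis_menten(np.asarray(m, dtype=float), self.rmax, self.k)

    def to_dict(self) -> dict:
        return {
            "rmax": float(self.rmax),
            "k": float(self.k),
            "sse": float(self.sse),
            "pearson_r": float(self.pearson_r),
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


def michaelis_menten(m: np.ndarray, rmax: float, k: float) -> np.ndarray:
    return rmax * m / (k + m)


def deflate(trade: TradeSeries) -> TradeSeries:
    """Divide each year's import value by that year's CPI.

    Years with a missing (NaN) CPI are dropped with a logged warning.
    """
    if trade.cpi is None:
        raise ValueError("trade series carries no CPI")
    ok = np.isfinite(trade.cpi)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning(
            "dropping %d year(s) without CPI from %s", n_drop, trade.country_id
        )
    return TradeSeries(
        country_id=trade.country_id,
        years=trade.years[ok],
        import_value=trade.import_value[ok] / trade.cpi[ok],
        cpi=trade.cpi[ok],
    )


def aggregate_total(series: list[TradeSeries], *, country_id: str = "TOTAL") -> TradeSeries:
    """Sum import values across reporting countries per year.

    A country contributes to a year's total only if it reports that
    year, mirroring how global import totals are assembled from an
    uneven country panel.
    """
    if not series:
        raise ValueError("no trade series to aggregate")
    frames = [
        pd.DataFrame({"year": s.years, "value": s.import_value}) for s in series
    ]
    total = (
        pd.concat(frames, ignore_index=True)
        .groupby("year", as_index=False)["value"]
        .sum()
        .sort_values("year")
    )
    return TradeSeries(
        country_id=country_id,
        years=total["year"].to_numpy(),
        import_value=total["value"].to_numpy(),
    )


def align(rates: RateSeries, trade: TradeSeries) -> pd.DataFrame:
    """Pair first-record rates with import values on overlapping years.

    Annual rate series are inner-joined on year.  Coarser series pair
    each bin with the *mean* annual import value over the years of that
    bin (only years the trade series reports).  Returns a frame with
    columns ``year`` (bin start), ``M`` and ``R`` sorted by year.
    """
    trade_by_year = pd.Series(trade.import_value, index=trade.years)
    rows = []
    for start, count in zip(rates.bin_start_years, rates.counts):
        yrs = np.arange(start, start + rates.bin_width)
        vals = trade_by_year.reindex(yrs).dropna()
        if len(vals) == 0:
            continue
        rows.append({"year": int(start), "M": float(vals.mean()), "R": float(count)})
    if not rows:
        raise ValueError("rate and trade series share no years")
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def fit_michaelis_menten(
    pairs: pd.DataFrame,
    *,
    n_restarts: int = 10,
    rng: np.random.Generator | None = None,
) -> MMFit:
    """Least-squares Michaelis--Menten fit of R against M.

    Needs at least 4 pairs with positive M.  Rmax and K are kept
    positive by optimizing on a log scale.  A constant observed R is a
    saturated limit (Rmax -> R, K -> 0) and is flagged degenerate; the
    Pearson r is undefined there and reported as NaN.
    """
    m = np.asarray(pairs["M"], dtype=float)
    r = np.asarray(pairs["R"], dtype=float)
    if len(m) < 4:
        raise ValueError("need at least 4 (M, R) pairs")
    if np.any(m <= 0):
        raise ValueError("import values must be positive")
    if rng is None:
        rng = np.random.default_rng(0)

    def objective(z: np.ndarray) -> float:
        rmax, k = np.exp(np.clip(z, -700, 700))
        resid = r - michaelis_menten(m, rmax, k)
        return float(resid @ resid)

    rmax0 = max(float(np.max(r)), 1e-12) * 1.2
    k0 = float(np.median(m))
    z0 = np.log([rmax0, k0])
    starts = [z0]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(z0 + rng.normal(0.0, 1.0, size=2))
    z_best, sse, converged, _ = minimize_multistart(objective, starts)
    if z_best is None:
        return MMFit(
            rmax=np.nan,
            k=np.nan,
            sse=np.inf,
            fitted=np.full_like(r, np.nan),
            pearson_r=np.nan,
            converged=False,
        )
    rmax, k = np.exp(z_best)
    fitted = michaelis_menten(m, rmax, k)
    degenerate = float(np.std(fitted)) < 1e-12 or float(np.std(r)) < 1e-12
    if degenerate or not converged:
        pearson = np.nan
    else:
        pearson = float(stats.pearsonr(r, fitted).statistic)
    return MMFit(
        rmax=float(rmax),
        k=float(k),
        sse=float(sse),
        fitted=fitted,
        pearson_r=pearson,
        converged=converged,
        degenerate=degenerate,
    )


def read_trade_table(path) -> list[TradeSeries]:
    """Read a tab-separated trade table: ``country_id year import_usd [cpi]``."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for country, grp in df.groupby("country_id"):
        grp = grp.sort_values("year")
        cpi = grp["cpi"].to_numpy(dtype=float) if "cpi" in grp.columns else None
        out.append(
            TradeSeries(
                country_id=str(country),
                years=grp["year"].to_numpy(dtype=int),
                import_value=grp["import_usd"].to_numpy(dtype=float),
                cpi=cpi,
            )
        )
    return out
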