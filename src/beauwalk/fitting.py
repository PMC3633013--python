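"""Parameter estimation from displacement curves.

Two fitters recover macroscopic parameters from an MSD curve — the exact
asymptotic line of the pause-and-run model (slope ``2M``, intercept
``-2 M t_free / 3``) and Fürth's persistent-random-walk equation — plus the
grid-ranking machinery that scores candidate microscopic triplets against a
reference curve by sum of squared residuals (SSR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .errors import DataError, FitError
from .model import ModelParams, NO_TAXIS
from .simulate import simulate_ensemble
from .theory import furth_msd, motility_coefficient
from .trackstats import StatCurve, mean_displacement, mean_square_displacement

__all__ = ["FitResult", "fit_linear_msd", "fit_furth", "rank_parameter_grid"]

log = logging.getLogger("beauwalk")


@dataclass
class FitResult:
    """Estimated parameters with goodness of fit.

    ``estimates`` maps parameter names to values (per observed dimension
    for M); ``ssr`` is the unweighted sum of squared residuals over the
    ``n_points`` fitted points.
    """

    estimates: dict
    ssr: float
    n_points: int
    method: str
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ssr < 0:
            raise ValueError("SSR must be >= 0")
        if self.estimates.get("M", 0.0) < 0:
            raise ValueError("estimated M must be >= 0")


def _select_range(curve: StatCurve, fit_range) -> np.ndarray:
    lo, hi = fit_range
    mask = (curve.t >= lo - 1e-9) & (curve.t <= hi + 1e-9)
    if mask.sum() < 3:
        raise DataError(
            f"fewer than 3 curve points in fit range [{lo}, {hi}] "
            f"(grid spans [{curve.t[0]}, {curve.t[-1]}])"
        )
    return mask


def _wls_line(t, y, se) -> tuple[float, float, float]:
    """Weighted least squares of y = alpha t + beta; returns (alpha, beta, ssr)."""
    X = sm.add_constant(t)
    if np.all(se > 0):
        res = sm.WLS(y, X, weights=1.0 / se**2).fit()
    else:
        res = sm.OLS(y, X).fit()
    beta, alpha = res.params
    ssr = float(np.sum((y - (alpha * t + beta)) ** 2))
    return float(alpha), float(beta), ssr


def fit_linear_msd(curve: StatCurve, fit_range: tuple[float, float] | None = None) -> FitResult:
    """Fit the asymptotic line ``alpha t + beta`` to an MSD curve.

    Returns per-dimension ``M = alpha / (2 * dims)`` and
    ``t_free = -3 beta / alpha``; a positive intercept (no resolvable
    persistence) reports ``t_free = 0`` with a warning.  Points are weighted
    by ``1 / SE²`` when standard errors are available.

    The line holds only for ``t >= t_free``, so when no ``fit_range`` is
    given the fit is run once over the full grid to get a ``t_free`` guess
    and then repeated over ``[max(grid start, 2 * guess), grid end]``.
    """
    if curve.statistic != "msd":
        raise DataError(f"fit_linear_msd needs an MSD curve, got {curve.statistic!r}")
    ndim = len(curve.dims)
    warnings: list[str] = []

    if fit_range is None:
        mask0 = curve.t > 0
        if mask0.sum() < 3:
            raise DataError("need at least 3 positive-time points")
        a0, b0, _ = _wls_line(curve.t[mask0], curve.value[mask0], curve.se[mask0])
        guess = max(0.0, -3.0 * b0 / a0) if a0 > 0 else 0.0
        fit_range = (max(float(curve.t[mask0][0]), 2.0 * guess), float(curve.t[-1]))
        log.debug("fit_linear_msd: auto range %s from t_free guess %.3g", fit_range, guess)

    mask = _select_range(curve, fit_range)
    alpha, beta, ssr = _wls_line(curve.t[mask], curve.value[mask], curve.se[mask])
    if alpha <= 0:
        raise FitError(f"non-positive fitted MSD slope {alpha}")
    if beta > 0:
        warnings.append(f"positive intercept {beta:.4g}; reporting t_free = 0")
        t_free = 0.0
    else:
        t_free = -3.0 * beta / alpha
    return FitResult(
        estimates={"M": alpha / (2.0 * ndim), "t_free": t_free, "alpha": alpha, "beta": beta},
        ssr=ssr,
        n_points=int(mask.sum()),
        method="linear_msd",
        warnings=warnings,
    )


def fit_furth(curve: StatCurve) -> FitResult:
    """Nonlinear least squares of Fürth's equation ``2M (t - P (1 - e^{-t/P}))``.

    Multistart over several persistence-time initial values with positivity
    bounds; raises :class:`FitError` if no start converges.  ``M`` is
    reported per observed dimension.
    """
    if curve.statistic != "msd":
        raise DataError(f"fit_furth needs an MSD curve, got {curve.statistic!r}")
    mask = curve.t > 0
    if mask.sum() < 5:
        raise DataError("need at least 5 positive-time points for a Fürth fit")
    t, y, se = curve.t[mask], curve.value[mask], curve.se[mask]
    w = 1.0 / se if np.all(se > 0) else np.ones_like(t)
    ndim = len(curve.dims)

    a0, b0, _ = _wls_line(t, y, se)
    M0 = max(a0 / 2.0, 1e-6)
    span = float(t[-1] - t[0])
    p_starts = [max(-3.0 * b0 / a0, 1e-3) if a0 > 0 else 1.0, span / 10.0, 1.0, 1e-3]

    def resid(theta):
        M, P = theta
        return w * (furth_msd(t, M, P) - y)

    best = None
    for P0 in p_starts:
        try:
            sol = least_squares(resid, x0=[M0, P0], bounds=([0.0, 0.0], [np.inf, np.inf]))
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(
            f"Fürth fit did not converge from starts {p_starts} (M0={M0:.4g})"
        )
    M, P = best.x
    ssr = float(np.sum((furth_msd(t, M, P) - y) ** 2))
    return FitResult(
        estimates={"M": M / ndim, "P": P},
        ssr=ssr,
        n_points=int(mask.sum()),
        method="furth",
    )


def rank_parameter_grid(
    reference: StatCurve,
    grid: list[ModelParams],
    n_per_sim: int = 10_000,
    seed: int = 0,
    phase_mode: str = "stationary",
) -> pd.DataFrame:
    """Score candidate triplets against a reference curve by simulation.

    For each triplet, ``n_per_sim`` tracks are simulated (stationary phase,
    unbiased) on the reference grid, the matching statistic (MSD or mean
    displacement, same coordinate view) is computed, and its SSR against
    the reference recorded.  The table is sorted ascending by SSR with the
    column normalized to the best fit (best = 1.00) and includes each
    triplet's motility coefficient.

    SSR uses uniform weighting over the reference grid points.
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    if reference.statistic not in ("msd", "mean_displacement"):
        raise DataError(
            f"reference must be an MSD or mean-displacement curve, got {reference.statistic!r}"
        )
    dts = np.diff(reference.t)
    if not np.allclose(dts, dts[0]):
        raise DataError("reference grid must be uniform")
    sample_dt = float(dts[0])
    duration = float(reference.t[-1])
    stat_fn = (
        mean_square_displacement
        if reference.statistic == "msd"
        else mean_displacement
    )

    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(grid))
    for params, child in zip(grid, seeds):
        ts = simulate_ensemble(
            n_per_sim, params, NO_TAXIS, duration, sample_dt, phase_mode, seed=child
        )
        est = stat_fn(ts, dims=reference.dims)
        common = np.isin(np.round(est.t, 9), np.round(reference.t, 9))
        if int(common.sum()) != len(reference):
            raise DataError("reference grid is not a subset of the simulated grid")
        ssr = float(np.sum((est.value[common] - reference.value) ** 2))
        rows.append(
            {
                "t_pause": params.t_pause,
                "t_free": params.t_free,
                "v_free": params.v_free,
                "M": motility_coefficient(params),
                "ssr_raw": ssr,
            }
        )
    table = pd.DataFrame(rows).sort_values("ssr_raw", kind="stable").reset_index(drop=True)
    table["SSR"] = table["ssr_raw"] / table["ssr_raw"].iloc[0]
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table[["rank", "t_pause", "t_free", "v_free", "M", "SSR", "ssr_raw"]]
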