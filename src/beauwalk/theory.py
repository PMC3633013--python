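"""Closed forms for the pause-and-run model.

The model's Brownian scaling limit has per-dimension motility (diffusion)
coefficient

    M = (v_free * t_free)^2 / (6 * (t_free + t_pause))      [μm²/min]

because one cycle displaces the cell by a vector uniform on the sphere of
radius ``r = v_free * t_free``, whose Cartesian components are uniform on
[-r, r] with variance r²/3, and a cycle takes ``t_run = t_free + t_pause``
minutes.  All square-displacement formulas below are per observed dimension
and multiply by ``dims`` for 2-D or 3-D views (the dimensions of the walk
are pairwise uncorrelated and share one variance).

Conventions: times in minutes, lengths in micrometres; ``t_run`` denotes
``t_free + t_pause`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .model import ModelParams, TaxisMode, TaxisSpec

__all__ = [
    "MacroParams",
    "motility_coefficient",
    "msd_single",
    "msd_ensemble",
    "msd_linear_coeffs",
    "sq_confinement",
    "normalized_sq_confinement",
    "convection_speed",
    "macro_params",
    "furth_msd",
    "gaussian_density",
]


@dataclass(frozen=True)
class MacroParams:
    """Macroscopic description: motility coefficient M (μm²/min) and
    convection velocity vector C (μm/min)."""

    M: float
    C: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError(f"motility coefficient must be >= 0, got {self.M}")
        object.__setattr__(self, "C", np.asarray(self.C, dtype=float))


def motility_coefficient(params: ModelParams) -> float:
    """Per-dimension motility coefficient M = (v_free t_free)² / (6 t_run)."""
    return params.step_radius**2 / (6.0 * params.t_run)


def msd_single(t, tau, params: ModelParams, dims: int = 1):
    """Expected square displacement of a single synchronized cell.

    The cell starts a fresh cycle at time 0; the observation time is
    decomposed as ``t + tau`` with ``t`` an integer multiple of ``t_run``
    and ``0 <= tau < t_run``.  Within a cycle the variance is flat during
    the pause and grows quadratically during the run:

        E[D²(t + tau)] = dims * (2 M t + v_free²/3 * max(tau - t_pause, 0)²)
    """
    _check_dims(dims)
    t = np.asarray(t, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    cycles = t / params.t_run
    if not np.allclose(cycles, np.round(cycles), atol=1e-9):
        raise ValueError(f"t must be an integer multiple of t_run={params.t_run}")
    if np.any(tau < 0) or np.any(tau >= params.t_run):
        raise ValueError(f"tau must lie in [0, t_run={params.t_run})")
    M = motility_coefficient(params)
    out = dims * (
        2.0 * M * t + params.v_free**2 / 3.0 * np.maximum(tau - params.t_pause, 0.0) ** 2
    )
    return float(out) if out.ndim == 0 else out


def msd_ensemble(t, params: ModelParams, dims: int = 1):
    """Expected mean square displacement of an asynchronous ensemble.

    Averaging the single-cell pulses over a uniform cycle phase gives, per
    dimension,

        E[D²(t)] = 2 M t - 2 M t_free * g(t / t_free)

    with ``g(u) = u³/3 - u² + u`` for ``u < 1`` and ``g = 1/3`` for
    ``u >= 1``; i.e. for ``t >= t_free`` the curve is the exact line
    ``alpha t + beta`` of :func:`msd_linear_coeffs`.  The curve starts at 0
    with zero slope and is continuously differentiable at ``t = t_free``.
    """
    _check_dims(dims)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    M = motility_coefficient(params)
    u = t / params.t_free
    g = np.where(u >= 1.0, 1.0 / 3.0, u**3 / 3.0 - u**2 + u)
    out = dims * (2.0 * M * t - 2.0 * M * params.t_free * g)
    return float(out) if out.ndim == 0 else out


def msd_linear_coeffs(params: ModelParams) -> tuple[float, float]:
    """Slope and intercept of the asymptotic per-dimension MSD line.

    Returns ``(alpha, beta)`` with ``alpha = 2M`` and
    ``beta = -2 M t_free / 3``; the line is exact for ``t >= t_free``.
    Note ``beta / alpha = -t_free / 3`` for any triplet, so the population
    MSD carries only two degrees of freedom (M and t_free).
    """
    M = motility_coefficient(params)
    return 2.0 * M, -2.0 * M * params.t_free / 3.0


def sq_confinement(t, params: ModelParams, allow_pause: bool = False):
    """Expected squared confinement ratio E[C²(t)] = E[D²(t)] / (t v_free)².

    ``D²`` is the one-dimensional square displacement, while the path length
    ``t v_free`` is traversed in three dimensions, hence the ``t -> 0``
    limit is 1/3 (for ``t_pause = 0``).  With zero pause the closed form is

        E[C²(t)] = (3 max(t, t_free) - min(t, t_free)) * t_free
                   / (3 max(t, t_free))²

    which decays from 1/3 through 2/9 at ``t = t_free`` towards 0.  The
    derivation assumes ``t_pause = 0``; with ``allow_pause=True`` the same
    ratio is evaluated from the general ensemble MSD as an extrapolation
    (the path length then overcounts time spent pausing).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if params.t_pause != 0.0 and not allow_pause:
        raise ValueError(
            "squared confinement closed form assumes t_pause = 0; "
            "pass allow_pause=True to evaluate the extrapolation"
        )
    if params.v_free == 0:
        raise ValueError("squared confinement undefined for v_free = 0")
    # E[D²(t)] / (t v)² with the exact t -> 0 limit 2M / (t_free v²).
    M = motility_coefficient(params)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = msd_ensemble(t, params) / (t * params.v_free) ** 2
    limit0 = 2.0 * M / (params.t_free * params.v_free**2)
    out = np.where(t == 0.0, limit0, ratio)
    return float(out) if out.ndim == 0 else out


def normalized_sq_confinement(t, params: ModelParams, allow_pause: bool = False):
    """Duration-robust variant ``t * E[C²(t)]`` (units: min).

    For ``t >= t_free`` (and ``t_pause = 0``) this equals
    ``t_free (3t - t_free) / (9t)`` and increases monotonically to the
    limit ``t_free / 3``, which makes it a quick persistence-time gauge.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    out = t * sq_confinement(t, params, allow_pause=allow_pause)
    return float(out) if out.ndim == 0 else out


def convection_speed(mode: TaxisMode | str, p: float, params: ModelParams) -> float:
    """Length of the convection coefficient ‖C‖ for a taxis mode (μm/min).

    simple:      p * v_free * t_pause / t_run
    orthotaxis, topotaxis, klinotaxis:  v_free * p * t_free / (3 t_run)
    none:        0

    The three semi-mechanistic modes share one bias speed; only the simple
    mode (drift during pauses) differs, and it alone leaves the random
    motility component untouched.
    """
    mode = TaxisMode.coerce(mode)
    if not 0.0 <= float(p) <= 1.0:
        raise ValueError(f"bias strength p must lie in [0, 1], got {p}")
    if mode is TaxisMode.NONE:
        return 0.0
    if mode is TaxisMode.SIMPLE:
        return p * params.v_free * params.t_pause / params.t_run
    return params.v_free * p * params.t_free / (3.0 * params.t_run)


def macro_params(params: ModelParams, taxis: TaxisSpec) -> MacroParams:
    """Macroscopic (M, C) pair for a parameter triplet and taxis setting."""
    speed = convection_speed(taxis.mode, taxis.p, params)
    return MacroParams(M=motility_coefficient(params), C=speed * taxis.b)


def furth_msd(t, M: float, P: float):
    """Fürth's persistent-random-walk MSD, 2M (t - P (1 - e^{-t/P})).

    ``P`` is the persistence time; ``P = 0`` is the memoryless limit
    ``2 M t``.  Unlike the pause-and-run model, whose persistence ends
    abruptly after each cycle, Fürth persistence decays exponentially —
    but both share the asymptotic slope ``2M``.
    """
    if M < 0 or P < 0:
        raise ValueError("M and P must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if P == 0.0:
        out = 2.0 * M * t
    else:
        out = 2.0 * M * (t + P * np.expm1(-t / P))
    return float(out) if out.ndim == 0 else out


def gaussian_density(x, t: float, C: float, M: float):
    """Density of the scaling-limit position: N(C t, 2 M t) evaluated at x.

    This Gaussian solves the 1-D convection-diffusion equation
    ``phi_t = -C phi_x + M phi_xx`` with a point source at the origin.
    """
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if M <= 0:
        raise ValueError(f"M must be > 0, got {M}")
    return _stats.norm.pdf(np.asarray(x, dtype=float), loc=C * t, scale=np.sqrt(2.0 * M * t))


def _check_dims(dims: int) -> None:
    if dims not in (1, 2, 3):
        raise ValueError(f"dims must be 1, 2 or 3, got {dims}")
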