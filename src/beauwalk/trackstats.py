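"""Estimators of track statistics with per-point standard errors.

All estimators operate on zero-aligned track sets sharing one observation
grid (always true for simulated data; imported tracks with heterogeneous
grids can be binned with :func:`to_common_grid`).  Standard errors are
plain per-point sample SEs over tracks — no time-lag pooling or
overlapping-interval MSD estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .tracks import Track, TrackSet

__all__ = [
    "StatCurve",
    "zero_align",
    "to_common_grid",
    "mean_displacement",
    "mean_square_displacement",
    "empirical_confinement",
    "displacement_covariance",
]

log = logging.getLogger("beauwalk")

_DIM_NAMES = {0: "x", 1: "y", 2: "z"}


@dataclass
class StatCurve:
    """A time-indexed statistic with per-point sample size and SE.

    ``statistic`` tags what was computed: ``mean_displacement``, ``msd``,
    ``sq_confinement``, ``norm_sq_confinement`` or ``classic_confinement``.
    ``dims`` records which coordinates entered the estimate.
    """

    t: np.ndarray
    value: np.ndarray
    se: np.ndarray
    n: np.ndarray
    statistic: str
    dims: tuple[int, ...] = (0, 1, 2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (self.t.shape == self.value.shape == self.se.shape == self.n.shape):
            raise DataError("StatCurve arrays must share one shape")
        if np.any(np.diff(self.t) <= 0):
            raise DataError("StatCurve time grid must be increasing")
        if np.any(self.se < 0):
            raise DataError("standard errors must be >= 0")
        self.dims = tuple(int(d) for d in self.dims)

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "estimate": self.value, "se": self.se, "n": self.n}
        )


def _resolve_dims(dims) -> tuple[int, ...]:
    """Accept a coordinate-index tuple or a count (1 -> x, 2 -> xy, 3 -> xyz)."""
    if isinstance(dims, (int, np.integer)):
        if not 1 <= dims <= 3:
            raise ValueError(f"dims count must be 1..3, got {dims}")
        return tuple(range(int(dims)))
    dims = tuple(int(d) for d in dims)
    if not dims or any(d not in (0, 1, 2) for d in dims):
        raise ValueError(f"dims must select among coordinates 0, 1, 2; got {dims}")
    return dims


def zero_align(ts: TrackSet) -> TrackSet:
    """Subtract each track's first observation (time and position).

    Idempotent; pairwise displacement differences within a track are
    unchanged.
    """
    aligned = [
        Track(tr.t - tr.t[0], tr.xyz - tr.xyz[0], track_id=tr.track_id) for tr in ts
    ]
    return TrackSet(
        tracks=aligned,
        aligned=True,
        sample_dt=ts.sample_dt,
        params=ts.params,
        taxis=ts.taxis,
        meta=dict(ts.meta),
    )


def to_common_grid(ts: TrackSet, sample_dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Positions of all tracks on one grid, NaN where a track has no data.

    Tracks already sharing a grid pass through unchanged.  Otherwise each
    observation is assigned to the nearest multiple of ``sample_dt``
    (default: the set's recorded ``sample_dt``, else the median time step);
    observations further than ``sample_dt / 2`` from any grid point are
    dropped and logged.

    Returns ``(times, positions)`` with positions ``(n_tracks, n_times, 3)``.
    """
    if not ts.tracks:
        raise DataError("empty track set")
    if ts.has_common_grid:
        return ts.stacked()
    if sample_dt is None:
        sample_dt = ts.sample_dt or float(
            np.median(np.concatenate([np.diff(tr.t) for tr in ts if len(tr) > 1]))
        )
    t_max = max(tr.t[-1] for tr in ts)
    n_bins = int(round(t_max / sample_dt)) + 1
    grid = np.arange(n_bins) * sample_dt
    pos = np.full((len(ts.tracks), n_bins, 3), np.nan)
    dropped = 0
    for i, tr in enumerate(ts):
        idx = np.round(tr.t / sample_dt).astype(int)
        ok = (np.abs(tr.t - idx * sample_dt) <= sample_dt / 2) & (idx >= 0) & (idx < n_bins)
        dropped += int((~ok).sum())
        pos[i, idx[ok]] = tr.xyz[ok]
    if dropped:
        log.info("to_common_grid: dropped %d observations beyond dt/2 tolerance", dropped)
    return grid, pos


def _require_aligned(ts: TrackSet) -> None:
    if not ts.aligned and not all(tr.is_zero_aligned for tr in ts):
        raise DataError("track set must be zero-aligned; call zero_align() first")


def _curve_from_samples(t, samples, statistic, dims, meta=None) -> StatCurve:
    """Per-point mean/SE/n over tracks, tolerating NaN entries."""
    n = np.sum(np.isfinite(samples), axis=0)
    if np.any(n < 1):
        raise DataError("some time points have no contributing tracks")
    est = np.nanmean(samples, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # points with a single contributing track have no spread estimate
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(samples, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(n), 0.0)
    return StatCurve(t, est, se, n, statistic, dims, meta or {})


def mean_displacement(ts: TrackSet, dims=(0, 1, 2)) -> StatCurve:
    """Mean displacement D(t): average of ||x_i(t)|| over tracks."""
    _require_aligned(ts)
    dims = _resolve_dims(dims)
    t, pos = to_common_grid(ts)
    norms = np.linalg.norm(pos[:, :, dims], axis=2)
    return _curve_from_samples(t, norms, "mean_displacement", dims)


def mean_square_displacement(ts: TrackSet, dims=(0, 1, 2)) -> StatCurve:
    """Mean square displacement D²(t): average of ||x_i(t)||² over tracks.

    The 3-D view is, per track and time point, the exact sum of the three
    1-D views (Pythagoras).
    """
    _require_aligned(ts)
    dims = _resolve_dims(dims)
    t, pos = to_common_grid(ts)
    sq = np.sum(pos[:, :, dims] ** 2, axis=2)
    return _curve_from_samples(t, sq, "msd", dims)


def empirical_confinement(
    ts: TrackSet,
    variant: str = "squared",
    v_free: float | None = None,
    dims=(0,),
) -> StatCurve:
    """Confinement-ratio curves.

    variant="squared"
        mean over tracks of ``||x_i(t)||² / (t² v_free²)`` on the selected
        (default 1-D) view; needs the model speed ``v_free`` (taken from the
        set's provenance when not given).  The t -> 0 expectation is 1/3
        because the path length is traversed in three dimensions while the
        displacement is projected to one.
    variant="classic"
        mean over tracks of 3-D displacement over observed path length,
        ``||x_i(t)|| / L_i(t)`` — in [0, 1] by the triangle inequality.

    The t = 0 point is 0/0 and is omitted; the returned grid starts at the
    first positive time (flagged in ``meta['t0_omitted']``).
    """
    _require_aligned(ts)
    t, pos = to_common_grid(ts)
    keep = t > 0
    if not keep.any():
        raise DataError("need at least one positive observation time")
    if variant == "squared":
        dims = _resolve_dims(dims)
        if v_free is None:
            if ts.params is None:
                raise ValueError("variant='squared' needs v_free (or set provenance)")
            v_free = ts.params.v_free
        if v_free <= 0:
            raise ValueError("v_free must be > 0 for the squared confinement ratio")
        sq = np.sum(pos[:, :, dims] ** 2, axis=2)[:, keep]
        samples = sq / (t[keep] * v_free) ** 2
        tag = "sq_confinement"
    elif variant == "classic":
        dims = (0, 1, 2)
        lengths = np.stack([tr.path_length() for tr in ts])[:, keep]
        disp = np.linalg.norm(pos[:, keep, :], axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            samples = np.where(lengths > 0, disp / np.where(lengths > 0, lengths, 1.0), np.nan)
        tag = "classic_confinement"
    else:
        raise ValueError(f"unknown confinement variant {variant!r}")
    return _curve_from_samples(t[keep], samples, tag, dims, meta={"t0_omitted": True})


def displacement_covariance(ts: TrackSet, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample covariance of (x, y, z) displacements at time ``t``.

    Returns ``(cov, se)``; ``se`` holds delete-one jackknife standard
    errors of each covariance entry.  Requires at least 3 tracks with an
    observation at ``t``.
    """
    _require_aligned(ts)
    grid, pos = to_common_grid(ts)
    idx = np.flatnonzero(np.isclose(grid, t))
    if idx.size == 0:
        raise ValueError(f"t={t} is not on the observation grid")
    X = pos[:, idx[0], :]
    X = X[np.all(np.isfinite(X), axis=1)]
    n = X.shape[0]
    if n < 3:
        raise DataError(f"need >= 3 tracks with data at t={t}, got {n}")
    mu = X.mean(axis=0)
    Xc = X - mu
    S = Xc.T @ Xc  # scatter matrix
    cov = S / (n - 1)
    # Delete-one covariances via rank-1 downdate of the scatter matrix.
    outer = np.einsum("ni,nj->nij", Xc, Xc)
    S_loo = S[None, :, :] - outer * (n / (n - 1))
    cov_loo = S_loo / (n - 2)
    mean_loo = cov_loo.mean(axis=0)
    se = np.sqrt((n - 1) / n * np.sum((cov_loo - mean_loo) ** 2, axis=0))
    return cov, se
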