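"""Track containers: discrete-time 3-D observations of migrating cells."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .model import ModelParams, TaxisSpec

__all__ = ["Track", "TrackSet"]


@dataclass
class Track:
    """One cell track: observation times ``t`` (min, strictly increasing)
    and positions ``xyz`` of shape ``(len(t), 3)`` in micrometres."""

    t: np.ndarray
    xyz: np.ndarray
    track_id: str | int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise DataError(
                f"track {self.track_id!r}: need times (k,) and positions (k, 3), "
                f"got {self.t.shape} and {self.xyz.shape}"
            )
        if self.t.size == 0:
            raise DataError(f"track {self.track_id!r} is empty")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xyz)):
            raise DataError(f"track {self.track_id!r} contains non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise DataError(f"track {self.track_id!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def is_zero_aligned(self) -> bool:
        return self.t[0] == 0.0 and np.all(self.xyz[0] == 0.0)

    def path_length(self) -> np.ndarray:
        """Cumulative 3-D polyline length up to each observation (μm)."""
        steps = np.linalg.norm(np.diff(self.xyz, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class TrackSet:
    """A collection of tracks with provenance.

    When produced by the simulator all tracks share one observation grid and
    are zero-aligned by construction; ``stacked()`` then exposes the
    positions as a single ``(n_tracks, n_times, 3)`` array for vectorized
    statistics.
    """

    tracks: list[Track]
    aligned: bool = False
    sample_dt: float | None = None
    params: ModelParams | None = None
    taxis: TaxisSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tracks:
            self.aligned = True  # vacuously

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def has_common_grid(self) -> bool:
        if not self.tracks:
            return True
        t0 = self.tracks[0].t
        return all(tr.t.size == t0.size and np.array_equal(tr.t, t0) for tr in self.tracks)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(times, positions)`` with positions of shape (n, k, 3).

        Raises :class:`DataError` if the tracks do not share one grid; use
        :func:`beauwalk.trackstats.to_common_grid` first in that case.
        """
        if not self.tracks:
            raise DataError("empty track set")
        if not self.has_common_grid:
            raise DataError("tracks do not share a common observation grid")
        times = self.tracks[0].t
        return times, np.stack([tr.xyz for tr in self.tracks])
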