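"""Core parameter types of the Beauchemin pause-and-run migration model.

The model describes a cell as a massless particle that alternates between a
stationary *pause* of length ``t_pause`` (minutes), during which it picks a
new direction uniformly at random on the unit sphere, and a straight *free
run* of length ``t_free`` (minutes) at speed ``v_free`` (micrometres per
minute).  Biased migration ("taxis") is switched on by a :class:`TaxisSpec`,
which fixes a unit bias direction ``b`` and a dimensionless strength
``p in [0, 1]`` and selects one of four mechanisms:

``simple``
    the cell drifts at ``p * v_free`` along ``b`` during pauses;
``orthotaxis``
    the run speed becomes ``v_free * (1 + p * <b, d>)`` for run direction d;
``topotaxis``
    the component of the run direction along ``b`` is drawn from the skewed
    density ``(1 + p x) / 2`` on [-1, 1] instead of the uniform ``1/2``;
``klinotaxis``
    the run duration becomes ``t_free * (1 + p * <b, d>)``.

All times are minutes and all lengths micrometres throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["TaxisMode", "ModelParams", "TaxisSpec"]


class TaxisMode(str, Enum):
    """Bias mechanism of the migration model."""

    NONE = "none"
    SIMPLE = "simple"
    ORTHOTAXIS = "orthotaxis"
    TOPOTAXIS = "topotaxis"
    KLINOTAXIS = "klinotaxis"

    @classmethod
    def coerce(cls, value: "TaxisMode | str") -> "TaxisMode":
        """Accept enum members, full names and the short CLI aliases."""
        if isinstance(value, cls):
            return value
        aliases = {"ortho": "orthotaxis", "topo": "topotaxis", "klino": "klinotaxis"}
        name = str(value).lower()
        return cls(aliases.get(name, name))


@dataclass(frozen=True)
class ModelParams:
    """Microscopic parameter triplet ``(t_pause, t_free, v_free)``.

    Parameters
    ----------
    t_pause
        Pause (turning) time in minutes; must be >= 0.
    t_free
        Free-run time in minutes; must be > 0.
    v_free
        Free-run speed in micrometres per minute; must be >= 0.
    """

    t_pause: float
    t_free: float
    v_free: float

    def __post_init__(self) -> None:
        for name in ("t_pause", "t_free", "v_free"):
            val = float(getattr(self, name))
            if not math.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val!r}")
            object.__setattr__(self, name, val)
        if self.t_pause < 0:
            raise ValueError(f"t_pause must be >= 0, got {self.t_pause}")
        if self.t_free <= 0:
            raise ValueError(f"t_free must be > 0, got {self.t_free}")
        if self.v_free < 0:
            raise ValueError(f"v_free must be >= 0, got {self.v_free}")

    @property
    def t_run(self) -> float:
        """Full cycle time ``t_free + t_pause`` in minutes."""
        return self.t_free + self.t_pause

    @property
    def step_radius(self) -> float:
        """Length ``v_free * t_free`` of one unperturbed free run (μm)."""
        return self.v_free * self.t_free

    def to_dict(self) -> dict:
        return {"t_pause": self.t_pause, "t_free": self.t_free, "v_free": self.v_free}


def _as_unit_vector(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.shape != (3,):
        raise ValueError(f"bias direction must be a 3-vector, got shape {b.shape}")
    norm = float(np.linalg.norm(b))
    if not np.isfinite(norm) or norm < 1e-12:
        raise ValueError("bias direction must have nonzero length")
    b = b / norm
    b.setflags(write=False)
    return b


@dataclass(frozen=True)
class TaxisSpec:
    """Bias specification: mechanism, strength ``p`` and unit direction ``b``.

    ``mode='none'`` forces ``p = 0``; ``b`` is normalized on construction.
    """

    mode: TaxisMode = TaxisMode.NONE
    p: float = 0.0
    b: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", TaxisMode.coerce(self.mode))
        p = float(self.p)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"bias strength p must lie in [0, 1], got {p}")
        if self.mode is TaxisMode.NONE:
            p = 0.0
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "b", _as_unit_vector(self.b))

    @property
    def unbiased(self) -> bool:
        return self.mode is TaxisMode.NONE or self.p == 0.0

    def to_dict(self) -> dict:
        return {"mode": self.mode.value, "p": self.p, "b": [float(v) for v in self.b]}


#: Unbiased migration (no taxis).
NO_TAXIS = TaxisSpec()
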