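"""Random draws for run directions, speeds and durations.

All randomness flows through an injected :class:`numpy.random.Generator`;
the module never touches global random state.  Ensembles derive one
independent substream per track from a single master seed (see
:func:`spawn_generators`), so results are reproducible regardless of
execution order.
"""

from __future__ import annotations

import numpy as np

from .model import TaxisMode, TaxisSpec

__all__ = [
    "draw_unit_direction",
    "draw_topotaxis_direction",
    "run_speed",
    "run_duration",
    "pause_drift",
    "spawn_generators",
]


def draw_unit_direction(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Draw points uniformly distributed on the unit sphere.

    Uses the normalized-Gaussian-triple construction, which is exactly
    uniform.  Each Cartesian component is then marginally uniform on
    [-1, 1] (the spherical-cap/Archimedes property) and the components are
    pairwise uncorrelated.

    Parameters
    ----------
    rng
        Seeded random generator.
    size
        If ``None`` return one direction of shape ``(3,)``; otherwise an
        array of shape ``(size, 3)``.
    """
    n = 1 if size is None else int(size)
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    # Guard against astronomically unlikely near-zero triples.
    bad = norms < 1e-12
    while bad.any():
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms[bad] = np.linalg.norm(v[bad], axis=1)
        bad = norms < 1e-12
    v /= norms[:, None]
    return v[0] if size is None else v


def _orthonormal_complement(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to unit vector ``b``."""
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(b)))] = 1.0
    e1 = np.cross(b, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(b, e1)
    return e1, e2


def draw_topotaxis_direction(
    p: float,
    b,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw run directions with the topotaxis-skewed axial component.

    The component ``x = <b, d>`` has density ``(1 + p x) / 2`` on [-1, 1];
    conditional on ``x`` the perpendicular part is uniform on the circle of
    radius ``sqrt(1 - x^2)`` in the plane normal to ``b``.  ``p = 0``
    recovers the uniform sphere distribution.

    Sampling of ``x`` is by inverse transform of
    ``F(x) = (x + 1)/2 + p (x^2 - 1)/4`` (closed-form quadratic root), which
    keeps the draw count per direction fixed and the stream reproducible.
    """
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"bias strength p must lie in [0, 1], got {p}")
    b = np.asarray(b, dtype=float)
    b = b / np.linalg.norm(b)

    n = 1 if size is None else int(size)
    u = rng.uniform(size=n)
    if p < 1e-12:
        x = 2.0 * u - 1.0
    else:
        # Root of p x^2 + 2 x + (2 - p - 4u) = 0 lying in [-1, 1].
        x = (-1.0 + np.sqrt(1.0 - p * (2.0 - p - 4.0 * u))) / p
        np.clip(x, -1.0, 1.0, out=x)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    e1, e2 = _orthonormal_complement(b)
    s = np.sqrt(np.maximum(0.0, 1.0 - x * x))
    d = (
        x[:, None] * b[None, :]
        + (s * np.cos(phi))[:, None] * e1[None, :]
        + (s * np.sin(phi))[:, None] * e2[None, :]
    )
    return d[0] if size is None else d


def run_speed(mode: TaxisMode | str, p: float, dot, v_free: float):
    """Speed of a free run whose direction has component ``dot = <b, d>``.

    Only orthotaxis modifies the speed: ``v_free * (1 + p * dot)``; movement
    perpendicular to the bias (``dot = 0``) is unaffected, and full
    opposition at ``p = 1`` stalls the cell.  All other modes return
    ``v_free`` unchanged.
    """
    mode = TaxisMode.coerce(mode)
    dot = np.asarray(dot, dtype=float)
    if mode is TaxisMode.ORTHOTAXIS:
        out = v_free * (1.0 + p * dot)
    else:
        out = np.broadcast_to(np.asarray(float(v_free)), dot.shape).copy()
    return float(out) if out.ndim == 0 else out


def run_duration(mode: TaxisMode | str, p: float, dot, t_free: float):
    """Duration of a free run; only klinotaxis modifies it:
    ``t_free * (1 + p * dot)``.  Zero-length runs (``p = 1``, ``dot = -1``)
    are valid degenerate values."""
    mode = TaxisMode.coerce(mode)
    dot = np.asarray(dot, dtype=float)
    if mode is TaxisMode.KLINOTAXIS:
        out = t_free * (1.0 + p * dot)
    else:
        out = np.broadcast_to(np.asarray(float(t_free)), dot.shape).copy()
    return float(out) if out.ndim == 0 else out


def pause_drift(taxis: TaxisSpec, v_free: float) -> np.ndarray:
    """Velocity during pauses: ``p * v_free * b`` in simple mode, else zero."""
    if taxis.mode is TaxisMode.SIMPLE:
        return taxis.p * v_free * taxis.b
    return np.zeros(3)


def spawn_generators(master_seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    seq = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    return [np.random.default_rng(child) for child in seq.spawn(n)]
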