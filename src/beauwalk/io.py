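"""Plain-CSV serialization for tracks and statistic curves.

Dialect is fixed: comma separators, '.' decimals, UTF-8, LF line endings,
with provenance carried in '#'-prefixed comment lines before the header.
Units are a documented contract (minutes, micrometres) and are not encoded
per file.  Floats are written with Python's shortest round-trip
representation, so write/read cycles are bit-exact.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from .errors import DataError
from .model import ModelParams, TaxisSpec
from .tracks import Track, TrackSet
from .trackstats import StatCurve

__all__ = ["read_tracks", "write_tracks", "read_curve", "write_curve"]

TRACK_HEADER = "track_id,t,x,y,z"
CURVE_HEADER = "t,estimate,se,n"


def _package_version() -> str:
    try:
        return version("beauwalk")
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "unknown"


def _format_float(v: float) -> str:
    return repr(float(v))


def _metadata_lines(ts: TrackSet) -> list[str]:
    lines = [f"# beauwalk-tracks v1 (package {_package_version()})"]
    if ts.params is not None:
        lines.append(f"# params: {json.dumps(ts.params.to_dict())}")
    if ts.taxis is not None:
        lines.append(f"# taxis: {json.dumps(ts.taxis.to_dict())}")
    if ts.sample_dt is not None:
        lines.append(f"# sample_dt: {_format_float(ts.sample_dt)}")
    lines.append(f"# aligned: {json.dumps(bool(ts.aligned))}")
    if ts.meta:
        lines.append(f"# meta: {json.dumps(ts.meta, default=str)}")
    return lines


def write_tracks(ts: TrackSet, path) -> None:
    """Write a track set as CSV with a provenance comment block.

    Output is deterministic for a fixed track set; an empty set yields a
    header-only file (after the metadata block).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _metadata_lines(ts):
            fh.write(line + "\n")
        fh.write(TRACK_HEADER + "\n")
        for tr in ts:
            for t, (x, y, z) in zip(tr.t, tr.xyz):
                fh.write(
                    f"{tr.track_id},{_format_float(t)},{_format_float(x)},"
                    f"{_format_float(y)},{_format_float(z)}\n"
                )


def _parse_comment_block(path) -> tuple[dict, int]:
    """Read leading '#' lines; returns (metadata dict, #lines consumed)."""
    meta: dict = {}
    consumed = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            consumed += 1
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, _, raw = body.partition(":")
            key, raw = key.strip(), raw.strip()
            if key in ("params", "taxis", "meta", "aligned", "sample_dt"):
                try:
                    meta[key] = json.loads(raw)
                except json.JSONDecodeError:
                    meta[key] = raw
    return meta, consumed


def read_tracks(path) -> TrackSet:
    """Read a track CSV written by :func:`write_tracks` (or compatible).

    Files without a metadata block load with empty provenance.  Times must
    be strictly increasing within each track; violations raise
    :class:`DataError` naming the offending track id.
    """
    meta, skip = _parse_comment_block(path)
    try:
        df = pd.read_csv(path, skiprows=skip, dtype={"track_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty or header-less file") from exc
    if list(df.columns) != TRACK_HEADER.split(","):
        raise DataError(
            f"{path}: header must be exactly {TRACK_HEADER!r}, got {list(df.columns)}"
        )
    for col in ("t", "x", "y", "z"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise DataError(f"{path}: non-numeric values in column {col!r}")

    tracks = []
    for tid in df["track_id"].unique():
        sub = df[df["track_id"] == tid]
        t = sub["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"{path}: non-increasing times in track {tid!r}")
        tracks.append(Track(t, sub[["x", "y", "z"]].to_numpy(dtype=float), track_id=tid))

    params = ModelParams(**meta["params"]) if "params" in meta else None
    taxis = (
        TaxisSpec(mode=meta["taxis"]["mode"], p=meta["taxis"]["p"], b=meta["taxis"]["b"])
        if "taxis" in meta
        else None
    )
    aligned = bool(meta.get("aligned", False)) or (
        bool(tracks) and all(tr.is_zero_aligned for tr in tracks)
    )
    return TrackSet(
        tracks=tracks,
        aligned=aligned,
        sample_dt=meta.get("sample_dt"),
        params=params,
        taxis=taxis,
        meta=meta.get("meta", {}),
    )


def write_curve(curve: StatCurve, path) -> None:
    """Write a statistic curve as CSV (t, estimate, se, n) with metadata."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# beauwalk-curve v1 (package {_package_version()})\n")
        fh.write(f"# statistic: {curve.statistic}\n")
        fh.write(f"# dims: {json.dumps(list(curve.dims))}\n")
        if curve.meta:
            fh.write(f"# meta: {json.dumps(curve.meta, default=str)}\n")
        fh.write(CURVE_HEADER + "\n")
        for t, v, s, n in zip(curve.t, curve.value, curve.se, curve.n):
            fh.write(f"{_format_float(t)},{_format_float(v)},{_format_float(s)},{int(n)}\n")


def read_curve(path) -> StatCurve:
    """Read a statistic curve written by :func:`write_curve`."""
    meta: dict = {}
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            key, _, raw = body.partition(":")
            meta[key.strip()] = raw.strip()
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty curve file") from exc
    if list(df.columns) != CURVE_HEADER.split(","):
        raise DataError(f"{path}: header must be exactly {CURVE_HEADER!r}")
    dims = tuple(json.loads(meta["dims"])) if "dims" in meta else (0, 1, 2)
    extra = json.loads(meta["meta"]) if "meta" in meta else {}
    return StatCurve(
        t=df["t"].to_numpy(float),
        value=df["estimate"].to_numpy(float),
        se=df["se"].to_numpy(float),
        n=df["n"].to_numpy(int),
        statistic=meta.get("statistic", "msd"),
        dims=dims,
        meta=extra,
    )
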