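"""Delimited-text I/O for Z-spectra, relaxation series and DOSY tables.

All tables are plain CSV with ``#``-prefixed ``key = value`` metadata
header lines, so files diff cleanly and survive version control.  Columns
are matched by name (order-independent); values round-trip at 12
significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bloch import ZSpectrum
from .dosy import DosyDataset

__all__ = ["read_table", "write_table", "read_zspectrum", "write_zspectrum",
           "read_relaxation", "write_relaxation", "read_dosy", "write_dosy"]

_KINDS = ("zspectrum", "relaxation", "dosy")


def _write_csv(path, meta: dict, frame: pd.DataFrame) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {val}\n")
        fh.write(",".join(frame.columns) + "\n")
        for _, row in frame.iterrows():
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def _read_csv(path) -> tuple[dict, pd.DataFrame]:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            try:
                meta[key.strip()] = float(val.strip())
            except ValueError:
                meta[key.strip()] = val.strip()
    try:
        frame = pd.read_csv(path, skiprows=n_header)
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"{path}: could not parse CSV table: {exc}") from exc
    if frame.empty:
        raise ValueError(f"{path}: table contains no data rows")
    return meta, frame


def _require(frame: pd.DataFrame, columns: tuple, path) -> None:
    for col in columns:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column '{col}'")


def write_zspectrum(path, zs: ZSpectrum) -> None:
    meta = {"kind": "zspectrum"}
    if zs.temperature is not None:
        meta["temperature_K"] = f"{zs.temperature:.12g}"
    if zs.nutation is not None:
        meta["nutation_hz"] = f"{zs.nutation:.12g}"
    if zs.duration is not None:
        meta["duration_s"] = f"{zs.duration:.12g}"
    _write_csv(path, meta, pd.DataFrame({"offset_hz": zs.offsets, "z": zs.z}))


def read_zspectrum(path) -> ZSpectrum:
    meta, frame = _read_csv(path)
    _require(frame, ("offset_hz", "z"), path)
    return ZSpectrum(
        offsets=frame["offset_hz"].to_numpy(),
        z=frame["z"].to_numpy(),
        temperature=meta.get("temperature_K"),
        nutation=meta.get("nutation_hz"),
        duration=meta.get("duration_s"),
    )


def write_relaxation(path, table: np.ndarray | pd.DataFrame) -> None:
    """Write a relaxation series with columns (temperature_K, R1_per_s, R2_per_s)."""
    if isinstance(table, pd.DataFrame):
        frame = table
    else:
        frame = pd.DataFrame(np.asarray(table),
                             columns=["temperature_K", "R1_per_s", "R2_per_s"])
    _write_csv(path, {"kind": "relaxation"}, frame)


def read_relaxation(path) -> pd.DataFrame:
    meta, frame = _read_csv(path)
    _require(frame, ("temperature_K", "R1_per_s", "R2_per_s"), path)
    return frame[["temperature_K", "R1_per_s", "R2_per_s"]]


def write_dosy(path, ds: DosyDataset) -> None:
    meta = {
        "kind": "dosy",
        "gamma_rad_per_s_T": f"{ds.gamma:.12g}",
        "delta_small_s": f"{ds.delta_small:.12g}",
        "delta_big_s": f"{ds.delta_big:.12g}",
    }
    if ds.T is not None:
        meta["temperature_K"] = f"{ds.T:.12g}"
    _write_csv(path, meta, pd.DataFrame({"gradient_T_per_m": ds.gradients,
                                         "intensity": ds.intensities}))


def read_dosy(path) -> DosyDataset:
    meta, frame = _read_csv(path)
    _require(frame, ("gradient_T_per_m", "intensity"), path)
    kwargs = {}
    for src, dst in (("gamma_rad_per_s_T", "gamma"), ("delta_small_s", "delta_small"),
                     ("delta_big_s", "delta_big"), ("temperature_K", "T")):
        if src in meta:
            kwargs[dst] = float(meta[src])
    return DosyDataset(gradients=frame["gradient_T_per_m"].to_numpy(),
                       intensities=frame["intensity"].to_numpy(), **kwargs)


def write_table(path, data, kind: str) -> None:
    """Dispatch on ``kind`` in {'zspectrum', 'relaxation', 'dosy'}."""
    if kind == "zspectrum":
        write_zspectrum(path, data)
    elif kind == "relaxation":
        write_relaxation(path, data)
    elif kind == "dosy":
        write_dosy(path, data)
    else:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")


def read_table(path, kind: str):
    if kind == "zspectrum":
        return read_zspectrum(path)
    if kind == "relaxation":
        return read_relaxation(path)
    if kind == "dosy":
        return read_dosy(path)
    raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
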