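"""Record types and CSV time-series I/O.

The on-disk dialect is deliberately simple and diff-able:

* comment-style header lines ``# key=value`` (``fs_hz`` required; ``t0_s``,
  ``tilt_deg``, ``target_rate``, ``target_depth`` optional),
* a column-name row (``t,ax,ay,az`` for acceleration, ``t,cd_mm`` for
  displacement),
* numeric data rows, UTF-8, '.' decimal separator.

The time column exists for human inspection only; ``fs_hz`` and ``t0_s``
from the header are authoritative on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import RecordFormatError

__all__ = [
    "AccelerationRecord",
    "DisplacementRecord",
    "SessionMeta",
    "read_record",
    "write_record",
]


@dataclass
class AccelerationRecord:
    """Uniformly sampled triaxial acceleration, m/s^2.

    Parameters
    ----------
    samples : ndarray, shape (n, 3)
        (ax, ay, az) rows in m/s^2.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Start time in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples.reshape(-1, 3)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(
                f"acceleration samples must have shape (n, 3), got {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("acceleration samples must be finite")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return len(self) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs


@dataclass
class DisplacementRecord:
    """Uniformly sampled chest-displacement (compression-depth) signal, mm.

    Zero is the resting chest position; positive values mean the chest is
    compressed.  Negative values (recoil overshoot) are allowed.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("displacement samples must be finite")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs


Record = Union[AccelerationRecord, DisplacementRecord]


@dataclass
class SessionMeta:
    """Identity and targets of one recording session.

    ``session_kind`` is ``"regular"`` (sensor axis normal to the chest) or
    ``"tilt"`` (axis misaligned by ``tilt_deg``, 18 degrees in the emulated
    study design; other angles are allowed for extended experiments).
    """

    rescuer_id: str
    target_rate: float
    target_depth: float
    session_kind: str = "regular"
    tilt_deg: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.session_kind not in ("regular", "tilt"):
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        if self.session_kind == "regular" and self.tilt_deg != 0.0:
            raise ValueError("regular sessions have tilt_deg = 0")


_ACCEL_COLUMNS = ["t", "ax", "ay", "az"]
_DISP_COLUMNS = ["t", "cd_mm"]


def read_record(path, kind: str) -> Record:
    """Read an :class:`AccelerationRecord` or :class:`DisplacementRecord`.

    Parameters
    ----------
    path : path-like
        CSV file in the package dialect (module docstring).
    kind : {"accel", "displacement"}
        Expected record type; the file's column count must match.

    Raises
    ------
    RecordFormatError
        Missing/garbled header or non-numeric rows, with the offending
        line named.
    """
    if kind not in ("accel", "displacement"):
        raise ValueError(f"kind must be 'accel' or 'displacement', got {kind!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    meta: dict[str, float] = {}
    body_lines: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if "=" not in payload:
                raise RecordFormatError(
                    f"{path}:{lineno}: header line {stripped!r} is not 'key=value'"
                )
            key, _, value = payload.partition("=")
            try:
                meta[key.strip()] = float(value)
            except ValueError as exc:
                raise RecordFormatError(
                    f"{path}:{lineno}: non-numeric header value in {stripped!r}"
                ) from exc
        else:
            body_lines.append(line)
    if "fs_hz" not in meta:
        raise RecordFormatError(f"{path}: missing required header '# fs_hz=<rate>'")
    fs = meta["fs_hz"]
    if not fs > 0:
        raise RecordFormatError(f"{path}: fs_hz must be positive, got {fs}")
    t0 = meta.get("t0_s", 0.0)

    expected = _ACCEL_COLUMNS if kind == "accel" else _DISP_COLUMNS
    if not body_lines:
        raise RecordFormatError(f"{path}: missing column-name row {expected}")
    names = [c.strip() for c in body_lines[0].split(",")]
    if names != expected:
        raise RecordFormatError(
            f"{path}: column row {names} does not match expected {expected} for kind={kind!r}"
        )
    try:
        frame = pd.read_csv(
            io.StringIO("\n".join(body_lines)),
            dtype=float,
            na_filter=False,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise RecordFormatError(f"{path}: unparseable data rows: {exc}") from exc
    if frame.isnull().to_numpy().any():
        bad = int(frame.isnull().any(axis=1).idxmax())
        raise RecordFormatError(f"{path}: non-numeric value in data row {bad}")
    if kind == "accel":
        return AccelerationRecord(frame[["ax", "ay", "az"]].to_numpy(), fs=fs, t0=t0)
    return DisplacementRecord(frame["cd_mm"].to_numpy(), fs=fs, t0=t0)


def write_record(record: Record, path, extra_meta: dict | None = None):
    """Write a record in the package CSV dialect; returns the path.

    ``read_record(write_record(r, p))`` reproduces ``r`` to the written
    precision (17 significant digits, i.e. exact for float64).
    """
    path = Path(path)
    if isinstance(record, AccelerationRecord):
        columns = _ACCEL_COLUMNS
        data = np.column_stack([record.times(), record.samples])
    elif isinstance(record, DisplacementRecord):
        columns = _DISP_COLUMNS
        data = np.column_stack([record.times(), record.samples])
    else:
        raise TypeError(f"cannot write object of type {type(record).__name__}")
    lines = [f"# fs_hz={record.fs!r}", f"# t0_s={record.t0!r}"]
    for key, value in (extra_meta or {}).items():
        lines.append(f"# {key}={value!r}")
    lines.append(",".join(columns))
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.17g")
    return path
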