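"""Multichannel EMG containers and plain-text signal I/O.

A :class:`SignalRecord` holds a sampled multichannel EMG signal (mV) together
with its sampling rate, the physiological role of each channel and free-form
acquisition metadata (subject id, condition label, seed, ...).

Records are persisted as self-describing delimited text: ``# key: value``
header lines followed by a column of time stamps (s) and one column per
channel (mV). The format is deliberately dependency-light so that signal
files remain diff-able and portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical channel ordering. Patient recordings use the four
#: affected/unaffected x tibialis/gastrocnemius roles; single-channel
#: (rat) recordings use the generic ``emg`` role.
CANONICAL_ROLES = (
    "tibialis_affected",
    "gastrocnemius_affected",
    "tibialis_unaffected",
    "gastrocnemius_unaffected",
    "emg",
)

_ROLE_RANK = {role: i for i, role in enumerate(CANONICAL_ROLES)}


class SignalFormatError(ValueError):
    """Raised when a signal file cannot be parsed; message names the line."""


class UnknownRoleError(ValueError):
    """Raised when a channel role is not one of :data:`CANONICAL_ROLES`."""


def role_rank(role: str) -> int:
    """Position of *role* in the canonical channel order.

    Raises
    ------
    UnknownRoleError
        If *role* is not a recognized channel role.
    """
    try:
        return _ROLE_RANK[role]
    except KeyError:
        raise UnknownRoleError(
            f"unknown channel role {role!r}; expected one of {CANONICAL_ROLES}"
        ) from None


@dataclass
class SignalRecord:
    """A sampled multichannel EMG recording.

    Parameters
    ----------
    data
        Array of shape ``(n_samples, n_channels)`` in mV.
    fs
        Sampling rate in Hz.
    channel_roles
        One role per column, e.g. ``"emg"`` or ``"tibialis_affected"``.
    meta
        Free-form string metadata (subject, condition, seed, ...).
    """

    data: np.ndarray
    fs: float
    channel_roles: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        if data.ndim != 2:
            raise ValueError("data must be 1-D or 2-D (samples x channels)")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        roles = tuple(self.channel_roles)
        if len(roles) == 0:
            raise ValueError("record must have at least one channel")
        if len(roles) != data.shape[1]:
            raise ValueError(
                f"{len(roles)} channel roles for {data.shape[1]} data columns"
            )
        self.data = data
        self.channel_roles = roles

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, role: str) -> np.ndarray:
        """Return the 1-D samples of the channel with the given role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise UnknownRoleError(
                f"record has no channel with role {role!r}; "
                f"available: {self.channel_roles}"
            ) from None
        return self.data[:, idx]

    def with_data(self, data: np.ndarray, **meta_updates) -> "SignalRecord":
        """Copy of this record with new sample data (and optional metadata)."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return replace(self, data=np.asarray(data, dtype=float), meta=meta)


# -- plain-text signal format ---------------------------------------------


def write_signal_record(record: SignalRecord, path) -> None:
    """Write *record* as delimited text with a ``# key: value`` header.

    Floats are written with 17 significant digits so that read/write
    round-trips are bit-exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# flexemg-signal: v1\n")
        fh.write(f"# fs: {record.fs!r}\n")
        fh.write(f"# roles: {','.join(record.channel_roles)}\n")
        for key in sorted(record.meta):
            fh.write(f"# {key}: {record.meta[key]}\n")
        cols = np.column_stack([record.times, record.data])
        np.savetxt(fh, cols, fmt="%.17g", delimiter="\t")


def read_signal_record(path) -> SignalRecord:
    """Parse a signal file written by :func:`write_signal_record`.

    Raises
    ------
    SignalFormatError
        On a missing sampling rate, an empty channel set, a ragged row or a
        non-numeric cell. The message cites the 1-based file line number.
    """
    fs = None
    roles: tuple[str, ...] | None = None
    meta: dict = {}
    rows: list[list[float]] = []
    n_cols = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    continue
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key == "fs":
                    try:
                        fs = float(value)
                    except ValueError:
                        raise SignalFormatError(
                            f"line {lineno}: non-numeric sampling rate {value!r}"
                        ) from None
                elif key == "roles":
                    roles = tuple(r for r in value.split(",") if r)
                elif key != "flexemg-signal":
                    meta[key] = value
                continue
            fields = line.split()
            if n_cols is None:
                n_cols = len(fields)
            elif len(fields) != n_cols:
                raise SignalFormatError(
                    f"line {lineno}: ragged row with {len(fields)} fields, "
                    f"expected {n_cols}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError:
                raise SignalFormatError(
                    f"line {lineno}: non-numeric cell in data row"
                ) from None
    if fs is None:
        raise SignalFormatError("header is missing the sampling rate ('# fs: ...')")
    if roles is None or len(roles) == 0:
        raise SignalFormatError("header declares an empty channel set ('# roles: ...')")
    if not rows:
        raise SignalFormatError("file contains no data rows")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] != len(roles) + 1:
        raise SignalFormatError(
            f"{arr.shape[1] - 1} data columns for {len(roles)} declared roles"
        )
    return SignalRecord(data=arr[:, 1:], fs=fs, channel_roles=roles, meta=meta)


# -- tabular text helpers ---------------------------------------------------


def write_table(df: pd.DataFrame, path, *, header_meta: dict | None = None) -> None:
    """Write a DataFrame as CSV, optionally preceded by ``# key: value`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV table written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")
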