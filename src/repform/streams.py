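"""Raw IMU recordings: the 9-channel stream container and its CSV round trip.

A recording is one uninterrupted capture from a single body-worn inertial
measurement unit: triaxial accelerometer (g), gyroscope (deg/s) and
magnetometer (Ga), uniformly sampled (51.2 Hz by default).  Full-scale
sensor ranges (+-2 g, +-500 deg/s, +-1.9 Ga) are enforced at this boundary
so downstream stages can assume physically plausible values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ImuStream",
    "StreamValidationError",
    "StreamParseError",
    "read_stream",
    "write_stream",
    "CHANNEL_COLUMNS",
]

#: fixed column order of the on-disk format (after the timestamp column "t")
CHANNEL_COLUMNS = (
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "mag_x", "mag_y", "mag_z",
)

DEFAULT_FS = 51.2

#: full-scale ranges in the stream's native units (g, deg/s, Ga)
FULL_SCALE = {"acc": 2.0, "gyro": 500.0, "mag": 1.9}

#: permitted deviation from exact uniform sampling, in seconds
TIMESTAMP_TOLERANCE = 1e-6


class StreamValidationError(ValueError):
    """A stream violates a structural or physical invariant."""


class StreamParseError(ValueError):
    """A stream file could not be parsed."""


@dataclass
class ImuStream:
    """Uniformly sampled 9-channel inertial recording.

    Parameters
    ----------
    session_id, exercise : str
        Free-text identifiers attached by the recording session.
    fs : float
        Sampling rate in Hz.
    t : ndarray
        Timestamps in seconds, strictly increasing and uniform.
    acc_x .. mag_z : ndarray
        Sensor channels in g, deg/s and Ga respectively.
    """

    session_id: str
    exercise: str
    fs: float
    t: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    gyro_z: np.ndarray
    mag_x: np.ndarray
    mag_y: np.ndarray
    mag_z: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in CHANNEL_COLUMNS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise StreamValidationError("stream must contain at least 2 samples")
        for name in CHANNEL_COLUMNS:
            if len(getattr(self, name)) != n:
                raise StreamValidationError(
                    f"channel {name!r} has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if not np.isfinite(self.t).all():
            raise StreamValidationError("timestamps contain non-finite values")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise StreamValidationError("timestamps must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.fs) > TIMESTAMP_TOLERANCE):
            raise StreamValidationError(
                f"sampling non-uniform beyond {TIMESTAMP_TOLERANCE} s "
                f"for fs={self.fs} Hz"
            )
        for name in CHANNEL_COLUMNS:
            values = getattr(self, name)
            if not np.isfinite(values).all():
                raise StreamValidationError(f"channel {name!r} contains non-finite values")
            limit = FULL_SCALE[name.split("_")[0]]
            worst = np.max(np.abs(values)) if n else 0.0
            if worst > limit:
                raise StreamValidationError(
                    f"channel {name!r} exceeds full-scale +-{limit}: |value| up to {worst:g}"
                )

    # -- conveniences ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.t)

    @property
    def acc(self) -> np.ndarray:
        """(n, 3) accelerometer block in g."""
        return np.column_stack([self.acc_x, self.acc_y, self.acc_z])

    @property
    def gyro(self) -> np.ndarray:
        """(n, 3) gyroscope block in deg/s."""
        return np.column_stack([self.gyro_x, self.gyro_y, self.gyro_z])

    @property
    def mag(self) -> np.ndarray:
        """(n, 3) magnetometer block in Ga."""
        return np.column_stack([self.mag_x, self.mag_y, self.mag_z])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t": self.t}
        data.update({name: getattr(self, name) for name in CHANNEL_COLUMNS})
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        fs: float = DEFAULT_FS,
        session_id: str = "",
        exercise: str = "",
    ) -> "ImuStream":
        missing = [c for c in CHANNEL_COLUMNS if c not in df.columns]
        if missing:
            raise StreamParseError(f"missing channel columns: {missing}")
        if "t" in df.columns:
            t = df["t"].to_numpy(dtype=float)
        else:
            t = np.arange(len(df)) / fs
        return cls(
            session_id=session_id,
            exercise=exercise,
            fs=fs,
            t=t,
            **{name: df[name].to_numpy(dtype=float) for name in CHANNEL_COLUMNS},
        )


def read_stream(
    path: str | Path,
    fs: float = DEFAULT_FS,
    *,
    session_id: str | None = None,
    exercise: str = "",
) -> ImuStream:
    """Read a 9-channel IMU stream from a comma-separated text file.

    The file must carry a single header line naming the nine channels; a
    ``t`` column is optional and synthesized from ``fs`` when absent.
    Malformed rows raise :class:`StreamParseError` naming the offending
    line; range or uniformity violations raise
    :class:`StreamValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise StreamParseError(f"{path}: {exc}") from exc
    for column in df.columns:
        if not pd.api.types.is_numeric_dtype(df[column]):
            bad = df[pd.to_numeric(df[column], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"  # +1 header, +1 one-based
            raise StreamParseError(
                f"{path}: non-numeric value in column {column!r} near line {line}"
            )
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0]) + 2
        raise StreamParseError(f"{path}: missing value near line {row}")
    return ImuStream.from_dataframe(
        df,
        fs=fs,
        session_id=path.stem if session_id is None else session_id,
        exercise=exercise,
    )


def write_stream(
    stream: ImuStream,
    path: str | Path,
    *,
    header_comments: dict[str, str] | None = None,
) -> Path:
    """Write a stream as CSV with the fixed column order ``t, acc_x .. mag_z``.

    Values are written with 12 significant digits so a write/read round
    trip preserves them to better than 9 significant digits.  Optional
    provenance key/value pairs are emitted as ``# key: value`` comment
    lines before the header.
    """
    stream.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = stream.to_dataframe()
    with open(path, "w") as handle:
        for key, value in (header_comments or {}).items():
            handle.write(f"# {key}: {value}\n")
        df.to_csv(handle, index=False, float_format="%.12g")
    return path


def truncate(stream: ImuStream, start: int, stop: int) -> ImuStream:
    """Return the sub-stream covering sample indices ``[start, stop)``."""
    if not (0 <= start < stop <= len(stream)):
        raise IndexError(f"invalid slice [{start}, {stop}) for stream of length {len(stream)}")
    kwargs = {name: getattr(stream, name)[start:stop] for name in CHANNEL_COLUMNS}
    return replace(stream, t=stream.t[start:stop], **kwargs)
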