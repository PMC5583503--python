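"""Synthetic single-IMU exercise sessions with ground truth.

Emulates a left-thigh sensor during cyclical lower-limb exercise
(squat / deadlift / lunge style movements).  Each repetition is a smooth
raised-cosine excursion of thigh pitch (sagittal plane), optionally with
a frontal-plane roll component; repetitions are separated by rest gaps of
near-zero motion.  The rendered stream contains gravity-only
accelerometer readings, finite-difference body-rate gyroscope readings
and a fixed earth magnetic field, all rotated into the moving sensor
frame, plus i.i.d. Gaussian sensor noise.

Two technique classes of tunable separation are produced by the
``deviation`` field: an amplitude deficit (shallow movement), frontal
wobble (knee valgus/varus style roll), or tempo asymmetry (rushed
descent).  ``deviation_magnitude`` in [0, 1] scales the effect, with 0
meaning the aberrant class is distributionally identical to the
acceptable one.

The simulated descent occupies slightly less than half of the repetition
(descent fraction 0.45 by default), so the positive descent lobe of the
pitch-rate signal is strictly the dominant one and the downstream
peak/zero-crossing segmentation has a well-defined polarity.  Ground
truth records, per repetition, the zero-velocity samples bracketing that
dominant lobe together with its maximum-rate sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .preprocess import euler_to_quaternion
from .streams import DEFAULT_FS, ImuStream

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_repetition",
    "render_imu",
    "generate_session",
    "generate_labeled_dataset",
    "DEVIATIONS",
]

DEVIATIONS = ("none", "amplitude_deficit", "frontal_wobble", "tempo_asymmetry")

#: roll excursion (rad) induced by frontal_wobble at deviation_magnitude 1
WOBBLE_GAIN = 0.4

#: fraction of the repetition spent descending (acceptable technique)
DESCENT_FRACTION = 0.45

#: earth magnetic field in the world frame, Ga (horizontal, 0, vertical)
EARTH_FIELD = np.array([0.4, 0.0, -0.3])

RAD2DEG = 180.0 / np.pi


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one simulated exercise session (single class)."""

    n_reps: int = 20
    rep_period: float = 3.0          # s per repetition
    rest_gap: float = 0.5            # s of near-zero motion between reps
    pitch_amplitude: float = 1.2     # rad sagittal thigh excursion
    roll_amplitude: float = 0.0      # rad frontal-plane excursion (base)
    tempo_jitter: float = 0.05       # CV of rep_period across reps
    noise_sd_acc: float = 0.02       # g
    noise_sd_gyro: float = 1.0       # deg/s
    noise_sd_mag: float = 0.01       # Ga
    deviation: str = "none"
    deviation_magnitude: float = 0.0
    seed: int = 0
    fs: float = DEFAULT_FS
    session_id: str = "synthetic"
    exercise: str = "squat"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.rep_period <= 0:
            raise ValueError("rep_period must be positive")
        if not 0.0 <= self.deviation_magnitude <= 1.0:
            raise ValueError("deviation_magnitude must lie in [0, 1]")
        if self.deviation not in DEVIATIONS:
            raise ValueError(f"deviation must be one of {DEVIATIONS}")
        for name in ("noise_sd_acc", "noise_sd_gyro", "noise_sd_mag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Per-repetition construction truth for one session."""

    boundaries: list[tuple[int, int, int]]  # (start, peak, end) sample indices
    labels: list[str]

    def __post_init__(self) -> None:
        last_end = -1
        for start, peak, end in self.boundaries:
            if not start < peak < end:
                raise ValueError("ground-truth triple must satisfy start < peak < end")
            if start <= last_end - 1:
                raise ValueError("ground-truth repetitions must be ordered, non-overlapping")
            last_end = end
        if len(self.labels) != len(self.boundaries):
            raise ValueError("one label per repetition required")

    @property
    def n_reps(self) -> int:
        return len(self.boundaries)


def _effective_shape(cfg: SynthConfig) -> tuple[float, float, float]:
    """(pitch amplitude, roll amplitude, descent fraction) after deviation."""
    amplitude = cfg.pitch_amplitude
    roll = cfg.roll_amplitude
    descent = DESCENT_FRACTION
    m = cfg.deviation_magnitude
    if cfg.deviation == "amplitude_deficit":
        amplitude *= 1.0 - m
    elif cfg.deviation == "frontal_wobble":
        roll = roll + m * WOBBLE_GAIN
    elif cfg.deviation == "tempo_asymmetry":
        descent *= 1.0 - 0.5 * m  # rushed descent: same depth in less time
    return amplitude, roll, descent


def _rep_rng(cfg: SynthConfig, rep_index: int) -> np.random.Generator:
    # counter-based substream: repetition k is reproducible in isolation
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, 1 + rep_index])


def simulate_repetition(
    cfg: SynthConfig, rep_index: int, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray | float | int]:
    """Orientation trajectory of one repetition, sampled at ``cfg.fs``.

    The pitch rises from 0 to the effective amplitude over the descent
    interval ``[0, d*T]`` as a raised cosine and returns to 0 over the
    ascent; the optional roll component is ``R * sin(2*pi*t / T)``.  The
    repetition period ``T`` is jittered per repetition by
    ``tempo_jitter`` (coefficient of variation, truncated at +-3 SD).

    Returns a dict with ``pitch`` and ``roll`` arrays (radians), the
    realized period ``T`` and the sample indices of the descent's
    maximum-rate point (``peak``) and end (``descent_end``).
    """
    if rng is None:
        rng = _rep_rng(cfg, rep_index)
    amplitude, roll_amp, descent = _effective_shape(cfg)
    jitter = float(np.clip(rng.standard_normal(), -3.0, 3.0)) * cfg.tempo_jitter
    period = cfg.rep_period * max(1.0 + jitter, 0.2)
    n = max(int(round(period * cfg.fs)), 4)
    t = np.arange(n) / cfg.fs
    t_descent = descent * period
    pitch = np.where(
        t < t_descent,
        0.5 * amplitude * (1.0 - np.cos(np.pi * t / t_descent)),
        0.5 * amplitude * (1.0 + np.cos(np.pi * (t - t_descent) / (period - t_descent))),
    )
    roll = roll_amp * np.sin(2.0 * np.pi * t / period)
    peak = int(round(0.5 * t_descent * cfg.fs))          # max pitch rate
    descent_end = int(np.ceil(t_descent * cfg.fs - 1e-9))  # first sample at/after zero rate
    return {
        "pitch": pitch,
        "roll": roll,
        "period": period,
        "peak": min(peak, n - 1),
        "descent_end": min(descent_end, n - 1),
    }


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """(n, 4) unit quaternions (w, x, y, z) -> (n, 3, 3) body-to-world matrices."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=-2,
    )


def _body_rates(q: np.ndarray, fs: float) -> np.ndarray:
    """Finite-difference body-frame angular velocity (rad/s) of a quaternion path."""
    n = q.shape[0]
    if n < 2:
        raise ValueError("trajectory must contain at least 2 samples")
    omega = np.zeros((n, 3))
    # relative rotation q_k^{-1} ⊗ q_{k+1} -> rotation vector / dt
    a, b = q[:-1], q[1:]
    w = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1] + a[:, 2] * b[:, 2] + a[:, 3] * b[:, 3]
    x = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0] - a[:, 2] * b[:, 3] + a[:, 3] * b[:, 2]
    y = a[:, 0] * b[:, 2] + a[:, 1] * b[:, 3] - a[:, 2] * b[:, 0] - a[:, 3] * b[:, 1]
    z = a[:, 0] * b[:, 3] - a[:, 1] * b[:, 2] + a[:, 2] * b[:, 1] - a[:, 3] * b[:, 0]
    vec_norm = np.sqrt(x * x + y * y + z * z)
    angle = 2.0 * np.arctan2(vec_norm, np.abs(w))
    sign = np.where(w < 0, -1.0, 1.0)  # shortest arc
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(vec_norm > 0, sign * angle / np.maximum(vec_norm, 1e-300), 0.0)
    omega[:-1] = np.stack([x, y, z], axis=-1) * scale[:, None] * fs
    omega[-1] = omega[-2]
    return omega


def render_imu(
    pitch: np.ndarray,
    roll: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> ImuStream:
    """Render an orientation trajectory into a 9-channel IMU stream.

    Accelerometer: the world gravity unit vector (0, 0, 1) g rotated into
    the sensor frame.  Gyroscope: finite-difference body rates of the
    trajectory, in deg/s.  Magnetometer: the fixed earth field rotated
    into the sensor frame.  Gaussian noise with the configured SDs is
    added per channel from the supplied (or seed-derived) generator.
    """
    pitch = np.asarray(pitch, dtype=float)
    roll = np.asarray(roll, dtype=float)
    if pitch.shape != roll.shape or pitch.ndim != 1:
        raise ValueError("pitch and roll must be equal-length 1-D arrays")
    if len(pitch) < 2:
        raise ValueError("trajectory must contain at least 2 samples")
    if rng is None:
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 999983])
    q = euler_to_quaternion(pitch, roll, np.zeros_like(pitch))
    rot = _quat_to_matrix(q)  # body -> world
    # world vectors observed in the sensor frame: v_s = R^T v_w
    acc = rot[:, 2, :].copy()               # R^T (0,0,1) = third row of R
    mag = np.einsum("nij,i->nj", rot, EARTH_FIELD)
    gyro = _body_rates(q, cfg.fs) * RAD2DEG
    n = len(pitch)
    acc += rng.normal(0.0, cfg.noise_sd_acc, size=(n, 3))
    gyro += rng.normal(0.0, cfg.noise_sd_gyro, size=(n, 3))
    mag += rng.normal(0.0, cfg.noise_sd_mag, size=(n, 3))
    return ImuStream(
        session_id=cfg.session_id,
        exercise=cfg.exercise,
        fs=cfg.fs,
        t=np.arange(n) / cfg.fs,
        acc_x=acc[:, 0], acc_y=acc[:, 1], acc_z=acc[:, 2],
        gyro_x=gyro[:, 0], gyro_y=gyro[:, 1], gyro_z=gyro[:, 2],
        mag_x=mag[:, 0], mag_y=mag[:, 1], mag_z=mag[:, 2],
    )


def generate_session(cfg: SynthConfig) -> tuple[ImuStream, GroundTruth]:
    """One session: ``n_reps`` repetitions separated by rest gaps.

    Deterministic given ``cfg.seed``.  Ground-truth boundaries are the
    zero-velocity samples bracketing each repetition's dominant (descent)
    pitch-rate lobe plus its maximum-rate sample; labels are "Acceptable"
    for ``deviation == "none"`` and "Aberrant" otherwise.
    """
    gap_n = max(int(round(cfg.rest_gap * cfg.fs)), 1)
    pitch_parts: list[np.ndarray] = [np.zeros(gap_n)]
    roll_parts: list[np.ndarray] = [np.zeros(gap_n)]
    boundaries: list[tuple[int, int, int]] = []
    cursor = gap_n
    for k in range(cfg.n_reps):
        rep = simulate_repetition(cfg, k)
        pitch_parts.append(rep["pitch"])
        roll_parts.append(rep["roll"])
        boundaries.append((cursor, cursor + rep["peak"], cursor + rep["descent_end"]))
        cursor += len(rep["pitch"])
        pitch_parts.append(np.zeros(gap_n))
        roll_parts.append(np.zeros(gap_n))
        cursor += gap_n
    pitch = np.concatenate(pitch_parts)
    roll = np.concatenate(roll_parts)
    stream = render_imu(pitch, roll, cfg)
    label = "Acceptable" if cfg.deviation == "none" else "Aberrant"
    truth = GroundTruth(boundaries=boundaries, labels=[label] * cfg.n_reps)
    return stream, truth


def generate_labeled_dataset(
    cfg_acceptable: SynthConfig,
    cfg_aberrant: SynthConfig,
    seed: int = 0,
):
    """Build a classifier-ready labeled database from two class configs.

    The two configs should differ only in their deviation fields (a
    warning is emitted otherwise).  Each class becomes one session whose
    repetitions are cut at the ground-truth boundaries and labeled
    "Acceptable" / "Aberrant".  Returns a
    :class:`~repform.store.SessionDatabase`.
    """
    from .preprocess import build_signal_set
    from .segment import Repetition
    from .store import SessionDatabase

    ignore = {"deviation", "deviation_magnitude", "seed", "session_id", "roll_amplitude"}
    for f in fields(SynthConfig):
        if f.name in ignore:
            continue
        if getattr(cfg_acceptable, f.name) != getattr(cfg_aberrant, f.name):
            warnings.warn(
                f"class configs differ in non-deviation field {f.name!r}; "
                "class separation will reflect more than the technique deviation",
                stacklevel=2,
            )
    db = SessionDatabase()
    exercise = cfg_acceptable.exercise
    db.add_exercise(exercise)
    db.add_label(exercise, "Aberrant")
    for class_index, (cfg, label) in enumerate(
        [(cfg_acceptable, "Acceptable"), (cfg_aberrant, "Aberrant")]
    ):
        cfg = replace(
            cfg,
            seed=(seed * 2 + class_index) & 0x7FFFFFFF,
            session_id=f"{cfg.session_id}-{label.lower()}",
        )
        stream, truth = generate_session(cfg)
        signals = build_signal_set(stream)
        reps = []
        for i, (start, peak, end) in enumerate(truth.boundaries):
            reps.append(
                Repetition(
                    session_id=cfg.session_id,
                    exercise=exercise,
                    rep_number=i + 1,
                    start_index=start,
                    peak_index=peak,
                    end_index=end,
                    signals=signals.slice(start, end),
                    label=label,
                )
            )
        db.add_session(signals, reps, labeled=True)
    return db
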