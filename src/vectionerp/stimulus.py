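"""Rotating dot-field stimulus kinematics.

Two stimulus classes drive the experiment: a *coherent* field in which 1000
dots rotate rigidly in the roll plane at 30 deg/s, and an *incoherent* field in
which each dot additionally carries an independent random sinusoidal offset in
X and Y, so each dot wanders locally while the global pattern keeps the same
mean angular velocity.  This module generates trajectories as arrays (dots x
frames x 2, degrees of visual field, origin at fixation) and measures their
velocity statistics; it does not render anything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import Condition, Direction, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DotFieldSpec",
    "DotTrajectory",
    "generate_coherent",
    "generate_incoherent",
    "mean_global_angular_speed",
    "build_trial_timeline",
    "build_session_schedule",
]


@dataclass(frozen=True)
class DotFieldSpec:
    """Parameters of the rotating dot field.

    omega is the global angular velocity in deg/s, signed (+ = CCW).  The
    perturbation ranges parameterize the per-dot sinusoids of the incoherent
    condition: amplitudes in degrees of visual field per axis, frequencies in
    Hz; both drawn uniformly per dot per axis.
    """

    n_dots: int = 1000
    omega: float = 30.0
    duration: float = 20.0
    frame_rate: float = 60.0
    perturb_amp_range: tuple[float, float] = (0.5, 3.0)
    perturb_freq_range: tuple[float, float] = (0.2, 1.0)
    field_radius: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_dots < 1:
            raise ValidationError("n_dots must be >= 1")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValidationError("frame_rate and duration must be positive")
        if self.field_radius <= 0:
            raise ValidationError("field_radius must be positive")
        lo, hi = self.perturb_amp_range
        if not (0 <= lo <= hi):
            raise ValidationError("invalid perturbation amplitude range")
        if hi > self.field_radius:
            raise ValidationError(
                "perturbation amplitude exceeds field radius; dots would leave the field"
            )
        flo, fhi = self.perturb_freq_range
        if not (0 <= flo <= fhi):
            raise ValidationError("invalid perturbation frequency range")


@dataclass
class DotTrajectory:
    """Planar dot positions over frames (deg of visual field, origin at fixation)."""

    positions: np.ndarray  # (n_dots, n_frames, 2)
    spec: DotFieldSpec
    per_dot_params: dict | None = None  # sinusoid phase/amp/freq per dot per axis

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.shape[1]) / self.spec.frame_rate


def _initial_positions(spec: DotFieldSpec, rng: np.random.Generator) -> np.ndarray:
    # uniform over the disc by area: radius ~ R*sqrt(u)
    r = spec.field_radius * np.sqrt(rng.random(spec.n_dots))
    theta = rng.uniform(0, 2 * np.pi, spec.n_dots)
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def _rigid_rotation(spec: DotFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Rigid-rotation positions (n_dots, n_frames, 2) about the origin."""
    n_frames = int(round(spec.duration * spec.frame_rate)) + 1
    t = np.arange(n_frames) / spec.frame_rate
    p0 = _initial_positions(spec, rng)
    phi = np.deg2rad(spec.omega) * t  # (n_frames,)
    c, s = np.cos(phi), np.sin(phi)
    x = p0[:, None, 0] * c[None, :] - p0[:, None, 1] * s[None, :]
    y = p0[:, None, 0] * s[None, :] + p0[:, None, 1] * c[None, :]
    return np.stack([x, y], axis=2)


def generate_coherent(spec: DotFieldSpec) -> DotTrajectory:
    """Rigid roll-plane rotation of the whole field at ``spec.omega`` deg/s."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    return DotTrajectory(positions=_rigid_rotation(spec, rng), spec=spec)


def generate_incoherent(spec: DotFieldSpec) -> DotTrajectory:
    """Rigid rotation plus an independent X/Y sinusoid per dot.

    Phase, amplitude and frequency of each dot's two sinusoids are drawn from
    the configured ranges; the initial dot placement uses the same seed stream
    as :func:`generate_coherent`, so a zero-amplitude perturbation range
    reproduces the coherent trajectory exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = _rigid_rotation(spec, rng)
    n_frames = base.shape[1]
    t = np.arange(n_frames) / spec.frame_rate

    lo, hi = spec.perturb_amp_range
    flo, fhi = spec.perturb_freq_range
    amp = rng.uniform(lo, hi, size=(spec.n_dots, 2))
    freq = rng.uniform(flo, fhi, size=(spec.n_dots, 2))
    phase = rng.uniform(0, 2 * np.pi, size=(spec.n_dots, 2))

    # (n_dots, n_frames, 2) sinusoidal offsets
    arg = 2 * np.pi * freq[:, None, :] * t[None, :, None] + phase[:, None, :]
    offsets = amp[:, None, :] * np.sin(arg)
    params = {"amplitude": amp, "frequency": freq, "phase": phase}
    return DotTrajectory(positions=base + offsets, spec=spec, per_dot_params=params)


def mean_global_angular_speed(
    traj: DotTrajectory,
    t0: float = 0.0,
    t1: float | None = None,
    radius_floor: float = 1e-9,
) -> float:
    """Across-dot mean angular velocity about the origin over [t0, t1], deg/s.

    Each dot contributes its net unwrapped angular displacement divided by the
    window length.  Dots whose radial distance dips below ``radius_floor``
    (origin crossing; the angle is undefined there) are excluded from the mean
    with a logged count.
    """
    spec = traj.spec
    if t1 is None:
        t1 = spec.duration
    if not (0 <= t0 < t1 <= spec.duration + 1e-12):
        raise ValidationError("window [t0, t1] must lie within the trajectory duration")
    i0 = int(round(t0 * spec.frame_rate))
    i1 = int(round(t1 * spec.frame_rate))
    pos = traj.positions[:, i0 : i1 + 1, :]
    radius = np.hypot(pos[..., 0], pos[..., 1])
    ok = radius.min(axis=1) > radius_floor
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("mean_global_angular_speed: excluded %d origin-crossing dots", n_excluded)
    if not ok.any():
        raise ValidationError("no dots with well-defined angle in the window")
    ang = np.unwrap(np.arctan2(pos[ok, :, 1], pos[ok, :, 0]), axis=1)
    net = np.rad2deg(ang[:, -1] - ang[:, 0])
    duration = (i1 - i0) / spec.frame_rate
    return float(np.mean(net) / duration)


def build_trial_timeline(
    spec: DotFieldSpec | None = None,
    jitter_range: tuple[float, float] = (3.0, 5.0),
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, float]]:
    """Trial segment timeline: jittered stationary, 20 s rotation, 10 s stationary.

    The pre-motion stationary period is drawn uniformly from ``jitter_range``
    (default 3-5 s); the rotation segment lasts ``spec.duration`` (default
    20 s) and the post-motion stationary period 10 s.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = jitter_range
    if not (0 <= lo <= hi):
        raise ValidationError("invalid jitter range")
    rotating = spec.duration if spec is not None else 20.0
    return [
        ("stationary", float(rng.uniform(lo, hi))),
        ("rotating", float(rotating)),
        ("stationary", 10.0),
    ]


def build_session_schedule(
    n_trials: int = 100,
    block_size: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Randomized session schedule: condition x direction balanced trial list.

    Every session contains equal numbers of coherent and incoherent trials,
    each split equally between CW and CCW (the default 100 trials give 50 per
    condition, 25 per direction within each).  Trial order is a random
    permutation presented in blocks of ``block_size``.
    """
    if n_trials % 4:
        raise ValidationError("n_trials must be divisible by 4 for a balanced design")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = [
        (cond, direc)
        for cond in (Condition.COHERENT, Condition.INCOHERENT)
        for direc in (Direction.CW, Direction.CCW)
    ]
    rows = [(cond, direc) for cond, direc in cells for _ in range(n_trials // 4)]
    order = rng.permutation(len(rows))
    df = pd.DataFrame(
        {
            "trial": np.arange(1, n_trials + 1),
            "block": np.arange(n_trials) // block_size + 1,
            "condition": [rows[i][0].value for i in order],
            "direction": [rows[i][1].value for i in order],
        }
    )
    return df


def export_trajectory(traj: DotTrajectory, path) -> None:
    """Export a trajectory as a documented binary array file (dots x frames x 2)."""
    np.save(path, traj.positions)
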