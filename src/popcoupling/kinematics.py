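"""Kinematic feature extraction from 3D bead trajectories.

Bead positions are low-pass filtered (zero-phase Butterworth, 5 Hz cutoff by
default) and differentiated to velocities.  From the eight bead velocities we
derive the mean body speed and 27 movement *aspects*:

1. centre-of-mass (COM) speed, mm/s;
2. left-right turning angular speed, rad/s — azimuthal rate of the body
   vector's horizontal projection;
3. up-down rearing angular speed, rad/s — elevation rate of the body vector;
4-27. three orthogonal components (rostrocaudal, right-left, up-down) of each
   bead's velocity relative to the COM, expressed in the body frame,
   mm/s, bead-major order.

The *body vector* is the principal axis of the three points {COM, head bead,
neck-base bead}, oriented toward the head.  Frames where the body vector is
(numerically) vertical have no defined horizontal heading; aspects depending
on it are set to NaN there and counted in ``degenerate_frames``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data_io import BeadTrajectories

__all__ = [
    "ASPECT_NAMES",
    "KinematicsSeries",
    "preprocess_positions",
    "mean_body_speed",
    "compute_aspects",
    "export_aspects_csv",
]

_AXES = ("rostrocaudal", "rightleft", "updown")

ASPECT_NAMES: tuple[str, ...] = (
    "com_speed",
    "turn_speed",
    "rear_speed",
) + tuple(
    f"{bead}_vel_{axis}"
    for bead in (
        "head",
        "neck_base",
        "back_1",
        "back_2",
        "back_3",
        "back_4",
        "hips",
        "tail_base",
    )
    for axis in _AXES
)
assert len(ASPECT_NAMES) == 27


@dataclass
class KinematicsSeries:
    """Per-sample kinematic features for one session."""

    sample_rate_hz: float
    bead_speeds: np.ndarray  # (8, T) mm/s
    mean_speed: np.ndarray  # (T,) mm/s
    aspects: np.ndarray  # (27, T)
    aspect_names: tuple[str, ...] = ASPECT_NAMES
    degenerate_frames: int = 0

    @property
    def n_samples(self) -> int:
        return self.mean_speed.size


def preprocess_positions(
    beads: BeadTrajectories, cutoff_hz: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase low-pass filter positions, then differentiate.

    Returns ``(smoothed_positions, velocities)``, both ``(8, T, 3)``;
    velocities in mm/s via central differences at the motion sample rate.
    """
    fs = beads.sample_rate_hz
    pos = beads.positions
    if pos.shape[1] < int(fs):
        raise ValueError("bead series shorter than filter warm-up (need >= 1 s)")
    b, a = signal.butter(4, cutoff_hz / (fs / 2.0))
    smooth = signal.filtfilt(b, a, pos, axis=1)
    vel = np.gradient(smooth, axis=1) * fs
    return smooth, vel


def mean_body_speed(bead_speeds: np.ndarray) -> np.ndarray:
    """Pointwise arithmetic mean of the eight bead speeds."""
    if bead_speeds.shape[0] != 8:
        raise ValueError("expected 8 bead speed series")
    return bead_speeds.mean(axis=0)


def _body_vector(com: np.ndarray, head: np.ndarray, neck: np.ndarray) -> np.ndarray:
    """Principal axis of {COM, head, neck} per frame, oriented toward head.

    Returns a (T, 3) array of unit vectors.
    """
    pts = np.stack([com, head, neck], axis=0)  # (3, T, 3)
    centred = pts - pts.mean(axis=0, keepdims=True)
    # scatter matrix per frame; principal eigenvector = best-fit line direction
    scat = np.einsum("ptk,ptl->tkl", centred, centred)
    _, vecs = np.linalg.eigh(scat)
    v = vecs[:, :, -1]  # eigenvector of the largest eigenvalue
    sign = np.sign(np.einsum("tk,tk->t", head - pts.mean(axis=0), v))
    sign[sign == 0] = 1.0
    return v * sign[:, None]


def compute_aspects(
    beads: BeadTrajectories, cutoff_hz: float = 5.0
) -> KinematicsSeries:
    """Compute bead speeds, mean body speed, and the 27 movement aspects."""
    fs = beads.sample_rate_hz
    smooth, vel = preprocess_positions(beads, cutoff_hz)
    bead_speeds = np.linalg.norm(vel, axis=2)
    mean_speed = mean_body_speed(bead_speeds)

    com = smooth.mean(axis=0)  # equal-weight COM, (T, 3)
    com_vel = vel.mean(axis=0)
    T = com.shape[0]
    aspects = np.empty((27, T))
    aspects[0] = np.linalg.norm(com_vel, axis=1)

    body = _body_vector(com, smooth[0], smooth[1])  # head, neck_base beads
    horiz = np.hypot(body[:, 0], body[:, 1])
    degenerate = horiz < 1e-9

    azimuth = np.unwrap(np.arctan2(body[:, 1], body[:, 0]))
    elevation = np.arctan2(body[:, 2], horiz)
    aspects[1] = np.gradient(azimuth) * fs
    aspects[2] = np.gradient(elevation) * fs

    # body-frame axes: rostrocaudal = horizontal heading, right-left = its
    # horizontal perpendicular, up-down = lab vertical
    with np.errstate(invalid="ignore", divide="ignore"):
        rostro = np.zeros((T, 3))
        rostro[:, 0] = body[:, 0] / horiz
        rostro[:, 1] = body[:, 1] / horiz
    rightleft = np.zeros((T, 3))
    rightleft[:, 0] = rostro[:, 1]
    rightleft[:, 1] = -rostro[:, 0]

    rel = vel - com_vel[None, :, :]  # (8, T, 3)
    for b in range(8):
        aspects[3 + 3 * b + 0] = np.einsum("tk,tk->t", rel[b], rostro)
        aspects[3 + 3 * b + 1] = np.einsum("tk,tk->t", rel[b], rightleft)
        aspects[3 + 3 * b + 2] = rel[b, :, 2]

    if degenerate.any():
        aspects[1, degenerate] = np.nan
        for b in range(8):
            aspects[3 + 3 * b + 0, degenerate] = np.nan
            aspects[3 + 3 * b + 1, degenerate] = np.nan

    return KinematicsSeries(
        sample_rate_hz=fs,
        bead_speeds=bead_speeds,
        mean_speed=mean_speed,
        aspects=aspects,
        degenerate_frames=int(degenerate.sum()),
    )


def export_aspects_csv(kin: KinematicsSeries, path) -> None:
    """Write the 27 aspect series as ``time_s,aspect_01..aspect_27``."""
    import pandas as pd

    t = np.arange(kin.n_samples) / kin.sample_rate_hz
    data = {"time_s": t}
    for i in range(27):
        data[f"aspect_{i + 1:02d}"] = kin.aspects[i]
    pd.DataFrame(data).to_csv(path, index=False)
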