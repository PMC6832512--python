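"""Attitude-angle posture assessment for a buckle-worn device.

Three rotations are recovered from the direction of measured acceleration
(assumed gravity-dominated while sitting):

    theta = atan( Acc_x / sqrt(Acc_y^2 + Acc_z^2) )    rotation about X
    psi   = atan( Acc_y / sqrt(Acc_x^2 + Acc_z^2) )    rotation about Y
    phi   = atan( sqrt(Acc_x^2 + Acc_y^2) / |Acc_z| )  rotation about Z

all in degrees: theta, psi in [-90, 90], phi in [0, 90] (phi = 90 when
Acc_z = 0). A sitting posture is called good when the belt is laterally
level (|psi| within a tolerance of 0) and the trunk near vertical
(phi inside a band close to 90 degrees); both thresholds live in
:class:`PostureRule` and are deliberately configurable policy, not
physiology.

Angles for whole recordings are computed on the low-passed gravity
component of the acceleration so that transient body motion does not flip
the assessment sample-to-sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import ImuRecording, denoise, separate_gravity

__all__ = [
    "PostureAngles",
    "PostureRule",
    "SessionStats",
    "attitude_angles",
    "assess_posture",
    "assess_recording",
    "poor_posture_rate",
    "improvement_rate",
]


@dataclass(frozen=True)
class PostureAngles:
    """Device attitude in degrees: rotations about the X, Y and Z axes."""

    theta: float
    psi: float
    phi: float


@dataclass(frozen=True)
class PostureRule:
    """Good-posture policy: lateral tilt near zero, trunk near vertical."""

    psi_tolerance: float = 10.0
    phi_min: float = 80.0
    phi_max: float = 90.0

    def __post_init__(self) -> None:
        if not (0 <= self.phi_min <= self.phi_max <= 90):
            raise ValueError("require 0 <= phi_min <= phi_max <= 90")
        if self.psi_tolerance < 0:
            raise ValueError("psi_tolerance must be non-negative")


@dataclass(frozen=True)
class SessionStats:
    """Fraction of assessed time spent in poor posture over a session."""

    poor_posture_rate: float
    duration: float

    def __post_init__(self) -> None:
        if not 0 <= self.poor_posture_rate <= 1:
            raise ValueError("poor_posture_rate must lie in [0, 1]")


def attitude_angles(acc) -> PostureAngles:
    """Attitude angles (degrees) of one acceleration sample.

    Scale-invariant: only the direction of ``acc`` matters. A zero vector is
    rejected (free fall has no defined attitude).
    """
    a = np.asarray(acc, dtype=float)
    if a.shape != (3,):
        raise ValueError("acc must be a 3-vector")
    if not np.all(np.isfinite(a)):
        raise ValueError("acc must be finite")
    ax, ay, az = a
    if ax == 0 and ay == 0 and az == 0:
        raise ValueError("zero acceleration vector: attitude undefined")
    theta = np.degrees(np.arctan2(ax, np.hypot(ay, az)))
    psi = np.degrees(np.arctan2(ay, np.hypot(ax, az)))
    phi = np.degrees(np.arctan2(np.hypot(ax, ay), abs(az)))
    return PostureAngles(theta=float(theta), psi=float(psi), phi=float(phi))


def assess_posture(angles: PostureAngles, rule: PostureRule = PostureRule()) -> str:
    """``"good"`` iff |psi| <= tolerance and phi inside [phi_min, phi_max]."""
    ok = abs(angles.psi) <= rule.psi_tolerance and (
        rule.phi_min <= angles.phi <= rule.phi_max
    )
    return "good" if ok else "poor"


def assess_recording(
    rec: ImuRecording, rule: PostureRule = PostureRule(), smooth: bool = True
) -> tuple[list[PostureAngles], list[str]]:
    """Per-sample attitude angles and good/poor assessment for a recording.

    With ``smooth`` (default) angles come from the 0.3 Hz gravity component
    of the denoised acceleration; otherwise from the raw samples.
    """
    if smooth:
        acc = denoise(rec.acc, rec.sample_rate)
        acc, _body = separate_gravity(acc, rec.sample_rate)
    else:
        acc = rec.acc
    angles = [attitude_angles(a) for a in acc]
    return angles, [assess_posture(a, rule) for a in angles]


def poor_posture_rate(assessments, duration: float) -> SessionStats:
    """Fraction of uniformly spaced assessments that are poor.

    ``assessments`` is a sequence of ``"good"``/``"poor"`` strings (or
    booleans, True meaning poor); ``duration`` is the session length in
    seconds, carried through for reporting.
    """
    seq = list(assessments)
    if not seq:
        raise ValueError("empty assessment series")
    poor = sum(1 for a in seq if (a == "poor" or a is True))
    return SessionStats(poor_posture_rate=poor / len(seq), duration=float(duration))


def improvement_rate(rate_without: float, rate_with: float) -> float:
    """Percent reduction of poor-posture rate attributable to intervention.

    ``100 * (rate_without - rate_with) / rate_without``; undefined (raises)
    when the baseline rate is zero.
    """
    if rate_without <= 0:
        raise ValueError("improvement rate undefined for a zero baseline rate")
    return 100.0 * (rate_without - rate_with) / rate_without
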