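"""Derivation of the 17 named time/frequency signals from raw belt IMU streams.

The pre-processing chain is: median filter + 20 Hz third-order Butterworth
low-pass on both sensors, gravity/body split of the acceleration with a
0.3 Hz Butterworth low-pass, jerk (time derivative) of the body acceleration
and of the angular speed, Euclidean magnitudes, and a per-window magnitude
spectrum for the seven signals that carry a frequency-domain version.

All filters are applied zero-phase (forward-backward) so no group delay is
introduced between channels; this assumes an offline recording, not a
streaming buffer. Acceleration is kept in units of g and angular speed in
rad/s throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ImuRecording",
    "Channel",
    "SignalSet",
    "TIME_SIGNALS",
    "FREQ_SIGNALS",
    "denoise",
    "separate_gravity",
    "jerk",
    "magnitude",
    "to_frequency",
    "derive_signals",
]

#: Default sampling rate in Hz (128 samples span 1.28 s).
DEFAULT_SAMPLE_RATE = 100.0

#: Low-pass cutoff (Hz) of the denoising stage.
NOISE_CUTOFF_HZ = 20.0
#: Low-pass cutoff (Hz) separating gravity from body motion.
GRAVITY_CUTOFF_HZ = 0.3
#: Butterworth order used by both filters.
FILTER_ORDER = 3
#: Median-filter kernel width (samples). Width 3 removes single-sample spikes
#: without distorting band-limited motion.
MEDIAN_KERNEL = 3

# filtfilt pads 3*max(len(a), len(b)) samples on each side; order-3 filters
# therefore need strictly more than 12 samples.
_MIN_FILTER_LEN = 3 * (2 * FILTER_ORDER + 2) // 2 + 1  # = 13

#: The ten time-domain signal names, in derivation order.
TIME_SIGNALS = (
    "body_acc",
    "gravity_acc",
    "body_acc_jerk",
    "body_gyro",
    "body_gyro_jerk",
    "body_acc_mag",
    "gravity_acc_mag",
    "body_acc_jerk_mag",
    "body_gyro_mag",
    "body_gyro_jerk_mag",
)

#: The seven signals that also carry a frequency-domain version
#: (everything except gravity and the angular-acceleration XYZ triplet).
FREQ_SIGNALS = (
    "body_acc",
    "body_acc_jerk",
    "body_gyro",
    "body_acc_mag",
    "body_acc_jerk_mag",
    "body_gyro_mag",
    "body_gyro_jerk_mag",
)


def _as_triaxial(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must have shape (n, 3), got {x.shape}")
    return x


@dataclass(frozen=True)
class ImuRecording:
    """A uniformly sampled tri-axial accelerometer + gyroscope recording.

    Parameters
    ----------
    sample_rate : float
        Sampling rate in Hz, > 0.
    acc : ndarray, shape (n, 3)
        Acceleration in g.
    gyro : ndarray, shape (n, 3)
        Angular speed in rad/s.
    time : ndarray, shape (n,), optional
        Sample times in seconds; defaults to ``arange(n) / sample_rate``.
        Must be a strictly increasing uniform grid.
    labels : sequence of str or None
        Optional per-sample activity tag.
    """

    sample_rate: float
    acc: np.ndarray
    gyro: np.ndarray
    time: np.ndarray = None  # type: ignore[assignment]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        acc = _as_triaxial(self.acc, "acc")
        gyro = _as_triaxial(self.gyro, "gyro")
        if len(acc) != len(gyro):
            raise ValueError("acc and gyro must share one length")
        if len(acc) < 1:
            raise ValueError("recording must contain at least one sample")
        t = self.time
        if t is None:
            t = np.arange(len(acc)) / self.sample_rate
        else:
            t = np.asarray(t, dtype=float)
            if t.shape != (len(acc),):
                raise ValueError("time must be one value per sample")
            if len(t) > 1:
                dt = np.diff(t)
                if np.any(dt <= 0):
                    raise ValueError("time must be strictly increasing")
                dt0 = 1.0 / self.sample_rate
                if np.max(np.abs(dt - dt0)) > 1e-9 * max(dt0, 1.0):
                    raise ValueError(
                        "time must be a uniform grid at the stated sample_rate "
                        "(relative tolerance 1e-9)"
                    )
        labels = self.labels
        if labels is not None:
            labels = np.asarray(labels, dtype=object)
            if labels.shape != (len(acc),):
                raise ValueError("labels must be one tag per sample")
        object.__setattr__(self, "acc", acc)
        object.__setattr__(self, "gyro", gyro)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.acc)


@dataclass(frozen=True)
class Channel:
    """One named signal: tri-axial or scalar, time or frequency domain.

    Time-domain data has shape ``(n,)`` or ``(n, 3)``. Frequency-domain data
    is per analysis window: shape ``(n_windows, bins)`` or
    ``(n_windows, bins, 3)``.
    """

    name: str
    data: np.ndarray
    domain: str  # "time" | "freq"

    @property
    def n_components(self) -> int:
        return 3 if self.data.shape[-1] == 3 and self.data.ndim > 1 else 1


@dataclass(frozen=True)
class SignalSet:
    """The 17 derived channels: 10 time-domain, 7 frequency-domain.

    Frequency channels are magnitude spectra computed per 128-sample window
    (see :func:`to_frequency`); ``window_starts`` records the window grid the
    spectra were computed on.
    """

    channels: dict[str, Channel]
    sample_rate: float
    window_starts: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    labels: np.ndarray | None = None

    def __getitem__(self, key: str) -> Channel:
        return self.channels[key]

    @property
    def time_names(self) -> list[str]:
        return [c.name for c in self.channels.values() if c.domain == "time"]

    @property
    def freq_names(self) -> list[str]:
        return [c.name for c in self.channels.values() if c.domain == "freq"]

    @property
    def n_samples(self) -> int:
        return len(self.channels["body_acc"].data)


def _check_filter_input(x: np.ndarray, sample_rate: float, cutoff: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    if sample_rate <= 2 * cutoff:
        raise ValueError(
            f"sample_rate {sample_rate} Hz must exceed twice the "
            f"{cutoff} Hz cutoff (Nyquist)"
        )
    if x.shape[0] < _MIN_FILTER_LEN:
        raise ValueError(
            f"need at least {_MIN_FILTER_LEN} samples for stable zero-phase "
            f"filtering, got {x.shape[0]}"
        )
    return x


def denoise(raw: np.ndarray, sample_rate: float) -> np.ndarray:
    """Median filter (width 3) then 20 Hz third-order Butterworth low-pass.

    Applied per axis, zero-phase; output length equals input length. Removes
    single-sample spikes and attenuates content above 20 Hz.
    """
    x = _check_filter_input(raw, sample_rate, NOISE_CUTOFF_HZ)
    med = sps.medfilt(x, kernel_size=(MEDIAN_KERNEL, 1) if x.ndim == 2 else MEDIAN_KERNEL)
    sos = sps.butter(FILTER_ORDER, NOISE_CUTOFF_HZ, fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, med, axis=0)


def separate_gravity(acc: np.ndarray, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Split denoised acceleration into gravity (<= 0.3 Hz) and body motion.

    Returns ``(gravity, body)`` with ``gravity + body == acc`` exactly, per
    sample and axis: the body component is defined as the residual.
    """
    x = _check_filter_input(acc, sample_rate, GRAVITY_CUTOFF_HZ)
    sos = sps.butter(FILTER_ORDER, GRAVITY_CUTOFF_HZ, fs=sample_rate, output="sos")
    gravity = sps.sosfiltfilt(sos, x, axis=0)
    return gravity, x - gravity


def jerk(body: np.ndarray, sample_rate: float) -> np.ndarray:
    """Time derivative: central differences interior, one-sided at the ends.

    Output length equals input length so all channels stay window-aligned.
    """
    x = np.asarray(body, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("jerk needs at least 2 samples")
    return np.gradient(x, axis=0) * sample_rate


def magnitude(xyz: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a tri-axial channel."""
    x = _as_triaxial(xyz, "xyz")
    return np.linalg.norm(x, axis=1)


def to_frequency(window: np.ndarray) -> np.ndarray:
    """Magnitude spectrum of one analysis window.

    Convention: one-sided spectrum, ``|rfft(w)|[:n//2] / n`` — the first n/2
    bins (DC included, Nyquist bin dropped), normalized by the window length
    so spectral features are scale-stable. No taper is applied. Accepts any
    power-of-two length; tri-axial input is transformed per axis.
    """
    w = np.asarray(window, dtype=float)
    n = w.shape[0]
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"window length must be a power of two, got {n}")
    spec = np.abs(np.fft.rfft(w, axis=0))[: n // 2] / n
    return spec


def _window_spectra(data: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    """Stack per-window magnitude spectra: (n_windows, window//2[, 3])."""
    if len(starts) == 0:
        shape = (0, window // 2) + ((3,) if data.ndim == 2 else ())
        return np.empty(shape)
    idx = starts[:, None] + np.arange(window)[None, :]
    segs = data[idx]  # (n_windows, window[, 3])
    return np.abs(np.fft.rfft(segs, axis=1))[:, : window // 2] / window


def derive_signals(
    rec: ImuRecording, window: int = 128, overlap: float = 0.5
) -> SignalSet:
    """Run the full pre-processing chain, yielding the 17-channel SignalSet.

    Order: denoise both sensors -> gravity/body split of acceleration ->
    jerk of body acceleration and of angular speed -> magnitudes -> per-window
    magnitude spectra of the seven signals with a frequency-domain version.
    """
    from .features import make_windows  # local import to avoid a cycle

    fs = rec.sample_rate
    try:
        acc = denoise(rec.acc, fs)
        gyro = denoise(rec.gyro, fs)
    except ValueError as e:
        raise ValueError(f"denoise stage failed: {e}") from e
    try:
        gravity, body = separate_gravity(acc, fs)
    except ValueError as e:
        raise ValueError(f"gravity separation stage failed: {e}") from e
    try:
        body_jerk = jerk(body, fs)
        gyro_jerk = jerk(gyro, fs)
    except ValueError as e:
        raise ValueError(f"jerk stage failed: {e}") from e

    time_data: dict[str, np.ndarray] = {
        "body_acc": body,
        "gravity_acc": gravity,
        "body_acc_jerk": body_jerk,
        "body_gyro": gyro,
        "body_gyro_jerk": gyro_jerk,
        "body_acc_mag": magnitude(body),
        "gravity_acc_mag": magnitude(gravity),
        "body_acc_jerk_mag": magnitude(body_jerk),
        "body_gyro_mag": magnitude(gyro),
        "body_gyro_jerk_mag": magnitude(gyro_jerk),
    }

    starts = np.asarray(make_windows(len(rec), window=window, overlap=overlap), int)
    channels: dict[str, Channel] = {
        name: Channel(name, data, "time") for name, data in time_data.items()
    }
    for name in FREQ_SIGNALS:
        channels["f_" + name] = Channel(
            "f_" + name, _window_spectra(time_data[name], starts, window), "freq"
        )
    return SignalSet(
        channels=channels,
        sample_rate=fs,
        window_starts=starts,
        labels=rec.labels,
    )
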