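"""Windowing and the 561-element feature vector.

The derived signals are sliced into 128-sample windows with 50% overlap and
a fixed, ordered bank of statistics is computed per window. The enumeration
follows the established waist-worn HAR convention and lands on exactly 561
features:

* 5 time-domain XYZ signals x 40 features
  (mean/std/mad/max/min/energy/iqr/entropy per axis, sma, 4 Burg AR
  coefficients per axis, 3 pairwise correlations)             -> 200
* 5 time-domain magnitude signals x 13 features               ->  65
* 3 frequency-domain XYZ signals x 79 features
  (the scalar stats per axis plus maxFreqInd/meanFreq/skewness/kurtosis
  per axis and 14 band energies per axis)                     -> 237
* 4 frequency-domain magnitude signals x 13 features          ->  52
* 7 angle features between window-mean vectors and gravity    ->   7

Conventions that matter for reproducibility (all encoded below and frozen in
``feature_names()``): population (1/N) standard deviation; energy is the
mean square; sma carries an extra 1/N so it is window-length invariant;
entropy is Shannon entropy (natural log) of the |s|-normalized weights with
0 log 0 = 0; quartiles use linear interpolation; Burg coefficients use the
positive-AR-parameter sign convention without demeaning; correlation of a
constant channel is defined as 0; band energies average the squared one-sided
spectrum over 1-based inclusive bin ranges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg as _sm_burg

from .signals import SignalSet

__all__ = [
    "FeatureWindow",
    "StandardizationParams",
    "N_FEATURES",
    "make_windows",
    "feature_names",
    "extract_features",
    "extract_all",
    "fit_standardizer",
    "apply_standardizer",
]

N_FEATURES = 561

#: 1-based inclusive bin bands over the 64-bin one-sided spectrum:
#: eight 8-bin bands, four 16-bin bands, two 24-bin bands.
ENERGY_BANDS: tuple[tuple[int, int], ...] = (
    (1, 8), (9, 16), (17, 24), (25, 32), (33, 40), (41, 48), (49, 56), (57, 64),
    (1, 16), (17, 32), (33, 48), (49, 64),
    (1, 24), (25, 48),
)

_TIME_XYZ = ("body_acc", "gravity_acc", "body_acc_jerk", "body_gyro", "body_gyro_jerk")
_TIME_MAG = (
    "body_acc_mag",
    "gravity_acc_mag",
    "body_acc_jerk_mag",
    "body_gyro_mag",
    "body_gyro_jerk_mag",
)
_FREQ_XYZ = ("f_body_acc", "f_body_acc_jerk", "f_body_gyro")
_FREQ_MAG = ("f_body_acc_mag", "f_body_acc_jerk_mag", "f_body_gyro_mag", "f_body_gyro_jerk_mag")

#: Angle features: window-mean of each body XYZ signal against the
#: window-mean gravity vector, then the three unit axes against it.
_ANGLE_SIGNALS = ("body_acc", "body_acc_jerk", "body_gyro", "body_gyro_jerk")
_AXES = "xyz"


# ---------------------------------------------------------------------------
# windowing

def make_windows(length: int, window: int = 128, overlap: float = 0.5) -> list[int]:
    """Start indices of fully contained windows; trailing partials dropped."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = int(round(window * (1 - overlap)))
    if step <= 0:
        raise ValueError("overlap too large: step collapses to zero")
    return list(range(0, length - window + 1, step))


# ---------------------------------------------------------------------------
# feature functions (Table-2 bank); each takes 1-D window(s) of finite reals

def mean(s: np.ndarray) -> float:
    return float(np.mean(s))


def std(s: np.ndarray) -> float:
    """Population (1/N) standard deviation."""
    return float(np.std(s))


def mad(s: np.ndarray) -> float:
    """Median absolute deviation from the median."""
    return float(np.median(np.abs(s - np.median(s))))


def max_(s: np.ndarray) -> float:
    return float(np.max(s))


def min_(s: np.ndarray) -> float:
    return float(np.min(s))


def energy(s: np.ndarray) -> float:
    """Mean of squares."""
    return float(np.mean(np.square(s)))


def sma(s1: np.ndarray, s2: np.ndarray | None = None, s3: np.ndarray | None = None) -> float:
    """Signal magnitude area, normalized by both axis count and length.

    For a scalar (magnitude) signal pass only ``s1``.
    """
    if s2 is None:
        return float(np.mean(np.abs(s1)))
    return float((np.mean(np.abs(s1)) + np.mean(np.abs(s2)) + np.mean(np.abs(s3))) / 3.0)


def entropy(s: np.ndarray) -> float:
    """Shannon entropy (nats) of |s| normalized to a weight vector.

    All-zero windows have entropy 0 by the 0 log 0 = 0 convention.
    """
    a = np.abs(np.asarray(s, float))
    tot = a.sum()
    if tot == 0:
        return 0.0
    p = a / tot
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def iqr(s: np.ndarray) -> float:
    """Q3 - Q1 with linear-interpolation quantiles."""
    q3, q1 = np.percentile(s, [75, 25], method="linear")
    return float(q3 - q1)


def autoregression(s: np.ndarray, order: int = 4) -> np.ndarray:
    """Burg AR coefficients, positive-parameter convention, no demeaning.

    A zero-variance window yields all-zero coefficients.
    """
    s = np.asarray(s, float)
    if np.ptp(s) == 0:
        # constant windows (zero or not) make the Burg lattice degenerate
        return np.zeros(order)
    coeffs, _sigma2 = _sm_burg(s, order=order, demean=False)
    return np.asarray(coeffs, float)


def correlation(s1: np.ndarray, s2: np.ndarray) -> float:
    """Pearson correlation; defined as 0 when either channel is constant."""
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    if np.std(s1) == 0 or np.std(s2) == 0:
        return 0.0
    return float(np.corrcoef(s1, s2)[0, 1])


def angle(mean_vec: np.ndarray, v: np.ndarray) -> float:
    """Angle (radians, [0, pi]) between two 3-vectors via atan2(|uxv|, u.v).

    Zero-length input on either side gives 0.
    """
    u = np.asarray(mean_vec, float)
    v = np.asarray(v, float)
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        return 0.0
    return float(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))


def range_(s: np.ndarray) -> float:
    return float(np.max(s) - np.min(s))


def rms(s: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(s))))


def skewness(s: np.ndarray) -> float:
    """Third standardized moment (population); 0 for constant windows."""
    s = np.asarray(s, float)
    m = s.mean()
    m2 = np.mean((s - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((s - m) ** 3) / m2**1.5)


def kurtosis(s: np.ndarray) -> float:
    """Fourth moment over squared variance (non-excess); 0 for constants."""
    s = np.asarray(s, float)
    m = s.mean()
    m2 = np.mean((s - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((s - m) ** 4) / m2**2)


def max_freq_ind(s: np.ndarray) -> int:
    """0-based index of the largest spectral component (first on ties)."""
    return int(np.argmax(s))


def mean_freq(s: np.ndarray) -> float:
    """Weighted average of 1-based bin index, weights the spectrum itself."""
    s = np.asarray(s, float)
    tot = s.sum()
    if tot == 0:
        return 0.0
    i = np.arange(1, len(s) + 1)
    return float(np.sum(i * s) / tot)


def energy_band(s: np.ndarray, a: int, b: int) -> float:
    """Mean squared spectrum over the 1-based inclusive bin range [a, b]."""
    if not 1 <= a <= b <= len(s):
        raise ValueError(f"band [{a}, {b}] outside spectrum of length {len(s)}")
    return float(np.mean(np.square(s[a - 1 : b])))


# ---------------------------------------------------------------------------
# the frozen 561-name enumeration

def _xyz_time_names(sig: str) -> list[str]:
    names = []
    for fn in ("mean", "std", "mad", "max", "min"):
        names += [f"{sig}_{fn}_{ax}" for ax in _AXES]
    names.append(f"{sig}_sma")
    for fn in ("energy", "iqr", "entropy"):
        names += [f"{sig}_{fn}_{ax}" for ax in _AXES]
    for ax in _AXES:
        names += [f"{sig}_ar{k}_{ax}" for k in (1, 2, 3, 4)]
    names += [f"{sig}_corr_{p}" for p in ("xy", "xz", "yz")]
    return names


def _mag_time_names(sig: str) -> list[str]:
    return [f"{sig}_{fn}" for fn in
            ("mean", "std", "mad", "max", "min", "sma", "energy", "iqr", "entropy")] + [
        f"{sig}_ar{k}" for k in (1, 2, 3, 4)
    ]


def _xyz_freq_names(sig: str) -> list[str]:
    names = []
    for fn in ("mean", "std", "mad", "max", "min"):
        names += [f"{sig}_{fn}_{ax}" for ax in _AXES]
    names.append(f"{sig}_sma")
    for fn in ("energy", "iqr", "entropy", "max_freq_ind", "mean_freq",
               "skewness", "kurtosis"):
        names += [f"{sig}_{fn}_{ax}" for ax in _AXES]
    for ax in _AXES:
        names += [f"{sig}_bands_energy_{a}_{b}_{ax}" for a, b in ENERGY_BANDS]
    return names


def _mag_freq_names(sig: str) -> list[str]:
    return [f"{sig}_{fn}" for fn in
            ("mean", "std", "mad", "max", "min", "sma", "energy", "iqr",
             "entropy", "max_freq_ind", "mean_freq", "skewness", "kurtosis")]


def _angle_names() -> list[str]:
    names = [f"angle_{sig}_mean_gravity" for sig in _ANGLE_SIGNALS]
    names += [f"angle_{ax}_axis_gravity" for ax in _AXES]
    return names


_FEATURE_NAMES: list[str] | None = None


def feature_names() -> list[str]:
    """The frozen, ordered list of the 561 feature names."""
    global _FEATURE_NAMES
    if _FEATURE_NAMES is None:
        names: list[str] = []
        for sig in _TIME_XYZ:
            names += _xyz_time_names(sig)
        for sig in _TIME_MAG:
            names += _mag_time_names(sig)
        for sig in _FREQ_XYZ:
            names += _xyz_freq_names(sig)
        for sig in _FREQ_MAG:
            names += _mag_freq_names(sig)
        names += _angle_names()
        assert len(names) == N_FEATURES, len(names)
        _FEATURE_NAMES = names
    return list(_FEATURE_NAMES)


# ---------------------------------------------------------------------------
# extraction

@dataclass(frozen=True)
class FeatureWindow:
    """One window's 561-element feature vector plus provenance."""

    start_index: int
    features: np.ndarray
    label: str | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.shape != (N_FEATURES,):
            raise ValueError(
                f"feature vector must have length {N_FEATURES}, got {f.shape}"
            )
        object.__setattr__(self, "features", f)

    @property
    def feature_names(self) -> list[str]:
        return feature_names()


def _scalar_stats_time(w: np.ndarray) -> list[float]:
    return [mean(w), std(w), mad(w), max_(w), min_(w)]


def _xyz_time_features(seg: np.ndarray) -> list[float]:
    cols = [seg[:, 0], seg[:, 1], seg[:, 2]]
    out: list[float] = []
    for fn in (mean, std, mad, max_, min_):
        out += [fn(c) for c in cols]
    out.append(sma(*cols))
    for fn in (energy, iqr, entropy):
        out += [fn(c) for c in cols]
    for c in cols:
        out += list(autoregression(c))
    out += [correlation(cols[0], cols[1]), correlation(cols[0], cols[2]),
            correlation(cols[1], cols[2])]
    return out


def _mag_time_features(w: np.ndarray) -> list[float]:
    return (_scalar_stats_time(w)
            + [sma(w), energy(w), iqr(w), entropy(w)]
            + list(autoregression(w)))


def _xyz_freq_features(spec: np.ndarray) -> list[float]:
    cols = [spec[:, 0], spec[:, 1], spec[:, 2]]
    out: list[float] = []
    for fn in (mean, std, mad, max_, min_):
        out += [fn(c) for c in cols]
    out.append(sma(*cols))
    for fn in (energy, iqr, entropy, max_freq_ind, mean_freq, skewness, kurtosis):
        out += [float(fn(c)) for c in cols]
    for c in cols:
        out += [energy_band(c, a, b) for a, b in ENERGY_BANDS]
    return out


def _mag_freq_features(spec: np.ndarray) -> list[float]:
    return ([mean(spec), std(spec), mad(spec), max_(spec), min_(spec),
             sma(spec), energy(spec), iqr(spec), entropy(spec),
             float(max_freq_ind(spec)), mean_freq(spec), skewness(spec),
             kurtosis(spec)])


def _majority_label(labels: np.ndarray | None, start: int, window: int) -> str | None:
    if labels is None:
        return None
    seg = labels[start : start + window]
    counts = Counter(seg)
    best = max(counts.values())
    # ties broken by earliest occurrence within the window
    for lab in seg:
        if counts[lab] == best:
            return lab
    return None


def extract_features(
    signals: SignalSet, start: int, window: int = 128, subject: str | None = None
) -> FeatureWindow:
    """Compute the ordered 561-feature vector for one window.

    ``start`` must be one of the window starts the SignalSet was derived
    with, so the frequency-domain spectra line up with the time slice.
    """
    starts = signals.window_starts
    hits = np.nonzero(starts == start)[0]
    if len(hits) == 0:
        raise ValueError(
            f"start {start} is not on the window grid of this SignalSet"
        )
    widx = int(hits[0])

    out: list[float] = []
    for sig in _TIME_XYZ:
        out += _xyz_time_features(signals[sig].data[start : start + window])
    for sig in _TIME_MAG:
        out += _mag_time_features(signals[sig].data[start : start + window])
    for sig in _FREQ_XYZ:
        out += _xyz_freq_features(signals[sig].data[widx])
    for sig in _FREQ_MAG:
        out += _mag_freq_features(signals[sig].data[widx])

    grav_mean = signals["gravity_acc"].data[start : start + window].mean(axis=0)
    for sig in _ANGLE_SIGNALS:
        sig_mean = signals[sig].data[start : start + window].mean(axis=0)
        out.append(angle(sig_mean, grav_mean))
    for ax in range(3):
        unit = np.zeros(3)
        unit[ax] = 1.0
        out.append(angle(unit, grav_mean))

    vec = np.asarray(out, dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = feature_names()[int(np.nonzero(~np.isfinite(vec))[0][0])]
        raise ValueError(f"non-finite feature: {bad}")
    return FeatureWindow(
        start_index=start,
        features=vec,
        label=_majority_label(signals.labels, start, window),
        subject=subject,
    )


def extract_all(
    signals: SignalSet, window: int = 128, subject: str | None = None
) -> list[FeatureWindow]:
    """Feature vectors for every window on the SignalSet's grid."""
    return [
        extract_features(signals, int(s), window=window, subject=subject)
        for s in signals.window_starts
    ]


# ---------------------------------------------------------------------------
# standardization

@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature location/scale learned on training windows only.

    Degenerate (zero-variance) features get scale 1 and are listed in
    ``degenerate`` so downstream users can see them.
    """

    location: np.ndarray
    scale: np.ndarray
    degenerate: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, float)
        sc = np.asarray(self.scale, float)
        if loc.shape != sc.shape or loc.ndim != 1:
            raise ValueError("location and scale must be matching 1-D arrays")
        if np.any(sc <= 0):
            raise ValueError("scale must be strictly positive")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "scale", sc)


def fit_standardizer(train: list[FeatureWindow]) -> StandardizationParams:
    """Mean / population-std standardizer fit on the training set."""
    if len(train) < 2:
        raise ValueError("need at least 2 training windows to standardize")
    X = np.stack([w.features for w in train])
    loc = X.mean(axis=0)
    sc = X.std(axis=0)
    degenerate = tuple(int(i) for i in np.nonzero(sc == 0)[0])
    sc = np.where(sc == 0, 1.0, sc)
    return StandardizationParams(location=loc, scale=sc, degenerate=degenerate)


def apply_standardizer(
    params: StandardizationParams, window: FeatureWindow
) -> FeatureWindow:
    """Transform one window with frozen training-set parameters."""
    z = (window.features - params.location) / params.scale
    return FeatureWindow(
        start_index=window.start_index,
        features=z,
        label=window.label,
        subject=window.subject,
    )
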