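"""Time-frequency features from the discrete wavelet transform.

Each axis of a window is decomposed with a Daubechies-4 wavelet into five
detail bands and the level-5 approximation band (periodization boundary
mode, so coefficient counts halve per level and energy is conserved).
Twelve summary statistics per band x 6 bands x 3 axes give a 216-dimensional
feature vector regardless of window length.  Features are z-scored per
domain: source and target domains each use their own statistics, since
target features (but not labels) are available in unsupervised adaptation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InsufficientDataError
from .preprocess import LabelledWindow

WAVELET = "db4"
LEVELS = 5
#: Band order: detail levels 1..5 (finest to coarsest), then the level-5
#: approximation (scaling) band.
BANDS = ("d1", "d2", "d3", "d4", "d5", "a5")
STATS = (
    "mean",
    "rms",
    "mad",
    "sd",
    "min",
    "max",
    "median",
    "p25",
    "p75",
    "entropy",
    "zc",
    "mc",
)
AXES = ("x", "y", "z")
N_FEATURES = len(AXES) * len(BANDS) * len(STATS)  # 216


def dwt_bands(
    signal: np.ndarray, wavelet: str = WAVELET, levels: int = LEVELS
) -> list[np.ndarray]:
    """Decompose one axis into [d1, d2, d3, d4, d5, a5] coefficient arrays."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if signal.size < 2**levels:
        raise ValueError(
            f"signal of length {signal.size} too short for {levels} levels"
        )
    with warnings.catch_warnings():
        # 4-s windows (128 samples) sit one level past pywt's advisory
        # maximum for db4; the decomposition is still exact under
        # periodization and the band layout must match the 10-s pipeline.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(signal, wavelet, mode="periodization", level=levels)
    a5, details = coeffs[0], coeffs[1:]  # details are [d5, d4, d3, d2, d1]
    return list(reversed(details)) + [a5]


def _crossings(c: np.ndarray) -> int:
    return int(np.sum(c[:-1] * c[1:] < 0))


def band_stats(coeffs: np.ndarray) -> np.ndarray:
    """Twelve summary statistics of one coefficient band.

    Order: mean, RMS, mean absolute deviation, SD (population), min, max,
    median, 25th percentile, 75th percentile, energy entropy, zero
    crossings, mean crossings.  Entropy is the Shannon entropy of the
    normalized squared-coefficient distribution (0 for an all-zero band);
    crossings count strict sign changes between consecutive elements.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("coefficient array is empty")
    mean = float(np.mean(c))
    energy = c**2
    total = float(energy.sum())
    if total > 0:
        p = energy / total
        p = p[p > 0]
        entropy = float(-np.sum(p * np.log(p)))
    else:
        entropy = 0.0
    return np.array(
        [
            mean,
            float(np.sqrt(np.mean(energy))),
            float(np.mean(np.abs(c - mean))),
            float(np.std(c)),
            float(np.min(c)),
            float(np.max(c)),
            float(np.median(c)),
            float(np.percentile(c, 25)),
            float(np.percentile(c, 75)),
            entropy,
            float(_crossings(c)),
            float(_crossings(c - mean)),
        ]
    )


def extract_features(window: LabelledWindow | np.ndarray) -> np.ndarray:
    """216-dimensional feature vector of one triaxial window.

    Ordering is axis-major (x, y, z), then band (d1..d5, a5), then the 12
    statistics.
    """
    samples = window.samples if isinstance(window, LabelledWindow) else window
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("window samples must be (n, 3)")
    parts = []
    for axis in range(3):
        for band in dwt_bands(samples[:, axis]):
            parts.append(band_stats(band))
    vec = np.concatenate(parts)
    assert vec.size == N_FEATURES
    return vec


def feature_names() -> list[str]:
    """Column names matching :func:`extract_features`, e.g. ``x_d3_rms``."""
    return [f"{ax}_{band}_{stat}" for ax in AXES for band in BANDS for stat in STATS]


@dataclass
class DomainDataset:
    """Feature matrix of one (subject, sensor, scenario) domain.

    ``mean_`` / ``sd_`` hold the z-scoring statistics once
    :func:`standardize` has been applied.
    """

    X: np.ndarray
    y: Optional[np.ndarray] = None
    subject: str = ""
    sensor: str = ""
    scenario: str = ""
    mean_: Optional[np.ndarray] = None
    sd_: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError("label length must match the number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def windows_to_dataset(
    windows: Sequence[LabelledWindow],
    subject: str = "",
    sensor: str = "",
    scenario: str = "",
) -> DomainDataset:
    """Extract features from windows and assemble one labelled domain."""
    if not windows:
        raise InsufficientDataError("no windows to featurize")
    X = np.vstack([extract_features(w) for w in windows])
    y = np.array([w.label for w in windows])
    return DomainDataset(
        X=X,
        y=y,
        subject=subject or windows[0].subject,
        sensor=sensor or windows[0].sensor,
        scenario=scenario or windows[0].scenario,
    )


def standardize(domain: DomainDataset) -> DomainDataset:
    """Z-score each column with the domain's own statistics.

    Columns with vanishing spread (sd < 1e-12) are centered only; the
    transformation parameters are stored on the returned dataset.
    """
    if domain.n < 2:
        raise InsufficientDataError("need at least 2 rows to standardize")
    mean = domain.X.mean(axis=0)
    sd = domain.X.std(axis=0)
    scale = np.where(sd < 1e-12, 1.0, sd)
    return replace(domain, X=(domain.X - mean) / scale, mean_=mean, sd_=scale)


class WaveletFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer over stacks of triaxial windows.

    ``transform`` accepts a sequence of :class:`LabelledWindow` or an array
    of shape (n_windows, n_samples, 3) and returns (n_windows, 216).
    """

    def fit(self, X, y=None):  # noqa: D102 - stateless
        return self

    def transform(self, X) -> np.ndarray:  # noqa: D102
        return np.vstack([extract_features(w) for w in X])
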