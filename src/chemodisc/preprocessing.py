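"""Spectral preprocessing chain: smoothing, baseline, min-max, centering.

The chain applied before any multivariate step is, in order:

1. Savitzky-Golay smoothing (default second-order polynomial, 13-point
   window) -- removes high-frequency instrumental noise without distorting
   band shapes;
2. baseline correction (``linear_endpoints`` by default: subtract the chord
   through the first and last point, standard for ATR offset/tilt; ``offset``
   subtracts the minimum);
3. per-spectrum min-max normalization to [0, 1];
4. mean-centering of the resulting matrix.

Centering can be fitted on a training partition and re-applied to held-out
spectra (``fitted_means``) so supervised validation never sees test
statistics; exploratory runs center globally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectralDataset

__all__ = [
    "PreprocessConfig",
    "DegenerateSpectrumError",
    "savgol_smooth",
    "baseline_correct",
    "minmax_normalize",
    "mean_center",
    "preprocess_dataset",
]

_BASELINE_MODES = ("none", "linear_endpoints", "offset")
_NORMALIZE_MODES = ("minmax01", "none")
_CENTER_MODES = ("global_mean", "none")


class DegenerateSpectrumError(ValueError):
    """Raised for a constant spectrum (dead detector / blank) in min-max."""


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain; defaults are the standard run."""

    sg_window: int = 13
    sg_polyorder: int = 2
    baseline_mode: str = "linear_endpoints"
    normalize: str = "minmax01"
    center: str = "global_mean"

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError(
                f"sg_window must be odd and > polyorder, got {self.sg_window}/{self.sg_polyorder}"
            )
        if self.baseline_mode not in _BASELINE_MODES:
            raise ValueError(f"baseline_mode must be one of {_BASELINE_MODES}")
        if self.normalize not in _NORMALIZE_MODES:
            raise ValueError(f"normalize must be one of {_NORMALIZE_MODES}")
        if self.center not in _CENTER_MODES:
            raise ValueError(f"center must be one of {_CENTER_MODES}")

    @classmethod
    def none(cls) -> "PreprocessConfig":
        """Identity chain (smoothing disabled via window=3/order=1 is still a
        filter; this config skips every stage)."""
        cfg = cls(baseline_mode="none", normalize="none", center="none")
        cfg.sg_window = 0  # sentinel: skip smoothing
        return cfg


def savgol_smooth(spectrum: np.ndarray, window: int = 13, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing, length-preserving.

    Edges are handled by fitting the polynomial over the first/last full
    window and evaluating it at the edge positions (scipy ``mode="interp"``),
    so the output length equals the input length.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(f"window must be odd and > polyorder, got {window}/{polyorder}")
    if spectrum.shape[-1] < window:
        raise ValueError(
            f"spectrum length {spectrum.shape[-1]} shorter than window {window}"
        )
    return savgol_filter(spectrum, window_length=window, polyorder=polyorder, mode="interp")


def baseline_correct(spectrum: np.ndarray, axis: np.ndarray, mode: str = "linear_endpoints") -> np.ndarray:
    """Subtract a baseline model from one spectrum.

    ``offset`` subtracts the minimum; ``linear_endpoints`` subtracts the
    straight line through the first and last (axis, value) pair; ``none`` is
    the identity.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if mode == "none":
        return spectrum.copy()
    if mode == "offset":
        return spectrum - spectrum.min()
    if mode == "linear_endpoints":
        x0, x1 = axis[0], axis[-1]
        y0, y1 = spectrum[0], spectrum[-1]
        line = y0 + (axis - x0) / (x1 - x0) * (y1 - y0)
        return spectrum - line
    raise ValueError(f"unknown baseline mode {mode!r}")


def minmax_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale one spectrum to [0, 1]: ``(x - min) / (max - min)``."""
    spectrum = np.asarray(spectrum, dtype=float)
    lo, hi = spectrum.min(), spectrum.max()
    if hi == lo:
        raise DegenerateSpectrumError("constant spectrum cannot be min-max normalized")
    return (spectrum - lo) / (hi - lo)


def mean_center(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a matrix; returns the centered matrix and the means."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("mean centering needs at least 2 rows")
    means = matrix.mean(axis=0)
    return matrix - means, means


def preprocess_dataset(
    ds: SpectralDataset,
    cfg: PreprocessConfig | None = None,
    fitted_means: np.ndarray | None = None,
) -> tuple[SpectralDataset, np.ndarray | None]:
    """Apply the full chain to every row of a dataset.

    Per-spectrum stages (smoothing, baseline, normalization) are applied row
    by row; centering then uses ``fitted_means`` when provided (test-set
    application) or computes and returns the column means (training / global
    application).
    """
    cfg = cfg or PreprocessConfig()
    X = ds.intensities.copy()
    if cfg.sg_window:
        X = np.vstack([savgol_smooth(row, cfg.sg_window, cfg.sg_polyorder) for row in X])
    if cfg.baseline_mode != "none":
        X = np.vstack([baseline_correct(row, ds.axis, cfg.baseline_mode) for row in X])
    if cfg.normalize == "minmax01":
        X = np.vstack([minmax_normalize(row) for row in X])
    means = fitted_means
    if cfg.center == "global_mean":
        if fitted_means is not None:
            if len(fitted_means) != X.shape[1]:
                raise ValueError("fitted_means length does not match column count")
            X = X - np.asarray(fitted_means, dtype=float)
        else:
            X, means = mean_center(X)
    chain = {k: v for k, v in asdict(cfg).items()}
    out = ds.with_intensities(X, preprocess=chain)
    return out, (None if cfg.center != "global_mean" else np.asarray(means))
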