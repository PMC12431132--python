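"""Morlet continuous wavelet transform and scalogram rendering.

The CWT of a segment x is the family of inner products

    W(l, n) = sum_k x[k] * (1/sqrt(l)) * conj(psi((k - n) / l))

with the complex Morlet mother wavelet

    psi(t) = (pi*B)^(-1/2) * exp(2*pi*i*C*t) * exp(-t**2 / B),

B = 2 and center frequency C = 6/(2*pi) (the common omega0 = 6 Morlet).
Scales l are in samples; the pseudo-frequency of scale l at sampling
rate fs is C*fs/l.  The transform is evaluated exactly (up to a 6-sigma
truncation of the Gaussian envelope, relative error ~1e-8) by FFT-based
linear convolution, so it matches direct numerical evaluation of the sum
to machine precision.

Scalograms render |W| on a log scale, min-max normalized per image,
through a fixed colormap: time on the horizontal axis, frequency on the
vertical axis with low frequencies at the bottom, no axes burned in.
Native render size is 662x536; images are stored at 256x256 and resized
again to the 64x64 network input, both bicubic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.fft import fft, ifft, next_fast_len

MORLET_B = 2.0
MORLET_CENTER_FREQ = 6.0 / (2.0 * np.pi)  # cycles per unit time, omega0 = 6
_SUPPORT_SIGMA = 6.0  # Gaussian envelope truncation (std = 1 wavelet-time unit)

NATIVE_SIZE = (662, 536)  # (width, height)
STORE_SIZE = (256, 256)
MODEL_SIZE = (64, 64)
DEFAULT_N_SCALES = 64
DEFAULT_FREQ_RANGE = (0.5, 30.0)
DEFAULT_COLORMAP = "viridis"


def morlet(t: np.ndarray) -> np.ndarray:
    """The complex Morlet mother wavelet sampled at times ``t``."""
    t = np.asarray(t, float)
    return (np.pi * MORLET_B) ** -0.5 * np.exp(2j * np.pi * MORLET_CENTER_FREQ * t
                                               ) * np.exp(-(t**2) / MORLET_B)


def scale_to_frequency(scale: float | np.ndarray, sampling_rate: float) -> float | np.ndarray:
    """Pseudo-frequency (Hz) of a scale given in samples.

    f = C * fs / l: strictly decreasing in the scale; doubling the scale
    halves the frequency.
    """
    scale = np.asarray(scale, float)
    if np.any(scale <= 0):
        raise ValueError("scales must be positive")
    out = MORLET_CENTER_FREQ * sampling_rate / scale
    return float(out) if out.ndim == 0 else out


def frequency_to_scale(freq: float | np.ndarray, sampling_rate: float) -> float | np.ndarray:
    """Inverse of :func:`scale_to_frequency`."""
    freq = np.asarray(freq, float)
    if np.any(freq <= 0):
        raise ValueError("frequencies must be positive")
    out = MORLET_CENTER_FREQ * sampling_rate / freq
    return float(out) if out.ndim == 0 else out


def default_scales(
    sampling_rate: float,
    n_scales: int = DEFAULT_N_SCALES,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
) -> np.ndarray:
    """Geometric scale ladder spanning ``freq_range`` (high to low freq)."""
    fmin, fmax = freq_range
    freqs = np.geomspace(fmax, fmin, n_scales)
    return frequency_to_scale(freqs, sampling_rate)


@dataclass
class ScalogramGrid:
    """CWT coefficients on a scales x times grid."""

    coefficients: np.ndarray
    scales: np.ndarray
    sampling_rate: float
    wavelet: dict = field(default_factory=lambda: {
        "family": "morlet", "B": MORLET_B, "center_frequency": MORLET_CENTER_FREQ,
    })

    @property
    def pseudo_frequencies(self) -> np.ndarray:
        return scale_to_frequency(self.scales, self.sampling_rate)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coefficients)


_BANK_CACHE: dict[tuple, tuple[int, np.ndarray]] = {}


def _kernel_bank(scales: np.ndarray, n: int) -> tuple[int, np.ndarray]:
    """FFTs of the truncated, time-reversed conjugate wavelets.

    The FFT length pads past the widest kernel so the circular product
    equals linear convolution; banks are cached because transforming a
    segment stack reuses the same (scales, length) pair throughout.
    """
    key = (scales.tobytes(), n)
    if key in _BANK_CACHE:
        return _BANK_CACHE[key]
    halves = np.ceil(_SUPPORT_SIGMA * scales).astype(int)
    N = next_fast_len(n + 2 * int(halves.max()))
    K = np.empty((scales.size, N), dtype=complex)
    for i, (s, half) in enumerate(zip(scales, halves)):
        m = np.arange(-half, half + 1)
        kernel = (1.0 / np.sqrt(s)) * np.conj(morlet(-m / s))
        buf = np.zeros(N, dtype=complex)
        buf[: kernel.size] = kernel
        K[i] = fft(np.roll(buf, -half))
    if len(_BANK_CACHE) >= 4:
        _BANK_CACHE.pop(next(iter(_BANK_CACHE)))
    _BANK_CACHE[key] = (N, K)
    return N, K


def cwt_morlet(
    x: np.ndarray,
    scales: np.ndarray | list[float] | None = None,
    sampling_rate: float = 512.0,
) -> ScalogramGrid:
    """Morlet CWT of a 1-D segment at the given scales (in samples)."""
    x = np.asarray(x, float).ravel()
    if x.size == 0:
        raise ValueError("segment is empty")
    if scales is None:
        scales = default_scales(sampling_rate)
    scales = np.asarray(scales, float)
    if scales.size == 0:
        raise ValueError("scale list is empty")
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")

    n = x.size
    worst = int(np.ceil(_SUPPORT_SIGMA * scales.max()))
    if worst >= n:
        raise ValueError(
            f"scale {scales.max():.1f} has wavelet support ({2 * worst + 1} samples) "
            f"exceeding the {n}-sample segment"
        )
    N, K = _kernel_bank(scales, n)
    W = ifft(fft(x, N)[None, :] * K, axis=1)[:, :n]
    return ScalogramGrid(coefficients=W, scales=scales, sampling_rate=sampling_rate)


@dataclass
class ScalogramImage:
    """A rendered RGB scalogram with provenance."""

    pixels: np.ndarray  # (H, W, 3), float in [0, 1]
    source: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)


def _normalize_log_magnitude(mag: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization of log magnitude to [0, 1].

    The floor inside the log is proportional to the image maximum, so
    grids differing by a positive global factor normalize identically.
    Degenerate (constant) grids map to a flat 0.5.
    """
    peak = float(mag.max())
    if peak <= 0:
        return np.full(mag.shape, 0.5)
    logmag = np.log10(mag + 1e-6 * peak)
    lo, hi = float(logmag.min()), float(logmag.max())
    if hi - lo < 1e-12:
        return np.full(mag.shape, 0.5)
    return (logmag - lo) / (hi - lo)


def _block_mean_time(a: np.ndarray, max_cols: int) -> np.ndarray:
    """Average neighbouring time columns down to at most ``max_cols``."""
    n = a.shape[1]
    factor = int(np.ceil(n / max_cols))
    if factor <= 1:
        return a
    keep = (n // factor) * factor
    return a[:, :keep].reshape(a.shape[0], -1, factor).mean(axis=2)


def _bicubic(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bicubic resample of a 2-D map or an H x W x C image to (width, height)."""
    if arr.ndim == 2:
        return np.asarray(Image.fromarray(arr.astype(np.float32), mode="F")
                          .resize(size, Image.BICUBIC), dtype=np.float64)
    chans = [
        Image.fromarray(arr[..., c].astype(np.float32), mode="F").resize(size, Image.BICUBIC)
        for c in range(arr.shape[2])
    ]
    return np.stack([np.asarray(c, dtype=np.float64) for c in chans], axis=-1)


def render_scalogram(
    grid: ScalogramGrid,
    colormap: str = DEFAULT_COLORMAP,
    size: tuple[int, int] = NATIVE_SIZE,
    source: dict | None = None,
) -> ScalogramImage:
    """Render |W| as an RGB image of ``size`` = (width, height).

    Rows of the grid are ordered by increasing scale (decreasing
    frequency), which places low frequencies at the bottom of the image.
    Long grids are block-averaged along time before the bicubic resize
    (a pure speed optimization; the target raster is ~2 orders of
    magnitude coarser than a 30-s segment).
    """
    w, h = size
    if w <= 0 or h <= 0:
        raise ValueError("render size must be positive")
    norm = _normalize_log_magnitude(grid.magnitude)
    if norm.min() == norm.max():
        # degenerate grid: skip resampling so float32 jitter cannot
        # straddle a colormap quantization boundary
        norm = np.full((h, w), norm.flat[0])
    else:
        norm = _block_mean_time(norm, max_cols=4 * w)
        if norm.shape != (h, w):
            norm = _bicubic(norm, (w, h))
    norm = np.clip(norm, 0.0, 1.0)
    rgb = colormaps[colormap](norm)[..., :3]
    return ScalogramImage(
        pixels=rgb.astype(np.float64),
        source=dict(source or {}),
        render={
            "colormap": colormap,
            "size": size,
            "normalization": "per-image min-max of log10 magnitude",
            "wavelet": grid.wavelet,
        },
    )


def resize_image(img: ScalogramImage | np.ndarray, target: tuple[int, int]) -> ScalogramImage | np.ndarray:
    """Bicubic resize to ``target`` = (width, height), values clipped to [0, 1].

    Accepts and returns either a bare array or a :class:`ScalogramImage`.
    """
    w, h = target
    if w <= 0 or h <= 0:
        raise ValueError("target size must be positive")
    arr = img.pixels if isinstance(img, ScalogramImage) else np.asarray(img, float)
    out = np.clip(_bicubic(arr, (w, h)), 0.0, 1.0)
    if isinstance(img, ScalogramImage):
        render = dict(img.render)
        render["size"] = target
        return ScalogramImage(pixels=out, source=dict(img.source), render=render)
    return out


class ScalogramTransformer:
    """sklearn-style transformer: raw segments -> scalogram image stack.

    ``transform`` maps an (n_segments, n_samples) array to an image
    array.  With ``output='model'`` (default) images pass through the
    native render and the 256x256 storage resolution before a final
    bicubic resize to the 64x64 network input, returned as float32 in
    [0, 1]; ``output='store'`` stops at 256x256 and returns uint8.
    """

    def __init__(self, sampling_rate: float = 512.0, n_scales: int = DEFAULT_N_SCALES,
                 freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
                 colormap: str = DEFAULT_COLORMAP, output: str = "model"):
        self.sampling_rate = sampling_rate
        self.n_scales = n_scales
        self.freq_range = freq_range
        self.colormap = colormap
        self.output = output

    def fit(self, X=None, y=None):
        self.scales_ = default_scales(self.sampling_rate, self.n_scales, self.freq_range)
        return self

    def transform_one(self, x: np.ndarray, source: dict | None = None) -> np.ndarray:
        if not hasattr(self, "scales_"):
            self.fit()
        grid = cwt_morlet(x, self.scales_, self.sampling_rate)
        img = render_scalogram(grid, self.colormap, NATIVE_SIZE, source=source)
        img256 = resize_image(img, STORE_SIZE)
        if self.output == "store":
            return (img256.pixels * 255).round().astype(np.uint8)
        img64 = resize_image(img256, MODEL_SIZE)
        return img64.pixels.astype(np.float32)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return np.stack([self.transform_one(row) for row in X])

    def fit_transform(self, X, y=None):
        return self.fit().transform(X)

    def get_params(self, deep=True):
        return {"sampling_rate": self.sampling_rate, "n_scales": self.n_scales,
                "freq_range": self.freq_range, "colormap": self.colormap,
                "output": self.output}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
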