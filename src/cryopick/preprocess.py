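"""Micrograph denoising and contrast enhancement.

The chain, in fixed order: Gaussian blur -> z-score normalization ->
linear 8-bit grayscale mapping -> fast non-local means -> Wiener filter
-> CLAHE -> guided filter (guide = the CLAHE output, input = the Wiener
output), then conversion back to float and a final re-normalization.
Every stage can be toggled off independently, which is what makes the
raw-vs-denoised training comparison possible; with all toggles off the
input passes through untouched.

Filter parameters follow each filter's common conventions and are fully
exposed in :class:`DenoiseConfig`.  Note ``clahe_clip_limit`` is given in
percent of the per-tile histogram (2.0 means clipping at 2% of the tile
pixel count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import exposure, restoration

from cryopick.io import Micrograph

__all__ = [
    "DenoiseConfig",
    "denoise",
    "normalize_standard",
    "to_grayscale_uint",
    "guided_filter",
]


@dataclass
class DenoiseConfig:
    gaussian_sigma: float = 1.0
    nlmeans_strength: float = 10.0  # h, in 8-bit intensity units
    nlmeans_template_window: int = 7
    nlmeans_search_window: int = 21
    wiener_window: int = 5
    clahe_clip_limit: float = 2.0  # percent of tile histogram
    clahe_tile_grid: tuple[int, int] = (8, 8)
    guided_radius: int = 8
    guided_epsilon: float = 0.01
    use_gaussian: bool = True
    use_normalize: bool = True
    use_grayscale: bool = True
    use_nlmeans: bool = True
    use_wiener: bool = True
    use_clahe: bool = True
    use_guided: bool = True

    def __post_init__(self):
        for name in ("nlmeans_template_window", "nlmeans_search_window",
                     "wiener_window"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        if self.guided_radius < 1:
            raise ValueError("guided_radius must be >= 1")

    @classmethod
    def raw(cls) -> "DenoiseConfig":
        """All stages off: the identity configuration."""
        return cls(
            use_gaussian=False, use_normalize=False, use_grayscale=False,
            use_nlmeans=False, use_wiener=False, use_clahe=False,
            use_guided=False,
        )


def normalize_standard(pixels: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling; constant images are only centered."""
    x = np.asarray(pixels, dtype=np.float64)
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        return (x - mu).astype(np.float32)
    return ((x - mu) / sd).astype(np.float32)


def to_grayscale_uint(pixels: np.ndarray) -> np.ndarray:
    """Linear map of the intensity range onto 0..255 (uint8).

    The minimum maps to 0 and the maximum to 255 with round-half-even
    rounding; a constant image maps to all zeros.
    """
    x = np.asarray(pixels, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=np.uint8)
    scaled = (x - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def _box(x: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.uniform_filter(x, size=2 * radius + 1, mode="reflect")


def guided_filter(guide: np.ndarray, src: np.ndarray, radius: int,
                  eps: float) -> np.ndarray:
    """Edge-preserving guided filter (He et al. scheme) on float images."""
    I = np.asarray(guide, dtype=np.float64)
    p = np.asarray(src, dtype=np.float64)
    mean_i = _box(I, radius)
    mean_p = _box(p, radius)
    corr_ip = _box(I * p, radius)
    corr_ii = _box(I * I, radius)
    var_i = corr_ii - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p
    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    return (_box(a, radius) * I + _box(b, radius)).astype(np.float64)


def denoise(micrograph: Micrograph, config: DenoiseConfig | None = None) -> Micrograph:
    """Run the (toggle-able) denoising chain on one micrograph."""
    cfg = config or DenoiseConfig()
    x = micrograph.pixels
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{micrograph.name}: non-finite input pixels")
    h, w = x.shape
    needs_window = cfg.use_nlmeans or cfg.use_wiener or cfg.use_clahe or cfg.use_guided
    largest = max(
        cfg.nlmeans_search_window if cfg.use_nlmeans else 1,
        cfg.wiener_window if cfg.use_wiener else 1,
        2 * cfg.guided_radius + 1 if cfg.use_guided else 1,
    )
    if needs_window and min(h, w) < largest:
        raise ValueError(
            f"image {h}x{w} is smaller than the largest filter window "
            f"({largest}); denoising would be ill-defined"
        )

    out = x.astype(np.float64)
    if cfg.use_gaussian:
        out = ndimage.gaussian_filter(out, sigma=cfg.gaussian_sigma)
    if cfg.use_normalize:
        out = normalize_standard(out).astype(np.float64)

    eight_bit = False
    if cfg.use_grayscale:
        out = to_grayscale_uint(out).astype(np.float64)
        eight_bit = True

    if cfg.use_nlmeans:
        scale = out / 255.0 if eight_bit else out
        den = restoration.denoise_nl_means(
            scale.astype(np.float64),
            h=cfg.nlmeans_strength / 255.0,
            patch_size=cfg.nlmeans_template_window,
            patch_distance=(cfg.nlmeans_search_window - 1) // 2,
            fast_mode=True,
        )
        out = den * 255.0 if eight_bit else den

    wiener_out = out
    if cfg.use_wiener:
        with np.errstate(invalid="ignore", divide="ignore"):
            # zero local variance (flat regions) divides 0/0; map to 0
            wiener_out = signal.wiener(out,
                                       (cfg.wiener_window, cfg.wiener_window))
        wiener_out = np.nan_to_num(wiener_out, nan=0.0)
        out = wiener_out

    clahe_out = out
    if cfg.use_clahe:
        rows, cols = cfg.clahe_tile_grid
        span = out.max() - out.min()
        unit = (out - out.min()) / span if span > 0 else np.zeros_like(out)
        clahe_out = exposure.equalize_adapthist(
            unit,
            kernel_size=(max(h // rows, 1), max(w // cols, 1)),
            clip_limit=cfg.clahe_clip_limit / 100.0,
        )
        clahe_out = clahe_out * 255.0 if eight_bit else clahe_out
        out = clahe_out

    if cfg.use_guided:
        denom = 255.0 if eight_bit else max(abs(out).max(), 1e-12)
        out = guided_filter(
            clahe_out / denom, wiener_out / denom, cfg.guided_radius,
            cfg.guided_epsilon,
        ) * denom

    if cfg.use_normalize:
        out = normalize_standard(out).astype(np.float64)
    result = out.astype(np.float32)
    if not np.all(np.isfinite(result)):
        raise RuntimeError(f"{micrograph.name}: denoising produced non-finite values")
    return Micrograph(pixels=result, name=micrograph.name,
                      pixel_size=micrograph.pixel_size)
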