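"""Reference-channel spectral unmixing of chloroplast autofluorescence.

Chloroplast pigments emit broadly, so a red reference channel captures pure
autofluorescence while the reporter (green/yellow) channel captures
reporter + bleed-through.  Assuming a spatially uniform green-per-red ratio
F, the per-pixel model is

    G = F * R + k * CYC        =>        CYC = (G - F * R) / k

where G and R are the green and red signals, CYC the reporter amount in
arbitrary units, and k an arbitrary scale constant (default 1).  F is
estimated from the brightest-red pixels, which are presumed pure
chloroplast, and re-estimated for every frame so that lamp/exposure drift
cancels.  Negative residuals are preserved: clipping at zero would bias
totals upward.

Also provides the z-axis (0.5, 1, 0.5) blur followed by maximum projection
used to denoise grainy z-stacks before projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .movie_io import Movie


@dataclass
class UnmixingModel:
    """Per-frame bleed-through ratios and the scale constant used."""

    F_per_frame: np.ndarray
    top_fraction: float
    k: float = 1.0

    def __post_init__(self) -> None:
        self.F_per_frame = np.asarray(self.F_per_frame, dtype=float)
        if np.any(self.F_per_frame <= 0):
            raise ValueError("all per-frame F must be > 0")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.k <= 0:
            raise ValueError("k must be > 0")


def estimate_bleedthrough_ratio(
    green: np.ndarray,
    red: np.ndarray,
    top_fraction: float = 0.01,
    mask: np.ndarray | None = None,
    method: str = "mean_ratio",
    rank_sigma: float = 2.0,
) -> float:
    """Estimate the green-per-red bleed-through ratio F from one frame pair.

    Ranks pixels by red intensity (ties broken by raster order) and uses the
    top ``top_fraction`` as the pure-chloroplast set.  ``method`` is either
    ``"mean_ratio"`` (mean of per-pixel green/red ratios, the default) or
    ``"sum_ratio"`` (ratio of summed green to summed red over the set, which
    is less biased when the reference is noisy).

    Ranking uses a Gaussian-smoothed (sigma ``rank_sigma``) copy of the red
    image: picking the brightest *raw* pixels preferentially selects
    upward shot-noise excursions, which biases F low and leaves a spurious
    positive unmixing residual; smoothing only the ranking key removes that
    selection bias while the ratio itself stays per-pixel.  Set
    ``rank_sigma=0`` to rank on raw values.

    An optional boolean ``mask`` restricts the ranking to cell pixels.

    Raises
    ------
    ValueError
        If the images differ in shape, the red image has no positive pixel,
        or the selected top set contains zero-red pixels.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError(f"shape mismatch: {green.shape} vs {red.shape}")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    rank_key = red
    if rank_sigma > 0:
        rank_key = ndimage.gaussian_filter(red, sigma=rank_sigma)
    g = green.ravel()
    r = red.ravel()
    key = rank_key.ravel()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != red.shape:
            raise ValueError("mask shape mismatch")
        sel = mask.ravel()
        g, r, key = g[sel], r[sel], key[sel]
    if r.size == 0 or np.max(r) <= 0:
        raise ValueError("reference image has no positive pixel")
    n_top = max(1, int(np.ceil(top_fraction * r.size)))
    # stable sort on -key keeps raster order among ties
    order = np.argsort(-key, kind="stable")[:n_top]
    r_top = r[order]
    g_top = g[order]
    if np.any(r_top <= 0):
        raise ValueError("top red set contains non-positive pixels; "
                         "reduce top_fraction or supply a cell mask")
    if method == "mean_ratio":
        return float(np.mean(g_top / r_top))
    if method == "sum_ratio":
        return float(np.sum(g_top) / np.sum(r_top))
    raise ValueError(f"unknown method {method!r}")


def unmix_frame(
    green: np.ndarray, red: np.ndarray, F: float, k: float = 1.0
) -> np.ndarray:
    """Per-pixel reporter amount CYC = (G - F*R) / k, sign preserved."""
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError(f"shape mismatch: {green.shape} vs {red.shape}")
    if F <= 0 or k <= 0:
        raise ValueError("F and k must be > 0")
    return (green - F * red) / k


def unmix_movie(
    movie: Movie,
    top_fraction: float = 0.01,
    k: float = 1.0,
    mask: np.ndarray | None = None,
    method: str = "mean_ratio",
    rank_sigma: float = 2.0,
) -> tuple[Movie, UnmixingModel]:
    """Unmix the reporter channel of a whole movie, frame by frame.

    F is estimated independently for each frame (optionally within a cell
    ``mask``); the returned movie has the reporter channel replaced by the
    signed unmixing residual, other channels untouched.
    """
    if not movie.has_channel("reporter") or not movie.has_channel("reference"):
        raise ValueError("unmixing requires reporter and reference channels")
    g_idx = movie.channel_index("reporter")
    r_idx = movie.channel_index("reference")
    out = movie.data.astype(float).copy()
    Fs = np.empty(movie.n_frames)
    for i in range(movie.n_frames):
        green = movie.data[i, g_idx]
        red = movie.data[i, r_idx]
        F = estimate_bleedthrough_ratio(green, red, top_fraction, mask=mask,
                                        method=method, rank_sigma=rank_sigma)
        Fs[i] = F
        out[i, g_idx] = unmix_frame(green, red, F, k)
    unmixed = Movie(
        data=out,
        channel_names=list(movie.channel_names),
        frame_interval=movie.frame_interval,
        pixel_size=movie.pixel_size,
        z_spacing=movie.z_spacing,
        meta=movie.meta,
    )
    return unmixed, UnmixingModel(F_per_frame=Fs, top_fraction=top_fraction, k=k)


def z_blur_max_project(stack: np.ndarray) -> np.ndarray:
    """(0.5, 1, 0.5) blur along z, then pixelwise maximum projection.

    Each plane is replaced by ``0.5*I(n-1) + I(n) + 0.5*I(n+1)`` with the
    kernel truncated at the stack boundaries (missing neighbours omitted),
    then the maximum over planes is taken.  A single-plane stack is returned
    unchanged.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty sequence of z-planes")
    n = stack.shape[0]
    blurred = stack.copy()
    if n > 1:
        blurred[:-1] += 0.5 * stack[1:]
        blurred[1:] += 0.5 * stack[:-1]
    return blurred.max(axis=0)
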