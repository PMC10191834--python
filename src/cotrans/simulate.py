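"""Ground-truthed synthetic experiments for the co-expression pipeline.

Cells receive i.i.d. Poisson(lambda/k) genome counts per color (equimolar
mix).  Per-channel signal is ``m_c * brightness_c * LogNormal(0, sigma)``; the
measured integrated density adds ``roi_area * background_draw`` with the
background drawn per cell and channel from Normal(mean, sd) truncated at 0.
The measurement table reports the *configured* background mean (the
quantifier's estimate), so corrected values keep a residual background error
— exactly what threshold calibration has to absorb.

Optionally, cells can be rendered into a multi-channel image (uniform disks,
Gaussian PSF, optional shot noise) and re-quantified from a labeled mask,
closing the loop the real pipeline runs on confocal data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .quant import DEFAULT_CHANNELS, MEASUREMENT_COLUMNS

__all__ = [
    "SimulationConfig",
    "quantify_image",
    "render_image",
    "simulate_cells",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; noise defaults are generator choices."""

    lam: float
    n_cells: int
    seed: int
    k: int = 3
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    brightness: tuple[float, ...] | float = 500.0  # a.u. per genome, per channel
    noise_sigma: float = 0.25  # lognormal multiplicative expression noise
    background_mean: float = 10.0  # a.u. per pixel
    background_sd: float = 0.5
    roi_area_range: tuple[float, float] = (50.0, 120.0)  # pixel^2
    # image-mode options
    canvas_shape: tuple[int, int] = (512, 512)
    cell_radius_range: tuple[float, float] = (4.0, 7.0)
    psf_sigma: float = 1.0
    shot_noise: bool = False
    max_placement_tries: int = 200

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        channels = tuple(self.channels)[: self.k]
        if len(channels) < self.k:
            channels = channels + tuple(f"ch{i}" for i in range(len(channels), self.k))
        object.__setattr__(self, "channels", channels)
        b = self.brightness
        b = (float(b),) * self.k if np.isscalar(b) else tuple(float(x) for x in b)
        if len(b) != self.k or any(x <= 0 for x in b):
            raise ValueError("brightness must be positive, scalar or length k")
        object.__setattr__(self, "brightness", b)
        if self.noise_sigma < 0 or self.background_sd < 0 or self.background_mean < 0:
            raise ValueError("noise parameters must be >= 0")
        lo, hi = self.roi_area_range
        if not 0 < lo <= hi:
            raise ValueError("roi_area_range must be positive and ordered")


def simulate_cells(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ground-truth genome counts and a matching measurement table.

    Returns
    -------
    truth
        One row per cell: ``cell_id``, per-color genome counts ``m_<channel>``,
        boolean ``expr_<channel>`` flags (m >= 1), ``n_colors_true``, and the
        per-channel noisy signal intensities ``sig_<channel>`` used for both
        the table and image paths.
    measurements
        Long-format table with the standard measurement columns; the
        ``background_mean`` column carries the configured mean.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_cells, config.k

    m = rng.poisson(config.lam / k, size=(n, k))
    noise = rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=(n, k)) if config.noise_sigma > 0 else np.ones((n, k))
    signal = m * np.asarray(config.brightness) * noise

    roi_area = rng.uniform(*config.roi_area_range, size=n)
    bg = rng.normal(config.background_mean, config.background_sd, size=(n, k))
    np.clip(bg, 0.0, None, out=bg)
    integrated = signal + roi_area[:, None] * bg

    cell_ids = np.arange(1, n + 1)
    truth = pd.DataFrame({"cell_id": cell_ids})
    for j, ch in enumerate(config.channels):
        truth[f"m_{ch}"] = m[:, j]
    for j, ch in enumerate(config.channels):
        truth[f"expr_{ch}"] = m[:, j] >= 1
    truth["n_colors_true"] = (m >= 1).sum(axis=1)
    for j, ch in enumerate(config.channels):
        truth[f"sig_{ch}"] = signal[:, j]

    measurements = pd.DataFrame(
        {
            "cell_id": np.repeat(cell_ids, k),
            "channel": np.tile(np.asarray(config.channels, dtype=object), n),
            "integrated_density": integrated.ravel(),
            "roi_area": np.repeat(roi_area, k),
            "background_mean": config.background_mean,
        },
        columns=MEASUREMENT_COLUMNS,
    )
    return truth, measurements


def _place_cells(rng: np.random.Generator, n: int, shape: tuple[int, int], r_range: tuple[float, float], max_tries: int):
    """Rejection-sample non-overlapping disk centers; bounded retries per cell."""
    h, w = shape
    ys = np.empty(n)
    xs = np.empty(n)
    rs = np.empty(n)
    for i in range(n):
        for _ in range(max_tries):
            r = rng.uniform(*r_range)
            y = rng.uniform(r, h - r)
            x = rng.uniform(r, w - r)
            if i == 0 or np.all((ys[:i] - y) ** 2 + (xs[:i] - x) ** 2 > (rs[:i] + r) ** 2):
                ys[i], xs[i], rs[i] = y, x, r
                break
        else:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n} after {max_tries} tries; use a larger canvas"
            )
    return ys, xs, rs


def render_image(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render ground-truth cells as uniform disks into a multi-channel image.

    Each cell's per-channel total intensity (``sig_<channel>`` from
    :func:`simulate_cells`) is spread uniformly over its disk, convolved with
    a Gaussian PSF, and added to a background field; an optional Poisson shot
    noise stage follows.  Returns ``(image, mask, placed_truth)`` where image
    is float (k, H, W), mask is uint16 labeled by cell_id (0 = background),
    and placed_truth is truth plus ``y, x, radius`` columns.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC311]))
    n = len(truth)
    h, w = config.canvas_shape
    ys, xs, rs = _place_cells(rng, n, (h, w), config.cell_radius_range, config.max_placement_tries)

    sig_cols = [f"sig_{ch}" for ch in config.channels]
    signal = truth[sig_cols].to_numpy(dtype=float)

    image = np.zeros((config.k, h, w), dtype=float)
    mask = np.zeros((h, w), dtype=np.uint16)
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(n):
        disk = (yy - ys[i]) ** 2 + (xx - xs[i]) ** 2 <= rs[i] ** 2
        area = disk.sum()
        if area == 0:
            raise RuntimeError("degenerate cell disk with zero pixels")
        mask[disk] = int(truth["cell_id"].iloc[i])
        image[:, disk] += signal[i][:, None] / area

    if config.psf_sigma > 0:
        for c in range(config.k):
            image[c] = ndimage.gaussian_filter(image[c], config.psf_sigma, mode="constant")

    if config.background_mean > 0 or config.background_sd > 0:
        bg = rng.normal(config.background_mean, config.background_sd, size=image.shape)
        image += np.clip(bg, 0.0, None)
    if config.shot_noise:
        image = rng.poisson(np.clip(image, 0.0, None)).astype(float)

    placed = truth.copy()
    placed["y"], placed["x"], placed["radius"] = ys, xs, rs
    return image, mask, placed


def quantify_image(
    image: np.ndarray, mask: np.ndarray, channels: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per-cell, per-channel measurements from a labeled mask.

    integrated_density = pixel sum over the cell's mask; roi_area = pixel
    count; background_mean = per-channel mean over mask-zero pixels.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.ndim != 3:
        raise ValueError("image must be (channels, H, W)")
    if mask.shape != image.shape[1:]:
        raise ValueError(f"mask shape {mask.shape} does not match image {image.shape[1:]}")
    k = image.shape[0]
    if channels is None:
        channels = DEFAULT_CHANNELS[:k] if k <= len(DEFAULT_CHANNELS) else tuple(f"ch{i}" for i in range(k))
    if len(channels) != k:
        raise ValueError("need one channel name per image plane")

    bg_pixels = mask == 0
    if not bg_pixels.any():
        raise ValueError("no background pixels: mask covers the whole canvas")
    bg_means = image[:, bg_pixels].mean(axis=1)

    labels = np.unique(mask)
    labels = labels[labels != 0]
    rows = []
    for cell_id in labels:
        cell_pixels = mask == cell_id
        area = int(cell_pixels.sum())
        for c, ch in enumerate(channels):
            rows.append(
                {
                    "cell_id": int(cell_id),
                    "channel": ch,
                    "integrated_density": float(image[c, cell_pixels].sum()),
                    "roi_area": float(area),
                    "background_mean": float(bg_means[c]),
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
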