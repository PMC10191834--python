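"""Ternary projection and bounded-support density estimation of color mixtures."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

__all__ = [
    "DensityCurve",
    "density_estimate",
    "plot_density",
    "plot_ternary",
    "ternary_coordinates",
]

_SQRT3 = np.sqrt(3.0)
#: Reference triangle: vertices for fractions (a, b, c) = (1,0,0), (0,1,0), (0,0,1).
TRIANGLE_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, _SQRT3 / 2]])


def ternary_coordinates(fractions: Sequence[float]) -> tuple[float, float]:
    """Barycentric embedding of fractions (a, b, c) into the reference triangle.

    x = b + c/2, y = (sqrt(3)/2) * c.  Bijective on the simplex: vertex a at
    the origin, b at (1, 0), c at (1/2, sqrt(3)/2).
    """
    f = np.asarray(fractions, dtype=float)
    if f.shape != (3,):
        raise ValueError("ternary coordinates need exactly 3 fractions")
    if np.any(f < -1e-9) or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions must be non-negative and sum to 1, got {f}")
    a, b, c = f
    return (b + c / 2.0, (_SQRT3 / 2.0) * c)


@dataclass(frozen=True)
class DensityCurve:
    """Kernel density of mixture percentages on [0, 100]."""

    grid: np.ndarray
    density: np.ndarray
    channel: str = ""
    bandwidth: float = float("nan")

    @property
    def mode(self) -> float:
        """Grid location of the density maximum."""
        return float(self.grid[int(np.argmax(self.density))])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def density_estimate(
    percentages: Sequence[float],
    bandwidth: float | str = "scott",
    channel: str = "",
    grid_size: int = 512,
) -> DensityCurve:
    """Gaussian KDE on [0, 100] with boundary reflection at both edges.

    Mass that a plain Gaussian kernel would leak past 0 or 100 is folded back
    by evaluating the unbounded KDE at x, -x and 200 - x, which keeps the
    curve mass-conserving on the support.
    """
    values = np.asarray(percentages, dtype=float)
    if values.size < 2:
        raise ValueError("density estimation needs at least 2 values")
    if np.any((values < 0) | (values > 100)):
        raise ValueError("percentages must lie in [0, 100]")

    if np.ptp(values) == 0:
        # degenerate sample: gaussian_kde cannot factor a singular covariance;
        # fall back to a narrow fixed-width kernel around the common value
        width = 1.0 if bandwidth == "scott" or bandwidth == "silverman" else float(bandwidth)
        kde = lambda x: stats.norm.pdf(x, loc=values[0], scale=width)  # noqa: E731
        bw = width
    else:
        kde_obj = stats.gaussian_kde(values, bw_method=bandwidth)
        kde = kde_obj
        bw = float(np.sqrt(kde_obj.covariance[0, 0]))

    grid = np.linspace(0.0, 100.0, grid_size)
    density = np.asarray(kde(grid)) + np.asarray(kde(-grid)) + np.asarray(kde(200.0 - grid))
    curve = DensityCurve(grid=grid, density=density, channel=channel, bandwidth=bw)
    # renormalize residual truncation error (kernels wider than the support)
    integral = curve.integral()
    if not 0.9 < integral < 1.1:
        density = density / integral
        curve = DensityCurve(grid=grid, density=density, channel=channel, bandwidth=bw)
    return curve


def plot_ternary(
    points: Sequence[Sequence[float]],
    path: str,
    labels: Sequence[str] = ("EGFP", "mCherry", "mTurq2"),
    **scatter_kwargs,
) -> None:
    """Scatter mixture fractions inside the reference triangle and save."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("no points to plot")
    xy = np.array([ternary_coordinates(p) for p in points])

    fig, ax = plt.subplots(figsize=(5, 4.6))
    tri = np.vstack([TRIANGLE_VERTICES, TRIANGLE_VERTICES[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    kwargs = {"s": 6, "color": "tab:blue", "alpha": 0.5, "linewidths": 0}
    kwargs.update(scatter_kwargs)
    ax.scatter(xy[:, 0], xy[:, 1], **kwargs)
    offsets = [(-0.03, -0.04), (0.03, -0.04), (0.0, 0.03)]
    for (vx, vy), label, (dx, dy) in zip(TRIANGLE_VERTICES, labels, offsets):
        ax.annotate(label, (vx + dx, vy + dy), ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_density(curves: Sequence[DensityCurve], path: str) -> None:
    """Overlay percentage density curves and save."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to plot")
    fig, ax = plt.subplots(figsize=(5.5, 3.8))
    for curve in curves:
        ax.plot(curve.grid, curve.density, label=curve.channel or None)
    ax.set_xlabel("color mixture percentage (%)")
    ax.set_ylabel("probability density")
    ax.set_xlim(0, 100)
    if any(c.channel for c in curves):
        ax.legend(frameon=False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
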