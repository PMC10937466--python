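"""Plot outputs: channel overlays, distortion quiver maps, coloc maps, box plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .image import Image2D
from .registration import DistortionField


def _norm(px: np.ndarray) -> np.ndarray:
    lo, hi = px.min(), px.max()
    return (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)


def save_overlay(fixed: Image2D, moving: Image2D, path) -> None:
    """Magenta (fixed/post) over green (moving/pre) composite."""
    rgb = np.zeros((*fixed.shape, 3))
    rgb[..., 0] = _norm(fixed.pixels)
    rgb[..., 2] = _norm(fixed.pixels)
    rgb[..., 1] = _norm(moving.pixels)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_quiver(field: DistortionField, path, scale: float | None = None) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    gp, dv = field.grid_points, field.displacement_vectors
    ax.quiver(gp[:, 0], gp[:, 1], dv[:, 0], dv[:, 1], color="red",
              angles="xy", scale_units="xy", scale=scale)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    s = field.summary
    ax.set_title(f"distortion mean {s['mean_px']:.2f} px, max {s['max_px']:.2f} px",
                 fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_coloc_map(a: Image2D, b: Image2D, overlap: np.ndarray, path) -> None:
    """Two channels in green/magenta with the overlap mask in red."""
    rgb = np.zeros((*a.shape, 3))
    rgb[..., 1] = _norm(a.pixels)
    rgb[..., 0] = _norm(b.pixels) * 0.7
    rgb[..., 2] = _norm(b.pixels) * 0.7
    rgb[overlap] = [1.0, 0.0, 0.0]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_group_boxplot(groups: dict[str, list[float]], path, ylabel: str = "PCC") -> None:
    """Box plots with median and 25/75% boxes; whiskers span the full range of
    the retained data points, individual synapses overplotted as dots."""
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1.5, 4))
    labels = list(groups)
    data = [np.asarray(groups[k], float) for k in labels]
    ax.boxplot(data, tick_labels=labels, whis=(0, 100), showfliers=False)
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.08, 0.08, len(vals)), vals, "k.", ms=4, alpha=0.6)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
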