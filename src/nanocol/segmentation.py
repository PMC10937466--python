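"""Synaptic ROI detection: Otsu threshold, connected components, shape rules.

The selection procedure mirrors the study protocol: Otsu-binarize the channel,
label connected regions, sort by area, and accept the synapse if the largest
region has area >= 300 px and major/minor axis ratio >= 2; if it fails, retry on
the union of the three largest clusters; if that still fails, discard. A QC
plot of the evaluated region(s) can be written for manual review of every
decision.

Shape descriptors come from the second central moments of the binary pixel set
(the normalized-second-moment ellipse, axis length = 4*sqrt(eigenvalue));
orientation is the major-axis angle versus the +x (column) axis, measured
counter-clockwise in (x = col, y = row) coordinates, in (-pi/2, pi/2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .image import Image2D

__all__ = [
    "RegionShape",
    "LabeledRegions",
    "SynapseCandidate",
    "otsu_threshold",
    "label_and_sort",
    "merge_top_clusters",
    "select_synapse",
    "shape_from_mask",
]

#: selection thresholds of the analysis protocol
MIN_AREA_PX = 300
MIN_AXIS_RATIO = 2.0


@dataclass
class RegionShape:
    """Moment-derived descriptors of one labeled pixel set."""

    area_px: int
    centroid: tuple[float, float]               # (x, y) px
    orientation: float                          # rad in (-pi/2, pi/2], vs +x axis
    major_axis_px: float
    minor_axis_px: float
    bounding_box: tuple[int, int, int, int]     # (row_min, col_min, row_max, col_max), half-open

    @property
    def axis_ratio(self) -> float:
        if self.minor_axis_px == 0:
            return np.inf
        return self.major_axis_px / self.minor_axis_px


@dataclass
class LabeledRegions:
    """Connected regions of a thresholded image, largest first."""

    label_map: np.ndarray                       # H×W ints, 0 = background
    regions: list[RegionShape]
    source_threshold: float

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class SynapseCandidate:
    """Outcome of the selection rule for one channel."""

    channel_name: str
    accepted: bool
    stage: str                                  # primary_region | merged_region | discarded
    shape: RegionShape | None
    qc_plot_path: str | None = None
    note: str = ""


def shape_from_mask(mask: np.ndarray) -> RegionShape:
    """Second-central-moment shape of the True pixels of ``mask``.

    Works identically for a single connected region and for a union of
    clusters, which is what the merge fallback needs.
    """
    rows, cols = np.nonzero(mask)
    n = rows.size
    if n == 0:
        raise ValueError("empty mask")
    x = cols.astype(float)
    y = rows.astype(float)
    cx, cy = x.mean(), y.mean()
    mu20 = np.mean((x - cx) ** 2)
    mu02 = np.mean((y - cy) ** 2)
    mu11 = np.mean((x - cx) * (y - cy))
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    eig = np.sort(np.linalg.eigvalsh(cov))      # ascending
    major = 4.0 * np.sqrt(max(eig[1], 0.0))
    minor = 4.0 * np.sqrt(max(eig[0], 0.0))
    if theta <= -np.pi / 2:
        theta += np.pi
    return RegionShape(
        area_px=int(n),
        centroid=(cx, cy),
        orientation=float(theta),
        major_axis_px=float(major),
        minor_axis_px=float(minor),
        bounding_box=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
    )


def otsu_threshold(image: Image2D) -> float:
    """Otsu's threshold over a 256-bin histogram; foreground is ``pixels > t``."""
    px = image.pixels
    if np.ptp(px) == 0:
        raise ValueError("degenerate histogram: image is constant")
    return float(threshold_otsu(px, nbins=256))


def label_and_sort(image: Image2D, threshold: float, connectivity: int = 2) -> LabeledRegions:
    """Label connected foreground (8-connectivity by default), sort by area.

    Labels in the returned map are renumbered 1..K in descending area order; an
    empty foreground yields an empty region list.
    """
    mask = image.pixels > threshold
    raw = sk_label(mask, connectivity=connectivity)
    k = raw.max()
    if k == 0:
        return LabeledRegions(raw, [], float(threshold))
    areas = np.bincount(raw.ravel())[1:]
    order = np.argsort(-areas, kind="stable") + 1
    remap = np.zeros(k + 1, dtype=raw.dtype)
    remap[order] = np.arange(1, k + 1)
    label_map = remap[raw]
    regions = [shape_from_mask(label_map == i) for i in range(1, k + 1)]
    return LabeledRegions(label_map, regions, float(threshold))


def merge_top_clusters(regions: LabeledRegions, k: int = 3) -> RegionShape:
    """Shape of the pixel-set union of the ``min(k, K)`` largest regions."""
    if len(regions) == 0:
        raise ValueError("no regions to merge")
    kk = min(k, len(regions))
    mask = (regions.label_map >= 1) & (regions.label_map <= kk)
    return shape_from_mask(mask)


def _passes(shape: RegionShape, min_area: int, min_axis_ratio: float) -> bool:
    return shape.area_px >= min_area and shape.axis_ratio >= min_axis_ratio


def select_synapse(
    regions: LabeledRegions,
    min_area: int = MIN_AREA_PX,
    min_axis_ratio: float = MIN_AXIS_RATIO,
    channel_name: str = "",
    qc_plot_path: str | None = None,
) -> SynapseCandidate:
    """Apply the two-stage selection rule to the labeled regions of a channel.

    Stage 1 evaluates the largest region; on failure stage 2 re-evaluates the
    union of the three largest clusters; if both fail the synapse is discarded.
    When ``qc_plot_path`` is given, a plot of the evaluated region(s) is saved
    so the decision can be verified by eye.
    """
    if len(regions) == 0:
        cand = SynapseCandidate(channel_name, False, "discarded", None,
                                qc_plot_path, note="no foreground")
        if qc_plot_path:
            _write_qc_plot(regions, cand, qc_plot_path)
        return cand

    primary = regions.regions[0]
    if _passes(primary, min_area, min_axis_ratio):
        cand = SynapseCandidate(channel_name, True, "primary_region", primary, qc_plot_path)
    else:
        merged = merge_top_clusters(regions, 3)
        if _passes(merged, min_area, min_axis_ratio):
            cand = SynapseCandidate(channel_name, True, "merged_region", merged, qc_plot_path)
        else:
            cand = SynapseCandidate(
                channel_name, False, "discarded", merged, qc_plot_path,
                note=f"area={merged.area_px}px axis_ratio={merged.axis_ratio:.2f} "
                     f"(need >={min_area}px and >={min_axis_ratio})",
            )
    if qc_plot_path:
        _write_qc_plot(regions, cand, qc_plot_path)
    return cand


def _write_qc_plot(regions: LabeledRegions, cand: SynapseCandidate, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(regions.label_map, cmap="tab10", interpolation="nearest")
    title = f"{cand.channel_name}: {cand.stage}"
    if cand.shape is not None:
        s = cand.shape
        title += f"\narea={s.area_px}px ratio={s.axis_ratio:.2f} theta={np.degrees(s.orientation):.1f}deg"
        r0, c0, r1, c1 = s.bounding_box
        ax.add_patch(plt.Rectangle((c0 - 0.5, r0 - 0.5), c1 - c0, r1 - r0,
                                   fill=False, edgecolor="red"))
    ax.set_title(title, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
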