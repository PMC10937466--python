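"""Alignment and colocalization statistics, scale conversions, group summaries.

Contains the Pearson cross-correlation used to score nanocolumn alignment, the
orientation-shift cosine check (a trans-synaptic shift is perpendicular to the
synapse axis, so the cosine should be near zero), the colocalization map of a
trans-synaptic channel, expansion-factor arithmetic, the 1.5-SD outlier rule of
the group box plots, and the Shapiro-Wilk-validated two-sample t-test used to
compare groups of per-synapse PCCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image import Image2D
from .segmentation import label_and_sort, otsu_threshold

__all__ = [
    "GroupSummary",
    "ExpansionEstimate",
    "OrientationShift",
    "GroupComparison",
    "pearson_cc",
    "orientation_shift_cosine",
    "coloc_map",
    "macroscopic_expansion_factor",
    "to_biological_scale",
    "summarize_group",
    "compare_groups",
]


@dataclass
class GroupSummary:
    """Summary of one group of per-synapse values after 1.5-SD outlier exclusion."""

    n_total: int
    n_used: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    min: float
    max: float
    excluded_indices: list[int] = field(default_factory=list)


@dataclass
class ExpansionEstimate:
    """A linear expansion factor, macroscopic (gel diameters) or structural
    (image-registration scale)."""

    factor: float
    method: str                                  # "macroscopic" | "structural"
    pcc_similarity: float | None = None
    pcc_affine: float | None = None
    distortion_summary: dict | None = None

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"expansion factor must be positive, got {self.factor}")


@dataclass
class OrientationShift:
    """Cosine between the synapse major axis and the alignment shift vector."""

    cosine: float
    trans_synaptic_consistent: bool
    note: str = ""


@dataclass
class GroupComparison:
    normal_a: bool
    normal_b: bool
    shapiro_p_a: float
    shapiro_p_b: float
    test: str                                    # "t-test" | "mann-whitney"
    statistic: float
    p_value: float


def _as_array(a) -> np.ndarray:
    return a.pixels if isinstance(a, Image2D) else np.asarray(a, dtype=float)


def pearson_cc(a, b, mask=None) -> float:
    """Pearson correlation of two channels over the masked pixels.

    ``a``/``b`` may be :class:`Image2D` or arrays of one shape; ``mask`` (bool,
    same shape; default all pixels) selects the region -- typically the synaptic
    ROI. Raises on fewer than two masked pixels or a zero-variance channel.
    """
    av, bv = _as_array(a), _as_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        av, bv = av[mask], bv[mask]
    else:
        av, bv = av.ravel(), bv.ravel()
    if av.size < 2:
        raise ValueError("mask must cover at least 2 pixels")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("zero variance: a channel is constant within the mask")
    am, bm = av - av.mean(), bv - bv.mean()
    return float(am @ bm / np.sqrt((am @ am) * (bm @ bm)))


def orientation_shift_cosine(orientation: float, shift, threshold: float = 0.3) -> OrientationShift:
    """Cosine between the unit major-axis vector (cos t, sin t) and the shift.

    A magnitude below ``threshold`` flags the shift as trans-synaptic-consistent
    (pointing across the cleft rather than along the synapse). A zero shift is
    reported as cosine 0 with a "no shift" note.
    """
    dx, dy = float(shift[0]), float(shift[1])
    norm = np.hypot(dx, dy)
    if norm == 0:
        return OrientationShift(0.0, True, note="no shift")
    axis = np.array([np.cos(orientation), np.sin(orientation)])
    cos = float(axis @ np.array([dx, dy]) / norm)
    return OrientationShift(cos, abs(cos) < threshold)


def coloc_map(a: Image2D, b: Image2D, anchor: str = "a") -> tuple[np.ndarray, float]:
    """Colocalization of two unmoved channels: overlap mask and Pearson value.

    The binary map is the pixelwise AND of the per-channel Otsu masks; the PCC
    is computed over the bounding box of the anchor channel's largest region so
    the anchor (the trans-synaptic signal in the study design) fixes a stable
    ROI and orientation. No alignment transform is applied.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("channels must share one shape")
    mask_a = a.pixels > otsu_threshold(a)
    mask_b = b.pixels > otsu_threshold(b)
    overlap = mask_a & mask_b

    anchor_img = a if anchor == "a" else b
    regions = label_and_sort(anchor_img, otsu_threshold(anchor_img))
    if len(regions) == 0:
        raise ValueError("anchor channel has no foreground")
    r0, c0, r1, c1 = regions.regions[0].bounding_box
    roi = np.zeros(a.pixels.shape, dtype=bool)
    roi[r0:r1, c0:c1] = True
    try:
        pcc = pearson_cc(a, b, roi)
    except ValueError:
        pcc = float("nan")    # a channel is flat inside the anchor ROI
    return overlap, pcc


def macroscopic_expansion_factor(pre_diameter: float, post_diameter: float) -> ExpansionEstimate:
    """Gel-diameter ratio, e.g. 12 mm before and ~10 cm after expansion -> ~8.3x."""
    if not (pre_diameter > 0 and post_diameter > 0):
        raise ValueError("gel diameters must be positive")
    return ExpansionEstimate(factor=post_diameter / pre_diameter, method="macroscopic")


def to_biological_scale(distance_expanded: float, factor: float) -> float:
    """Convert a distance measured in expanded dimensions back to biological nm
    (e.g. a ~318 nm expanded cleft at 8x is ~40 nm in the non-expanded state)."""
    if not factor > 0:
        raise ValueError(f"expansion factor must be positive, got {factor}")
    return distance_expanded / factor


def summarize_group(values) -> GroupSummary:
    """Box-plot summary with single-pass 1.5-SD outlier exclusion.

    Values with |v - mean| > 1.5 * sd (mean and sample sd over the full group,
    computed once) are excluded; the summary statistics and quartiles (linear
    interpolation) describe the survivors.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"need at least 3 values, got {v.size}")
    mean0 = v.mean()
    sd0 = v.std(ddof=1)
    excluded = np.nonzero(np.abs(v - mean0) > 1.5 * sd0)[0]
    keep = np.delete(v, excluded)
    return GroupSummary(
        n_total=int(v.size),
        n_used=int(keep.size),
        mean=float(keep.mean()),
        sd=float(keep.std(ddof=1)) if keep.size > 1 else 0.0,
        median=float(np.median(keep)),
        q25=float(np.percentile(keep, 25)),
        q75=float(np.percentile(keep, 75)),
        min=float(keep.min()),
        max=float(keep.max()),
        excluded_indices=excluded.tolist(),
    )


def compare_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Two-sample comparison of per-synapse values between conditions.

    Each group is first checked for normality with Shapiro-Wilk (alpha 0.05).
    If both pass, a two-sided pooled-variance two-sample t-test is applied; if
    either fails, a Mann-Whitney U test is reported instead and flagged via the
    ``test`` field.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 3 or bv.size < 3:
        raise ValueError("each group needs at least 3 values")
    if av.std() == 0 and bv.std() == 0 and av.mean() == bv.mean():
        return GroupComparison(True, True, 1.0, 1.0, "t-test", 0.0, 1.0)
    pa = float(stats.shapiro(av).pvalue) if av.std() > 0 else 0.0
    pb = float(stats.shapiro(bv).pvalue) if bv.std() > 0 else 0.0
    normal_a, normal_b = pa >= alpha, pb >= alpha
    if normal_a and normal_b:
        res = stats.ttest_ind(av, bv, equal_var=True)
        return GroupComparison(normal_a, normal_b, pa, pb, "t-test",
                               float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(av, bv, alternative="two-sided")
    return GroupComparison(normal_a, normal_b, pa, pb, "mann-whitney",
                           float(res.statistic), float(res.pvalue))
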