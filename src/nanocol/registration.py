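"""Image registration: constrained affine pre/post-synapse alignment and
similarity + full-affine alignment of pre-/post-expansion pairs.

Nanocolumn alignment uses an affine transform with scale hard-locked at 1
(an expanded synapse must not be rescaled to fake correlation) and the degrees
of freedom released in stages -- translation first, then rotation, then shear --
so translation carries the highest weight. The objective is the Pearson /
normalized cross-correlation inside the synaptic ROI, maximized with a coarse
integer-shift search followed by Powell refinement per stage; the identity is
always in the candidate set, so the aligned PCC can never fall below the
unaligned one.

Expansion-factor registration first fits a 4-DOF similarity transform
(rotation, uniform scale, translation), then refines with a free 6-DOF affine;
the displacement between the two models on a regular grid is the distortion
map that reveals non-uniform gel expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .image import Image2D
from .metrics import ExpansionEstimate, pearson_cc

__all__ = [
    "AffineParams",
    "SimilarityParams",
    "DistortionField",
    "AlignmentResult",
    "apply_transform",
    "estimate_constrained_affine",
    "estimate_similarity",
    "refine_affine_full",
    "expansion_factor_structural",
]


@dataclass
class AffineParams:
    """2-D affine transform decomposed as rotation . shear . scale about a
    centre: p' = R(theta) Sh(h) S(sx, sy) (p - c) + c + t, with p = (x, y) in
    pixels (x = column, y = row). Constrained mode locks sx = sy = 1."""

    rotation: float = 0.0
    shear: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def linear(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        sh = np.array([[1.0, self.shear], [0.0, 1.0]])
        sc = np.diag([self.scale_x, self.scale_y])
        return rot @ sh @ sc

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix of the forward map in (x, y) coordinates."""
        m = np.eye(3)
        lin = self.linear
        c = np.asarray(self.center, float)
        t = np.asarray(self.translation, float)
        m[:2, :2] = lin
        m[:2, 2] = c + t - lin @ c
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, center=(0.0, 0.0)) -> "AffineParams":
        """Recover (rotation, shear, scales, translation) about ``center``.

        Inverse of :attr:`matrix`; the round trip is exact to floating point.
        """
        m = np.asarray(matrix, float)
        lin = m[:2, :2]
        theta = float(np.arctan2(lin[1, 0], lin[0, 0]))
        c, s = np.cos(theta), np.sin(theta)
        b = np.array([[c, s], [-s, c]]) @ lin          # Sh(h) . S
        sx = float(b[0, 0])
        sy = float(b[1, 1])
        h = float(b[0, 1] / sy)
        cen = np.asarray(center, float)
        t = m[:2, 2] + lin @ cen - cen
        return cls(rotation=theta, shear=h, scale_x=sx, scale_y=sy,
                   translation=(float(t[0]), float(t[1])),
                   center=(float(cen[0]), float(cen[1])))

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Forward-map (N, 2) pixel points (x, y)."""
        pts = np.atleast_2d(np.asarray(pts, float))
        c = np.asarray(self.center, float)
        t = np.asarray(self.translation, float)
        return (pts - c) @ self.linear.T + c + t

    def is_identity(self) -> bool:
        return (self.rotation == 0 and self.shear == 0 and self.scale_x == 1
                and self.scale_y == 1 and tuple(self.translation) == (0.0, 0.0))


@dataclass
class SimilarityParams:
    """4-DOF transform: rotation, uniform scale, translation in x and y."""

    rotation: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def to_affine(self, center=(0.0, 0.0)) -> AffineParams:
        return AffineParams(rotation=self.rotation, scale_x=self.scale,
                            scale_y=self.scale, translation=self.translation,
                            center=center)


@dataclass
class DistortionField:
    """Residual displacement vectors on a regular grid of sample points."""

    grid_points: np.ndarray            # (N, 2) px, (x, y)
    displacement_vectors: np.ndarray   # (N, 2) px

    def __post_init__(self) -> None:
        self.grid_points = np.atleast_2d(np.asarray(self.grid_points, float))
        self.displacement_vectors = np.atleast_2d(np.asarray(self.displacement_vectors, float))
        if len(self.grid_points) != len(self.displacement_vectors):
            raise ValueError("grid points and vectors must have equal length")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.hypot(*self.displacement_vectors.T)

    @property
    def summary(self) -> dict:
        m = self.magnitudes
        return {"mean_px": float(m.mean()) if m.size else 0.0,
                "max_px": float(m.max()) if m.size else 0.0}


@dataclass
class AlignmentResult:
    """Per-synapse alignment record: transform, PCC before/after, shift,
    orientation-shift cosine (filled by the pipeline), distortion field."""

    transform: AffineParams
    pcc_before: float
    pcc_after: float
    shift_vector: tuple[float, float]
    distortion: DistortionField
    orientation_dot: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("pcc_before", "pcc_after"):
            v = getattr(self, name)
            if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [-1, 1]")


def _validate_params(params: AffineParams) -> None:
    vals = [params.rotation, params.shear, params.scale_x, params.scale_y,
            *params.translation, *params.center]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite transform parameters")


def apply_transform(image: Image2D, params) -> Image2D:
    """Resample ``image`` under the forward transform (linear interpolation,
    zero fill outside). An identity transform returns the input bit-exactly."""
    if isinstance(params, SimilarityParams):
        h, w = image.shape
        params = params.to_affine(center=((w - 1) / 2.0, (h - 1) / 2.0))
    _validate_params(params)
    if params.is_identity():
        return image.copy()
    # output pixel p' samples the input at T^{-1}(p'); convert (x,y) -> (row,col)
    inv = np.linalg.inv(params.matrix)
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    mat_rc = swap @ inv[:2, :2] @ swap
    off_rc = inv[:2, 2][::-1]
    out = ndimage.affine_transform(image.pixels, mat_rc, offset=off_rc,
                                   order=1, mode="constant", cval=0.0)
    return Image2D(out, image.pixel_size)


def _geometric_center(image: Image2D) -> tuple[float, float]:
    h, w = image.shape
    return (w - 1) / 2.0, (h - 1) / 2.0


def _roi_mask(shape, roi) -> np.ndarray:
    r0, c0, r1, c1 = roi
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def _shift_int(pixels: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(pixels)
    h, w = pixels.shape
    r0, r1 = max(0, dr), min(h, h + dr)
    c0, c1 = max(0, dc), min(w, w + dc)
    out[r0:r1, c0:c1] = pixels[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def _safe_pcc(a, b, mask) -> float:
    try:
        return pearson_cc(a, b, mask)
    except ValueError:
        return -1.0


def estimate_constrained_affine(
    fixed: Image2D,
    moving: Image2D,
    roi: tuple[int, int, int, int],
    max_shift_frac: float = 0.25,
    max_eval_per_stage: int = 500,
    grid_step_px: int = 8,
) -> AlignmentResult:
    """Align ``moving`` onto ``fixed`` with the scale-locked affine transform.

    ``roi`` is the (row_min, col_min, row_max, col_max) half-open synapse
    bounding box from segmentation; the PCC objective is evaluated inside it.
    Optimization is staged -- translation, then + rotation about the geometric
    image centre, then + shear -- seeded by a coarse integer-shift search over
    +-``max_shift_frac`` of the image size. The identity is always a candidate,
    so ``pcc_after >= pcc_before`` up to 1e-6.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share one shape")
    r0, c0, r1, c1 = roi
    if r1 - r0 < 3 or c1 - c0 < 3:
        raise ValueError(f"roi {roi} smaller than 3x3 px")
    mask = _roi_mask(fixed.shape, roi)
    center = _geometric_center(fixed)
    pcc_before = _safe_pcc(fixed, moving, mask)

    # coarse integer-translation scan; keep a few well-separated starts because
    # quasi-periodic nanodomain bars have near-degenerate lattice offsets
    h, w = fixed.shape
    reach = max(2, int(round(max_shift_frac * min(h, w))))
    step = max(1, reach // 10)
    coarse = [(pcc_before, (0.0, 0.0))]
    for dr in range(-reach, reach + 1, step):
        for dc in range(-reach, reach + 1, step):
            p = _safe_pcc(fixed.pixels, _shift_int(moving.pixels, dr, dc), mask)
            coarse.append((p, (float(dc), float(dr))))
    coarse.sort(key=lambda c: -c[0])
    starts: list[tuple[float, float]] = []
    for _, t in coarse:
        if all(np.hypot(t[0] - s[0], t[1] - s[1]) > 2 * step for s in starts):
            starts.append(t)
        if len(starts) == 3:
            break

    converged = True

    def objective(vec, n_free):
        tx, ty = vec[0], vec[1]
        theta = vec[2] if n_free >= 3 else 0.0
        shear = vec[3] if n_free >= 4 else 0.0
        params = AffineParams(rotation=theta, shear=shear, translation=(tx, ty),
                              center=center)
        warped = apply_transform(moving, params)
        return -_safe_pcc(fixed, warped, mask)

    best_x, best_obj = None, np.inf
    for start in starts:
        x = np.array(start)
        obj = np.inf
        for n_free in (2, 3, 4):
            if len(x) < n_free:
                x = np.append(x, 0.0)
            res = optimize.minimize(
                objective, x, args=(n_free,), method="Powell",
                options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": max_eval_per_stage},
            )
            x = np.asarray(res.x, float)
            obj = float(res.fun)
            converged = converged and bool(res.success)
        if obj < best_obj:
            best_x, best_obj = x, obj

    x = best_x
    tx, ty = float(x[0]), float(x[1])
    params = AffineParams(rotation=float(x[2]), shear=float(x[3]),
                          translation=(tx, ty), center=center)
    pcc_after = _safe_pcc(fixed, apply_transform(moving, params), mask)
    if pcc_after < pcc_before:                     # identity fallback
        params = AffineParams(center=center)
        pcc_after = pcc_before
    grid = _regular_grid(fixed.shape, grid_step_px)
    field = DistortionField(grid, params.map_points(grid) - grid)
    return AlignmentResult(
        transform=params,
        pcc_before=pcc_before,
        pcc_after=pcc_after,
        shift_vector=params.translation,
        distortion=field,
        converged=converged,
    )


def _regular_grid(shape, step):
    h, w = shape
    ys, xs = np.mgrid[step // 2:h:step, step // 2:w:step]
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def _sample_similarity(fixed: Image2D, moving: Image2D, theta, scale, tx, ty):
    """Sample ``moving`` at p_mov = scale R(theta) (p_fix - c_fix) + c_mov + t
    over the fixed grid."""
    hf, wf = fixed.shape
    hm, wm = moving.shape
    cf = np.array([(wf - 1) / 2.0, (hf - 1) / 2.0])
    cm = np.array([(wm - 1) / 2.0, (hm - 1) / 2.0])
    ys, xs = np.mgrid[0:hf, 0:wf]
    pts = np.column_stack([xs.ravel() - cf[0], ys.ravel() - cf[1]])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    mov = scale * pts @ rot.T + cm + np.array([tx, ty])
    sampled = ndimage.map_coordinates(
        moving.pixels, [mov[:, 1], mov[:, 0]], order=1, mode="constant", cval=0.0
    ).reshape(hf, wf)
    return sampled


def estimate_similarity(
    fixed: Image2D,
    moving: Image2D,
    scale_span: float = 1.35,
    n_scales: int = 11,
) -> tuple[SimilarityParams, float]:
    """Fit the 4-DOF similarity transform mapping the fixed frame into the
    moving frame, maximizing the Pearson correlation on the fixed grid.

    The scale axis is searched on a coarse geometric grid centred on the
    image-size ratio (spanning x/÷ ``scale_span``), each candidate seeded with
    the best integer translation from FFT cross-correlation, then refined with
    Powell over (rotation, log-scale, tx, ty). Returns the parameters and the
    achieved PCC; the recovered ``scale`` is in pixel units (combine with the
    pixel-size ratio for physical factors).
    """
    for im, name in ((fixed, "fixed"), (moving, "moving")):
        if np.ptp(im.pixels) == 0:
            raise ValueError(f"{name} image is constant (featureless)")

    s_guess = np.sqrt(moving.pixels.size / fixed.pixels.size)
    scales = s_guess * np.geomspace(1.0 / scale_span, scale_span, n_scales)

    fpix = fixed.pixels - fixed.pixels.mean()
    best = None
    for s in scales:
        # coarse translation at this scale via FFT cross-correlation
        samp = _sample_similarity(fixed, moving, 0.0, s, 0.0, 0.0)
        xc = np.real(np.fft.ifft2(np.fft.fft2(samp - samp.mean()).conj() * np.fft.fft2(fpix)))
        dr, dc = np.unravel_index(np.argmax(xc), xc.shape)
        h, w = fixed.shape
        dr = dr - h if dr > h // 2 else dr
        dc = dc - w if dc > w // 2 else dc
        tx, ty = -dc * s, -dr * s     # fixed-frame shift -> moving-frame offset
        p = _safe_pcc(fixed.pixels, _sample_similarity(fixed, moving, 0.0, s, tx, ty), None)
        if best is None or p > best[0]:
            best = (p, s, tx, ty)

    _, s0, tx0, ty0 = best

    def objective(vec):
        theta, logs, tx, ty = vec
        samp = _sample_similarity(fixed, moving, theta, np.exp(logs), tx, ty)
        return -_safe_pcc(fixed.pixels, samp, None)

    res = optimize.minimize(objective, [0.0, np.log(s0), tx0, ty0], method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-8, "maxfev": 2000})
    theta, logs, tx, ty = res.x
    params = SimilarityParams(rotation=float(theta), scale=float(np.exp(logs)),
                              translation=(float(tx), float(ty)))
    return params, float(-res.fun)


def refine_affine_full(
    fixed: Image2D,
    moving: Image2D,
    init: SimilarityParams,
    grid_step_px: int = 8,
) -> tuple[AffineParams, float, DistortionField]:
    """Refine a similarity fit with a free 6-DOF affine transform.

    The returned PCC is never below the similarity PCC (the similarity model is
    inside the affine family); the distortion field is the displacement of the
    affine map relative to the similarity map on a regular grid over the fixed
    frame -- the vectorial-shift map of non-uniform expansion.
    """
    hm, wm = moving.shape
    cm = np.array([(wm - 1) / 2.0, (hm - 1) / 2.0])

    def sample_affine(vec):
        theta, sx, sy, shear, tx, ty = vec
        aff = AffineParams(rotation=theta, shear=shear, scale_x=sx, scale_y=sy,
                           center=(0.0, 0.0))
        hf, wf = fixed.shape
        cf = np.array([(wf - 1) / 2.0, (hf - 1) / 2.0])
        ys, xs = np.mgrid[0:hf, 0:wf]
        pts = np.column_stack([xs.ravel() - cf[0], ys.ravel() - cf[1]])
        mov = pts @ aff.linear.T + cm + np.array([tx, ty])
        return ndimage.map_coordinates(moving.pixels, [mov[:, 1], mov[:, 0]],
                                       order=1, mode="constant", cval=0.0).reshape(hf, wf)

    def objective(vec):
        return -_safe_pcc(fixed.pixels, sample_affine(vec), None)

    x0 = np.array([init.rotation, init.scale, init.scale, 0.0, *init.translation])
    pcc_init = -objective(x0)
    res = optimize.minimize(objective, x0, method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-8, "maxfev": 3000})
    pcc = float(-res.fun)
    x = np.asarray(res.x, float)
    if pcc < pcc_init:
        x, pcc = x0, pcc_init

    theta, sx, sy, shear, tx, ty = (float(v) for v in x)
    hf, wf = fixed.shape
    cf = ((wf - 1) / 2.0, (hf - 1) / 2.0)
    affine = AffineParams(rotation=theta, shear=shear, scale_x=sx, scale_y=sy,
                          translation=(tx + cm[0] - cf[0], ty + cm[1] - cf[1]),
                          center=cf)
    grid = _regular_grid(fixed.shape, grid_step_px)
    sim_aff = init.to_affine(center=cf)
    sim_aff = replace(sim_aff, translation=(init.translation[0] + cm[0] - cf[0],
                                            init.translation[1] + cm[1] - cf[1]))
    field = DistortionField(grid, affine.map_points(grid) - sim_aff.map_points(grid))
    return affine, pcc, field


def expansion_factor_structural(pre: Image2D, post: Image2D) -> ExpansionEstimate:
    """Estimate the expansion factor by registering pre- onto post-expansion
    images: similarity fit, affine refinement, and conversion from the
    pixel-frame scale to physical units via the pixel-size ratio."""
    sim, pcc_sim = estimate_similarity(pre, post)
    _, pcc_aff, field = refine_affine_full(pre, post, sim)
    factor = sim.scale * (post.pixel_size / pre.pixel_size)
    return ExpansionEstimate(
        factor=float(factor),
        method="structural",
        pcc_similarity=pcc_sim,
        pcc_affine=pcc_aff,
        distortion_summary=field.summary,
    )
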