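"""Calibrated image analysis of single-leaf and single-tiller photographs.

The pipeline mirrors bench photography of detached rice organs on a dark
background: a binary-quadratic pixel-to-world calibration fitted from a grid
of point correspondences, excess-green thresholding, and geometry extraction
(leaf half-width profile, stem length/radius, leaf node and midrib curve).

Pixel convention: ``i`` is the column and ``j`` the row, ``j`` increasing
downward; the calibration maps into a y-up real frame in centimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .datamodel import LeafShapeProfile, MidribCurve2D, StemRecord

__all__ = [
    "CalibrationModel",
    "OrganSet",
    "TillerFrame",
    "fit_calibration",
    "pixel_to_real",
    "pixel_pitch",
    "gray_plant",
    "binarize_leaf",
    "binarize_tiller",
    "extract_leaf_shape",
    "separate_tiller_organs",
    "fit_tiller_frame",
    "extract_stem",
    "extract_leaf_midrib",
    "base_angle",
    "dropping_angle",
]


class CalibrationError(ValueError):
    """Calibration fit failed (degenerate correspondence grid)."""


class SegmentationError(ValueError):
    """An organ-separation step could not find the expected structure."""


@dataclass
class CalibrationModel:
    """Binary-quadratic pixel -> real map.

    ``coefficients`` holds (a1, b1, c1, d1, e1, f1, a2, b2, c2, d2, e2, f2)
    of::

        x = a1 i^2 + b1 i j + c1 j^2 + d1 i + e1 j + f1
        y = a2 i^2 + b2 i j + c2 j^2 + d2 i + e2 j + f2

    ``rmse`` is the fit residual (cm) over the calibration grid.
    """

    coefficients: np.ndarray
    rmse: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(12)

    @classmethod
    def identity(cls) -> "CalibrationModel":
        c = np.zeros(12)
        c[3] = 1.0  # d1: x = i
        c[10] = 1.0  # e2: y = j
        return cls(c)

    @classmethod
    def scale(cls, cm_per_px: float, *, y_up_height: int | None = None) -> "CalibrationModel":
        """Pure-scale model; if ``y_up_height`` is given, y is flipped so the
        image bottom row maps to y = 0 (y-up frame)."""
        c = np.zeros(12)
        c[3] = cm_per_px
        if y_up_height is None:
            c[10] = cm_per_px
        else:
            c[10] = -cm_per_px
            c[11] = cm_per_px * (y_up_height - 1)
        return cls(c)


def _design(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    i = np.asarray(i, dtype=float)
    j = np.asarray(j, dtype=float)
    return np.stack([i * i, i * j, j * j, i, j, np.ones_like(i)], axis=-1)


def fit_calibration(correspondences) -> CalibrationModel:
    """Least-squares fit of the binary-quadratic calibration map.

    ``correspondences`` is a sequence of ((i, j), (x, y)) pairs — pixel
    positions of grid intersections and their true positions in cm.  At least
    six non-degenerate points are required (six coefficients per axis).
    """
    pix = np.array([p for p, _ in correspondences], dtype=float)
    real = np.array([r for _, r in correspondences], dtype=float)
    if pix.shape[0] < 6:
        raise CalibrationError(f"need >= 6 correspondences, got {pix.shape[0]}")
    A = _design(pix[:, 0], pix[:, 1])
    if np.linalg.matrix_rank(A) < 6:
        raise CalibrationError("degenerate correspondence grid (rank-deficient design)")
    coefs, *_ = np.linalg.lstsq(A, real, rcond=None)
    resid = A @ coefs - real
    rmse = float(np.sqrt(np.mean(resid**2)))
    model = CalibrationModel(np.concatenate([coefs[:, 0], coefs[:, 1]]), rmse=rmse)
    # injectivity check over the fitted region: the Jacobian determinant must
    # keep one sign at every calibration point
    det = _jacobian_det(model, pix[:, 0], pix[:, 1])
    if np.any(det == 0) or (np.any(det > 0) and np.any(det < 0)):
        warnings.warn("calibration map is not injective over the fitted grid", stacklevel=2)
    return model


def pixel_to_real(cal: CalibrationModel, i, j) -> np.ndarray:
    """Map pixel (column ``i``, row ``j``) to real (x, y) in cm.

    Accepts scalars or arrays; returns an array with a trailing axis of 2.
    """
    c = cal.coefficients
    A = _design(i, j)
    return np.stack([A @ c[:6], A @ c[6:]], axis=-1)


def _jacobian_det(cal: CalibrationModel, i, j) -> np.ndarray:
    a1, b1, _c1, d1, e1, _f1, a2, b2, _c2, d2, e2, _f2 = cal.coefficients
    c1, c2 = cal.coefficients[2], cal.coefficients[8]
    xi = 2 * a1 * np.asarray(i, float) + b1 * np.asarray(j, float) + d1
    xj = b1 * np.asarray(i, float) + 2 * c1 * np.asarray(j, float) + e1
    yi = 2 * a2 * np.asarray(i, float) + b2 * np.asarray(j, float) + d2
    yj = b2 * np.asarray(i, float) + 2 * c2 * np.asarray(j, float) + e2
    return xi * yj - xj * yi


def pixel_pitch(cal: CalibrationModel, i: float, j: float) -> float:
    """Local real-space size of one pixel (cm), averaged over both axes."""
    p0 = pixel_to_real(cal, i, j)
    pi = pixel_to_real(cal, i + 1.0, j)
    pj = pixel_to_real(cal, i, j + 1.0)
    return float(0.5 * (np.linalg.norm(pi - p0) + np.linalg.norm(pj - p0)))


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def gray_plant(rgb: np.ndarray) -> np.ndarray:
    """Excess-green gray value G - R/3 - B/3, clamped at zero.

    The clamp suppresses backgrounds redder/bluer than green before Otsu
    thresholding.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {rgb.shape}")
    g = rgb[..., 1] - rgb[..., 0] / 3.0 - rgb[..., 2] / 3.0
    return np.clip(g, 0.0, None)


def _mean_filter_threshold(bw: np.ndarray, size: int) -> np.ndarray:
    smooth = ndimage.uniform_filter(bw.astype(float), size=size, mode="nearest")
    return smooth > 0.5


def binarize_leaf(gray: np.ndarray) -> np.ndarray:
    """Global-Otsu binarization followed by a 3x3 mean filter.

    The filter output is fractional, so the mask is re-thresholded at 0.5.
    A constant image yields an empty mask with a warning.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.max() == gray.min():
        warnings.warn("constant image: empty mask", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    bw = gray > threshold_otsu(gray)
    return _mean_filter_threshold(bw, 3)


def binarize_tiller(
    gray: np.ndarray, *, blocks: int = 4, min_block_contrast: float = 0.05
) -> np.ndarray:
    """Blockwise-Otsu binarization for tiller images with uneven lighting.

    The image is partitioned into ``blocks x blocks`` equal sub-blocks (16 by
    default), each thresholded by Otsu independently, then smoothed with a
    2x2 mean filter and re-thresholded at 0.5.  Images whose sides are not
    divisible by ``blocks`` are edge-padded and cropped back.  A sub-block
    whose contrast is below ``min_block_contrast`` of the global range is
    treated as background (Otsu on pure background noise would otherwise
    mark half of it foreground).
    """
    gray = np.asarray(gray, dtype=float)
    if gray.size == 0 or gray.max() == gray.min():
        return np.zeros(gray.shape, dtype=bool)
    H, W = gray.shape
    ph = (-H) % blocks
    pw = (-W) % blocks
    padded = np.pad(gray, ((0, ph), (0, pw)), mode="edge")
    bh, bw_ = padded.shape[0] // blocks, padded.shape[1] // blocks
    out = np.zeros(padded.shape, dtype=bool)
    grange = gray.max() - gray.min()
    for bi in range(blocks):
        for bj in range(blocks):
            sl = np.s_[bi * bh : (bi + 1) * bh, bj * bw_ : (bj + 1) * bw_]
            block = padded[sl]
            if block.max() - block.min() < min_block_contrast * grange:
                continue
            out[sl] = block > threshold_otsu(block)
    return _mean_filter_threshold(out, 2)[:H, :W]


# ---------------------------------------------------------------------------
# leaf image analysis
# ---------------------------------------------------------------------------


def _mask_real_points(mask: np.ndarray, cal: CalibrationModel) -> tuple[np.ndarray, np.ndarray]:
    """Real-frame coordinates of foreground pixels plus their pixel columns."""
    jj, ii = np.nonzero(mask)
    return pixel_to_real(cal, ii.astype(float), jj.astype(float)), ii


def _principal_rotation(pts: np.ndarray) -> np.ndarray:
    """Rotation matrix sending the principal axis of ``pts`` to +x."""
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    c, s = v  # rotate v onto (1, 0)
    return np.array([[c, s], [-s, c]])


def extract_leaf_shape(
    mask: np.ndarray, cal: CalibrationModel, *, poly_degree: int = 6
) -> LeafShapeProfile:
    """Half-width profile of a single detached leaf.

    The foreground is rotated so its principal axis parallels the abscissa,
    the base (the end nearer the image's left edge) is shifted to the origin,
    widths are collected in bins one pixel pitch wide, and the half-widths
    are fitted by a 6th-degree polynomial.
    """
    if cc_label(mask).max() > 1:
        raise SegmentationError("mask has multiple components; label organs first")
    pts, cols = _mask_real_points(mask, cal)
    if pts.shape[0] == 0:
        raise SegmentationError("empty mask")
    jj, ii = np.nonzero(mask)
    pitch = pixel_pitch(cal, float(ii.mean()), float(jj.mean()))
    R = _principal_rotation(pts)
    rot = pts @ R.T
    # orient the base (image-left end) toward x = 0
    xmid = np.median(rot[:, 0])
    if cols[rot[:, 0] < xmid].mean() > cols[rot[:, 0] >= xmid].mean():
        rot = -rot
    rot[:, 0] -= rot[:, 0].min()
    base = rot[rot[:, 0] <= pitch]
    rot[:, 1] -= base[:, 1].mean()

    length = float(rot[:, 0].max()) + pitch
    nbins = max(int(np.ceil(length / pitch)), 2)
    idx = np.clip((rot[:, 0] / pitch).astype(int), 0, nbins - 1)
    ls, hws = [], []
    for k in range(nbins):
        y = rot[idx == k, 1]
        if y.size == 0:
            continue
        ls.append((k + 0.5) * pitch)
        hws.append((y.max() - y.min() + pitch) / 2.0)
    l = np.array(ls)
    hw = np.array(hws)
    deg = min(poly_degree, len(l) - 1)
    poly = np.polyfit(l, hw, deg)
    if deg < poly_degree:  # pad to the documented 7-coefficient form
        poly = np.concatenate([np.zeros(poly_degree - deg), poly])
    return LeafShapeProfile(samples=np.column_stack([l, hw]), poly=poly)


# ---------------------------------------------------------------------------
# tiller image analysis
# ---------------------------------------------------------------------------


@dataclass
class OrganSet:
    """Stem and leaf masks separated from one tiller image.

    Leaves are ordered bottom-up by the height of their attachment to the
    stem corridor.
    """

    stem: np.ndarray
    leaves: list[np.ndarray]


def _lad_line(j: np.ndarray, i: np.ndarray, iters: int = 30) -> tuple[float, float]:
    """L1 (least-absolute-deviation) fit i = a*j + b via IRLS."""
    a, b = 0.0, float(np.median(i))
    w = np.ones_like(i, dtype=float)
    A = np.column_stack([j, np.ones_like(j, dtype=float)])
    for _ in range(iters):
        sol, *_ = np.linalg.lstsq(A * w[:, None], i * w, rcond=None)
        a, b = sol
        r = np.abs(i - (a * j + b))
        w = 1.0 / np.sqrt(np.maximum(r, 1e-6))
    return float(a), float(b)


def separate_tiller_organs(mask: np.ndarray, *, min_size: int = 50) -> OrganSet:
    """Split a tiller mask into the stem corridor and individual leaves.

    The stem is located as a near-vertical corridor: a least-absolute-
    deviation line through the row-wise median foreground columns, with
    corridor width twice the median stem half-width.  Remaining connected
    components larger than ``min_size`` pixels become leaves, ordered
    bottom-up by attachment height.
    """
    mask = np.asarray(mask, dtype=bool)
    jj, ii = np.nonzero(mask)
    if jj.size == 0:
        raise SegmentationError("empty tiller mask")
    rows = np.unique(jj)[::-1]  # walk upward from the stem base
    runs_by_row: dict[int, list[np.ndarray]] = {}
    for r in rows:
        cols_r = np.sort(ii[jj == r])
        runs_by_row[int(r)] = np.split(cols_r, np.nonzero(np.diff(cols_r) > 1)[0] + 1)
    # the bottom of the image holds only the stem (the lowest leaf node sits
    # well above the base): track its run upward until the first node merges
    # a leaf into it, and fit the corridor line on that clean prefix only
    run = max(runs_by_row[int(rows[0])], key=len)
    base_hw = (run[-1] - run[0] + 1) / 2.0
    prev = (run[0] + run[-1]) / 2.0
    prefix: list[tuple[float, float]] = []
    for r in rows:
        containing = [q for q in runs_by_row[int(r)] if q[0] - 1 <= prev <= q[-1] + 1]
        if not containing:
            break
        cand = min(containing, key=len)
        hw_run = (cand[-1] - cand[0] + 1) / 2.0
        # the stem only tapers with height, so any width increase beyond
        # pixel noise means a leaf base has merged into the run
        if hw_run > base_hw + 2.0:
            break
        prev = (cand[0] + cand[-1]) / 2.0
        prefix.append((float(r), prev))
    if len(prefix) < 2:
        raise SegmentationError("stem corridor crosses no foreground")
    arr = np.array(prefix)
    a, b = _lad_line(arr[:, 0], arr[:, 1])
    if abs(a) > 1.0:
        raise SegmentationError("no near-vertical stem corridor found")

    # corridor: per row, the run the fitted line passes through; the stem
    # ends where the line stops hitting foreground (small gaps tolerated)
    row_hw: dict[int, float] = {}
    miss = 0
    for r in rows:
        line_i = a * r + b
        hit = [q for q in runs_by_row[int(r)] if q[0] - 2 <= line_i <= q[-1] + 2]
        if not hit:
            miss += 1
            if miss > 5:
                break  # above the stem tip
            continue
        miss = 0
        q = min(hit, key=len)
        row_hw[int(r)] = (q[-1] - q[0] + 1) / 2.0
    med = float(np.median(list(row_hw.values())))
    # follow the local stem width (tapered stems) but never wider than twice
    # the median, so leaf bases attached at nodes are not swallowed
    hw_of_row = {r: min(h, 2.0 * med) for r, h in row_hw.items()}

    line_cols = a * jj + b
    hw_rows = np.array([hw_of_row.get(int(r), -1.0) for r in jj])
    in_corridor = np.abs(ii - line_cols) <= hw_rows + 0.5
    stem = np.zeros_like(mask)
    stem[jj[in_corridor], ii[in_corridor]] = True
    rest = mask & ~stem
    lab = cc_label(rest, connectivity=2)
    leaves: list[tuple[float, np.ndarray]] = []
    for lid in range(1, lab.max() + 1):
        comp = lab == lid
        if comp.sum() < min_size:
            continue
        cj, ci = np.nonzero(comp)
        near = np.argmin(np.abs(ci - (a * cj + b)))
        leaves.append((float(cj[near]), comp))
    leaves.sort(key=lambda t: -t[0])  # j grows downward: bottom leaf first
    return OrganSet(stem=stem, leaves=[m for _, m in leaves])


@dataclass
class TillerFrame:
    """Rigid map from the calibrated real frame to the tiller frame.

    In the tiller frame the stem is vertical with its base centre at the
    origin; ``pitch`` is the pixel pitch (cm) at the stem centroid.
    """

    R: np.ndarray
    t: np.ndarray
    pitch: float

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) @ self.R.T) + self.t


def fit_tiller_frame(stem_mask: np.ndarray, cal: CalibrationModel) -> TillerFrame:
    """Frame rotating the stem to vertical and shifting its base to (0, 0)."""
    pts, _ = _mask_real_points(stem_mask, cal)
    if pts.shape[0] == 0:
        raise SegmentationError("empty stem mask")
    jj, ii = np.nonzero(stem_mask)
    pitch = pixel_pitch(cal, float(ii.mean()), float(jj.mean()))
    Rp = _principal_rotation(pts)  # principal axis -> +x
    rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])  # then +x -> +y
    R = rot90 @ Rp
    frame = TillerFrame(R=R, t=np.zeros(2), pitch=pitch)
    rot = pts @ R.T
    # the stem base is the lower end in the y-up real frame: flip the frame
    # if its y runs against the real y
    if np.corrcoef(rot[:, 1], pts[:, 1])[0, 1] < 0:
        frame.R = -frame.R
        rot = pts @ frame.R.T
    rot_y = rot[:, 1]
    base = rot[rot_y <= rot_y.min() + pitch]
    frame.t = -np.array([base[:, 0].mean(), rot_y.min()])
    return frame


def extract_stem(
    stem_mask: np.ndarray, cal: CalibrationModel, frame: TillerFrame | None = None
) -> StemRecord:
    """Stem length and radius profile from a stem mask.

    Heights are binned one pixel pitch wide; both length and radius include
    one pixel pitch of extent, so a one-pixel-wide stem reports a radius of
    half a pixel pitch.
    """
    if frame is None:
        frame = fit_tiller_frame(stem_mask, cal)
    pts, _ = _mask_real_points(stem_mask, cal)
    if pts.shape[0] == 0:
        raise SegmentationError("empty stem mask")
    uv = frame.apply(pts)
    pitch = frame.pitch
    length = float(uv[:, 1].max() - uv[:, 1].min()) + pitch
    nbins = max(int(np.ceil(length / pitch)), 1)
    idx = np.clip(((uv[:, 1] - uv[:, 1].min()) / pitch).astype(int), 0, nbins - 1)
    zs, rs = [], []
    for k in range(nbins):
        u = uv[idx == k, 0]
        if u.size == 0:
            continue
        zs.append((k + 0.5) * pitch)
        rs.append((u.max() - u.min() + pitch) / 2.0)
    return StemRecord(length=length, radius_profile=np.column_stack([zs, rs]))


def extract_leaf_midrib(
    leaf_mask: np.ndarray, cal: CalibrationModel, frame: TillerFrame
) -> tuple[np.ndarray, MidribCurve2D]:
    """Leaf node and fitted midrib curve in the tiller frame.

    The node is the leaf point nearest the stem axis (x = min |u|, y = the
    mean height there); the midrib is the per-x-bin mean height, shifted to
    the node and fitted by one quadratic per coordinate, parameterized by
    cumulative chord length (which at pixel density approximates arc
    length).  Returns ``(node, curve)`` with ``node = (|x|, y)``.
    """
    pts, _ = _mask_real_points(leaf_mask, cal)
    if pts.shape[0] == 0:
        raise SegmentationError("empty leaf mask")
    uv = frame.apply(pts)
    pitch = frame.pitch
    u, v = uv[:, 0], uv[:, 1]
    side = 1.0 if np.mean(u) >= 0 else -1.0
    s = side * u  # signed distance measured outward from the stem axis
    nbins = max(int(np.ceil((s.max() - s.min()) / pitch)) + 1, 1)
    idx = np.clip(((s - s.min()) / pitch).astype(int), 0, nbins - 1)
    xs, ys = [], []
    for k in range(nbins):
        sel = idx == k
        if not sel.any():
            continue
        xs.append(s[sel].mean())
        ys.append(v[sel].mean())
    xs = np.array(xs)
    ys = np.array(ys)
    order = np.argsort(xs)  # march outward from the stem
    xs, ys = xs[order], ys[order]
    node = np.array([max(xs[0], 0.0), ys[0]])
    if len(xs) < 3:
        raise SegmentationError("fewer than 3 midrib bins; cannot fit quadratics")
    dx = xs - xs[0]
    dy = ys - ys[0]
    l = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(dx), np.diff(dy)))])
    fx = np.polyfit(l, dx, 2)
    fy = np.polyfit(l, dy, 2)
    curve = MidribCurve2D(
        points=np.column_stack([dx, dy]),
        fit=np.array([fx[0], fx[1], fx[2], fy[0], fy[1], fy[2]]),
        length=float(l[-1]),
    )
    return node, curve


def base_angle(curve: MidribCurve2D) -> float:
    """Angle (rad) between the midrib tangent at the node and the stem axis."""
    a1, b1, _, a2, b2, _ = curve.fit
    t = np.array([b1, b2])
    t = t / np.linalg.norm(t)
    return float(np.arccos(np.clip(t[1], -1.0, 1.0)))


def dropping_angle(curve: MidribCurve2D) -> float:
    """Bend (rad) between the midrib tangents at the node and at the tip."""
    a1, b1, _, a2, b2, _ = curve.fit
    t0 = np.array([b1, b2])
    tL = np.array([2 * a1 * curve.length + b1, 2 * a2 * curve.length + b2])
    t0 = t0 / np.linalg.norm(t0)
    tL = tL / np.linalg.norm(tL)
    return float(np.arccos(np.clip(t0 @ tL, -1.0, 1.0)))
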