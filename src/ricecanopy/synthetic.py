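"""Parametric ground-truth canopies, calibration grids and rendered images.

Everything the measurement pipeline consumes can be produced here from a
seeded template: digital architectures with known 3D geometry, calibration
correspondence grids with controllable quadratic distortion, and rasterized
leaf/tiller photographs for render-and-recover testing.  All randomness
flows through one ``numpy.random.default_rng`` generator per call, so a
fixed seed reproduces the same canopy on any platform.

Default template values emulate transplanted indica-type rice around
heading: 20 x 20 cm spacing, ~10 tillers per hill, 4 expanded blades per
tiller of ~35 cm length, stems near 50 cm with small tilt, and uniformly
random leaf azimuths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    CanopyContext,
    DigitalArchitecture,
    Hill,
    HillPosition,
    LeafRecord,
    LeafShapeProfile,
    MidribCurve2D,
    PlantingSpec,
    StemRecord,
    Tiller,
)
from .imaging import CalibrationModel

__all__ = [
    "PlantTemplate",
    "RenderSpec",
    "default_context",
    "generate_architecture",
    "generate_calibration_grid",
    "random_calibration",
    "lanceolate_shape",
    "make_midrib",
    "render_leaf_image",
    "render_tiller_image",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PlantTemplate:
    """Distributional description of one canopy's plants.

    Angles are radians, lengths cm.  ``midrib_base_angle`` and
    ``midrib_droop_angle`` are (lo, hi) uniform ranges: the angle of the
    blade tangent from the vertical stem at the node, and the additional
    bend accumulated by the tip.  ``azimuth_scheme`` is ``"uniform"`` or a
    fixed list cycled over the leaves of each tiller.
    """

    tillers_per_hill: int = 10
    leaves_per_tiller: int = 4
    stem_length: tuple[float, float] = (50.0, 5.0)  # mean, sd
    stem_tilt_max: float = np.deg2rad(8.0)
    stem_radius: tuple[float, float] = (0.35, 0.05)
    leaf_length: tuple[float, float] = (35.0, 5.0)
    leaf_max_halfwidth: tuple[float, float] = (0.7, 0.1)
    midrib_base_angle: tuple[float, float] = (np.deg2rad(15.0), np.deg2rad(50.0))
    midrib_droop_angle: tuple[float, float] = (np.deg2rad(10.0), np.deg2rad(50.0))
    node_fraction_range: tuple[float, float] = (0.45, 0.95)
    hill_jitter: float = 1.0  # sd of stem-base scatter within a hill (cm)
    cc_points_per_stem: int = 2
    azimuth_scheme: str | tuple[float, ...] = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stem_length", "stem_radius", "leaf_length", "leaf_max_halfwidth"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} mean must be > 0")


def default_context(
    rows: int = 2, cols: int = 4, rs: float = 20.0, ps: float = 20.0, plantnum: int = 2
) -> CanopyContext:
    """Context for the standard validation block: 2 x 4 neighbouring hills."""
    return CanopyContext(
        pm=rows * cols, plantnum=plantnum, rows=rows, cols=cols,
        spec=PlantingSpec(rs=rs, ps=ps),
    )


# ---------------------------------------------------------------------------
# parametric parts
# ---------------------------------------------------------------------------


def lanceolate_shape(length: float, max_halfwidth: float, n_samples: int = 51) -> LeafShapeProfile:
    """Lanceolate half-width profile of a rice blade.

    h(l) = w (1 - t)(0.6 + 2.65 t) / f*,  t = l / L — a quadratic exactly
    inside the 6th-degree polynomial family, with a broad collar (60% of the
    maximum at the base), the widest point near 0.39 L, and a straight taper
    to a sharp tip (f* normalizes the maximum to ``max_halfwidth``).
    """
    a, b = 0.6, 2.65
    tstar = (b - a) / (2.0 * b)
    fmax = (1.0 - tstar) * (a + b * tstar)
    k = max_halfwidth / fmax
    poly = np.array([0.0, 0.0, 0.0, 0.0, -k * b / length**2, k * (b - a) / length, k * a])
    l = np.linspace(0.0, length, n_samples)
    hw = np.clip(np.polyval(poly, l), 0.0, None)
    return LeafShapeProfile(samples=np.column_stack([l, hw]), poly=poly)


def make_midrib(length: float, base_angle: float, droop_angle: float) -> MidribCurve2D:
    """Quadratic midrib whose tangent turns from ``base_angle`` (from the
    vertical) at the node to ``base_angle + droop_angle`` at the tip.

    The tangent interpolates two unit vectors, so the parameter stays close
    to arc length for moderate droop.
    """
    t0 = np.array([np.sin(base_angle), np.cos(base_angle)])
    tL = np.array([np.sin(base_angle + droop_angle), np.cos(base_angle + droop_angle)])
    a = (tL - t0) / (2.0 * length)
    fit = np.array([a[0], t0[0], 0.0, a[1], t0[1], 0.0])
    l = np.linspace(0.0, length, 25)
    pts = np.stack(
        [fit[0] * l**2 + fit[1] * l, fit[3] * l**2 + fit[4] * l], axis=-1
    )
    return MidribCurve2D(points=pts, fit=fit, length=length)


def _lift_leaf(leaf: LeafRecord, stem: StemRecord, n_samples: int = 101) -> None:
    """Populate ground-truth 3D fields directly from the analytic records.

    Kept separate from the reconstruct module so the system-level round trip
    (measure -> reconstruct vs generated truth) stays a real comparison.
    """
    x, y = leaf.node_image
    f = y / stem.length
    axis = stem.axis_bottom + f * (stem.axis_top - stem.axis_bottom)
    ca, sa = np.cos(leaf.azimuth), np.sin(leaf.azimuth)
    node = axis + x * np.array([ca, sa, 0.0])
    l = np.linspace(0.0, leaf.midrib2d.length, n_samples)
    xy = leaf.midrib2d.xy(l)
    tilt = stem.axis_top[2] / stem.length
    mid = np.column_stack(
        [l, xy[:, 0] * ca + node[0], xy[:, 0] * sa + node[1], node[2] + xy[:, 1] * tilt]
    )
    p = mid[:, 1:4]
    n = np.cross(p[len(p) // 2] - p[0], p[-1] - p[len(p) // 2])
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        chord = p[-1] - p[0]
        n = np.array([-chord[1], chord[0], 0.0])
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            n, nn = np.array([0.0, 1.0, 0.0]), 1.0
    nhat = n / nn
    hw = leaf.shape.halfwidth(l)
    e1, e2 = mid.copy(), mid.copy()
    e1[:, 1:4] -= hw[:, None] * nhat
    e2[:, 1:4] += hw[:, None] * nhat
    leaf.node3d = node
    leaf.midrib3d = mid
    leaf.edges3d = (e1, e2)


def _cc_points_for(stem: StemRecord, rng: np.random.Generator, n: int, noise_sd: float) -> np.ndarray:
    """Surface points an operator would take with the coordinatograph probe:
    radially outward from the hill axis, at heights spread along the stem."""
    bottom, top = stem.axis_bottom, stem.axis_top
    d = (top - bottom) / stem.length
    fracs = np.linspace(0.15, 0.85, n)
    pts = []
    for f in fracs:
        p = bottom + f * stem.length * d
        h = p[2]
        rho = np.hypot(p[0], p[1])
        if rho < 1e-9:
            a = rng.uniform(0, TWO_PI)
        else:
            a = np.arctan2(p[1], p[0])
        r = rho + stem.radius_at(h)
        if noise_sd > 0:
            r += rng.normal(0.0, noise_sd)
            h += rng.normal(0.0, noise_sd)
        pts.append([r, a % TWO_PI, h])
    return np.array(pts)


def generate_architecture(
    template: PlantTemplate,
    ctx: CanopyContext | None = None,
    cc_noise_sd: float = 0.0,
) -> DigitalArchitecture:
    """Generate a fully populated architecture (2D records and true 3D).

    Deterministic for a fixed ``template.seed``; hills fill the
    ``ctx.rows x ctx.cols`` block on the planting grid.
    """
    ctx = ctx or default_context()
    rng = np.random.default_rng(template.seed)
    hills: list[Hill] = []
    plausible = 100.0  # longest credible cereal blade (cm)
    for rn in range(1, ctx.rows + 1):
        for cn in range(1, ctx.cols + 1):
            pos = HillPosition(rn, cn)
            hill = Hill(pos, pos.origin(ctx.spec), [])
            for _ in range(template.tillers_per_hill):
                hill.tillers.append(_generate_tiller(template, ctx, rng, cc_noise_sd, plausible))
            hills.append(hill)
    arch = DigitalArchitecture(context=ctx, hills=hills, seed=template.seed)
    arch.validate()
    return arch


def _generate_tiller(
    template: PlantTemplate,
    ctx: CanopyContext,
    rng: np.random.Generator,
    cc_noise_sd: float,
    plausible_leaf: float,
) -> Tiller:
    sl = max(float(rng.normal(*template.stem_length)), 10.0)
    tilt = float(rng.uniform(0.0, template.stem_tilt_max))
    tilt_az = float(rng.uniform(0.0, TWO_PI))
    bottom = np.array([rng.normal(0.0, template.hill_jitter),
                       rng.normal(0.0, template.hill_jitter), 0.0])
    d = np.array([np.sin(tilt) * np.cos(tilt_az), np.sin(tilt) * np.sin(tilt_az), np.cos(tilt)])
    top = bottom + sl * d
    r0 = max(float(rng.normal(*template.stem_radius)), 0.12)
    zs = np.linspace(0.0, sl, 5)
    radii = r0 * (1.0 - 0.4 * zs / sl)
    stem = StemRecord(
        length=sl,
        radius_profile=np.column_stack([zs, radii]),
        axis_bottom=bottom,
        axis_top=top,
    )
    stem.cc_points = _cc_points_for(stem, rng, template.cc_points_per_stem, cc_noise_sd)

    nleaf = template.leaves_per_tiller
    fracs = np.sort(rng.uniform(*template.node_fraction_range, size=nleaf))
    if template.azimuth_scheme == "uniform":
        azimuths = rng.uniform(0.0, TWO_PI, size=nleaf)
    else:
        sched = np.asarray(template.azimuth_scheme, dtype=float)
        azimuths = np.array([sched[k % len(sched)] for k in range(nleaf)]) % TWO_PI
    leaves = []
    for k in range(nleaf):
        L = max(float(rng.normal(*template.leaf_length)), 8.0)
        if L > plausible_leaf:
            warnings.warn(f"implausibly long leaf ({L:.1f} cm) generated", stacklevel=2)
        whalf = max(float(rng.normal(*template.leaf_max_halfwidth)), 0.2)
        base = float(rng.uniform(*template.midrib_base_angle))
        droop = float(rng.uniform(*template.midrib_droop_angle))
        node_h = float(fracs[k] * sl)
        leaf = LeafRecord(
            azimuth=float(azimuths[k]),
            node_image=np.array([float(stem.radius_at(node_h)), node_h]),
            midrib2d=make_midrib(L, base, droop),
            shape=lanceolate_shape(L, whalf),
        )
        _lift_leaf(leaf, stem)
        leaves.append(leaf)
    return Tiller(stem=stem, leaves=leaves)


# ---------------------------------------------------------------------------
# calibration fixtures
# ---------------------------------------------------------------------------


@dataclass
class RenderSpec:
    """Raster fixture parameters.

    ``calibration`` is the true pixel -> real map used for rendering (the
    default is a pure y-up scale); ``illumination_gradient`` multiplies the
    whole scene by 1 - g * (column / width), exercising blockwise
    thresholding when g > 0.
    """

    width: int = 2200
    height: int = 300
    cm_per_px: float = 0.02
    calibration: CalibrationModel | None = None
    illumination_gradient: float = 0.0
    background: tuple[int, int, int] = (18, 14, 16)
    foreground: tuple[int, int, int] = (32, 150, 45)
    supersample: int = 2

    def __post_init__(self) -> None:
        if self.cm_per_px <= 0:
            raise ValueError("cm_per_px must be > 0")

    @property
    def cal(self) -> CalibrationModel:
        if self.calibration is not None:
            return self.calibration
        return CalibrationModel.scale(self.cm_per_px, y_up_height=self.height)


def tiller_render_spec(**overrides) -> RenderSpec:
    """Canvas sized for a whole tiller (~60 cm of stem plus spread leaves)."""
    defaults = dict(width=1800, height=2200, cm_per_px=0.05)
    defaults.update(overrides)
    return RenderSpec(**defaults)


def generate_calibration_grid(spec: RenderSpec, nx: int, ny: int):
    """Grid of ((i, j) pixel, (x, y) cm) correspondences through the spec's
    calibration map, as laid out on a printed validation sheet."""
    if nx * ny < 6:
        raise ValueError("need nx*ny >= 6 correspondences")
    ii = np.linspace(0.08 * spec.width, 0.92 * spec.width, nx)
    jj = np.linspace(0.08 * spec.height, 0.92 * spec.height, ny)
    cal = spec.cal
    out = []
    for j in jj:
        for i in ii:
            x, y = pixel_to_real_one(cal, i, j)
            out.append(((float(i), float(j)), (float(x), float(y))))
    return out


def pixel_to_real_one(cal: CalibrationModel, i: float, j: float) -> tuple[float, float]:
    c = cal.coefficients
    x = c[0] * i * i + c[1] * i * j + c[2] * j * j + c[3] * i + c[4] * j + c[5]
    y = c[6] * i * i + c[7] * i * j + c[8] * j * j + c[9] * i + c[10] * j + c[11]
    return x, y


def random_calibration(
    rng: np.random.Generator, cm_per_px: float = 0.05, quad_scale: float = 2e-6
) -> CalibrationModel:
    """A randomly distorted but injective calibration model: a pure scale
    plus small random cross/quadratic terms."""
    c = np.zeros(12)
    c[0:3] = rng.uniform(-quad_scale, quad_scale, 3)
    c[6:9] = rng.uniform(-quad_scale, quad_scale, 3)
    c[3] = cm_per_px * rng.uniform(0.9, 1.1)
    c[4] = cm_per_px * rng.uniform(-0.05, 0.05)
    c[9] = cm_per_px * rng.uniform(-0.05, 0.05)
    c[10] = cm_per_px * rng.uniform(0.9, 1.1)
    c[5], c[11] = rng.uniform(-1.0, 1.0, 2)
    return CalibrationModel(c)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _subpixel_real(spec: RenderSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real coordinates of all supersampled pixel centres: (X, Y, column)."""
    ss = spec.supersample
    i = (np.arange(spec.width * ss) + 0.5) / ss - 0.5
    j = (np.arange(spec.height * ss) + 0.5) / ss - 0.5
    II, JJ = np.meshgrid(i, j)
    c = spec.cal.coefficients
    X = c[0] * II * II + c[1] * II * JJ + c[2] * JJ * JJ + c[3] * II + c[4] * JJ + c[5]
    Y = c[6] * II * II + c[7] * II * JJ + c[8] * JJ * JJ + c[9] * II + c[10] * JJ + c[11]
    return X, Y, II


def _compose(spec: RenderSpec, inside: np.ndarray) -> np.ndarray:
    """Downsample the boolean coverage and composite fg/bg with lighting."""
    ss = spec.supersample
    H, W = spec.height, spec.width
    cov = inside.astype(float).reshape(H, ss, W, ss).mean(axis=(1, 3))
    bg = np.array(spec.background, dtype=float)
    fg = np.array(spec.foreground, dtype=float)
    img = bg[None, None, :] + cov[:, :, None] * (fg - bg)[None, None, :]
    if spec.illumination_gradient > 0:
        # uneven studio lighting dims the green (chlorophyll) signal across
        # the frame; global thresholds then lose the dim side while
        # blockwise thresholds adapt
        cols = np.arange(W) / max(W - 1, 1)
        light = 1.0 - spec.illumination_gradient * cols
        img = img.copy()
        img[:, :, 1] *= light[None, :]
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_leaf_image(
    shape: LeafShapeProfile, spec: RenderSpec, origin: tuple[float, float] | None = None
) -> tuple[np.ndarray, CalibrationModel]:
    """Rasterize a flattened leaf blade lying along +x from ``origin`` (cm).

    Returns the RGB image and the true calibration used, so extraction can
    be exercised against either the true or a refitted model.  Warns when
    the blade degenerates to (sub)pixel width.
    """
    X, Y, _ = _subpixel_real(spec)
    x0, y0 = origin if origin is not None else _auto_origin(spec, shape.length)
    u = X - x0
    v = Y - y0
    with np.errstate(invalid="ignore"):
        hw = shape.halfwidth(np.clip(u, 0.0, shape.length))
    inside = (u >= 0) & (u <= shape.length) & (np.abs(v) <= hw)
    if shape.max_halfwidth <= spec.cm_per_px:
        warnings.warn("degenerate leaf: blade thinner than one pixel", stacklevel=2)
    if not inside.any():
        warnings.warn("leaf fell outside the canvas", stacklevel=2)
    return _compose(spec, inside), spec.cal


def _auto_origin(spec: RenderSpec, length: float) -> tuple[float, float]:
    corners = [pixel_to_real_one(spec.cal, i, j)
               for i in (0, spec.width - 1) for j in (0, spec.height - 1)]
    xs = [c[0] for c in corners]
    ys = [c[1] for c in corners]
    span = max(xs) - min(xs)
    if length > 0.98 * span:
        raise ValueError(f"leaf of length {length} cm exceeds the canvas extent")
    return min(xs) + 0.5 * (span - length), 0.5 * (min(ys) + max(ys))


def _band_profile(leaf: LeafRecord, n: int = 300):
    """Image-plane band of a drawn leaf as functions of the outward run u:
    (u samples, band centre height, band half-thickness)."""
    m = leaf.midrib2d
    lg = np.linspace(0.0, m.length, n)
    xy = m.xy(lg)
    u = xy[:, 0] + leaf.node_image[0]
    y = xy[:, 1] + leaf.node_image[1]
    # match the renderer, which keeps the midrib visible at sub-pixel taper
    hw = np.maximum(leaf.shape.halfwidth(lg), 0.1)
    return u, y, hw


def _min_clearance(b1, b2) -> float:
    """Smallest vertical gap between two same-side bands over their common
    horizontal extent (negative = touching/overlapping)."""
    u1, y1, h1 = b1
    u2, y2, h2 = b2
    lo, hi = max(u1[0], u2[0]), min(u1[-1], u2[-1])
    if hi <= lo:
        return np.inf
    u = np.linspace(lo, hi, 200)
    gap = np.abs(np.interp(u, u1, y1) - np.interp(u, u2, y2)) - (
        np.interp(u, u1, h1) + np.interp(u, u2, h2)
    )
    return float(gap.min())


def _separable_sides(tiller: Tiller, margin: float = 0.3) -> list[int]:
    """Assign leaves to image sides so drawn bands keep a vertical clearance.

    Leaves are placed bottom-up, preferring alternating sides; a side is
    acceptable when the candidate band clears every band already on it by
    ``margin`` cm.  If neither side clears, the larger-clearance side is
    used (the renderer's occlusion warning then reports the overlap).
    """
    bands = [_band_profile(leaf) for leaf in tiller.leaves]
    order = sorted(range(len(tiller.leaves)), key=lambda k: tiller.leaves[k].node_image[1])
    sides = [0] * len(tiller.leaves)
    placed: dict[int, list[int]] = {1: [], -1: []}
    prefer = 1
    for k in order:
        clearance = {
            s: min((_min_clearance(bands[k], bands[j]) for j in placed[s]), default=np.inf)
            for s in (1, -1)
        }
        if clearance[prefer] > margin:
            s = prefer
        elif clearance[-prefer] > margin:
            s = -prefer
        else:
            s = max((1, -1), key=lambda t: clearance[t])
            warnings.warn(
                "no separable side assignment for a leaf; drawn bands may "
                "touch and extraction is not guaranteed", stacklevel=3,
            )
        sides[k] = s
        placed[s].append(k)
        prefer = -s
    return sides


def render_tiller_image(
    tiller: Tiller,
    spec: RenderSpec,
    sides: list[int] | None = None,
    max_occlusion: float = 0.05,
) -> tuple[np.ndarray, CalibrationModel]:
    """Rasterize a detached tiller: vertical stem band plus leaf bands drawn
    from the midrib quadratics and half-width profiles.

    ``sides`` assigns each leaf to the left (-1) or right (+1) of the stem
    in the image plane (default alternates, keeping the fixture separable).
    Warns if drawn leaves overlap each other beyond ``max_occlusion`` of
    their pixels.
    """
    X, Y, _ = _subpixel_real(spec)
    corners_x = X.min(), X.max()
    corners_y = Y.min(), Y.max()
    xc = 0.5 * (corners_x[0] + corners_x[1])
    y0 = corners_y[0] + 0.05 * (corners_y[1] - corners_y[0])
    stem = tiller.stem
    srad = np.interp(np.clip(Y - y0, 0.0, stem.length),
                     stem.radius_profile[:, 0], stem.radius_profile[:, 1])
    inside = (np.abs(X - xc) <= srad) & (Y >= y0) & (Y <= y0 + stem.length)
    if sides is None:
        sides = _separable_sides(tiller)
    leaf_cov = np.zeros_like(inside, dtype=np.uint8)
    for leaf, s in zip(tiller.leaves, sides):
        m = leaf.midrib2d
        lgrid = np.linspace(0.0, m.length, 400)
        xy = m.xy(lgrid)
        node_x, node_y = leaf.node_image
        cx = xy[:, 0] + node_x  # outward run from the stem axis
        cy = xy[:, 1] + node_y + y0
        hw = leaf.shape.halfwidth(lgrid)
        u = s * (X - xc)
        sel = (u >= cx[0]) & (u <= cx[-1])
        lmap = np.interp(u, cx, lgrid)
        ymid = np.interp(lmap, lgrid, cy)
        # the midrib itself stays visible where the blade tapers sub-pixel
        hmap = np.maximum(np.interp(lmap, lgrid, hw), 2.0 * spec.cm_per_px)
        band = sel & (np.abs(Y - ymid) <= hmap)
        leaf_cov += band.astype(np.uint8)
        inside |= band
    overlap = np.count_nonzero(leaf_cov > 1)
    drawn = np.count_nonzero(leaf_cov > 0)
    if drawn and overlap / drawn > max_occlusion:
        warnings.warn(
            f"leaves overlap on {overlap/drawn:.1%} of their pixels; "
            "extraction is not guaranteed", stacklevel=2,
        )
    return _compose(spec, inside), spec.cal
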