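"""Domain types for digital rice-plant architectures and their archive format.

A *digital architecture* is the measured description of a canopy block: the
planting grid (row/plant spacing), the hills sampled from it, each hill's
tillers, and for every tiller a stem record (length, radius profile, measured
surface points, fitted 3D axis) plus leaf records (azimuth, node, 2D midrib
fit, half-width shape polynomial, and — once reconstructed — the 3D midrib
and blade-edge curves).

Archives are directories (or zip files) holding four CSV files named after
the deposited data set of the originating study:

* ``SystemData.csv`` — ``key,value`` pairs: planting spec, canopy context,
  optional calibration coefficients and RNG seed.
* ``SSP_LCAA.csv`` — stem spatial positions and leaf azimuths/nodes.
* ``leafvein.csv`` — leaf midrib curves (2D fits and 3D samples).
* ``leafshape.csv`` — leaf half-width samples and shape polynomials.

The three record files share one long layout::

    rn,cn,tiller,leaf,kind,idx,v1,v2,v3,v4

with ``leaf = -1`` for stem- or hill-level rows and blank trailing values.
All lengths are centimetres and all angles radians.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArchiveError",
    "ValidationError",
    "PlantingSpec",
    "HillPosition",
    "CanopyContext",
    "StemRecord",
    "LeafShapeProfile",
    "MidribCurve2D",
    "LeafRecord",
    "Tiller",
    "Hill",
    "DigitalArchitecture",
    "read_archive",
    "write_archive",
]

TWO_PI = 2.0 * np.pi

#: tolerance (cm) for "approximately zero" checks on fitted records
FIT_TOL = 0.5

ARCHIVE_FILES = ("SystemData.csv", "SSP_LCAA.csv", "leafvein.csv", "leafshape.csv")
_COLUMNS = ["rn", "cn", "tiller", "leaf", "kind", "idx", "v1", "v2", "v3", "v4"]


class ArchiveError(IOError):
    """A required archive member is missing or unreadable."""


class ValidationError(ValueError):
    """A record violates a structural invariant; the message names the record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantingSpec:
    """Row spacing ``rs`` and plant spacing ``ps`` of the paddy grid (cm)."""

    rs: float
    ps: float

    def validate(self) -> None:
        if not (self.rs > 0 and self.ps > 0):
            raise ValidationError(f"PlantingSpec: rs={self.rs}, ps={self.ps} must be > 0")


@dataclass(frozen=True)
class HillPosition:
    """1-based row/column indices of a hill within the sampled block."""

    rn: int
    cn: int

    def validate(self) -> None:
        if self.rn < 1 or self.cn < 1:
            raise ValidationError(f"HillPosition: ({self.rn}, {self.cn}) must be >= 1")

    def origin(self, spec: PlantingSpec) -> tuple[float, float]:
        """Ground-plane position: x along plant spacing, y along row spacing."""
        return ((self.cn - 1) * spec.ps, (self.rn - 1) * spec.rs)


@dataclass(frozen=True)
class CanopyContext:
    """Aggregation context for trait profiles.

    ``pm`` — hills aggregated, ``plantnum`` — plants per hill used by the
    count-based light normalization, ``rows``/``cols`` — extent of the
    sampled block, ``spec`` — planting spacings.
    """

    pm: int
    plantnum: int
    rows: int
    cols: int
    spec: PlantingSpec

    def validate(self) -> None:
        for name in ("pm", "plantnum", "rows", "cols"):
            if getattr(self, name) < 1:
                raise ValidationError(f"CanopyContext: {name} must be >= 1")
        self.spec.validate()

    @property
    def ground_area(self) -> float:
        """Ground area of the sampled block (cm^2)."""
        return self.rows * self.spec.rs * self.cols * self.spec.ps


@dataclass
class StemRecord:
    """One tiller's stem.

    ``length`` is the blade-measured stem length S_l (cm).  ``radius_profile``
    is an ``(N, 2)`` array of (height z, radius Sr(z)) with strictly
    increasing z.  ``cc_points`` are stem *surface* points (polar radius r,
    azimuth a, height h) measured by the cylindrical coordinatograph.
    ``axis_bottom``/``axis_top`` are the fitted 3D axis endpoints; bottom is
    on the ground plane and |top - bottom| = length.
    """

    length: float
    radius_profile: np.ndarray
    cc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    axis_bottom: np.ndarray | None = None
    axis_top: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.radius_profile = np.asarray(self.radius_profile, dtype=float).reshape(-1, 2)
        self.cc_points = np.asarray(self.cc_points, dtype=float).reshape(-1, 3)
        if self.axis_bottom is not None:
            self.axis_bottom = np.asarray(self.axis_bottom, dtype=float)
        if self.axis_top is not None:
            self.axis_top = np.asarray(self.axis_top, dtype=float)

    def radius_at(self, z: float | np.ndarray) -> np.ndarray:
        """Interpolated stem radius at height ``z`` (clamped to the profile)."""
        zp, rp = self.radius_profile[:, 0], self.radius_profile[:, 1]
        return np.interp(z, zp, rp)

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radius_profile[:, 1]))

    def validate(self, ident: str = "stem") -> None:
        if not self.length > 0:
            raise ValidationError(f"{ident}: stem length {self.length} must be > 0")
        z = self.radius_profile[:, 0]
        if z.size and np.any(np.diff(z) <= 0):
            raise ValidationError(f"{ident}: radius profile heights not strictly increasing")
        if np.any(self.radius_profile[:, 1] <= 0):
            raise ValidationError(f"{ident}: non-positive stem radius")
        if self.axis_top is not None:
            zt = float(self.axis_top[2])
            if not (0.0 <= zt <= self.length + 1e-9):
                raise ValidationError(f"{ident}: axis top height {zt} outside [0, S_l]")


@dataclass
class LeafShapeProfile:
    """Half-width of a leaf blade along its midrib.

    ``samples`` is an ``(N, 2)`` array of (arc distance l from the node,
    half-width) with strictly increasing l; ``poly`` holds the 7
    highest-degree-first coefficients of the 6th-degree half-width fit.
    """

    samples: np.ndarray
    poly: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 2)
        self.poly = np.asarray(self.poly, dtype=float)

    def halfwidth(self, l: float | np.ndarray) -> np.ndarray:
        """Fitted half-width at arc distance ``l``, clipped to be non-negative."""
        return np.clip(np.polyval(self.poly, l), 0.0, None)

    @property
    def length(self) -> float:
        return float(self.samples[-1, 0])

    @property
    def max_halfwidth(self) -> float:
        return float(self.samples[:, 1].max())

    @property
    def fitted_max_halfwidth(self) -> float:
        """Maximum half-width of the fitted polynomial.

        Smoother than the raw sample maximum, which carries one pixel of
        quantization noise when the profile comes from an image.
        """
        l = np.linspace(self.samples[0, 0], self.samples[-1, 0], 512)
        return float(self.halfwidth(l).max())

    def trapezoid_area(self) -> float:
        """Blade area from the sampled full widths (trapezoid rule)."""
        l, hw = self.samples[:, 0], self.samples[:, 1]
        return float(np.trapezoid(2.0 * hw, l))

    def validate(self, ident: str = "leaf shape", tip_tol: float = FIT_TOL) -> None:
        l, hw = self.samples[:, 0], self.samples[:, 1]
        if l.size < 2 or np.any(np.diff(l) <= 0):
            raise ValidationError(f"{ident}: arc-length grid not strictly increasing")
        if l[0] < 0:
            raise ValidationError(f"{ident}: arc length starts below 0")
        if np.any(hw < 0):
            raise ValidationError(f"{ident}: negative half-width")
        if hw[-1] > tip_tol:
            raise ValidationError(f"{ident}: half-width at tip {hw[-1]:.3g} exceeds tolerance")


@dataclass
class MidribCurve2D:
    """Planar midrib curve of a leaf, in the vertical plane of its azimuth.

    ``points`` are the extracted (x, y) midline samples relative to the leaf
    node (first point near the origin).  ``fit`` holds the six quadratic
    coefficients (a1, b1, c1, a2, b2, c2) of x(l) and y(l); ``length`` is the
    total arc length (cm).
    """

    points: np.ndarray
    fit: np.ndarray
    length: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.fit = np.asarray(self.fit, dtype=float).reshape(6)

    def xy(self, l: float | np.ndarray) -> np.ndarray:
        """Evaluate the fitted curve: columns (x, y) at parameter ``l``."""
        a1, b1, c1, a2, b2, c2 = self.fit
        l = np.asarray(l, dtype=float)
        return np.stack([a1 * l**2 + b1 * l + c1, a2 * l**2 + b2 * l + c2], axis=-1)

    def tangent_angle(self, l: float) -> float:
        """Angle (rad) of the curve tangent above the horizontal at ``l``."""
        a1, b1, _, a2, b2, _ = self.fit
        return float(np.arctan2(2 * a2 * l + b2, 2 * a1 * l + b1))

    def validate(self, ident: str = "midrib") -> None:
        if not self.length > 0:
            raise ValidationError(f"{ident}: length {self.length} must be > 0")
        if self.points.shape[0] and np.linalg.norm(self.points[0]) > FIT_TOL:
            raise ValidationError(f"{ident}: first point {self.points[0]} not at the node origin")


@dataclass
class LeafRecord:
    """One leaf: azimuth, node, midrib and shape, plus 3D curves when lifted.

    ``node_image`` is the (x, y) node position in the tiller-image frame
    (x = radial offset from the stem axis, y = height along the stem).
    ``midrib3d`` is an ``(N, 4)`` array of (l, x, y, z); ``edges3d`` holds the
    two blade margins on the same l grid.
    """

    azimuth: float
    node_image: np.ndarray
    midrib2d: MidribCurve2D
    shape: LeafShapeProfile
    node3d: np.ndarray | None = None
    midrib3d: np.ndarray | None = None
    edges3d: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.node_image = np.asarray(self.node_image, dtype=float).reshape(2)
        if self.node3d is not None:
            self.node3d = np.asarray(self.node3d, dtype=float).reshape(3)
        if self.midrib3d is not None:
            self.midrib3d = np.asarray(self.midrib3d, dtype=float).reshape(-1, 4)
        if self.edges3d is not None:
            e1, e2 = self.edges3d
            self.edges3d = (
                np.asarray(e1, dtype=float).reshape(-1, 4),
                np.asarray(e2, dtype=float).reshape(-1, 4),
            )

    @property
    def reconstructed(self) -> bool:
        return self.midrib3d is not None and self.edges3d is not None

    def validate(self, ident: str = "leaf") -> None:
        if not (0.0 <= self.azimuth < TWO_PI):
            raise ValidationError(f"{ident}: azimuth {self.azimuth} outside [0, 2pi)")
        self.midrib2d.validate(f"{ident} midrib")
        self.shape.validate(f"{ident} shape")
        if self.midrib3d is not None and self.edges3d is not None:
            l = self.midrib3d[:, 0]
            for k, e in enumerate(self.edges3d, start=1):
                if e.shape[0] != l.shape[0] or not np.allclose(e[:, 0], l):
                    raise ValidationError(f"{ident}: edge {k} l-grid differs from midrib grid")


@dataclass
class Tiller:
    stem: StemRecord
    leaves: list[LeafRecord] = field(default_factory=list)

    def validate(self, ident: str = "tiller") -> None:
        self.stem.validate(f"{ident} stem")
        for i, leaf in enumerate(self.leaves):
            leaf.validate(f"{ident} leaf {i}")
            if leaf.node_image[1] > self.stem.length + 1e-9:
                raise ValidationError(
                    f"{ident} leaf {i}: node height {leaf.node_image[1]} exceeds stem length"
                )


@dataclass
class Hill:
    position: HillPosition
    origin: tuple[float, float]
    tillers: list[Tiller] = field(default_factory=list)


@dataclass
class DigitalArchitecture:
    """A sampled canopy block: context plus hills of tillers."""

    context: CanopyContext
    hills: list[Hill] = field(default_factory=list)
    calibration: np.ndarray | None = None  # 12 Eq-1 coefficients, if known
    seed: int | None = None

    def validate(self) -> None:
        self.context.validate()
        for hill in self.hills:
            hill.position.validate()
            ident = f"hill ({hill.position.rn},{hill.position.cn})"
            for t, tiller in enumerate(hill.tillers):
                tiller.validate(f"{ident} tiller {t}")

    def iter_leaves(self) -> Iterator[tuple[Hill, Tiller, LeafRecord]]:
        for hill in self.hills:
            for tiller in hill.tillers:
                for leaf in tiller.leaves:
                    yield hill, tiller, leaf

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.iter_leaves())


# ---------------------------------------------------------------------------
# archive I/O
# ---------------------------------------------------------------------------


def _rows_for_stem(rn: int, cn: int, t: int, stem: StemRecord) -> list[list]:
    rows: list[list] = [[rn, cn, t, -1, "stem_length", 0, stem.length, None, None, None]]
    for k, (z, r) in enumerate(stem.radius_profile):
        rows.append([rn, cn, t, -1, "radius", k, z, r, None, None])
    for k, (r, a, h) in enumerate(stem.cc_points):
        rows.append([rn, cn, t, -1, "cc_point", k, r, a, h, None])
    if stem.axis_bottom is not None:
        rows.append([rn, cn, t, -1, "axis_bottom", 0, *stem.axis_bottom, None])
    if stem.axis_top is not None:
        rows.append([rn, cn, t, -1, "axis_top", 0, *stem.axis_top, None])
    return rows


def _frames(arch: DigitalArchitecture) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    ssp: list[list] = []
    vein: list[list] = []
    shape: list[list] = []
    for hill in arch.hills:
        rn, cn = hill.position.rn, hill.position.cn
        ssp.append([rn, cn, -1, -1, "hill_origin", 0, hill.origin[0], hill.origin[1], None, None])
        for t, tiller in enumerate(hill.tillers):
            ssp.extend(_rows_for_stem(rn, cn, t, tiller.stem))
            for li, leaf in enumerate(tiller.leaves):
                ssp.append([rn, cn, t, li, "azimuth", 0, leaf.azimuth, None, None, None])
                ssp.append([rn, cn, t, li, "node_image", 0, *leaf.node_image, None, None])
                if leaf.node3d is not None:
                    ssp.append([rn, cn, t, li, "node3d", 0, *leaf.node3d, None])
                m = leaf.midrib2d
                vein.append([rn, cn, t, li, "fit_x", 0, *m.fit[:3], None])
                vein.append([rn, cn, t, li, "fit_y", 0, *m.fit[3:], None])
                vein.append([rn, cn, t, li, "length", 0, m.length, None, None, None])
                for k, (x, y) in enumerate(m.points):
                    vein.append([rn, cn, t, li, "lmo_point", k, x, y, None, None])
                if leaf.midrib3d is not None:
                    for k, row in enumerate(leaf.midrib3d):
                        vein.append([rn, cn, t, li, "midrib3d", k, *row])
                if leaf.edges3d is not None:
                    for name, edge in zip(("edge1", "edge2"), leaf.edges3d):
                        for k, row in enumerate(edge):
                            vein.append([rn, cn, t, li, name, k, *row])
                for k, (l, hw) in enumerate(leaf.shape.samples):
                    shape.append([rn, cn, t, li, "sample", k, l, hw, None, None])
                for k, c in enumerate(leaf.shape.poly):
                    shape.append([rn, cn, t, li, "poly", k, c, None, None, None])
    return tuple(pd.DataFrame(rows, columns=_COLUMNS) for rows in (ssp, vein, shape))


def write_archive(arch: DigitalArchitecture, path: str | Path) -> None:
    """Write an architecture archive (directory, or zip if ``path`` ends in .zip)."""
    path = Path(path)
    sys_rows = [
        ("rs", arch.context.spec.rs),
        ("ps", arch.context.spec.ps),
        ("pm", arch.context.pm),
        ("plantnum", arch.context.plantnum),
        ("rows", arch.context.rows),
        ("cols", arch.context.cols),
    ]
    if arch.seed is not None:
        sys_rows.append(("seed", arch.seed))
    if arch.calibration is not None:
        for name, c in zip(_CAL_KEYS, arch.calibration):
            sys_rows.append((name, c))
    frames = dict(
        zip(
            ARCHIVE_FILES,
            (pd.DataFrame(sys_rows, columns=["key", "value"]), *_frames(arch)),
        )
    )
    if path.suffix == ".zip":
        with zipfile.ZipFile(path, "w") as zf:
            for name, df in frames.items():
                zf.writestr(name, df.to_csv(index=False, float_format="%.17g"))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(path / name, index=False, float_format="%.17g")


_CAL_KEYS = [f"cal_{c}{i}" for i in (1, 2) for c in "abcdef"]


def _load_frames(path: Path) -> dict[str, pd.DataFrame]:
    frames: dict[str, pd.DataFrame] = {}
    if path.is_file() and path.suffix == ".zip":
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            for name in ARCHIVE_FILES:
                if name not in names:
                    raise ArchiveError(f"archive member missing: {name}")
                frames[name] = pd.read_csv(io.BytesIO(zf.read(name)))
    elif path.is_dir():
        for name in ARCHIVE_FILES:
            member = path / name
            if not member.exists():
                raise ArchiveError(f"archive member missing: {name}")
            frames[name] = pd.read_csv(member)
    else:
        raise ArchiveError(f"no archive at {path}")
    return frames


def _group(df: pd.DataFrame) -> dict[tuple, pd.DataFrame]:
    if df.empty:
        return {}
    return {key: g for key, g in df.groupby(["rn", "cn", "tiller", "leaf"], sort=True)}


def _vals(g: pd.DataFrame, kind: str, ncol: int) -> np.ndarray:
    sub = g[g["kind"] == kind].sort_values("idx")
    return sub[_COLUMNS[6 : 6 + ncol]].to_numpy(dtype=float)


def _scalar(g: pd.DataFrame, kind: str) -> float:
    v = _vals(g, kind, 1)
    if v.size != 1:
        raise ArchiveError(f"expected one '{kind}' row, found {v.size}")
    return float(v[0, 0])


def read_archive(path: str | Path) -> DigitalArchitecture:
    """Read and validate an architecture archive written by :func:`write_archive`."""
    frames = _load_frames(Path(path))
    sysdata = dict(zip(frames["SystemData.csv"]["key"], frames["SystemData.csv"]["value"]))
    spec = PlantingSpec(rs=float(sysdata["rs"]), ps=float(sysdata["ps"]))
    ctx = CanopyContext(
        pm=int(float(sysdata["pm"])),
        plantnum=int(float(sysdata["plantnum"])),
        rows=int(float(sysdata["rows"])),
        cols=int(float(sysdata["cols"])),
        spec=spec,
    )
    cal = None
    if all(k in sysdata for k in _CAL_KEYS):
        cal = np.array([float(sysdata[k]) for k in _CAL_KEYS])
    seed = int(float(sysdata["seed"])) if "seed" in sysdata else None

    ssp = _group(frames["SSP_LCAA.csv"])
    vein = _group(frames["leafvein.csv"])
    shape = _group(frames["leafshape.csv"])

    hills: dict[tuple[int, int], Hill] = {}
    for (rn, cn, t, li), g in ssp.items():
        key = (int(rn), int(cn))
        if key not in hills:
            hills[key] = Hill(HillPosition(*key), (0.0, 0.0), [])
        hill = hills[key]
        if t == -1:
            org = _vals(g, "hill_origin", 2)
            hill.origin = (float(org[0, 0]), float(org[0, 1]))
            continue
        while len(hill.tillers) <= t:
            hill.tillers.append(Tiller(StemRecord(length=np.nan, radius_profile=np.empty((0, 2)))))
        tiller = hill.tillers[int(t)]
        if li == -1:
            ab = _vals(g, "axis_bottom", 3)
            at = _vals(g, "axis_top", 3)
            tiller.stem = StemRecord(
                length=_scalar(g, "stem_length"),
                radius_profile=_vals(g, "radius", 2),
                cc_points=_vals(g, "cc_point", 3),
                axis_bottom=ab[0] if ab.size else None,
                axis_top=at[0] if at.size else None,
            )
        else:
            vg = vein.get((rn, cn, t, li))
            sg = shape.get((rn, cn, t, li))
            if vg is None or sg is None:
                raise ArchiveError(f"leaf ({rn},{cn},{t},{li}) missing vein or shape rows")
            fit = np.concatenate([_vals(vg, "fit_x", 3)[0], _vals(vg, "fit_y", 3)[0]])
            midrib = MidribCurve2D(
                points=_vals(vg, "lmo_point", 2),
                fit=fit,
                length=_scalar(vg, "length"),
            )
            m3 = _vals(vg, "midrib3d", 4)
            e1 = _vals(vg, "edge1", 4)
            e2 = _vals(vg, "edge2", 4)
            n3 = _vals(g, "node3d", 3)
            leaf = LeafRecord(
                azimuth=_scalar(g, "azimuth"),
                node_image=_vals(g, "node_image", 2)[0],
                midrib2d=midrib,
                shape=LeafShapeProfile(
                    samples=_vals(sg, "sample", 2),
                    poly=_vals(sg, "poly", 1)[:, 0],
                ),
                node3d=n3[0] if n3.size else None,
                midrib3d=m3 if m3.size else None,
                edges3d=(e1, e2) if e1.size and e2.size else None,
            )
            while len(tiller.leaves) <= li:
                tiller.leaves.append(None)  # type: ignore[arg-type]
            tiller.leaves[int(li)] = leaf

    arch = DigitalArchitecture(
        context=ctx,
        hills=[hills[k] for k in sorted(hills)],
        calibration=cal,
        seed=seed,
    )
    arch.validate()
    return arch
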