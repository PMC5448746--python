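"""Lift measured tiller records into 3D and build renderable canopy meshes.

The stem axis is fitted from cylindrical-coordinatograph surface points
(corrected inward by the local stem radius), leaves are attached at their
node height and rotated about the stem by their azimuth, and the blade
margins are offset from the midrib perpendicular to the venation plane.
Stems render as cylinders and leaves as triangulated quad strips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    DigitalArchitecture,
    LeafRecord,
    LeafShapeProfile,
    MidribCurve2D,
    StemRecord,
    Tiller,
)

__all__ = [
    "ReconstructionError",
    "Mesh",
    "stem_axis_3d",
    "leaf_node_3d",
    "midrib_3d",
    "leaf_edges_3d",
    "reconstruct_tiller",
    "reconstruct_architecture",
    "build_scene",
    "export_mesh",
]


class ReconstructionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def stem_axis_3d(
    cc_points: np.ndarray,
    radius_at,
    S_l: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the 3D stem axis from coordinatograph surface points.

    Each measured point (polar radius r, azimuth a, height h) lies on the
    outward stem surface, so it is first pulled inward by the stem radius at
    that height: axis sample = ((r - Sr(h)) cos a, (r - Sr(h)) sin a, h).
    Two samples give the exact line; more are fitted by total least squares.
    Returns ``(bottom, top)`` with bottom on the ground plane and
    ``|top - bottom| = S_l``.
    """
    cc = np.asarray(cc_points, dtype=float).reshape(-1, 3)
    if cc.shape[0] < 2:
        raise ReconstructionError("need >= 2 coordinatograph points")
    r, a, h = cc[:, 0], cc[:, 1], cc[:, 2]
    if np.ptp(h) == 0:
        raise ReconstructionError("all coordinatograph points at the same height")
    rr = r - np.asarray(radius_at(h), dtype=float)
    pts = np.column_stack([rr * np.cos(a), rr * np.sin(a), h])
    centroid = pts.mean(axis=0)
    if pts.shape[0] == 2:
        d = pts[1] - pts[0]
    else:
        _, _, vt = np.linalg.svd(pts - centroid)
        d = vt[0]
    if d[2] == 0:
        raise ReconstructionError("degenerate axis direction (horizontal)")
    if d[2] < 0:
        d = -d
    d = d / np.linalg.norm(d)
    bottom = centroid - (centroid[2] / d[2]) * d
    top = bottom + S_l * d
    return bottom, top


def leaf_node_3d(node_image: np.ndarray, azimuth: float, stem: StemRecord) -> np.ndarray:
    """3D leaf node from its tiller-image position (radial offset x, height y).

    The node sits on the stem axis at height fraction y / S_l, pushed out by
    x in the leaf's azimuth direction.  For a vertical stem this reduces to
    (x cos(az), x sin(az), y) above the stem base.
    """
    x, y = float(node_image[0]), float(node_image[1])
    if y > stem.length + 1e-9:
        raise ReconstructionError(f"node height {y} exceeds stem length {stem.length}")
    if stem.axis_bottom is None or stem.axis_top is None:
        raise ReconstructionError("stem axis not fitted; run stem_axis_3d first")
    f = y / stem.length
    axis = stem.axis_bottom + f * (stem.axis_top - stem.axis_bottom)
    return axis + x * np.array([np.cos(azimuth), np.sin(azimuth), 0.0])


def midrib_3d(
    midrib2d: MidribCurve2D,
    azimuth: float,
    node3d: np.ndarray,
    stem: StemRecord,
    n_samples: int = 100,
) -> np.ndarray:
    """Sample the leaf midrib in 3D on an equal-l grid.

    The planar curve (x2d(l), y2d(l)) is placed in the vertical plane of the
    leaf azimuth through the 3D node, with its height run scaled by the stem
    tilt factor z_t / S_l.  Returns an (n_samples, 4) array of (l, x, y, z).
    """
    if stem.axis_top is None:
        raise ReconstructionError("stem axis not fitted")
    l = np.linspace(0.0, midrib2d.length, n_samples)
    xy = midrib2d.xy(l)
    tilt = float(stem.axis_top[2]) / stem.length
    x = xy[:, 0] * np.cos(azimuth) + node3d[0]
    y = xy[:, 0] * np.sin(azimuth) + node3d[1]
    z = node3d[2] + xy[:, 1] * tilt
    return np.column_stack([l, x, y, z])


def _venation_normal(midrib3d: np.ndarray) -> np.ndarray:
    """Unit normal of the leaf venation plane.

    Cross product of the first-half and second-half chords; when the midrib
    is straight the fallback is the horizontal unit vector perpendicular to
    its chord.
    """
    p = midrib3d[:, 1:4]
    first, mid, last = p[0], p[len(p) // 2], p[-1]
    n = np.cross(mid - first, last - mid)
    norm = np.linalg.norm(n)
    chord = last - first
    if norm < 1e-9 * max(np.linalg.norm(chord), 1.0):
        horiz = np.array([-chord[1], chord[0], 0.0])
        if np.linalg.norm(horiz) < 1e-12:  # vertical midrib: any horizontal works
            horiz = np.array([0.0, 1.0, 0.0])
        return horiz / np.linalg.norm(horiz)
    return n / norm


def leaf_edges_3d(
    midrib3d: np.ndarray, shape: LeafShapeProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Blade margins: midrib points offset by +-half-width along the venation
    plane normal.  Both edges share the midrib's l grid."""
    if midrib3d.shape[0] < 3:
        raise ReconstructionError("need >= 3 midrib samples")
    nhat = _venation_normal(midrib3d)
    l = midrib3d[:, 0]
    hw = shape.halfwidth(l)
    offset = hw[:, None] * nhat[None, :]
    e1 = midrib3d.copy()
    e2 = midrib3d.copy()
    e1[:, 1:4] -= offset
    e2[:, 1:4] += offset
    return e1, e2


def reconstruct_tiller(tiller: Tiller, n_samples: int = 100) -> None:
    """Populate a tiller's 3D fields in place from its measured records."""
    stem = tiller.stem
    if stem.cc_points.shape[0] >= 2:
        stem.axis_bottom, stem.axis_top = stem_axis_3d(
            stem.cc_points, stem.radius_at, stem.length
        )
    if stem.axis_bottom is None:
        raise ReconstructionError("stem has neither axis endpoints nor cc points")
    for leaf in tiller.leaves:
        leaf.node3d = leaf_node_3d(leaf.node_image, leaf.azimuth, stem)
        leaf.midrib3d = midrib_3d(leaf.midrib2d, leaf.azimuth, leaf.node3d, stem, n_samples)
        leaf.edges3d = leaf_edges_3d(leaf.midrib3d, leaf.shape)


def reconstruct_architecture(arch: DigitalArchitecture, n_samples: int = 100) -> DigitalArchitecture:
    """Reconstruct every tiller of an architecture in place and return it."""
    for hill in arch.hills:
        for tiller in hill.tillers:
            reconstruct_tiller(tiller, n_samples)
    return arch


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Triangle soup with per-face part labels (``stem`` / ``leaf``)."""

    vertices: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    labels: list[str] = field(default_factory=list)

    def add(self, vertices: np.ndarray, faces: np.ndarray, label: str) -> None:
        off = len(self.vertices)
        self.vertices = np.vstack([self.vertices, vertices])
        self.faces = np.vstack([self.faces, np.asarray(faces, dtype=int) + off])
        self.labels.extend([label] * len(faces))


def _cylinder(bottom: np.ndarray, top: np.ndarray, radius: float, segments: int):
    axis = top - bottom
    axis_n = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis_n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis_n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis_n, u)
    ang = np.linspace(0, 2 * np.pi, segments, endpoint=False)
    ring = radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    verts = np.vstack([bottom + ring, top + ring, bottom[None, :], top[None, :]])
    n = segments
    faces = []
    for k in range(n):
        k2 = (k + 1) % n
        faces.append([k, k2, n + k])  # side
        faces.append([k2, n + k2, n + k])
        faces.append([2 * n, k2, k])  # bottom cap
        faces.append([2 * n + 1, n + k, n + k2])  # top cap
    return verts, np.array(faces, dtype=int)


def _leaf_strip(leaf: LeafRecord):
    e1, e2 = leaf.edges3d
    n = e1.shape[0]
    verts = np.vstack([e1[:, 1:4], e2[:, 1:4]])
    faces = []
    for k in range(n - 1):
        faces.append([k, k + 1, n + k])
        faces.append([k + 1, n + k + 1, n + k])
    return verts, np.array(faces, dtype=int)


def build_scene(
    arch: DigitalArchitecture, cylinder_segments: int = 12, leaf_samples: int | None = None
) -> Mesh:
    """Triangle mesh of the whole canopy, hills placed on the planting grid.

    Each stem becomes a closed cylinder of its mean radius; each leaf a quad
    strip between its two 3D margins.  ``leaf_samples`` is accepted for
    callers that want to re-reconstruct at a different density first; the
    stored ``edges3d`` sampling is used as-is.
    """
    mesh = Mesh()
    for hill in arch.hills:
        shift = np.array([hill.origin[0], hill.origin[1], 0.0])
        for tiller in hill.tillers:
            stem = tiller.stem
            if stem.axis_bottom is None or stem.axis_top is None:
                raise ReconstructionError(
                    "stem axis missing; run reconstruct_architecture first"
                )
            v, f = _cylinder(
                stem.axis_bottom + shift, stem.axis_top + shift, stem.mean_radius,
                cylinder_segments,
            )
            mesh.add(v, f, "stem")
            for li, leaf in enumerate(tiller.leaves):
                if leaf.edges3d is None:
                    raise ReconstructionError(
                        "leaf edges missing; run reconstruct_architecture first"
                    )
                v, f = _leaf_strip(leaf)
                mesh.add(v + shift, f, f"leaf{li}")
    return mesh


def export_mesh(mesh: Mesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a mesh as ASCII OBJ or PLY (inferred from the suffix)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        with open(path, "w") as fh:
            fh.write("# ricecanopy scene\n")
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            current = None
            for face, lab in zip(mesh.faces, mesh.labels):
                if lab != current:
                    fh.write(f"g {lab}\n")
                    current = lab
                fh.write(f"f {face[0]+1} {face[1]+1} {face[2]+1}\n")
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(mesh.vertices)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                f"element face {len(mesh.faces)}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            for v in mesh.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for face in mesh.faces:
                fh.write(f"3 {face[0]} {face[1]} {face[2]}\n")
    else:
        raise ValueError(f"unknown mesh format: {fmt!r}")
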