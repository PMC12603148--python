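"""Airway surface meshing and multi-view snapshot rendering.

A binary airway mask is converted to a triangulated iso-surface (marching
cubes at level 0.5, vertices in mm), and a ring of virtual cameras on a
circle about the cranio-caudal (z) axis renders uniformly spaced grayscale
snapshots — by default 12 views, 30 degrees apart, at a camera radius of
150 mm and 224 x 224 pixels, matching the classifier's input contract.

Rendering is a pure-NumPy orthographic z-buffer rasterizer with flat
Lambertian "headlight" shading: deterministic, bit-reproducible, and
independent of any GPU or windowing system. Orthographic projection keeps
scale comparable across patients; the camera radius sets the default field
of view, and frames auto-scale (with a notice) if the mesh exceeds it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure


@dataclass(frozen=True)
class CameraPose:
    eye: tuple[float, float, float]
    forward: tuple[float, float, float]
    up: tuple[float, float, float]
    right: tuple[float, float, float]
    azimuth_deg: float
    center: tuple[float, float, float]


@dataclass
class ViewSet:
    """Ordered multi-view snapshots of one patient's airway surface."""

    images: np.ndarray  # (n_views, size, size) float32 in [0, 1]
    poses: list[CameraPose]
    n_views: int
    camera_radius_mm: float

    def __post_init__(self) -> None:
        if len(self.images) != self.n_views or len(self.poses) != self.n_views:
            raise ValueError("images/poses count must equal n_views")


def extract_mesh(mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> trimesh.Trimesh:
    """Triangulated iso-surface of a binary mask at level 0.5, vertices in mm.

    The mask is zero-padded by one voxel first so surfaces touching the
    array border close into watertight meshes; degenerate faces and
    unreferenced vertices are removed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing_mm)
    verts = verts - np.asarray(spacing_mm)  # undo the pad offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    if len(mesh.faces) == 0:
        raise ValueError("meshing produced no faces")
    return mesh


def camera_poses(n_views: int, radius_mm: float, center) -> list[CameraPose]:
    """Cameras equally spaced in azimuth on a circle about the z axis at
    elevation 0, all at ``radius_mm`` from ``center``, looking at it with a
    fixed +z up-vector."""
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    center = np.asarray(center, dtype=float)
    poses = []
    for k in range(n_views):
        az = 360.0 * k / n_views
        a = np.deg2rad(az)
        eye = center + radius_mm * np.array([np.cos(a), np.sin(a), 0.0])
        fwd = (center - eye)
        fwd /= np.linalg.norm(fwd)
        up = np.array([0.0, 0.0, 1.0])
        right = np.cross(fwd, up)
        right /= np.linalg.norm(right)
        poses.append(CameraPose(tuple(eye), tuple(fwd), tuple(up), tuple(right),
                                az, tuple(center)))
    return poses


def render_view(mesh: trimesh.Trimesh, pose: CameraPose, render_size: int = 224,
                frame_half_mm: float | None = None, auto_scale: bool = True,
                ambient: float = 0.1) -> np.ndarray:
    """Orthographic flat-shaded render of ``mesh`` from ``pose``.

    Returns a (render_size, render_size) float32 image in [0, 1], black
    background. The square frame half-extent defaults to the camera radius;
    if the projected mesh exceeds it and ``auto_scale`` is set, the frame
    grows to fit (a warning notes the new extent).
    """
    center = np.asarray(pose.center)
    fwd = np.asarray(pose.forward)
    up = np.asarray(pose.up)
    right = np.asarray(pose.right)
    eye = np.asarray(pose.eye)

    verts = mesh.vertices
    rel = verts - center
    x = rel @ right
    y = rel @ up
    depth = (verts - eye) @ fwd

    img = np.zeros((render_size, render_size), dtype=np.float32)
    if (depth <= 0).all():
        warnings.warn("mesh entirely behind the camera; blank image", stacklevel=2)
        return img

    half = float(np.linalg.norm(eye - center)) if frame_half_mm is None else float(frame_half_mm)
    max_extent = max(np.abs(x).max(), np.abs(y).max())
    if max_extent > half:
        if auto_scale:
            half = float(max_extent) * 1.05
            warnings.warn(f"mesh exceeds the orthographic frame; auto-scaled to "
                          f"half-extent {half:.1f} mm", stacklevel=2)
        # without auto-scale the mesh is clipped at the frame edge

    s = (render_size - 1) / 2.0
    px = x / half * s + s
    py = s - y / half * s  # +up is up in the image

    tri = np.stack([px[mesh.faces], py[mesh.faces]], axis=-1)  # (F, 3, 2)
    tz = depth[mesh.faces]

    # flat Lambertian headlight shading, orientation-agnostic
    normals = mesh.face_normals
    lam = np.abs(normals @ fwd)
    shade = (ambient + (1.0 - ambient) * lam).astype(np.float32)

    x0 = np.clip(np.floor(tri[:, :, 0].min(axis=1)), 0, render_size - 1).astype(np.int64)
    x1 = np.clip(np.ceil(tri[:, :, 0].max(axis=1)), 0, render_size - 1).astype(np.int64)
    y0 = np.clip(np.floor(tri[:, :, 1].min(axis=1)), 0, render_size - 1).astype(np.int64)
    y1 = np.clip(np.ceil(tri[:, :, 1].max(axis=1)), 0, render_size - 1).astype(np.int64)
    w = x1 - x0 + 1
    h = y1 - y0 + 1
    # drop faces fully outside the frame or fully behind the camera
    keep = (w > 0) & (h > 0) & (tz > 0).any(axis=1) & (
        (tri[:, :, 0].max(axis=1) >= 0) & (tri[:, :, 0].min(axis=1) <= render_size - 1)
        & (tri[:, :, 1].max(axis=1) >= 0) & (tri[:, :, 1].min(axis=1) <= render_size - 1))
    if not keep.any():
        return img
    tri, tz, shade = tri[keep], tz[keep], shade[keep]
    x0, y0, w, h = x0[keep], y0[keep], w[keep], h[keep]

    counts = (w * h).astype(np.int64)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    total = int(counts.sum())
    fidx = np.repeat(np.arange(len(counts)), counts)
    k = np.arange(total) - starts[fidx]
    pxi = x0[fidx] + k % w[fidx]
    pyi = y0[fidx] + k // w[fidx]

    a = tri[fidx, 0]
    d = tri[fidx, 1] - a
    e = tri[fidx, 2] - a
    det = d[:, 0] * e[:, 1] - d[:, 1] * e[:, 0]
    ok = np.abs(det) > 1e-12
    ap0 = pxi - a[:, 0]
    ap1 = pyi - a[:, 1]
    safe_det = np.where(ok, det, 1.0)
    u = (ap0 * e[:, 1] - ap1 * e[:, 0]) / safe_det
    v = (d[:, 0] * ap1 - d[:, 1] * ap0) / safe_det
    eps = 1e-9
    inside = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
    if not inside.any():
        return img
    fi = fidx[inside]
    z = (tz[fi, 0] + u[inside] * (tz[fi, 1] - tz[fi, 0])
         + v[inside] * (tz[fi, 2] - tz[fi, 0]))
    front = z > 0
    fi, z = fi[front], z[front]
    lin = (pyi[inside][front] * render_size + pxi[inside][front]).astype(np.int64)

    # z-buffer: per pixel keep the nearest fragment; ties resolved by face order
    order = np.lexsort((fi, z, lin))
    lin_s = lin[order]
    first = np.concatenate([[True], lin_s[1:] != lin_s[:-1]])
    sel = order[first]
    img.flat[lin[sel]] = shade[fi[sel]]
    return img


def render_viewset(mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0), n_views: int = 12,
                   radius_mm: float = 150.0, size: int = 224,
                   frame_half_mm: float | None = None) -> ViewSet:
    """Mesh a mask and render its full azimuthal snapshot ring.

    A pure function of (mask, spacing, configuration); images are ordered by
    increasing azimuth.
    """
    mesh = extract_mesh(mask, spacing_mm)
    center = mesh.vertices.mean(axis=0)
    poses = camera_poses(n_views, radius_mm, center)
    images = np.stack([
        render_view(mesh, p, render_size=size, frame_half_mm=frame_half_mm)
        for p in poses
    ])
    return ViewSet(images.astype(np.float32), poses, n_views, radius_mm)


def save_viewset(vs: ViewSet, out_dir: str | Path, patient_id: str) -> list[Path]:
    """Export views as 8-bit grayscale PNGs named {patient}_{azimuth:03d}.png."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, pose in zip(vs.images, vs.poses):
        p = out / f"{patient_id}_{int(round(pose.azimuth_deg)):03d}.png"
        iio.imwrite(p, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))
        paths.append(p)
    return paths
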