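"""Extrapolation of detected fissure patches to complete lobar boundaries.

The denominator of the integrity ratio is the full inter-lobar boundary
— the surface the fissure would occupy if it were complete, cutting all
the way through the lung.  It is estimated by fitting a thin-plate
spline height field over the patch's principal plane, evaluating it on
a regular in-plane grid spanning the lung's full lateral extent,
clipping to the lung mask (trilinear, so the rim is resolved at
sub-voxel precision) and triangulating what remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator

from .surfaces import mesh_area, voxel_sheet_area

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING = 1.0
DEFAULT_GRID_MM = 0.7
MAX_FIT_POINTS = 800


class CompletionError(ValueError):
    """Raised when a patch cannot define a surface."""


@dataclass
class CompleteBoundary:
    """Triangulated complete inter-lobar boundary for one fissure."""

    label: str
    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) int
    area_mm2: float
    _center: np.ndarray | None = None
    _axes: np.ndarray | None = None
    _spline: RBFInterpolator | None = None

    def signed_offset(self, points: np.ndarray) -> np.ndarray:
        """Height of physical points above/below this surface (mm).

        Positive on one fixed-but-arbitrary side of the fitted height
        field; used to clip other surfaces against this boundary.
        """
        if self._spline is None:
            raise CompletionError("boundary carries no height-field model")
        local = (np.atleast_2d(points) - self._center) @ self._axes
        return local[:, 2] - self._spline(local[:, :2])

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def surface_area(obj, spacing=None) -> float:
    """Area in mm^2 of a voxel sheet or a triangle mesh.

    Boolean arrays are treated as one-voxel-thick sheets (``spacing``
    required); :class:`CompleteBoundary` and (vertices, faces) pairs as
    meshes.  Empty input yields 0 with a warning.
    """
    if isinstance(obj, CompleteBoundary):
        return mesh_area(obj.vertices, obj.faces)
    if isinstance(obj, np.ndarray) and obj.dtype == bool:
        if spacing is None:
            raise ValueError("spacing is required for voxel-sheet input")
        return voxel_sheet_area(obj, spacing)
    vertices, faces = obj
    return mesh_area(np.asarray(vertices), np.asarray(faces))


def _principal_frame(pts: np.ndarray):
    """Centroid and principal axes (e1, e2 in-plane, e3 normal)."""
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    vals, vecs = np.linalg.eigh(cov)
    if vals[1] <= 1e-9:  # fewer than 3 non-collinear points
        raise CompletionError("patch has no well-defined plane (collinear points)")
    e3, e2, e1 = vecs[:, 0], vecs[:, 1], vecs[:, 2]
    return center, np.stack([e1, e2, e3], axis=1)  # columns are axes


def fit_complete_surface(
    patch,
    lung: np.ndarray,
    spacing,
    smoothing: float = DEFAULT_SMOOTHING,
    grid_mm: float = DEFAULT_GRID_MM,
    label: str | None = None,
    clip_to: list[tuple[CompleteBoundary, float]] | None = None,
) -> CompleteBoundary:
    """Fit and extrapolate the complete boundary through a fissure patch.

    Parameters
    ----------
    patch : FissurePatchSet or boolean voxel mask
    lung : boolean mask of the lung containing the patch
    spacing : voxel spacing (mm)
    smoothing : thin-plate-spline regularization; 0 interpolates exactly,
        larger values stiffen the extrapolation against detection jitter
    grid_mm : in-plane evaluation step of the triangulated surface
    clip_to : optional list of (boundary, margin_mm) pairs; triangles
        closer than ``margin_mm`` to the given boundary — or on its far
        side relative to the patch — are discarded.  Used for the
        horizontal fissure, whose complete boundary terminates at the
        oblique fissure rather than spanning the whole lung.

    Raises
    ------
    CompletionError
        If the patch has fewer than 3 non-collinear voxels.
    """
    voxels = patch.voxels if hasattr(patch, "voxels") else np.asarray(patch)
    if label is None:
        label = getattr(patch, "label", "fissure")
    spacing = np.asarray(spacing, dtype=float)
    coords = np.argwhere(voxels)
    if len(coords) < 3:
        raise CompletionError(
            f"patch of {len(coords)} voxels cannot define a surface"
        )
    pts = coords * spacing
    center, axes = _principal_frame(pts)
    local = (pts - center) @ axes  # columns: u, v, w

    fit = local
    if len(fit) > MAX_FIT_POINTS:
        fit = fit[np.linspace(0, len(fit) - 1, MAX_FIT_POINTS).astype(int)]
    # robust refit: voxels mislabeled onto a neighboring sheet would
    # otherwise bend the extrapolation far outside the true boundary
    for _ in range(3):
        spline = RBFInterpolator(
            fit[:, :2], fit[:, 2], kernel="thin_plate_spline", smoothing=smoothing
        )
        resid = np.abs(spline(fit[:, :2]) - fit[:, 2])
        keep = resid <= 3.0
        if keep.all() or keep.sum() < max(16, 0.5 * len(fit)):
            break
        fit = fit[keep]

    # in-plane extent of the whole lung, so the sheet cuts through it
    lung_pts = np.argwhere(lung) * spacing
    lung_local = (lung_pts - center) @ axes
    u_min, v_min = lung_local[:, :2].min(axis=0) - grid_mm
    u_max, v_max = lung_local[:, :2].max(axis=0) + grid_mm
    u = np.arange(u_min, u_max + grid_mm, grid_mm)
    v = np.arange(v_min, v_max + grid_mm, grid_mm)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    grid_uv = np.stack([uu.ravel(), vv.ravel()], axis=1)
    ww = spline(grid_uv)
    verts = center + np.column_stack([grid_uv, ww]) @ axes.T

    nu, nv = len(u), len(v)
    idx = np.arange(nu * nv).reshape(nu, nv)
    quads = np.stack(
        [idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[1:, 1:].ravel(),
         idx[:-1, 1:].ravel()],
        axis=1,
    )
    faces = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)

    # keep triangles whose centroid lies inside the lung (trilinear test)
    lung_f = lung.astype(np.float32)
    centroids = verts[faces].mean(axis=1) / spacing
    inside_val = ndimage.map_coordinates(
        lung_f, centroids.T, order=1, mode="constant", cval=0.0
    )
    faces = faces[inside_val >= 0.5]

    for clip_b, margin in clip_to or []:
        s_patch = np.median(clip_b.signed_offset(pts))
        sign = 1.0 if s_patch >= 0 else -1.0
        s_cent = sign * clip_b.signed_offset(verts[faces].mean(axis=1))
        faces = faces[s_cent >= margin]
    if len(faces) == 0:
        raise CompletionError("completed surface does not intersect the lung mask")

    used = np.unique(faces)
    remap = np.full(len(verts), -1, dtype=int)
    remap[used] = np.arange(len(used))
    boundary = CompleteBoundary(
        label=label,
        vertices=verts[used],
        faces=remap[faces],
        area_mm2=0.0,
        _center=center,
        _axes=axes,
        _spline=spline,
    )
    boundary.area_mm2 = mesh_area(boundary.vertices, boundary.faces)
    return boundary


def rasterize_boundary(
    boundary: CompleteBoundary, grid_shape, spacing
) -> np.ndarray:
    """Rasterize a completed surface back onto the voxel grid.

    Triangle centroids and vertices are sampled onto nearest voxels;
    used for idempotence checks (completing the rasterization of a
    completed surface should reproduce its area).
    """
    spacing = np.asarray(spacing, dtype=float)
    samples = np.concatenate(
        [boundary.vertices, boundary.vertices[boundary.faces].mean(axis=1)]
    )
    idx = np.round(samples / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid_shape)), axis=1)
    out = np.zeros(tuple(grid_shape), dtype=bool)
    idx = idx[ok]
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return out
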