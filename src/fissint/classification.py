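"""Anatomical labeling of detected fissure components.

Components in the left lung are by definition the left oblique fissure
(LOF); the left lung has no horizontal fissure.  In the right lung a
component is the right horizontal fissure (RHF) when its mean surface
normal lies within a cone around the cranio-caudal axis (the horizontal
fissure is near-axial) and its centroid sits in the anterior-superior
quadrant of the lung; anything else is the right oblique fissure (ROF).
The cone half-angle (default 35 degrees) and the quadrant gate are
config-exposed since anatomy-free data may need different settings.

Orientation is assumed RAS-consistent: +x patient right, +y anterior,
+z superior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import surfaces
from .phantom import LUNG_LEFT, LUNG_RIGHT

logger = logging.getLogger(__name__)

DEFAULT_CONE_DEG = 35.0

#: encoding used when all labels are written into one volume
LABEL_CODES = {"ROF": 1, "RHF": 2, "LOF": 3}


class ClassificationError(ValueError):
    """Raised when lungs cannot be separated or labeled."""


@dataclass
class FissurePatchSet:
    """Detected fissure voxels carrying one anatomical label."""

    label: str  # ROF, RHF or LOF
    voxels: np.ndarray  # boolean mask
    area_mm2: float
    mean_normal: np.ndarray  # unit vector, physical coordinates

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def split_lungs(lung_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Separate a lung mask into (left, right) boolean fields.

    A labeled mask (1=left, 2=right) is honored directly.  A binary
    mask is split into its two largest connected components, ordered
    along the left-right axis (+x is the patient's right under RAS).
    """
    lung_mask = np.asarray(lung_mask)
    labels = np.unique(lung_mask[lung_mask > 0])
    if set(labels.tolist()) == {LUNG_LEFT, LUNG_RIGHT}:
        return lung_mask == LUNG_LEFT, lung_mask == LUNG_RIGHT
    binary = lung_mask > 0
    lab, n = ndimage.label(binary)
    if n < 2:
        raise ClassificationError(
            "lung mask has fewer than two components and no side labels"
        )
    sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n + 1))
    top2 = np.argsort(sizes)[-2:] + 1
    cx = [np.argwhere(lab == i)[:, 0].mean() for i in top2]
    right_lab = top2[int(np.argmax(cx))]  # +x is the patient's right
    left_lab = top2[int(np.argmin(cx))]
    return lab == left_lab, lab == right_lab


def _plane_residuals(pts: np.ndarray, cluster: np.ndarray) -> np.ndarray:
    """|height residual| of all points against a plane fit to a cluster.

    Fits a low-order height field z = f(x, y) (quadratic, to follow the
    gentle bow of real fissure sheets) by least squares to the cluster's
    points, with robust reweighting passes (points beyond 2 mm are
    dropped and the surface refit), then evaluates absolute residuals
    everywhere.
    """

    def design_of(p):
        x, y = p[:, 0], p[:, 1]
        return np.column_stack([np.ones(len(p)), x, y, x * y, x**2, y**2])

    sel = pts[cluster]
    if len(sel) < 6:
        return np.full(len(pts), np.inf)
    for _ in range(3):
        design = design_of(sel)
        coef, *_ = np.linalg.lstsq(design, sel[:, 2], rcond=None)
        resid = np.abs(design @ coef - sel[:, 2])
        keep = resid <= 2.0
        if keep.sum() < 6 or keep.all():
            break
        sel = sel[keep]
    return np.abs(design_of(pts) @ coef - pts[:, 2])


def _mean_normal(voxels: np.ndarray, spacing) -> np.ndarray:
    """Mean surface orientation of a voxel sheet (principal of n n^T)."""
    # raw PCA normals suffice: the tensor average is itself the smoother
    coords, normals = surfaces.estimate_normals(voxels, spacing, smooth_mm=0.0)
    if len(coords) == 0:
        return np.array([0.0, 0.0, 1.0])
    tensor = np.einsum("ni,nj->ij", normals, normals) / len(normals)
    _, vecs = np.linalg.eigh(tensor)
    return vecs[:, 2]


def classify_patches(
    components: list[np.ndarray],
    side: str,
    lung: np.ndarray,
    spacing,
    cone_deg: float = DEFAULT_CONE_DEG,
) -> list[FissurePatchSet]:
    """Label detected components and merge them per anatomical fissure.

    Parameters
    ----------
    components : list of boolean masks (detected sheet components)
    side : "left" or "right"
    lung : boolean mask of the containing lung (for the quadrant gate)
    spacing : voxel spacing in mm

    Every component receives exactly one label; rigid translation of
    the volume does not change the assignment (all gates are relative
    to the lung's own centroid).
    """
    if side not in ("left", "right"):
        raise ClassificationError(f"side must be 'left' or 'right', got {side!r}")
    if any(not c.any() for c in components):
        raise ClassificationError("components must be nonempty voxel sets")

    lung_centroid = np.argwhere(lung).mean(axis=0) * np.asarray(spacing)
    cos_cone = np.cos(np.deg2rad(cone_deg))

    merged: dict[str, np.ndarray] = {}

    def add(label, voxels):
        merged.setdefault(label, np.zeros_like(voxels))
        merged[label] = merged[label] | voxels

    for comp in components:
        if side == "left":
            add("LOF", comp)
            continue
        # lightly smoothed normals: heavy smoothing blends orientations
        # across the oblique/horizontal junction
        coords, normals = surfaces.estimate_normals(comp, spacing, smooth_mm=1.5)
        pts = coords * np.asarray(spacing)
        horiz = (np.abs(normals[:, 2]) >= cos_cone) & (pts[:, 2] > lung_centroid[2])
        frac = horiz.mean()

        def quadrant_ok(centroid):
            return centroid[1] > lung_centroid[1] and centroid[2] > lung_centroid[2]

        if 0.05 < frac < 0.95:
            # The oblique and horizontal sheets merged into one
            # component near their junction.  Fit a plane to each
            # orientation cluster and reassign every voxel to the plane
            # with the smaller height residual; orientation estimates
            # blur near the junction, plane residuals do not.
            logger.info(
                "splitting orientation-mixed right-lung component "
                "(%.0f%% horizontal-like)", 100 * frac,
            )
            res_h = _plane_residuals(pts, horiz)
            res_o = _plane_residuals(pts, ~horiz)
            # ambiguous voxels (junction blur) go to the oblique sheet,
            # which is the larger surface and tolerates them better
            to_rhf = res_h + 1.0 < res_o
            rhf = np.zeros_like(comp)
            sel = coords[to_rhf]
            rhf[sel[:, 0], sel[:, 1], sel[:, 2]] = True
            add("RHF", rhf)
            add("ROF", comp & ~rhf)
        else:
            normal = _mean_normal(comp, spacing)
            axial = abs(normal[2]) >= cos_cone
            add("RHF" if axial and quadrant_ok(pts.mean(axis=0)) else "ROF", comp)

    out = []
    for label, voxels in merged.items():
        area = surfaces.voxel_sheet_area(voxels, spacing)
        out.append(
            FissurePatchSet(
                label=label,
                voxels=voxels,
                area_mm2=area,
                mean_normal=_mean_normal(voxels, spacing),
            )
        )
    return out


def label_volume(patches: list[FissurePatchSet]) -> np.ndarray:
    """Encode labeled patches into one uint8 volume (ROF=1, RHF=2, LOF=3)."""
    if not patches:
        raise ClassificationError("no patches to encode")
    out = np.zeros(patches[0].voxels.shape, dtype=np.uint8)
    for p in patches:
        out[p.voxels] = LABEL_CODES[p.label]
    return out
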