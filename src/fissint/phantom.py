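"""Synthetic thoracic phantoms with known fissure-integrity ground truth.

The phantom emulates the geometry a fissure-integrity pipeline must cope
with: two ellipsoidal lungs, the right one split by an oblique and a
near-axial (horizontal) fissure sheet into three lobes, the left one by
a single oblique sheet into two lobes.  Fissure sheets are height-field
graphs ``z = f(x, y)`` rasterized one voxel thick, slightly denser than
the surrounding parenchyma, and deliberately incomplete: roughly
circular defects are carved until a requested integrity (percentage of
the full inter-lobar boundary that remains) is reached.  Additive
Gaussian noise stresses the detector.

Ground truth (lung/lobe masks, present and complete fissure voxel sets,
true integrities) is returned alongside the volume, so every downstream
stage can be validated against a known answer.

A paired spirometry simulator produces FEV1/FVC values landing in a
requested GOLD severity category; integrity targets are drawn
independently of severity, so simulated cohorts carry no built-in
association between fissure completeness and lung function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .surfaces import voxel_sheet_area
from .volume import ImageVolume

logger = logging.getLogger(__name__)

#: anatomical fissure labels: right oblique, right horizontal, left oblique
FISSURE_LABELS = ("ROF", "RHF", "LOF")

GOLD_CATEGORIES = ("non-COPD", "GOLD-I", "GOLD-II", "GOLD-III", "GOLD-IV")

#: five-category cohort composition used as the simulator default
DEFAULT_GOLD_MIX = (0.387, 0.145, 0.246, 0.110, 0.112)

#: per-fissure (mean, sd) of integrity targets in %; the horizontal
#: fissure is lower and far more variable than the oblique fissures
DEFAULT_INTEGRITY_DIST = {"ROF": (82.0, 8.0), "RHF": (62.0, 18.0), "LOF": (82.0, 8.0)}

LUNG_LEFT, LUNG_RIGHT = 1, 2
LOBE_LABELS = {"LUL": 1, "LLL": 2, "RUL": 3, "RML": 4, "RLL": 5}


class PhantomConfigError(ValueError):
    """Raised when a phantom specification cannot be realized."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic thoracic volume.

    ``target_integrity`` is the requested percentage of each complete
    fissure surface (ROF, RHF, LOF order) left in place after defects
    are carved.  Intensities are HU-like: parenchyma near -850 HU,
    fissures slightly denser at -700 HU, background (body) at 0 HU.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.625)
    target_integrity: tuple[float, float, float] = (82.0, 62.0, 82.0)
    defect_count: int = 4
    noise_sd: float = 30.0
    intensity_parenchyma: float = -850.0
    intensity_fissure: float = -700.0
    intensity_background: float = 0.0
    seed: int = 0
    allow_marginal_defects: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise PhantomConfigError("spacing must be strictly positive")
        if any(not (0.0 <= t <= 100.0) for t in self.target_integrity):
            raise PhantomConfigError("target_integrity values must lie in [0, 100]")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom volume."""

    lung_mask: np.ndarray  # 0 background, 1 left, 2 right
    lobe_mask: np.ndarray  # labels per LOBE_LABELS
    fissure_truth: dict[str, np.ndarray]  # present (defected) sheets
    boundary_truth: dict[str, np.ndarray]  # complete sheets
    true_integrity: dict[str, float]  # % per fissure
    true_elf: float  # % entire lung, area-weighted


@dataclass
class SpirometrySim:
    """Simulated post-bronchodilator spirometry for one subject."""

    fev1_l: float
    fvc_l: float
    fev1_pct_pred: float
    intended_gold: str

    def __post_init__(self) -> None:
        if self.fev1_l <= 0 or self.fvc_l <= 0 or self.fev1_pct_pred <= 0:
            raise ValueError("spirometry values must be positive")
        if self.fev1_l > self.fvc_l:
            raise ValueError("FEV1 cannot exceed FVC")

    @property
    def fev1_fvc_pct(self) -> float:
        return 100.0 * self.fev1_l / self.fvc_l


def _lung_geometry(spec: PhantomSpec):
    """Centers and semi-axes (mm) of the two ellipsoidal lungs."""
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    semi = np.array([0.20, 0.38, 0.42]) * extent
    if np.any(semi < 3.0 * np.asarray(spec.spacing)):
        raise PhantomConfigError(
            f"grid {spec.grid_shape} too small to contain two lungs at "
            f"spacing {spec.spacing}"
        )
    # RAS convention: +x is the patient's right
    center_right = np.array([0.72 * extent[0], 0.5 * extent[1], 0.5 * extent[2]])
    center_left = np.array([0.28 * extent[0], 0.5 * extent[1], 0.5 * extent[2]])
    return center_left, center_right, semi


def _fissure_height_fields(spec: PhantomSpec):
    """Analytic sheets z=f(x,y) in mm, plus the RHF validity predicate.

    Oblique fissures run postero-superior to antero-inferior at ~40 deg
    from the axial plane (slope 0.85 mm/mm, kept below one voxel per
    voxel step so the rasterized sheet stays 26-connected); a mild
    quadratic bow in x makes them non-planar.  The horizontal fissure is
    a gently tilted near-axial sheet over the anterior-superior right
    lung, starting 2 mm anterior of its intersection with the oblique
    fissure so the two detected sheets remain separable components.
    """
    center_left, center_right, semi = _lung_geometry(spec)

    def f_oblique(center):
        def f(x_mm, y_mm):
            return (
                center[2]
                + 0.15 * semi[2]
                - 0.85 * (y_mm - center[1])
                + 0.004 * (x_mm - center[0]) ** 2
            )

        return f

    z_h = center_right[2] + 0.45 * semi[2]

    def f_horizontal(x_mm, y_mm):
        return z_h + 0.08 * (y_mm - center_right[1])

    f_rof = f_oblique(center_right)

    def rhf_valid(x_mm, y_mm):
        return f_horizontal(x_mm, y_mm) >= f_rof(x_mm, y_mm) + 2.0

    return f_rof, f_horizontal, f_oblique(center_left), rhf_valid


def _rasterize_sheet(f, lung: np.ndarray, spec: PhantomSpec, valid=None) -> np.ndarray:
    """Rasterize z=f(x,y) one voxel thick inside a lung mask."""
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    x_mm = np.arange(nx)[:, None] * sx
    y_mm = np.arange(ny)[None, :] * sy
    z_mm = np.broadcast_to(np.asarray(f(x_mm, y_mm), dtype=float), (nx, ny))
    z_idx = np.round(z_mm / sz).astype(int)
    ok = (z_idx >= 0) & (z_idx < nz)
    if valid is not None:
        ok = ok & np.broadcast_to(valid(x_mm, y_mm), (nx, ny))
    sheet = np.zeros(spec.grid_shape, dtype=bool)
    xi, yi = np.nonzero(ok)
    zi = z_idx[ok]
    inside = lung[xi, yi, zi]
    sheet[xi[inside], yi[inside], zi[inside]] = True
    return sheet


def carve_defects(
    surface_voxels: np.ndarray,
    target_integrity: float,
    defect_count: int,
    seed,
    spacing=(1.0, 1.0, 1.0),
    allow_marginal: bool = False,
    margin_mm: float = 3.0,
) -> np.ndarray:
    """Remove roughly circular patches until a target integrity remains.

    Defects are modeled as a union of balls with random centers and
    relative radii; the union is grown as a level set of the per-voxel
    metric ``min_i dist(v, c_i) / r_i`` and cut at the level that leaves
    exactly the requested fraction of voxels, so the hit is exact and
    deterministic for a fixed seed.  Centers are restricted to sheet
    voxels at least ``margin_mm`` from the sheet edge unless
    ``allow_marginal`` is set (marginal incompleteness is the clinically
    typical pattern, but interior holes are the harder detection case).

    Returns a boolean mask; always a subset of the input.
    """
    if not 0.0 <= target_integrity <= 100.0:
        raise ValueError("target_integrity must lie in [0, 100]")
    surface_voxels = np.asarray(surface_voxels, dtype=bool)
    out = surface_voxels.copy()
    coords = np.argwhere(surface_voxels)
    n = len(coords)
    if n == 0 or target_integrity >= 100.0:
        return out
    if target_integrity <= 0.0:
        return np.zeros_like(out)
    if defect_count < 1:
        raise ValueError("defect_count must be >= 1 when carving is required")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spacing = np.asarray(spacing, dtype=float)
    pts = coords * spacing

    removable = np.arange(n)
    if not allow_marginal:
        # edge voxels have sparse 26-neighborhoods on a one-voxel sheet
        from scipy import ndimage

        nb = ndimage.convolve(
            surface_voxels.astype(np.int8), np.ones((3, 3, 3), np.int8), mode="constant"
        )
        edge_count = nb[tuple(coords.T)] - 1
        edge_pts = pts[edge_count <= 5]
        if len(edge_pts):
            dist_to_edge, _ = cKDTree(edge_pts).query(pts, k=1)
            interior = np.flatnonzero(dist_to_edge > margin_mm)
            if len(interior) >= defect_count:
                removable = interior
            else:
                logger.warning(
                    "sheet too small for interior-only defects; using all voxels"
                )

    n_keep = int(round(n * target_integrity / 100.0))
    n_remove = n - n_keep
    if n_remove <= 0:
        return out
    if n_remove > len(removable):
        logger.warning(
            "target integrity %.1f%% unreachable with interior-only defects "
            "(%d of %d voxels removable); removing the whole interior",
            target_integrity, len(removable), n,
        )
        n_remove = len(removable)

    centers = pts[rng.choice(removable, size=defect_count, replace=False)]
    radii = rng.uniform(0.5, 1.5, size=defect_count)
    d, idx = cKDTree(centers).query(pts[removable], k=1)
    metric = d / radii[idx]

    order = np.argpartition(metric, n_remove - 1)[:n_remove]
    level = metric[order].max()
    if level > 2.0 * np.sqrt(n_remove / (np.pi * defect_count)) * np.mean(spacing[:2]):
        logger.info(
            "defects widened beyond nominal radii (level %.1f) to reach "
            "target integrity %.1f%%",
            level,
            target_integrity,
        )
    removed = coords[removable[order]]
    out[removed[:, 0], removed[:, 1], removed[:, 2]] = False
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Build a phantom volume and its ground truth.

    Deterministic for a fixed ``spec.seed``: the same spec yields
    voxel-identical volumes and masks.
    """
    rng = np.random.default_rng(spec.seed)
    center_left, center_right, semi = _lung_geometry(spec)
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    x = (np.arange(nx) * sx)[:, None, None]
    y = (np.arange(ny) * sy)[None, :, None]
    z = (np.arange(nz) * sz)[None, None, :]

    def ellipsoid(center):
        return (
            ((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2
        ) <= 1.0

    left = ellipsoid(center_left)
    right = ellipsoid(center_right)
    lung_mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    lung_mask[left] = LUNG_LEFT
    lung_mask[right] = LUNG_RIGHT

    f_rof, f_rhf, f_lof, rhf_valid = _fissure_height_fields(spec)
    boundary = {
        "ROF": _rasterize_sheet(f_rof, right, spec),
        "RHF": _rasterize_sheet(f_rhf, right, spec, valid=rhf_valid),
        "LOF": _rasterize_sheet(f_lof, left, spec),
    }

    fissure = {}
    for label, target in zip(FISSURE_LABELS, spec.target_integrity):
        fissure[label] = carve_defects(
            boundary[label],
            target,
            spec.defect_count,
            rng,
            spacing=spec.spacing,
            allow_marginal=spec.allow_marginal_defects,
        )

    # analytic lobe partition (independent of carved defects)
    z_rof = f_rof(x, y)
    z_rhf = f_rhf(x, y)
    z_lof = f_lof(x, y)
    lobe_mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    lobe_mask[left & (z >= z_lof)] = LOBE_LABELS["LUL"]
    lobe_mask[left & (z < z_lof)] = LOBE_LABELS["LLL"]
    lobe_mask[right & (z < z_rof)] = LOBE_LABELS["RLL"]
    lobe_mask[right & (z >= z_rof) & (z < z_rhf)] = LOBE_LABELS["RML"]
    lobe_mask[right & (z >= z_rof) & (z >= z_rhf)] = LOBE_LABELS["RUL"]

    data = np.full(spec.grid_shape, spec.intensity_background, dtype=np.float32)
    data[lung_mask > 0] = spec.intensity_parenchyma
    for label in FISSURE_LABELS:
        data[fissure[label]] = spec.intensity_fissure
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape).astype(
            np.float32
        )

    areas_b = {
        lb: voxel_sheet_area(boundary[lb], spec.spacing) for lb in FISSURE_LABELS
    }
    areas_f = {lb: voxel_sheet_area(fissure[lb], spec.spacing) for lb in FISSURE_LABELS}
    true_integrity = {}
    for lb in FISSURE_LABELS:
        if areas_b[lb] <= 0:
            raise PhantomConfigError(f"fissure {lb} has empty complete surface")
        true_integrity[lb] = min(100.0, 100.0 * areas_f[lb] / areas_b[lb])
    true_elf = 100.0 * sum(areas_f.values()) / sum(areas_b.values())

    volume = ImageVolume(data, spec.spacing)
    truth = PhantomTruth(lung_mask, lobe_mask, fissure, boundary, true_integrity, true_elf)
    return volume, truth


_BOUNDARY_AREA_CACHE: dict = {}


def boundary_areas(spec: PhantomSpec | None = None) -> dict[str, float]:
    """Complete-boundary area (mm^2) per fissure for a phantom geometry.

    Depends only on grid shape and spacing (not on targets, noise or
    seed), so results are cached per geometry.
    """
    spec = spec or PhantomSpec()
    key = (tuple(spec.grid_shape), tuple(spec.spacing))
    if key not in _BOUNDARY_AREA_CACHE:
        center_left, center_right, semi = _lung_geometry(spec)
        nx, ny, nz = spec.grid_shape
        sx, sy, sz = spec.spacing
        x = (np.arange(nx) * sx)[:, None, None]
        y = (np.arange(ny) * sy)[None, :, None]
        z = (np.arange(nz) * sz)[None, None, :]

        def ellipsoid(center):
            return (
                ((x - center[0]) / semi[0]) ** 2
                + ((y - center[1]) / semi[1]) ** 2
                + ((z - center[2]) / semi[2]) ** 2
            ) <= 1.0

        left, right = ellipsoid(center_left), ellipsoid(center_right)
        f_rof, f_rhf, f_lof, rhf_valid = _fissure_height_fields(spec)
        sheets = {
            "ROF": _rasterize_sheet(f_rof, right, spec),
            "RHF": _rasterize_sheet(f_rhf, right, spec, valid=rhf_valid),
            "LOF": _rasterize_sheet(f_lof, left, spec),
        }
        _BOUNDARY_AREA_CACHE[key] = {
            lb: voxel_sheet_area(m, spec.spacing) for lb, m in sheets.items()
        }
    return dict(_BOUNDARY_AREA_CACHE[key])


def _spirometry_bands(category: str):
    """(FEV1/FVC %, FEV1 %pred) uniform sampling bands per GOLD category.

    Bands sit strictly inside the staging cut-points (ratio 70;
    FEV1 %pred 80/50/30), so the staging rule recovers the intended
    category by construction.
    """
    return {
        "non-COPD": ((71.0, 88.0), (85.0, 120.0)),
        "GOLD-I": ((55.0, 69.0), (81.0, 110.0)),
        "GOLD-II": ((45.0, 69.0), (51.0, 79.0)),
        "GOLD-III": ((35.0, 65.0), (31.0, 49.0)),
        "GOLD-IV": ((22.0, 55.0), (16.0, 29.0)),
    }[category]


def simulate_spirometry(category: str, rng: np.random.Generator) -> SpirometrySim:
    """Draw one subject's spirometry landing in the given GOLD category."""
    (r_lo, r_hi), (p_lo, p_hi) = _spirometry_bands(category)
    ratio = rng.uniform(r_lo, r_hi)
    pct_pred = rng.uniform(p_lo, p_hi)
    fvc = float(np.exp(rng.normal(np.log(4.0), 0.18)))
    return SpirometrySim(
        fev1_l=fvc * ratio / 100.0,
        fvc_l=fvc,
        fev1_pct_pred=pct_pred,
        intended_gold=category,
    )


def simulate_cohort(
    n: int,
    gold_mix=DEFAULT_GOLD_MIX,
    integrity_dist=None,
    seed: int = 0,
    **spec_kwargs,
) -> list[tuple[PhantomSpec, SpirometrySim]]:
    """Draw a cohort of phantom specs with paired spirometry.

    GOLD categories are sampled from ``gold_mix``; integrity targets are
    drawn from ``integrity_dist`` independently of the category (no
    built-in association between severity and completeness).  Extra
    keyword arguments are forwarded to every :class:`PhantomSpec`.
    """
    if n < 1:
        raise PhantomConfigError("cohort size must be >= 1")
    mix = np.asarray(gold_mix, dtype=float)
    if len(mix) != len(GOLD_CATEGORIES) or np.any(mix < 0) or abs(mix.sum() - 1) > 1e-8:
        raise PhantomConfigError(
            "gold_mix must be 5 non-negative proportions summing to 1"
        )
    dist = dict(DEFAULT_INTEGRITY_DIST if integrity_dist is None else integrity_dist)

    rng = np.random.default_rng(seed)
    categories = rng.choice(len(GOLD_CATEGORIES), size=n, p=mix)
    out = []
    for i in range(n):
        cat = GOLD_CATEGORIES[categories[i]]
        spiro = simulate_spirometry(cat, rng)
        targets = tuple(
            float(np.clip(rng.normal(dist[lb][0], dist[lb][1]), 0.0, 100.0))
            for lb in FISSURE_LABELS
        )
        spec = PhantomSpec(
            target_integrity=targets,
            seed=int(rng.integers(2**31)),
            **spec_kwargs,
        )
        out.append((spec, spiro))
    return out
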