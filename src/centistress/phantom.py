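"""Digital brain phantom for amyloid-PET stress testing.

The phantom replaces real anatomy with nested ellipsoids on a regular grid,
keeping the adjacency relations that drive partial-volume effects: a
cortical grey-matter ribbon wraps a cerebral white-matter core, cerebellar
grey matter wraps a cerebellar white-matter core just beneath the cerebrum,
and the pons sits next to the cerebellum.  Uptake is piecewise constant per
compartment so the ideal SUVr of every simulated image is known in closed
form, which makes the whole quantification chain oracle-testable.

Compartment intensities are expressed relative to cerebellar grey matter
(= 1).  White matter is set to the tracer's WM/reference ratio, which drifts
linearly with age; the cortical target is scaled so that the ideal
(unsmoothed) target / whole-cerebellum ratio equals the tracer's SUVr at the
subject's true amyloid load, interpolated linearly between the tracer's
0-Centiloid and 100-Centiloid anchor SUVrs.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .errors import (CannotSharpenError, DegenerateSubjectError, GeometryError,
                     ModelParameterError)
from .transforms import grid_affine

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class Tissue(IntEnum):
    """Voxel labels of the phantom."""

    BACKGROUND = 0
    CORTICAL_TARGET_GM = 1
    OTHER_GM = 2
    CEREBRAL_WM = 3
    CEREBELLAR_GM = 4
    CEREBELLAR_WM = 5
    BRAINSTEM_PONS = 6


GM_LABELS = (Tissue.CORTICAL_TARGET_GM, Tissue.OTHER_GM, Tissue.CEREBELLAR_GM)
WM_LABELS = (Tissue.CEREBRAL_WM, Tissue.CEREBELLAR_WM, Tissue.BRAINSTEM_PONS)

#: Default region geometry.  Centres and radii are fractions of the half
#: field of view, so the same description scales to any grid size.  The
#: cerebellum nests into the posterior-inferior cerebrum (only its lower cap
#: faces background, mimicking the tentorium), and the brainstem/pons rises
#: into the cerebral mass while its lower half stays exposed to CSF.
DEFAULT_GEOMETRY: dict[str, dict] = {
    "cerebrum": {"center": (0.0, 0.0, 0.22), "radii": (0.62, 0.72, 0.60)},
    "cortical_thickness": 0.20,
    "deep_gm": {"center": (0.0, 0.06, 0.30), "radii": (0.14, 0.18, 0.12)},
    "cerebellum": {"center": (0.0, -0.28, -0.26), "radii": (0.30, 0.26, 0.22)},
    "cerebellar_cortical_thickness": 0.08,
    "pons": {"center": (0.0, 0.16, -0.56), "radii": (0.13, 0.12, 0.17)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Grid and region geometry of the template phantom."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 2.0
    region_geometry: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(n < 32 for n in self.grid_shape):
            raise GeometryError("grid_shape must be a triple with components >= 32")
        if self.voxel_size <= 0:
            raise GeometryError("voxel_size must be positive")


@dataclass
class LabelMap:
    """Tissue labels on a regular grid."""

    grid: np.ndarray
    voxel_size: float
    affine: np.ndarray

    def count(self, *labels: Tissue) -> int:
        return int(np.isin(self.grid, [int(l) for l in labels]).sum())

    def mask(self, *labels: Tissue) -> np.ndarray:
        return np.isin(self.grid, [int(l) for l in labels])

    def copy(self) -> "LabelMap":
        return LabelMap(self.grid.copy(), self.voxel_size, self.affine.copy())


@dataclass
class VolumeImage:
    """Uptake intensities (arbitrary units) on a regular grid."""

    grid: np.ndarray
    voxel_size: float
    affine: np.ndarray
    effective_fwhm: float = 0.0

    def __post_init__(self):
        if self.effective_fwhm < 0:
            raise ValueError("effective_fwhm must be >= 0")

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.grid.copy(), self.voxel_size,
                           self.affine.copy(), self.effective_fwhm)


@dataclass(frozen=True)
class TracerProfile:
    """Tracer-specific uptake behaviour.

    ``suvr_yc`` / ``suvr_ad100`` are the target/whole-cerebellum SUVr at 0 and
    100 Centiloid; ``wm_uptake_base`` is the white-matter / cerebellar-GM
    intensity ratio at age 70 and ``wm_age_slope`` its per-year drift;
    ``noise_sd`` is the SD of the multiplicative per-region noise.
    """

    name: str
    suvr_yc: float
    suvr_ad100: float
    wm_uptake_base: float
    wm_age_slope: float
    noise_sd: float = 0.02

    def __post_init__(self):
        if not (self.suvr_ad100 > self.suvr_yc > 0):
            raise ModelParameterError(
                f"{self.name}: need suvr_ad100 > suvr_yc > 0")
        if self.noise_sd < 0:
            raise ModelParameterError(f"{self.name}: noise_sd must be >= 0")

    def suvr_at(self, true_cl: float) -> float:
        """Ideal SUVr at a given amyloid load (linear through the anchors)."""
        return self.suvr_yc + (self.suvr_ad100 - self.suvr_yc) * true_cl / 100.0

    def wm_uptake(self, age: float) -> float:
        return self.wm_uptake_base + self.wm_age_slope * (age - 70.0)


#: Default tracer profiles.  PiB anchors the Centiloid scale; the three 18F
#: tracers differ in dynamic range and in how strongly white-matter uptake
#: drifts with age (largest for florbetaben), which is what drives the
#: pons-vs-WCB Centiloid discrepancies downstream.
DEFAULT_TRACERS: dict[str, TracerProfile] = {
    "PiB": TracerProfile("PiB", 1.05, 2.10, 2.10, 0.0020),
    "FMM": TracerProfile("FMM", 1.25, 2.00, 2.00, 0.0015),
    "FBB": TracerProfile("FBB", 1.08, 1.90, 1.90, 0.0070),
    "FBP": TracerProfile("FBP", 1.05, 1.75, 1.70, 0.0030),
}

ANCHOR_TRACER = "PiB"


@dataclass(frozen=True)
class SubjectParams:
    """Ground truth for one synthetic subject."""

    subject_id: str
    true_cl: float
    age: float
    atrophy: float
    tracer: str
    diagnosis: str
    native_fwhm: float

    def __post_init__(self):
        if not np.isfinite(self.true_cl):
            raise ValueError("true_cl must be finite")
        if not (0.0 < self.atrophy <= 1.0):
            raise ValueError("atrophy must be in (0, 1]")
        if self.native_fwhm < 0:
            raise ValueError("native_fwhm must be >= 0")


def subject_seed(root_seed: int, subject_id: str) -> int:
    """Stable per-subject child seed (< 2**31) from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{subject_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _ellipsoid(shape, voxel_size, center_frac, radii_frac) -> np.ndarray:
    half = voxel_size * (np.asarray(shape, dtype=float) - 1.0) / 2.0
    extent = float(np.min(half))
    coords = [voxel_size * np.arange(n) - h for n, h in zip(shape, half)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = (np.asarray(center_frac) * extent)
    rx, ry, rz = (np.asarray(radii_frac) * extent)
    if min(rx, ry, rz) <= 0:
        return np.zeros(shape, dtype=bool)
    return (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
            + ((zz - cz) / rz) ** 2) <= 1.0


def build_template(spec: PhantomSpec | None = None) -> LabelMap:
    """Deterministically paint the template label map from a spec.

    The cerebellum (and the upper brainstem) are carved out of the cerebral
    mass where they overlap it, so cerebellar grey matter is bounded by
    cerebellar white matter inside and mostly by cerebral tissue outside —
    the adjacency that makes the CGM reference region resolution-sensitive.
    Raises :class:`GeometryError` if the cerebellum and pons overlap each
    other, any compartment leaves the grid, or any required region (including
    all four candidate reference regions) comes out empty.
    """
    spec = spec or PhantomSpec()
    geo = spec.region_geometry
    shape, vx = spec.grid_shape, spec.voxel_size

    def ell(key, shrink=0.0):
        radii = np.asarray(geo[key]["radii"], dtype=float) - shrink
        return _ellipsoid(shape, vx, geo[key]["center"], radii)

    cerebrum_outer = ell("cerebrum")
    cerebrum_inner = ell("cerebrum", geo["cortical_thickness"])
    deep = ell("deep_gm")
    cereb_outer = ell("cerebellum")
    cereb_inner = ell("cerebellum", geo["cerebellar_cortical_thickness"])
    pons = ell("pons")

    if (pons & cereb_outer).any():
        raise GeometryError("pons overlaps the cerebellum")
    if (deep & ~cerebrum_inner).any():
        raise GeometryError("deep grey matter leaves the cerebral core")
    infratentorial = cereb_outer | pons
    compartments = {
        Tissue.CORTICAL_TARGET_GM: (cerebrum_outer & ~cerebrum_inner) & ~infratentorial,
        Tissue.OTHER_GM: deep & ~infratentorial,
        Tissue.CEREBRAL_WM: cerebrum_inner & ~deep & ~infratentorial,
        Tissue.CEREBELLAR_GM: cereb_outer & ~cereb_inner,
        Tissue.CEREBELLAR_WM: cereb_inner,
        Tissue.BRAINSTEM_PONS: pons,
    }
    grid = np.zeros(shape, dtype=np.uint8)
    for label, mask in compartments.items():
        if not mask.any():
            raise GeometryError(f"compartment {label.name} is empty")
        if (mask[0].any() or mask[-1].any() or mask[:, 0].any()
                or mask[:, -1].any() or mask[:, :, 0].any() or mask[:, :, -1].any()):
            raise GeometryError(f"compartment {label.name} touches the grid edge")
        grid[mask] = int(label)
    return LabelMap(grid, vx, grid_affine(shape, vx))


# ---------------------------------------------------------------------------
# subject morphing (atrophy + rigid jitter)
# ---------------------------------------------------------------------------

def morph_subject(template: LabelMap, params: SubjectParams,
                  seed: int | np.random.Generator = 0,
                  jitter_trans_mm: float = 0.5,
                  jitter_rot_deg: float = 0.5) -> tuple[LabelMap, np.ndarray]:
    """Erode grey matter to the requested atrophy level and sample jitter.

    ``params.atrophy`` is the grey-matter volume retained relative to the
    template (equivalently, the subject GM/TIV normalised to the template
    GM/TIV).  Erosion peels GM voxels from the CSF-facing surface inward
    (smallest distance-to-background first, deterministic tie-break), so the
    GM/WM interface is preserved and eroded voxels become CSF/background.
    Returns the morphed label map and the random rigid subject-to-template
    world affine.
    """
    from .transforms import sample_rigid_jitter

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    affine = sample_rigid_jitter(rng, jitter_trans_mm, jitter_rot_deg)

    out = template.copy()
    gm = out.mask(*GM_LABELS)
    n0 = int(gm.sum())
    n_remove = n0 - int(round(params.atrophy * n0))
    if n_remove > 0:
        head = out.grid != int(Tissue.BACKGROUND)
        depth = ndimage.distance_transform_edt(head, sampling=out.voxel_size)
        flat = np.flatnonzero(gm.ravel())
        order = np.lexsort((flat, depth.ravel()[flat]))
        doomed = flat[order[:n_remove]]
        out.grid.ravel()[doomed] = int(Tissue.BACKGROUND)
    for label in (Tissue.CORTICAL_TARGET_GM, Tissue.CEREBELLAR_GM):
        if not (out.grid == int(label)).any():
            raise DegenerateSubjectError(
                f"atrophy {params.atrophy} emptied {label.name}")
    return out, affine


# ---------------------------------------------------------------------------
# uptake simulation
# ---------------------------------------------------------------------------

def compartment_intensities(params: SubjectParams, tracer: TracerProfile,
                            labels: LabelMap) -> dict[Tissue, float]:
    """Noise-free per-compartment intensities (cerebellar GM = 1)."""
    if tracer.name != params.tracer:
        raise ModelParameterError(
            f"tracer profile {tracer.name} does not match subject "
            f"tracer {params.tracer}")
    wm = tracer.wm_uptake(params.age)
    if wm <= 0:
        raise ModelParameterError("white-matter uptake is non-positive")
    n_cgm = labels.count(Tissue.CEREBELLAR_GM)
    n_cwm = labels.count(Tissue.CEREBELLAR_WM)
    wcb_mean = (n_cgm * 1.0 + n_cwm * wm) / (n_cgm + n_cwm)
    target = tracer.suvr_at(params.true_cl) * wcb_mean
    if target <= 0:
        raise ModelParameterError(
            f"target intensity non-positive at true_cl={params.true_cl}")
    return {
        Tissue.CORTICAL_TARGET_GM: target,
        Tissue.OTHER_GM: 1.0,
        Tissue.CEREBRAL_WM: wm,
        Tissue.CEREBELLAR_GM: 1.0,
        Tissue.CEREBELLAR_WM: wm,
        Tissue.BRAINSTEM_PONS: wm,
    }


def simulate_uptake(labels: LabelMap, params: SubjectParams,
                    tracer: TracerProfile,
                    seed: int | np.random.Generator = 0,
                    noise_sd: float | None = None) -> VolumeImage:
    """Piecewise-constant uptake image with per-region multiplicative noise.

    With ``noise_sd`` 0 the ideal target/WCB ratio equals
    ``tracer.suvr_at(params.true_cl)`` exactly by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = tracer.noise_sd if noise_sd is None else noise_sd
    values = compartment_intensities(params, tracer, labels)
    data = np.zeros(labels.grid.shape, dtype=float)
    for label, value in values.items():
        factor = max(1.0 + rng.normal(0.0, sd), 0.0) if sd > 0 else 1.0
        data[labels.grid == int(label)] = value * factor
    return VolumeImage(data, labels.voxel_size, labels.affine.copy(), 0.0)


# ---------------------------------------------------------------------------
# point-spread and harmonization
# ---------------------------------------------------------------------------

def apply_psf(img: VolumeImage, fwhm: float) -> VolumeImage:
    """Isotropic Gaussian smoothing with the stated FWHM (mm).

    The convolution kernel sums to one and uses periodic boundary handling,
    so total intensity is conserved exactly; the phantom keeps a background
    margin that makes wrap-around spill negligible.  The effective resolution
    accumulates in quadrature.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return img.copy()
    sigma_vox = fwhm * GAUSSIAN_FWHM_TO_SIGMA / img.voxel_size
    data = ndimage.gaussian_filter(img.grid, sigma=sigma_vox, mode="wrap")
    new_fwhm = float(np.hypot(img.effective_fwhm, fwhm))
    return VolumeImage(data, img.voxel_size, img.affine.copy(), new_fwhm)


def harmonize_image(img: VolumeImage, target_fwhm: float = 8.0) -> VolumeImage:
    """Smooth to a common effective resolution (quadrature rule).

    Raises :class:`CannotSharpenError` when the image is already coarser than
    the target — resolution cannot be recovered by smoothing.
    """
    if img.effective_fwhm > target_fwhm + 1e-9:
        raise CannotSharpenError(
            f"effective FWHM {img.effective_fwhm:.2f} mm exceeds target "
            f"{target_fwhm:.2f} mm")
    kernel = float(np.sqrt(max(target_fwhm ** 2 - img.effective_fwhm ** 2, 0.0)))
    out = apply_psf(img, kernel)
    out.effective_fwhm = float(target_fwhm)
    return out
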