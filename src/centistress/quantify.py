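"""The 32-variant Centiloid quantification engine.

A pipeline is one combination of reference region (WCB, CGM, Pons,
WCB+BSTM), reference-region delineation (fixed template "GAAIN"-style vs
subject-based), cortical-target delineation (idem), and quantification
space (template/MNI vs subject/native) — 4 x 2 x 2 x 2 = 32 variants.
GAAIN-style masks are template masks whose cortical target is dilated one
voxel into white matter (a template ROI that overlaps WM); subject-based
masks are the subject's own exact tissue masks.  SUVr is the mean target
intensity over the mean reference-region intensity.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import SyntheticCohort
from .errors import AlignmentError, ConfigError, MaskError, MeasurementError
from .phantom import LabelMap, Tissue, VolumeImage
from .transforms import resample

RR_LEVELS = ("WCB", "CGM", "Pons", "WCB_BSTM")
PROVENANCE_LEVELS = ("GAAIN", "subject")
SPACE_LEVELS = ("MNI", "native")


@dataclass(frozen=True)
class PipelineSpec:
    """One quantification configuration."""

    rr: str
    rr_type: str
    t_type: str
    space: str

    def __post_init__(self):
        if self.rr not in RR_LEVELS:
            raise ConfigError(f"unknown reference region {self.rr!r}")
        if self.rr_type not in PROVENANCE_LEVELS or self.t_type not in PROVENANCE_LEVELS:
            raise ConfigError("rr_type/t_type must be 'GAAIN' or 'subject'")
        if self.space not in SPACE_LEVELS:
            raise ConfigError(f"unknown space {self.space!r}")

    @property
    def pipeline_id(self) -> str:
        return f"{self.rr}-{self.rr_type}-{self.t_type}-{self.space}"


#: The standard Centiloid pipeline: whole cerebellum, template masks, MNI.
STANDARD_PIPELINE = PipelineSpec("WCB", "GAAIN", "GAAIN", "MNI")


def enumerate_pipelines(rrs=RR_LEVELS, rr_types=PROVENANCE_LEVELS,
                        t_types=PROVENANCE_LEVELS,
                        spaces=SPACE_LEVELS) -> list[PipelineSpec]:
    """Full (or restricted) factorial of pipeline specs in a fixed order."""
    return [PipelineSpec(rr, rt, tt, sp)
            for rr, rt, tt, sp in itertools.product(rrs, rr_types, t_types, spaces)]


@dataclass
class MaskSet:
    """Binary reference-region and target masks on one grid."""

    masks: dict[str, np.ndarray]        # per RR_LEVELS entry
    target: np.ndarray
    provenance: str
    voxel_size: float
    affine: np.ndarray

    def __post_init__(self):
        for name, mask in {**self.masks, "target": self.target}.items():
            if mask.dtype != bool:
                raise MaskError(f"mask {name} is not binary")
            if not mask.any():
                raise MaskError(f"mask {name} is empty")

    def rr_mask(self, rr: str) -> np.ndarray:
        if rr not in self.masks:
            raise MaskError(f"no mask for reference region {rr!r}")
        return self.masks[rr]


def _rr_masks(labels: LabelMap) -> dict[str, np.ndarray]:
    cgm = labels.mask(Tissue.CEREBELLAR_GM)
    wcb = labels.mask(Tissue.CEREBELLAR_GM, Tissue.CEREBELLAR_WM)
    pons = labels.mask(Tissue.BRAINSTEM_PONS)
    return {"WCB": wcb, "CGM": cgm, "Pons": pons, "WCB_BSTM": wcb | pons}


def template_masks(template: LabelMap) -> MaskSet:
    """GAAIN-style masks: template regions, target dilated one voxel into WM."""
    core = template.mask(Tissue.CORTICAL_TARGET_GM)
    dilated = ndimage.binary_dilation(
        core, structure=ndimage.generate_binary_structure(3, 1))
    target = core | (dilated & template.mask(Tissue.CEREBRAL_WM))
    return MaskSet(_rr_masks(template), target, "GAAIN",
                   template.voxel_size, template.affine.copy())


def subject_masks(subject_labels: LabelMap) -> MaskSet:
    """Subject-based masks: the subject's own exact tissue masks."""
    return MaskSet(_rr_masks(subject_labels),
                   subject_labels.mask(Tissue.CORTICAL_TARGET_GM), "subject",
                   subject_labels.voxel_size, subject_labels.affine.copy())


def to_quant_space(img: VolumeImage, masks: MaskSet, space: str,
                   affine: np.ndarray) -> tuple[VolumeImage, MaskSet]:
    """Bring image and masks onto a common grid for one quantification space.

    ``affine`` is the recorded rigid subject-to-template world transform.
    MNI space resamples the image onto the template grid (trilinear) and
    keeps the masks; native space resamples the masks onto the subject grid
    (nearest neighbour) and keeps the image.
    """
    if space == "MNI":
        inv = np.linalg.inv(affine)
        data = resample(img.grid, img.affine, inv, masks.affine,
                        masks.target.shape, order=1)
        out_img = VolumeImage(data, masks.voxel_size, masks.affine.copy(),
                              img.effective_fwhm)
        return out_img, masks
    if space == "native":
        new_masks = {name: resample(m, masks.affine, affine, img.affine,
                                    img.grid.shape, order=0)
                     for name, m in masks.masks.items()}
        target = resample(masks.target, masks.affine, affine, img.affine,
                          img.grid.shape, order=0)
        return img, MaskSet(new_masks, target, masks.provenance,
                            img.voxel_size, img.affine.copy())
    raise ConfigError(f"unknown space {space!r}")


def compute_suvr(img: VolumeImage, target_mask: np.ndarray,
                 rr_mask: np.ndarray) -> float:
    """Mean target intensity divided by mean reference-region intensity."""
    if img.grid.shape != target_mask.shape or img.grid.shape != rr_mask.shape:
        raise AlignmentError("image and mask grids do not match")
    if not target_mask.any() or not rr_mask.any():
        raise MaskError("empty mask in SUVr computation")
    rr_mean = float(img.grid[rr_mask].mean())
    if rr_mean <= 0:
        raise MeasurementError(f"non-positive reference mean {rr_mean}")
    return float(img.grid[target_mask].mean()) / rr_mean


class _SubjectQuantifier:
    """Caches per-subject resampled images/masks shared across pipelines."""

    def __init__(self, template_set: MaskSet, subject_set: MaskSet,
                 affine: np.ndarray):
        self._sets = {"GAAIN": template_set, "subject": subject_set}
        self._affine = affine
        self._cache: dict = {}

    def _in_space(self, img: VolumeImage, provenance: str, space: str,
                  img_key) -> tuple[VolumeImage, MaskSet]:
        key = (img_key, provenance, space)
        if key not in self._cache:
            self._cache[key] = to_quant_space(
                img, self._sets[provenance], space, self._affine)
        return self._cache[key]

    def suvr(self, img: VolumeImage, spec: PipelineSpec, img_key) -> float:
        q_img, rr_set = self._in_space(img, spec.rr_type, spec.space, img_key)
        _, t_set = self._in_space(img, spec.t_type, spec.space, img_key)
        return compute_suvr(q_img, t_set.target, rr_set.rr_mask(spec.rr))


LONG_TABLE_COLUMNS = [
    "subject_id", "tracer", "diagnosis", "age", "atrophy", "true_cl",
    "native_fwhm", "harmonized", "rr", "rr_type", "t_type", "space",
    "pipeline_id", "suvr", "cl", "group",
]


def quantify_cohort(cohort: SyntheticCohort, pipelines: list[PipelineSpec],
                    calib_bank) -> pd.DataFrame:
    """Quantify every subject image with every pipeline into a long table.

    One row per subject x pipeline x harmonization status; subjects with
    both image versions contribute ``2 * len(pipelines)`` rows.  Raises
    :class:`ConfigError` when the calibration bank lacks an entry for a
    (tracer, pipeline) combination in use.
    """
    if calib_bank is not None:
        for params in cohort.subjects:
            for spec in pipelines:
                if not calib_bank.has(params.tracer, spec.pipeline_id):
                    raise ConfigError(
                        f"no calibration for ({params.tracer}, "
                        f"{spec.pipeline_id})")
    tmpl_set = template_masks(cohort.template)
    truth = cohort.truth.set_index("subject_id")
    rows = []
    for params in cohort.subjects:
        sid = params.subject_id
        quant = _SubjectQuantifier(tmpl_set,
                                   subject_masks(cohort.labels[sid]),
                                   cohort.affines[sid])
        info = truth.loc[sid]
        for harmonized, img in ((False, cohort.images[sid]["original"]),
                                (True, cohort.images[sid]["harmonized"])):
            if img is None:
                continue
            for spec in pipelines:
                suvr = quant.suvr(img, spec, harmonized)
                cl = (calib_bank.cl_from_suvr(params.tracer, spec.pipeline_id,
                                              suvr)
                      if calib_bank is not None else np.nan)
                rows.append((sid, params.tracer, params.diagnosis, params.age,
                             params.atrophy, params.true_cl,
                             params.native_fwhm, harmonized, spec.rr,
                             spec.rr_type, spec.t_type, spec.space,
                             spec.pipeline_id, suvr, cl, info["group"]))
    return pd.DataFrame(rows, columns=LONG_TABLE_COLUMNS)
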