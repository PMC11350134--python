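"""Synthetic cohort generation.

Draws per-subject ground truth (amyloid load, age, atrophy, tracer,
diagnosis, scanner resolution) from a configurable mixture that mimics a
memory-clinic population, then renders each subject's PET-like images at
native resolution and harmonized to a common 8 mm effective resolution.
Subjects scanned with the florbetapir-like tracer carry only a harmonized
image (mirroring a cohort whose original scans are unavailable), so the
full run yields 64 measurements for dual-image subjects and 32 otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .phantom import (DEFAULT_TRACERS, LabelMap, PhantomSpec, SubjectParams,
                      TracerProfile, VolumeImage, apply_psf, build_template,
                      harmonize_image, morph_subject, simulate_uptake,
                      subject_seed)
from .transforms import resample

DIAGNOSES = ("SCD", "MCI", "dementia")
POSITIVITY_CUTOFF_CL = 24.0


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate the composition of a memory-clinic amyloid-PET sample:
    roughly half amyloid-positive, ages ~71 +/- 7, three 18F tracers with
    the flutemetamol/florbetaben arms contributing both original and
    harmonized scans, atrophy coupled to clinical stage, and scanner
    point-spread between 5 and 8 mm harmonized to 8 mm.
    """

    n_subjects: int = 60
    group_mix: float = 0.5                      # fraction amyloid-positive
    cl_negative: tuple[float, float] = (2.0, 10.0)   # true-CL mean, SD
    cl_positive: tuple[float, float] = (78.0, 25.0)
    age_mean: float = 71.0
    age_sd: float = 6.7
    age_range: tuple[float, float] = (50.0, 90.0)
    atrophy_by_diagnosis: dict = field(default_factory=lambda: {
        "SCD": (0.96, 0.02), "MCI": (0.91, 0.03), "dementia": (0.85, 0.04)})
    atrophy_range: tuple[float, float] = (0.72, 1.0)
    diagnosis_probs_negative: tuple[float, float, float] = (0.45, 0.45, 0.10)
    diagnosis_probs_positive: tuple[float, float, float] = (0.20, 0.45, 0.35)
    tracer_fractions: dict = field(default_factory=lambda: {
        "FMM": 0.39, "FBB": 0.23, "FBP": 0.38})
    dual_image_tracers: tuple[str, ...] = ("FMM", "FBB")
    native_fwhm_range: tuple[float, float] = (5.0, 8.0)
    harmonized_fwhm: float = 8.0
    jitter_trans_mm: float = 0.5
    jitter_rot_deg: float = 0.5
    noise_sd: float | None = None               # None -> per-tracer default
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        grid_shape=(48, 48, 48)))
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not (0.0 <= self.group_mix <= 1.0):
            raise ConfigError("group_mix must lie in [0, 1]")
        total = sum(self.tracer_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("tracer allocation fractions must sum to 1")
        for probs in (self.diagnosis_probs_negative, self.diagnosis_probs_positive):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ConfigError("diagnosis probabilities must be a distribution")
        lo, hi = self.native_fwhm_range
        if not (0.0 <= lo <= hi <= self.harmonized_fwhm):
            raise ConfigError(
                "native FWHM range must lie within [0, harmonized_fwhm]")


@dataclass
class SyntheticCohort:
    """A generated cohort: template, per-subject truth, labels and images."""

    template: LabelMap
    subjects: list[SubjectParams]
    labels: dict[str, LabelMap]
    affines: dict[str, np.ndarray]              # subject -> template (world)
    images: dict[str, dict[str, VolumeImage | None]]
    truth: pd.DataFrame
    tracers: dict[str, TracerProfile]
    config: CohortConfig


def draw_subjects(cfg: CohortConfig, seed: int | None = None) -> list[SubjectParams]:
    """Sample per-subject ground-truth parameters (no imaging)."""
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    tracer_names = list(cfg.tracer_fractions)
    tracer_p = np.array([cfg.tracer_fractions[t] for t in tracer_names])
    subjects = []
    for i in range(cfg.n_subjects):
        positive = rng.random() < cfg.group_mix
        mean, sd = cfg.cl_positive if positive else cfg.cl_negative
        true_cl = rng.normal(mean, sd)
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), *cfg.age_range))
        probs = (cfg.diagnosis_probs_positive if positive
                 else cfg.diagnosis_probs_negative)
        diagnosis = DIAGNOSES[rng.choice(3, p=probs)]
        a_mean, a_sd = cfg.atrophy_by_diagnosis[diagnosis]
        atrophy = float(np.clip(rng.normal(a_mean, a_sd), *cfg.atrophy_range))
        tracer = tracer_names[rng.choice(len(tracer_names), p=tracer_p)]
        fwhm = float(rng.uniform(*cfg.native_fwhm_range))
        subjects.append(SubjectParams(
            subject_id=f"S{i:04d}", true_cl=float(true_cl), age=age,
            atrophy=atrophy, tracer=tracer, diagnosis=diagnosis,
            native_fwhm=fwhm))
    return subjects


def truth_table(subjects: list[SubjectParams]) -> pd.DataFrame:
    """Ground-truth table; ``group`` is assigned from noise-free true CL."""
    rows = [{
        "subject_id": s.subject_id, "tracer": s.tracer,
        "diagnosis": s.diagnosis, "age": s.age, "atrophy": s.atrophy,
        "true_cl": s.true_cl, "native_fwhm": s.native_fwhm,
        "group": "positive" if s.true_cl > POSITIVITY_CUTOFF_CL else "negative",
    } for s in subjects]
    return pd.DataFrame(rows)


def _render_subject(template: LabelMap, params: SubjectParams,
                    tracer: TracerProfile, cfg: CohortConfig,
                    rng: np.random.Generator):
    labels, affine = morph_subject(template, params, rng,
                                   cfg.jitter_trans_mm, cfg.jitter_rot_deg)
    uptake = simulate_uptake(labels, params, tracer, rng, noise_sd=cfg.noise_sd)
    # place the scan on the subject's native grid (inverse rigid motion)
    native_data = resample(uptake.grid, template.affine, affine,
                           template.affine, uptake.grid.shape, order=1)
    native = VolumeImage(native_data, uptake.voxel_size,
                         template.affine.copy(), 0.0)
    original = apply_psf(native, params.native_fwhm)
    harmonized = harmonize_image(original, cfg.harmonized_fwhm)
    return labels, affine, original, harmonized


def generate_cohort(cfg: CohortConfig | None = None,
                    seed: int | None = None,
                    tracers: dict[str, TracerProfile] | None = None) -> SyntheticCohort:
    """Generate a reproducible cohort of phantom subjects and images.

    Every subject derives its own RNG from a stable hash of the root seed
    and subject id, so any subset of subjects is reproducible in isolation.
    """
    cfg = cfg or CohortConfig()
    root = cfg.rng_seed if seed is None else seed
    tracers = tracers or DEFAULT_TRACERS
    for name in cfg.tracer_fractions:
        if name not in tracers:
            raise ConfigError(f"no tracer profile for {name!r}")
    template = build_template(cfg.phantom)
    subjects = draw_subjects(cfg, root)
    labels, affines, images = {}, {}, {}
    for params in subjects:
        rng = np.random.default_rng(subject_seed(root, params.subject_id))
        lab, aff, original, harmonized = _render_subject(
            template, params, tracers[params.tracer], cfg, rng)
        labels[params.subject_id] = lab
        affines[params.subject_id] = aff
        images[params.subject_id] = {
            "original": original if params.tracer in cfg.dual_image_tracers else None,
            "harmonized": harmonized,
        }
    return SyntheticCohort(template, subjects, labels, affines, images,
                           truth_table(subjects), dict(tracers), cfg)
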