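"""Centiloid anchoring and level-2 tracer calibration.

The Centiloid scale is an affine rescaling of SUVr fixed by two anchor
groups: a young-control group defining 0 CL and a typical-AD group defining
100 CL, both measured with the anchor tracer (PiB).  Each 18F tracer is
brought onto the scale through a "level-2" linear conversion fitted by
ordinary least squares of PiB SUVr on tracer SUVr over paired measurements.
Calibration is repeated for every pipeline, so each (tracer, pipeline) pair
owns its conversion equation and the two anchor points map to 0 and 100 CL
exactly by construction.

Calibration data are simulated phantom scans (recorded as such in the
reports): paired tracer/PiB images over a grid of true amyloid loads, with
age ramping from the young-control age at 0 CL to the typical-AD age at
100 CL so that age-dependent white-matter uptake enters the conversion the
way elderly reference subjects would.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, ConfigError, FitError
from .phantom import (ANCHOR_TRACER, DEFAULT_TRACERS, LabelMap, SubjectParams,
                      TracerProfile, apply_psf, simulate_uptake)
from .quantify import (PipelineSpec, _SubjectQuantifier, subject_masks,
                       template_masks)


@dataclass(frozen=True)
class Anchors:
    """Mean anchor-group SUVrs defining the 0 and 100 CL points."""

    suvr_yc_mean: float
    suvr_ad_mean: float
    pipeline_id: str = ""
    tracer: str = ANCHOR_TRACER

    def __post_init__(self):
        if not self.suvr_ad_mean > self.suvr_yc_mean:
            raise CalibrationError(
                f"AD anchor mean ({self.suvr_ad_mean}) must exceed "
                f"YC anchor mean ({self.suvr_yc_mean})")


def fit_anchors(yc_suvrs, ad_suvrs, pipeline_id: str = "",
                tracer: str = ANCHOR_TRACER) -> Anchors:
    """Anchor the CL scale at the two calibration-group means."""
    yc, ad = np.asarray(yc_suvrs, float), np.asarray(ad_suvrs, float)
    if yc.size == 0 or ad.size == 0:
        raise CalibrationError("anchor groups must be non-empty")
    return Anchors(float(yc.mean()), float(ad.mean()), pipeline_id, tracer)


def suvr_to_cl(suvr, anchors: Anchors):
    """Linear SUVr -> CL map: YC mean -> 0, AD mean -> 100."""
    span = anchors.suvr_ad_mean - anchors.suvr_yc_mean
    return 100.0 * (np.asarray(suvr, float) - anchors.suvr_yc_mean) / span


@dataclass(frozen=True)
class ConversionEq:
    """Linear map from tracer SUVr to PiB-equivalent SUVr."""

    slope: float
    intercept: float
    r2: float
    n_pairs: int

    def apply(self, suvr):
        return self.slope * np.asarray(suvr, float) + self.intercept


def fit_level2(tracer_suvrs, pib_suvrs) -> ConversionEq:
    """OLS of PiB SUVr on tracer SUVr over paired calibration scans."""
    x = np.asarray(tracer_suvrs, float)
    y = np.asarray(pib_suvrs, float)
    if x.size != y.size:
        raise FitError("paired SUVr lists must have equal length")
    if x.size < 3:
        raise FitError("need at least 3 calibration pairs")
    if np.ptp(x) == 0:
        raise FitError("zero variance in tracer SUVr")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    # guard the degenerate no-spread-in-y case linregress maps to r=0
    r2 = 1.0 if np.allclose(resid, 0.0, atol=1e-12) else float(res.rvalue ** 2)
    return ConversionEq(float(res.slope), float(res.intercept), r2, int(x.size))


@dataclass
class CalibrationReport:
    """Named pass/fail checks of the standard calibration criteria."""

    tracer: str
    pipeline_id: str
    anchors: Anchors
    conversion: ConversionEq
    criteria: dict[str, bool]
    overall: bool


def validate_calibration(eq: ConversionEq, tracer: str = "",
                         pipeline_id: str = "", anchors: Anchors | None = None,
                         min_r2: float = 0.70,
                         min_pairs: int = 3) -> CalibrationReport:
    """Apply the standard acceptance checks to a fitted conversion."""
    criteria = {
        f"r2 > {min_r2:.2f}": eq.r2 > min_r2,
        "slope > 0": eq.slope > 0,
        f"n_pairs >= {min_pairs}": eq.n_pairs >= min_pairs,
    }
    return CalibrationReport(tracer, pipeline_id, anchors, eq, criteria,
                             all(criteria.values()))


@dataclass(frozen=True)
class CalibrationConfig:
    """Conditions of the simulated calibration scans."""

    cl_levels: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0)
    yc_age: float = 25.0
    ad_age: float = 70.0
    fwhm: float = 8.0            # effective resolution of calibration scans
    noise_sd: float = 0.0        # zero-noise mode by default
    n_per_level: int = 2

    @classmethod
    def ideal(cls) -> "CalibrationConfig":
        """Noise-free, PSF-free, age-matched conditions.

        Under these conditions the SUVr of every pipeline is exactly affine
        in true CL, so the calibrated chain returns true CL to machine
        precision for matched subjects — the exactness baseline.
        """
        return cls(yc_age=70.0, ad_age=70.0, fwhm=0.0, noise_sd=0.0)

    def age_at(self, cl: float) -> float:
        return self.yc_age + (self.ad_age - self.yc_age) * cl / 100.0


@dataclass
class CalibrationEntry:
    """Everything needed to turn one (tracer, pipeline) SUVr into CL."""

    tracer: str
    pipeline_id: str
    anchors: Anchors
    conversion: ConversionEq
    report: CalibrationReport

    def cl_from_suvr(self, suvr):
        return suvr_to_cl(self.conversion.apply(suvr), self.anchors)


class CalibrationBank:
    """Per-(tracer, pipeline) conversion equations with JSON persistence."""

    def __init__(self, entries: dict[tuple[str, str], CalibrationEntry]):
        self.entries = entries

    def has(self, tracer: str, pipeline_id: str) -> bool:
        return (tracer, pipeline_id) in self.entries

    def get(self, tracer: str, pipeline_id: str) -> CalibrationEntry:
        try:
            return self.entries[(tracer, pipeline_id)]
        except KeyError:
            raise ConfigError(
                f"no calibration for ({tracer}, {pipeline_id})") from None

    def cl_from_suvr(self, tracer: str, pipeline_id: str, suvr):
        return float(self.get(tracer, pipeline_id).cl_from_suvr(suvr))

    def to_json(self) -> str:
        payload = []
        for (tracer, pid), e in sorted(self.entries.items()):
            payload.append({
                "tracer": tracer, "pipeline_id": pid,
                "anchors": asdict(e.anchors),
                "slope": e.conversion.slope,
                "intercept": e.conversion.intercept,
                "r2": e.conversion.r2, "n": e.conversion.n_pairs,
                "criteria": e.report.criteria, "overall": e.report.overall,
                "provenance": "simulated phantom calibration",
            })
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationBank":
        entries = {}
        for item in json.loads(text):
            anchors = Anchors(**item["anchors"])
            eq = ConversionEq(item["slope"], item["intercept"], item["r2"],
                              item["n"])
            report = CalibrationReport(item["tracer"], item["pipeline_id"],
                                       anchors, eq, item["criteria"],
                                       item["overall"])
            entries[(item["tracer"], item["pipeline_id"])] = CalibrationEntry(
                item["tracer"], item["pipeline_id"], anchors, eq, report)
        return cls(entries)


def _calibration_suvrs(template: LabelMap, pipelines: list[PipelineSpec],
                       tracer: TracerProfile, cfg: CalibrationConfig,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """SUVr per pipeline over the calibration grid (levels x replicates)."""
    tmpl_set = template_masks(template)
    subj_set = subject_masks(template)      # atrophy-free calibration subjects
    out = {spec.pipeline_id: [] for spec in pipelines}
    for cl in cfg.cl_levels:
        for rep in range(cfg.n_per_level):
            params = SubjectParams(
                subject_id=f"calib-{tracer.name}-{cl:g}-{rep}", true_cl=cl,
                age=cfg.age_at(cl), atrophy=1.0, tracer=tracer.name,
                diagnosis="SCD", native_fwhm=cfg.fwhm)
            img = simulate_uptake(template, params, tracer, rng,
                                  noise_sd=cfg.noise_sd)
            if cfg.fwhm > 0:
                img = apply_psf(img, cfg.fwhm)
            quant = _SubjectQuantifier(tmpl_set, subj_set, np.eye(4))
            for spec in pipelines:
                out[spec.pipeline_id].append(quant.suvr(img, spec, (cl, rep)))
    return {pid: np.asarray(v) for pid, v in out.items()}


def calibrate(template: LabelMap, pipelines: list[PipelineSpec],
              tracers: dict[str, TracerProfile] | None = None,
              config: CalibrationConfig | None = None,
              seed: int = 0) -> CalibrationBank:
    """Build the full calibration bank from simulated phantom scans."""
    tracers = tracers or DEFAULT_TRACERS
    cfg = config or CalibrationConfig()
    if ANCHOR_TRACER not in tracers:
        raise ConfigError(f"anchor tracer {ANCHOR_TRACER!r} missing")
    rng = np.random.default_rng(seed)
    suvrs = {name: _calibration_suvrs(template, pipelines, profile, cfg, rng)
             for name, profile in tracers.items()}

    yc_idx = [i for i, cl in enumerate(np.repeat(cfg.cl_levels, cfg.n_per_level))
              if cl == 0.0]
    ad_idx = [i for i, cl in enumerate(np.repeat(cfg.cl_levels, cfg.n_per_level))
              if cl == 100.0]
    if not yc_idx or not ad_idx:
        raise ConfigError("calibration cl_levels must include 0 and 100")

    entries = {}
    for spec in pipelines:
        pid = spec.pipeline_id
        pib = suvrs[ANCHOR_TRACER][pid]
        for name in tracers:
            eq = fit_level2(suvrs[name][pid], pib)
            # anchor each tracer at its own converted group means so the
            # calibration sets map to exactly 0 and 100 CL by construction
            converted = eq.apply(suvrs[name][pid])
            anchors = fit_anchors(converted[yc_idx], converted[ad_idx], pid,
                                  tracer=name)
            report = validate_calibration(eq, name, pid, anchors)
            entries[(name, pid)] = CalibrationEntry(name, pid, anchors, eq,
                                                    report)
    return CalibrationBank(entries)
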