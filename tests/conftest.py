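"""Shared fixtures: one small template, calibration banks and one image
cohort reused across the whole suite (session-scoped because image-level
simulation dominates test runtime)."""
import numpy as np
import pytest

import centistress as cs
from centistress.cohort import SyntheticCohort, truth_table
from centistress.phantom import PhantomSpec, SubjectParams, build_template


@pytest.fixture(scope="session")
def template48():
    return build_template(PhantomSpec(grid_shape=(48, 48, 48)))


@pytest.fixture(scope="session")
def pipelines():
    return cs.enumerate_pipelines()


@pytest.fixture(scope="session")
def ideal_bank(template48, pipelines):
    """Noise-free, PSF-free, age-matched calibration (exactness baseline)."""
    return cs.calibrate(template48, pipelines,
                        config=cs.CalibrationConfig.ideal(), seed=5)


@pytest.fixture(scope="session")
def default_bank(template48, pipelines):
    """Realistic calibration: 8 mm scans, young controls aged 25."""
    return cs.calibrate(template48, pipelines,
                        config=cs.CalibrationConfig(), seed=5)


@pytest.fixture(scope="session")
def image_cohort():
    """The default image-level study cohort (60 subjects, 48^3 grid)."""
    return cs.generate_cohort(cs.CohortConfig(n_subjects=60, rng_seed=11))


@pytest.fixture(scope="session")
def cohort_table(image_cohort, pipelines):
    """Long table of the default cohort under realistic calibration."""
    bank = cs.calibrate(image_cohort.template, pipelines,
                        image_cohort.tracers, cs.CalibrationConfig(), seed=5)
    return cs.quantify_cohort(image_cohort, pipelines, bank)


def single_subject_cohort(template, params: SubjectParams,
                          image: cs.VolumeImage, dual: bool = True,
                          labels=None) -> SyntheticCohort:
    """Minimal cohort wrapper around one explicit subject image."""
    sid = params.subject_id
    return SyntheticCohort(
        template=template, subjects=[params],
        labels={sid: labels if labels is not None else template},
        affines={sid: np.eye(4)},
        images={sid: {"original": image if dual else None,
                      "harmonized": image}},
        truth=truth_table([params]), tracers=dict(cs.DEFAULT_TRACERS),
        config=cs.CohortConfig(n_subjects=1))
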