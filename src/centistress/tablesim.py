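"""Table-level measurement simulator (no imaging).

Generates long-format CL tables with known additive pipeline-factor
offsets, subject random effects and residual noise.  This is the ground
truth used to validate the statistical battery: a fitted model should
recover the injected offsets, and null factors should reject at the
nominal rate.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import (PROVENANCE_LEVELS, RR_LEVELS, SPACE_LEVELS,
                       enumerate_pipelines)

_LEVELS = {"rr": RR_LEVELS, "rr_type": PROVENANCE_LEVELS,
           "t_type": PROVENANCE_LEVELS, "space": SPACE_LEVELS,
           "harmonized": (False, True)}


def simulate_long_table(n_subjects: int = 300,
                        offsets: dict[str, dict] | None = None,
                        base_mean: float = 0.0,
                        subject_sd: float = 15.0,
                        noise_sd: float = 3.0,
                        tracer_fractions: dict[str, float] | None = None,
                        harmonized_only: bool = True,
                        seed: int = 0) -> pd.DataFrame:
    """Long table with additive factor offsets.

    ``offsets`` maps factor name -> {level: CL offset}; omitted levels get
    0.  The response is base + subject effect + sum of offsets + noise,
    independent across rows given the subject effect.
    """
    rng = np.random.default_rng(seed)
    offsets = offsets or {}
    tracer_fractions = tracer_fractions or {"FMM": 0.39, "FBB": 0.23,
                                            "FBP": 0.38}
    tracers = list(tracer_fractions)
    probs = np.array([tracer_fractions[t] for t in tracers])
    pipelines = enumerate_pipelines()
    harm_levels = (True,) if harmonized_only else (False, True)

    rows = []
    for i in range(n_subjects):
        sid = f"T{i:04d}"
        subject_effect = rng.normal(0.0, subject_sd)
        tracer = tracers[rng.choice(len(tracers), p=probs)]
        age = float(np.clip(rng.normal(71.0, 6.7), 50, 90))
        atrophy = float(np.clip(rng.normal(0.9, 0.05), 0.72, 1.0))
        diagnosis = ["SCD", "MCI", "dementia"][rng.choice(3)]
        for harmonized in harm_levels:
            for spec in pipelines:
                setting = {"rr": spec.rr, "rr_type": spec.rr_type,
                           "t_type": spec.t_type, "space": spec.space,
                           "harmonized": harmonized, "tracer": tracer}
                shift = sum(offsets.get(f, {}).get(lv, 0.0)
                            for f, lv in setting.items())
                cl = (base_mean + subject_effect + shift
                      + rng.normal(0.0, noise_sd))
                rows.append((sid, tracer, diagnosis, age, atrophy, np.nan,
                             np.nan, harmonized, spec.rr, spec.rr_type,
                             spec.t_type, spec.space, spec.pipeline_id,
                             np.nan, cl,
                             "positive" if base_mean > 24 else "negative"))
    from .quantify import LONG_TABLE_COLUMNS
    return pd.DataFrame(rows, columns=LONG_TABLE_COLUMNS)


def simulate_two_way_table(n_subjects: int = 500, n_pipelines: int = 32,
                           grand_mean: float = 10.0, subject_sd: float = 20.0,
                           between_sd: float = 3.0, within_sd: float = 1.5,
                           seed: int = 0) -> pd.DataFrame:
    """Additive subject x pipeline table with known variance components."""
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, subject_sd, size=n_subjects)
    pipe = rng.normal(0.0, between_sd, size=n_pipelines)
    eps = rng.normal(0.0, within_sd, size=(n_subjects, n_pipelines))
    cl = grand_mean + subj[:, None] + pipe[None, :] + eps
    ids = [f"P{j:02d}" for j in range(n_pipelines)]
    frames = pd.DataFrame(cl, columns=ids)
    frames["subject_id"] = [f"T{i:04d}" for i in range(n_subjects)]
    long = frames.melt(id_vars="subject_id", var_name="pipeline_id",
                       value_name="cl")
    long["harmonized"] = True
    return long
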