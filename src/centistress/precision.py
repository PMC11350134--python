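"""Precision model: pipeline variance decomposition, ICC, Bland–Altman.

Within-pipeline variability is the subject-by-pipeline residual left after
removing subject and pipeline main effects from the long table; between-
pipeline variability is the spread of the pipeline effects themselves.
Both are reported as 95% half-widths (1.96 SD) per amyloid stratum, and the
within-pipeline half-width is linearly interpolated between the stratum
mean CLs to estimate confidence intervals at clinically used positivity
cutoffs (CL = 12 and CL = 24).  Agreement of measurements before and after
harmonization is quantified with ICC(2,1) (two-way random effects, absolute
agreement, single measurement) and Bland–Altman statistics of the
harmonized-minus-original differences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

from .errors import InsufficientDataError, InterpolationError

Z95 = 1.959963984540054


@dataclass
class PrecisionResult:
    """Variance decomposition of one stratum's long table."""

    stratum: str
    within_sd: float
    between_sd: float
    within_ci_halfwidth: float
    between_ci_halfwidth: float
    stratum_mean_cl: float
    n_subjects: int
    n_pipelines: int


def variance_decomposition(table: pd.DataFrame, stratum: str = "",
                           value: str = "cl",
                           strict: bool = False,
                           method: str = "moments") -> PrecisionResult:
    """Two-way additive decomposition CL = mu + subject + pipeline + resid.

    ``between_sd`` is the SD (ddof=1) of the pipeline effects; ``within_sd``
    is the root mean square of the interaction residuals on their
    (I-1)(J-1) degrees of freedom.  Requires a single harmonization status;
    missing cells are imputed additively with a warning (or rejected with
    ``strict``).  ``method='gee'`` cross-checks the pipeline effects via GEE
    marginal means instead of raw pipeline means.
    """
    if "harmonized" in table.columns and table["harmonized"].nunique() > 1:
        raise InsufficientDataError(
            "mixed harmonization statuses; filter to one before decomposing")
    wide = table.pivot_table(index="subject_id", columns="pipeline_id",
                             values=value, aggfunc="mean")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 pipelines")
    x = wide.to_numpy(dtype=float)
    if np.isnan(x).any():
        if strict:
            raise InsufficientDataError("unbalanced table (missing cells)")
        warnings.warn("missing cells imputed with subject+pipeline means")
        grand = np.nanmean(x)
        fill = (np.nanmean(x, axis=1, keepdims=True)
                + np.nanmean(x, axis=0, keepdims=True) - grand)
        x = np.where(np.isnan(x), fill, x)
    grand = x.mean()
    subj = x.mean(axis=1, keepdims=True)
    if method == "gee":
        pipe_effects = _gee_pipeline_effects(table, value) - grand
        pipe = (pipe_effects + grand)[np.newaxis, :]
    elif method == "moments":
        pipe = x.mean(axis=0, keepdims=True)
        pipe_effects = (pipe - grand).ravel()
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = x - subj - pipe + grand
    n_i, n_j = x.shape
    within_sd = float(np.sqrt((resid ** 2).sum() / ((n_i - 1) * (n_j - 1))))
    between_sd = float(np.std(pipe_effects, ddof=1))
    return PrecisionResult(stratum, within_sd, between_sd,
                           Z95 * within_sd, Z95 * between_sd,
                           float(grand), n_i, n_j)


def _gee_pipeline_effects(table: pd.DataFrame, value: str) -> np.ndarray:
    """Pipeline marginal means from a CL ~ pipeline GEE (cross-check mode)."""
    from .bias import ModelSpec, fit_gee, marginal_means

    spec = ModelSpec(response=value, between_factors=(),
                     within_factors=("pipeline_id",), interactions=())
    fit = fit_gee(table, spec)
    return np.asarray(marginal_means(fit, "pipeline_id").estimates)


@dataclass
class InterpolatedCI:
    """CI half-width read off the line through the two stratum anchors."""

    cl: float
    halfwidth: float
    extrapolated: bool


def interpolate_ci(neg: PrecisionResult, pos: PrecisionResult,
                   cl_value: float, which: str = "within") -> InterpolatedCI:
    """Linear interpolation of the CI half-width at a given CL value.

    Anchors are (stratum mean CL, stratum CI half-width) of the negative
    and positive strata; values outside the anchor interval extrapolate
    linearly and are flagged.
    """
    x0, x1 = neg.stratum_mean_cl, pos.stratum_mean_cl
    if not x0 < x1:
        raise InterpolationError(
            f"anchor CLs must be increasing (got {x0}, {x1})")
    y0, y1 = ((neg.within_ci_halfwidth, pos.within_ci_halfwidth)
              if which == "within"
              else (neg.between_ci_halfwidth, pos.between_ci_halfwidth))
    slope = (y1 - y0) / (x1 - x0)
    return InterpolatedCI(float(cl_value), float(y0 + slope * (cl_value - x0)),
                          bool(cl_value < x0 or cl_value > x1))


def ci_profile(neg: PrecisionResult, pos: PrecisionResult,
               cl_values=(12.0, 24.0)) -> pd.DataFrame:
    """Within-pipeline CI half-widths at the requested CL cutoffs."""
    rows = [vars(interpolate_ci(neg, pos, c)) for c in cl_values]
    return pd.DataFrame(rows)


@dataclass
class ICCResult:
    icc: float
    p: float
    n: int
    degenerate: bool


def icc_agreement(first, second) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``first``/``second`` are paired CL lists (e.g. original and harmonized
    measurements of the same subjects).  Identical pairs with zero spread
    are a degenerate case reported as ICC 1.
    """
    a = np.asarray(first, float)
    b = np.asarray(second, float)
    if a.size != b.size:
        raise InsufficientDataError("paired lists must have equal length")
    if a.size < 3:
        raise InsufficientDataError("need at least 3 pairs for ICC")
    if np.ptp(np.concatenate([a, b])) == 0:
        return ICCResult(1.0, 0.0, int(a.size), True)
    data = pd.DataFrame({
        "target": np.tile(np.arange(a.size), 2),
        "rater": np.repeat(["first", "second"], a.size),
        "score": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc = pg.intraclass_corr(data=data, targets="target", raters="rater",
                                 ratings="score")
    row = icc.set_index("Type").loc["ICC(A,1)"]  # two-way random, absolute
    return ICCResult(float(row["ICC"]), float(row["pval"]), int(a.size), False)


@dataclass
class AgreementResult:
    """Bland–Altman agreement of paired measurements (second - first)."""

    mean_diff: float
    sd_diff: float
    ci_of_mean: tuple[float, float]
    limits_of_agreement: tuple[float, float]
    icc: float | None
    n_pairs: int


def bland_altman(first, second) -> AgreementResult:
    """Bland–Altman statistics of the differences ``second - first``.

    For harmonization analyses pass (original, harmonized) so the sign
    convention matches harmonized-minus-original.
    """
    a = np.asarray(first, float)
    b = np.asarray(second, float)
    if a.size != b.size or a.size < 2:
        raise InsufficientDataError("need >= 2 pairs of equal length")
    d = b - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = Z95 * sd
    ci = (mean - Z95 * sd / np.sqrt(d.size), mean + Z95 * sd / np.sqrt(d.size))
    icc = icc_agreement(a, b).icc if a.size >= 3 else None
    return AgreementResult(mean, sd, (float(ci[0]), float(ci[1])),
                           (mean - half, mean + half), icc, int(d.size))


def bland_altman_plot(first, second, ax=None, label: str = ""):
    """Scatter of pair differences against pair means with LoA lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    res = bland_altman(first, second)
    a = np.asarray(first, float)
    b = np.asarray(second, float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, b - a, s=12, alpha=0.6)
    ax.axhline(res.mean_diff, color="k", lw=1)
    for lim in res.limits_of_agreement:
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("pair mean (CL)")
    ax.set_ylabel("difference (CL)")
    if label:
        ax.set_title(label)
    return ax
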