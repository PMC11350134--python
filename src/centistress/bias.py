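"""Bias models: GEE fits, Type III Wald tests, marginal means and deltas.

The bias analysis asks how much each pipeline design factor (reference
region, mask delineations, quantification space, harmonization status)
shifts Centiloid values, and whether age or brain atrophy accounts for the
shifts.  Measurements are clustered within subject (32 or 64 rows each), so
models are Gaussian generalized estimating equations with an exchangeable
working correlation and robust (sandwich) covariance, fitted separately in
the amyloid-negative and amyloid-positive strata (standard-pipeline CL > 24
defines positivity).  Factors use sum-to-zero coding so Type III Wald tests
are invariant to level ordering; marginal means average predictions over a
balanced grid of the other factors.  Differences between marginal means and
the standard design are flagged "relevant" only beyond 3 CL, the
test-retest variability of amyloid PET on the Centiloid scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import FitError, InsufficientDataError, StratificationError
from .quantify import STANDARD_PIPELINE

POSITIVITY_CUTOFF_CL = 24.0
RELEVANCE_THRESHOLD_CL = 3.0
Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A bias-model formula: factors, covariates and interactions."""

    response: str = "cl"
    between_factors: tuple[str, ...] = ("diagnosis", "tracer")
    within_factors: tuple[str, ...] = ("rr", "rr_type", "t_type", "space")
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    cluster: str = "subject_id"

    def __post_init__(self):
        mains = set(self.between_factors) | set(self.within_factors) \
            | set(self.covariates)
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise FitError(
                    f"interaction {a}*{b} lacks a main effect in the model")

    @property
    def factors(self) -> tuple[str, ...]:
        return self.between_factors + self.within_factors

    def term(self, name: str) -> str:
        return name if name in self.covariates else f"C({name}, Sum)"

    @property
    def formula(self) -> str:
        parts = [self.term(f) for f in self.factors]
        parts += list(self.covariates)
        parts += [f"{self.term(a)}:{self.term(b)}" for a, b in self.interactions]
        return f"{self.response} ~ " + " + ".join(parts)

    # the four bias models of the analysis -------------------------------

    @classmethod
    def main_bias(cls) -> "ModelSpec":
        """Technical factors and their tracer interactions."""
        return cls(interactions=tuple(("tracer", f) for f in
                                      ("rr", "rr_type", "t_type", "space")))

    @classmethod
    def with_age(cls) -> "ModelSpec":
        return cls(covariates=("age",),
                   interactions=cls.main_bias().interactions
                   + tuple(("age", f) for f in ("rr", "rr_type", "t_type",
                                                "space")))

    @classmethod
    def with_atrophy(cls) -> "ModelSpec":
        return cls(covariates=("atrophy",),
                   interactions=cls.main_bias().interactions
                   + tuple(("atrophy", f) for f in ("rr", "rr_type", "t_type",
                                                    "space")))

    @classmethod
    def with_harmonization(cls) -> "ModelSpec":
        """Adds harmonization status; fit it on dual-image subjects only."""
        return cls(within_factors=("rr", "rr_type", "t_type", "space",
                                   "harmonized"),
                   interactions=cls.main_bias().interactions
                   + tuple(("harmonized", f) for f in ("rr", "rr_type",
                                                       "t_type", "space")))


@dataclass
class GEEFit:
    """A fitted GEE with the metadata needed for downstream inference."""

    result: object
    spec: ModelSpec
    design_info: object
    factor_levels: dict[str, list[str]]
    covariate_means: dict[str, float]
    cov_struct_name: str
    n_clusters: int
    converged: bool

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.result.params)

    @property
    def robust_cov(self) -> np.ndarray:
        return np.asarray(self.result.cov_params())


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    missing = [c for c in spec.factors + spec.covariates
               + (spec.cluster, spec.response) if c not in table.columns]
    if missing:
        raise FitError(f"table lacks required columns: {missing}")
    data = table.copy()
    for f in spec.factors:
        data[f] = data[f].astype(str)
    return data


def fit_gee(table: pd.DataFrame, spec: ModelSpec,
            cov_struct: str = "exchangeable") -> GEEFit:
    """Fit a Gaussian identity-link GEE clustered by subject.

    Deterministic given the data.  With a single observation per cluster an
    exchangeable working correlation is unidentified; the fit falls back to
    independence with a warning.
    """
    data = _prepare(table, spec)
    groups = data[spec.cluster]
    if np.ptp(data[spec.response].to_numpy(dtype=float)) == 0:
        # a constant response has zero scale, which GEE cannot iterate on;
        # the estimating equations are solved by the OLS solution exactly
        warnings.warn("constant response; fitting by least squares")
        model = smf.ols(spec.formula, data=data)
        result = model.fit()
        levels = {f: sorted(data[f].unique()) for f in spec.factors}
        means = {c: float(data[c].mean()) for c in spec.covariates}
        return GEEFit(result, spec, model.data.design_info, levels, means,
                      "degenerate", int(groups.nunique()), True)
    if cov_struct == "exchangeable" and groups.value_counts().max() == 1:
        warnings.warn("single observation per cluster; falling back to "
                      "independence working correlation")
        cov_struct = "independence"
    structure = {"exchangeable": sm.cov_struct.Exchangeable,
                 "independence": sm.cov_struct.Independence}[cov_struct]()
    model = smf.gee(spec.formula, groups=groups, data=data,
                    family=sm.families.Gaussian(), cov_struct=structure)
    result = model.fit()
    converged = bool(getattr(result, "converged", True))
    if not converged:
        warnings.warn("GEE did not converge")
    levels = {f: sorted(data[f].unique()) for f in spec.factors}
    means = {c: float(data[c].mean()) for c in spec.covariates}
    return GEEFit(result, spec, model.data.design_info, levels, means,
                  cov_struct, int(groups.nunique()), converged)


# ---------------------------------------------------------------------------
# Type III Wald tests
# ---------------------------------------------------------------------------

def _pretty_term(term: str) -> str:
    return (term.replace(", Sum)", ")").replace("C(", "").replace(")", "")
            .replace(":", " * "))


def wald_type3(fit: GEEFit) -> pd.DataFrame:
    """Joint Wald chi-square per model term using the robust covariance.

    With sum-to-zero factor coding each term is tested adjusted for all
    others (Type III); a singular covariance sub-block falls back to a
    pseudo-inverse with a warning.
    """
    if not fit.converged:
        raise FitError("cannot test an unconverged fit")
    params, cov = fit.params, fit.robust_cov
    rows = []
    for term, sl in fit.design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        b = params[sl]
        v = cov[sl, sl]
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            warnings.warn(f"singular covariance for term {term}; "
                          "using pseudo-inverse")
            chi2 = float(b @ np.linalg.pinv(v) @ b)
        df = int(b.size)
        rows.append({"term": _pretty_term(term), "chi2": chi2, "df": df,
                     "p": float(stats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marginal means and deltas
# ---------------------------------------------------------------------------

@dataclass
class MarginalMeans:
    """Estimated marginal means of one factor over a balanced grid."""

    factor: str
    levels: list[str]
    estimates: np.ndarray
    ses: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    contrast_matrix: np.ndarray        # rows: levels; columns: coefficients
    cov: np.ndarray
    reference_grid: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.factor, "level": self.levels,
            "estimate": self.estimates, "se": self.ses,
            "ci_low": self.ci_low, "ci_high": self.ci_high})


def marginal_means(fit: GEEFit, factor: str) -> MarginalMeans:
    """Marginal means: predictions averaged over a balanced factor grid.

    Every combination of the other factors' levels receives equal weight
    (whatever its observed frequency); covariates are held at their sample
    means.  Standard errors come from the robust covariance via the delta
    method; CIs are estimate +/- 1.96 SE.
    """
    if factor not in fit.factor_levels:
        raise ValueError(f"factor {factor!r} is not in the model")
    grids = {f: levels for f, levels in fit.factor_levels.items()}
    index = pd.MultiIndex.from_product(grids.values(), names=grids.keys())
    grid = index.to_frame(index=False)
    for cov_name, mean in fit.covariate_means.items():
        grid[cov_name] = mean
    (X,) = patsy.build_design_matrices([fit.design_info], grid)
    X = np.asarray(X)
    L = np.vstack([X[(grid[factor] == level).to_numpy()].mean(axis=0)
                   for level in fit.factor_levels[factor]])
    est = L @ fit.params
    cov = fit.robust_cov
    ses = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
    others = [f for f in grids if f != factor]
    desc = (f"balanced over {others}; covariates at means "
            f"{fit.covariate_means}" if fit.covariate_means
            else f"balanced over {others}")
    return MarginalMeans(factor, list(fit.factor_levels[factor]), est, ses,
                         est - Z95 * ses, est + Z95 * ses, L, cov, desc)


def pairwise_deltas(mm: MarginalMeans, reference_level: str,
                    threshold: float = RELEVANCE_THRESHOLD_CL) -> pd.DataFrame:
    """Level-minus-reference differences, flagged relevant beyond 3 CL."""
    if reference_level not in mm.levels:
        raise ValueError(f"reference level {reference_level!r} not found")
    ref = mm.levels.index(reference_level)
    rows = []
    for i, level in enumerate(mm.levels):
        d = mm.contrast_matrix[i] - mm.contrast_matrix[ref]
        delta = float(mm.estimates[i] - mm.estimates[ref])
        se = float(np.sqrt(d @ mm.cov @ d))
        rows.append({"factor": mm.factor, "level": level,
                     "reference": reference_level, "delta": delta, "se": se,
                     "ci_low": delta - Z95 * se, "ci_high": delta + Z95 * se,
                     "relevant": abs(delta) >= threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratification and targeted correlations
# ---------------------------------------------------------------------------

def standard_pipeline_cl(table: pd.DataFrame,
                         pipeline_id: str = STANDARD_PIPELINE.pipeline_id,
                         harmonized: bool = True) -> pd.Series:
    """Per-subject CL from the standard pipeline (harmonized scans)."""
    sel = table[(table["pipeline_id"] == pipeline_id)
                & (table["harmonized"] == harmonized)]
    missing = set(table["subject_id"]) - set(sel["subject_id"])
    if missing:
        raise StratificationError(
            "subjects lack the standard-pipeline record: "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}")
    return sel.set_index("subject_id")["cl"]


def stratify_amyloid(table: pd.DataFrame,
                     cutoff: float = POSITIVITY_CUTOFF_CL
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split all of a subject's rows by standard-pipeline CL > cutoff."""
    cl = standard_pipeline_cl(table)
    positive_ids = set(cl.index[cl > cutoff])
    is_pos = table["subject_id"].isin(positive_ids)
    return table[~is_pos].copy(), table[is_pos].copy()


_STANDARD_SETTINGS = {"rr_type": "GAAIN", "t_type": "GAAIN", "space": "MNI"}


def _per_subject_pivot(table: pd.DataFrame, factor: str,
                       fixed: dict) -> pd.DataFrame:
    sel = table[table["harmonized"] == True]  # noqa: E712 - column filter
    for col, val in fixed.items():
        sel = sel[sel[col] == val]
    return sel.pivot_table(index="subject_id", columns=factor, values="cl",
                           aggfunc="mean")


def factor_age_correlations(
        table: pd.DataFrame,
        contrasts: tuple[tuple[str, str], ...] = (
            ("WCB", "WCB_BSTM"), ("WCB", "Pons"), ("CGM", "WCB")),
) -> pd.DataFrame:
    """Spearman correlation of age with per-subject CL differences by RR.

    Differences use harmonized measurements at the standard delineation and
    space settings.  A constant difference (or constant age) has undefined
    rank correlation; it is reported as 0 with ``degenerate`` set.
    """
    wide = _per_subject_pivot(table, "rr", _STANDARD_SETTINGS)
    ages = table.groupby("subject_id")["age"].first().reindex(wide.index)
    if len(wide) < 3:
        raise InsufficientDataError("need at least 3 subjects")
    rows = []
    for a, b in contrasts:
        d = wide[a] - wide[b]
        degenerate = bool(np.ptp(d) == 0 or np.ptp(ages) == 0)
        if degenerate:
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(ages, d)
        rows.append({"contrast": f"dCL({a}-{b})", "rho": float(rho),
                     "p": float(p), "n": int(len(d)),
                     "degenerate": degenerate})
    return pd.DataFrame(rows)


@dataclass
class AtrophyTargetResult:
    """Atrophy sensitivity of the cortical-target delineation choice."""

    r: float
    p: float
    n: int
    degenerate: bool
    dementia_mean: float | None
    dementia_sd: float | None
    dementia_n: int


def atrophy_target_analysis(table: pd.DataFrame) -> AtrophyTargetResult:
    """Pearson correlation of GM/TIV with dCL(subject - GAAIN target).

    Also summarises the difference in the dementia subgroup of the positive
    stratum (mean +/- SD); the subgroup is reported as missing when empty.
    """
    wide = _per_subject_pivot(table, "t_type",
                              {"rr": "WCB", "rr_type": "GAAIN", "space": "MNI"})
    if not {"GAAIN", "subject"} <= set(wide.columns):
        raise InsufficientDataError("need both target types per subject")
    d = (wide["subject"] - wide["GAAIN"]).dropna()
    per_subject = table.groupby("subject_id")[["atrophy", "diagnosis",
                                               "group"]].first()
    atrophy = per_subject["atrophy"].reindex(d.index)
    degenerate = bool(np.ptp(d) == 0 or np.ptp(atrophy) == 0)
    if degenerate:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(atrophy, d)
    dem = d[(per_subject["diagnosis"] == "dementia")
            & (per_subject["group"] == "positive")]
    if len(dem):
        dem_stats = (float(dem.mean()),
                     float(dem.std(ddof=1)) if len(dem) > 1 else 0.0,
                     int(len(dem)))
    else:
        dem_stats = (None, None, 0)
    return AtrophyTargetResult(float(r), float(p), int(len(d)), degenerate,
                               *dem_stats)
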