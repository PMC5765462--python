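"""Mixed-effects inference for repeated behavioural/physiological traits.

Gaussian linear mixed models with fish-id-nested-in-group random
intercepts (fitted with statsmodels MixedLM in its variance-components
formulation), plus the derived quantities the analysis needs:

* random-structure comparison (random intercepts vs. individual slopes)
  by REML likelihood-ratio test;
* backward elimination of fixed effects — drop the term with the
  smallest |t| unless removal significantly worsens the fit (LRT / AIC),
  under ML;
* marginal and conditional R² from variance components (Nakagawa &
  Schielzeth decomposition);
* adjusted (consistency) repeatability
  r = v_id / (v_id + v_group + v_residual) with parametric-bootstrap CI
  and a boundary-corrected LRT p-value for the id variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import InsufficientDataError, UndefinedStatisticError, UnidentifiableError

__all__ = [
    "ModelSpec",
    "LMEFit",
    "VarianceComponents",
    "R2Pair",
    "RepeatabilityEstimate",
    "fit_lme",
    "compare_random_structures",
    "backward_eliminate",
    "r2_nakagawa",
    "repeatability",
]


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed_terms`` are patsy term strings (e.g. ``"smr_log"``,
    ``"C(oxygen_level)"``, ``"attacks_log:C(oxygen_level)"``).
    ``random`` chooses the random-intercept structure: ``"id_in_group"``
    (fish id nested in group), ``"id"`` or ``"group"``.
    """

    response: str
    fixed_terms: list[str] = field(default_factory=list)
    random: str = "id_in_group"
    transform: str = "identity"  # or "log1p"
    reml: bool = True
    id_col: str = "fish_id"
    group_col: str = "group_id"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"__y ~ {rhs}"


@dataclass
class VarianceComponents:
    v_fixed: float
    v_id: float
    v_group: float
    v_residual: float

    @property
    def total(self) -> float:
        return self.v_fixed + self.v_id + self.v_group + self.v_residual


@dataclass
class R2Pair:
    r2_marginal: float
    r2_conditional: float


@dataclass
class RepeatabilityEstimate:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    seed: int
    vc: VarianceComponents
    n_boot_failed: int = 0


class LMEFit:
    """A fitted Gaussian LME: coefficients, variance components, fit stats.

    Thin wrapper over a statsmodels MixedLMResults keeping the spec and
    data so derived procedures (elimination, bootstrap) can refit.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, result, design_info):
        self.spec = spec
        self.data = data
        self.result = result
        self.design_info = design_info
        self.converged = bool(getattr(result, "converged", True))

    # -- fixed effects -----------------------------------------------------
    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def coef_names(self) -> list[str]:
        return list(self.result.fe_params.index)

    def tvalues(self) -> pd.Series:
        fe = self.result.fe_params
        se = self.result.bse_fe
        return fe / se

    @property
    def df_resid(self) -> float:
        # implementation-defined residual df (n - n fixed coefficients);
        # reported, not matched to any particular denominator-df method
        return self.result.nobs - len(self.result.fe_params)

    def summary_frame(self) -> pd.DataFrame:
        t = self.tvalues()
        p = 2.0 * sps.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame(
            {
                "estimate": self.result.fe_params,
                "se": self.result.bse_fe,
                "df": self.df_resid,
                "t": t,
                "p": p,
            }
        )

    # -- likelihood --------------------------------------------------------
    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def k_params(self) -> int:
        # fixed effects + covariance parameters + residual variance
        return len(self.result.params) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    # -- variance components ----------------------------------------------
    def variance_components(self) -> VarianceComponents:
        res = self.result
        v_resid = float(res.scale)
        v_group = 0.0
        v_id = 0.0
        if self.spec.random == "id_in_group":
            v_group = float(np.asarray(res.cov_re)[0, 0])
            v_id = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        elif self.spec.random == "id":
            v_id = float(np.asarray(res.cov_re)[0, 0])
        elif self.spec.random == "group":
            v_group = float(np.asarray(res.cov_re)[0, 0])
        fitted_fixed = res.model.exog @ res.fe_params
        v_fixed = float(np.var(fitted_fixed, ddof=1))
        return VarianceComponents(v_fixed, v_id, v_group, v_resid)

    def fitted_fixed(self) -> np.ndarray:
        return np.asarray(self.result.model.exog @ self.result.fe_params)

    def term_columns(self, term: str) -> list[int]:
        """Design-matrix column indices belonging to a fixed term."""
        want = frozenset(term.split(":"))
        for name, sl in self.design_info.term_name_slices.items():
            if frozenset(name.split(":")) == want:
                return list(range(sl.start, sl.stop))
        raise KeyError(f"term {term!r} not in model")


def _prepare(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    df = data.copy()
    y = df[spec.response].astype(float)
    if spec.transform == "log1p":
        if (y < 0).any():
            raise ValueError("log1p transform requires non-negative response")
        y = np.log1p(y)
    elif spec.transform != "identity":
        raise ValueError(f"unknown transform {spec.transform!r}")
    df["__y"] = y
    return df


def fit_lme(
    spec: ModelSpec,
    data: pd.DataFrame,
    extra_vc: dict[str, str] | None = None,
    start_params=None,
) -> LMEFit:
    """Fit the mixed model described by ``spec``.

    REML or ML per ``spec.reml``.  Singular/boundary fits are reported
    through ``LMEFit.converged`` and the usual statsmodels warnings, not
    hidden.  ``extra_vc`` adds variance components (used for the random-
    slope comparison).
    """
    df = _prepare(spec, data)
    for col in (spec.id_col, spec.group_col):
        if spec.random != "group" and col == spec.id_col and col not in df.columns:
            raise InsufficientDataError(f"column {col!r} missing")
    if spec.random == "id_in_group":
        groups = spec.group_col
        vc = {"id": f"0 + C({spec.id_col})"}
    elif spec.random == "id":
        groups = spec.id_col
        vc = None
    elif spec.random == "group":
        groups = spec.group_col
        vc = None
    else:
        raise ValueError(f"unknown random structure {spec.random!r}")
    if df[groups].nunique() < 2:
        raise InsufficientDataError("need >= 2 levels in the random grouping factor")
    if extra_vc:
        vc = {**(vc or {}), **extra_vc}

    model = smf.mixedlm(spec.formula, df, groups=groups, re_formula="1", vc_formula=vc)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["lbfgs"], ["powell"], ["cg"]):
            try:
                result = model.fit(
                    reml=spec.reml, method=method, start_params=start_params
                )
                break
            except np.linalg.LinAlgError:
                start_params = None
                continue
    if result is None:
        raise InsufficientDataError("mixed model failed to converge (singular fit)")
    return LMEFit(spec, data, result, model.data.design_info)


def compare_random_structures(
    spec: ModelSpec,
    data: pd.DataFrame,
    slope_term: str,
    alpha: float = 0.05,
) -> dict:
    """Random intercepts vs. added per-individual slopes, by REML LRT.

    The slope model adds an uncorrelated variance component for the
    individual × ``slope_term`` interaction (``slope_term`` must be a
    numeric column, e.g. oxygen level as a number).  Because the tested
    variance sits on the boundary of its space, the LRT p-value is the
    halved chi-square(1) tail.  The intercept-only model is retained
    unless the slope model improves fit at ``alpha`` (equal likelihoods
    favour the simpler model).
    """
    spec_reml = replace(spec, reml=True)
    df = data.copy()
    x = df[slope_term].astype(float)
    # standardised slope covariate keeps the variance component on a
    # well-scaled axis regardless of the raw units
    df["__slope_z"] = (x - x.mean()) / (x.std() or 1.0)
    fit_int = fit_lme(spec_reml, df)
    fit_slp = fit_lme(
        spec_reml, df,
        extra_vc={"id_slope": f"0 + C({spec.id_col}):__slope_z"},
    )
    stat = 2.0 * (fit_slp.llf - fit_int.llf)
    p = 0.5 * sps.chi2.sf(max(stat, 0.0), 1) if stat > 0 else 1.0
    choice = "slope" if p < alpha else "intercept"
    table = pd.DataFrame(
        {
            "model": ["intercept", "slope"],
            "llf_reml": [fit_int.llf, fit_slp.llf],
            "k_params": [fit_int.k_params, fit_slp.k_params],
            "lrt_stat": [np.nan, stat],
            "lrt_p": [np.nan, p],
        }
    )
    return {
        "choice": choice,
        "table": table,
        "fit_intercept": fit_int,
        "fit_slope": fit_slp,
        "converged": fit_int.converged and fit_slp.converged,
    }


def _term_factors(term: str) -> frozenset:
    return frozenset(term.split(":"))


def _droppable(terms: list[str]) -> list[str]:
    """Terms not contained in any higher-order interaction still present."""
    out = []
    for t in terms:
        f = _term_factors(t)
        if not any(f < _term_factors(o) for o in terms if o != t):
            out.append(t)
    return out


def backward_eliminate(
    spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[LMEFit, pd.DataFrame]:
    """Backward elimination of fixed effects under ML.

    At each step the candidate is the droppable term with the smallest
    |t| (for multi-coefficient terms, the largest |t| among its
    coefficients, so a term with any strong coefficient is not an early
    candidate).  The term is dropped unless the likelihood-ratio test of
    its removal is significant at ``alpha`` (removal yielding a
    significantly larger AIC).  Main effects still present in an
    interaction are never candidates.  Returns the final ML fit and the
    full elimination trail (term, t, ΔAIC, LRT p, decision).
    """
    spec_ml = replace(spec, reml=False)
    terms = list(spec_ml.fixed_terms)
    trail: list[dict] = []
    step = 0
    while True:
        current = replace(spec_ml, fixed_terms=terms)
        fit_full = fit_lme(current, data)
        tvals = fit_full.tvalues()
        kept: set[str] = set()
        dropped_this_round = False
        while True:
            candidates = [t for t in _droppable(terms) if t not in kept]
            if not candidates:
                break
            term_t = {
                t: float(np.max(np.abs(tvals.iloc[fit_full.term_columns(t)])))
                for t in candidates
            }
            cand = min(term_t, key=term_t.get)
            reduced_terms = [t for t in terms if t != cand]
            fit_red = fit_lme(replace(spec_ml, fixed_terms=reduced_terms), data)
            stat = 2.0 * (fit_full.llf - fit_red.llf)
            df_diff = len(fit_full.fe_params) - len(fit_red.fe_params)
            p = sps.chi2.sf(max(stat, 0.0), max(df_diff, 1))
            d_aic = fit_red.aic - fit_full.aic
            step += 1
            decision = "kept" if p < alpha else "dropped"
            trail.append(
                {
                    "step": step,
                    "term": cand,
                    "t": term_t[cand],
                    "lrt_stat": stat,
                    "lrt_df": df_diff,
                    "lrt_p": p,
                    "delta_aic": d_aic,
                    "decision": decision,
                }
            )
            if decision == "kept":
                kept.add(cand)
                continue
            terms = reduced_terms
            dropped_this_round = True
            break
        if not dropped_this_round:
            break
    final = fit_lme(replace(spec_ml, fixed_terms=terms), data)
    return final, pd.DataFrame(trail)


def r2_nakagawa(fit: LMEFit) -> R2Pair:
    """Marginal and conditional R² from the variance decomposition.

    marginal = v_fixed / v_total; conditional adds the random-intercept
    variances to the numerator.  Both are invariant to affine rescaling
    of the response.
    """
    vc = fit.variance_components()
    if vc.total <= 0:
        raise UndefinedStatisticError("zero total variance")
    return R2Pair(
        r2_marginal=vc.v_fixed / vc.total,
        r2_conditional=(vc.v_fixed + vc.v_id + vc.v_group) / vc.total,
    )


def _refit_endog(model, y: np.ndarray, reml: bool):
    """Refit a MixedLM on a new response, reusing the cached design arrays
    (much cheaper than re-running the formula machinery)."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    m = MixedLM(
        y, model.exog, groups=model.groups,
        exog_re=model.exog_re, exog_vc=model.exog_vc,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.fit(reml=reml, method=["lbfgs"])


def _lrt_id_variance(spec: ModelSpec, data: pd.DataFrame) -> float:
    """Boundary-corrected LRT p for the id variance component (ML fits)."""
    spec_ml = replace(spec, reml=False)
    fit_full = fit_lme(spec_ml, data)
    df = _prepare(spec_ml, data)
    if spec.random == "id_in_group":
        fit_red = fit_lme(replace(spec_ml, random="group"), data)
        llf_red = fit_red.llf
    else:  # random == "id": reduced model is plain OLS
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(spec_ml.formula, df).fit()
        llf_red = float(ols.llf)
    stat = 2.0 * (fit_full.llf - llf_red)
    return float(0.5 * sps.chi2.sf(max(stat, 0.0), 1)) if stat > 0 else 1.0


def repeatability(
    data: pd.DataFrame,
    response: str,
    adjust_terms: list[str] | None = None,
    random: str = "id_in_group",
    n_boot: int = 1000,
    seed: int | None = None,
    transform: str = "identity",
    id_col: str = "fish_id",
    group_col: str = "group_id",
    lrt: bool = True,
) -> RepeatabilityEstimate:
    """Adjusted (consistency) repeatability of a trait.

    r = v_id / (v_id + v_group + v_residual), from a REML fit with the
    adjustment covariates as fixed effects.  The 95% CI comes from a
    parametric bootstrap (``n_boot`` refits of data simulated from the
    fitted model; ``seed`` is mandatory and recorded); the p-value from
    a boundary-corrected LRT of the id variance.  A boundary fit
    (v_id = 0) reports r = 0 with CI lower bound 0.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the repeatability bootstrap")
    counts = data.groupby(id_col).size()
    if (counts >= 2).mean() < 0.5:
        raise UnidentifiableError(
            "repeatability unidentifiable: most ids have a single observation"
        )
    spec = ModelSpec(
        response=response,
        fixed_terms=list(adjust_terms or []),
        random=random,
        transform=transform,
        reml=True,
        id_col=id_col,
        group_col=group_col,
    )
    fit = fit_lme(spec, data)
    vc = fit.variance_components()
    denom = vc.v_id + vc.v_group + vc.v_residual
    if denom <= 0:
        raise UndefinedStatisticError("zero random + residual variance")
    r = vc.v_id / denom
    p = _lrt_id_variance(spec, data) if lrt else float("nan")

    rng = np.random.default_rng(seed)
    fitted = fit.fitted_fixed()
    df = data.reset_index(drop=True)
    ids = df[id_col].to_numpy()
    groups = df[group_col].to_numpy() if group_col in df else np.zeros(len(df))
    uid, id_idx = np.unique(ids, return_inverse=True)
    ugr, gr_idx = np.unique(groups, return_inverse=True)
    # refit from the cached design arrays: same model, new simulated response
    base = fit.result.model
    boot_r = []
    n_failed = 0
    for _ in range(n_boot):
        y = (
            fitted
            + np.sqrt(vc.v_id) * rng.standard_normal(len(uid))[id_idx]
            + np.sqrt(vc.v_group) * rng.standard_normal(len(ugr))[gr_idx]
            + np.sqrt(vc.v_residual) * rng.standard_normal(len(df))
        )
        try:
            bres = _refit_endog(base, y, reml=True)
            b_resid = float(bres.scale)
            if random == "id_in_group":
                b_group = float(np.asarray(bres.cov_re)[0, 0])
                b_id = float(bres.vcomp[0]) if len(bres.vcomp) else 0.0
            else:
                b_group = 0.0
                b_id = float(np.asarray(bres.cov_re)[0, 0])
            bden = b_id + b_group + b_resid
            if bden > 0:
                boot_r.append(b_id / bden)
        except Exception:
            n_failed += 1
    if boot_r:
        lo, hi = np.percentile(boot_r, [2.5, 97.5])
    else:
        lo, hi = 0.0, 1.0
    lo = float(min(max(lo, 0.0), r))
    hi = float(max(min(hi, 1.0), r))
    return RepeatabilityEstimate(
        r=float(r),
        ci_low=lo,
        ci_high=hi,
        p=p,
        n_boot=n_boot,
        seed=seed,
        vc=vc,
        n_boot_failed=n_failed,
    )
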