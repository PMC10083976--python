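"""Mixed-effects growth models for mean-level and individual change.

Linear model: ``value ~ 1 + month`` with person-level random intercepts and
random month slopes (unstructured 2x2 covariance).  The quadratic model adds
a fixed ``month**2`` term to the same random structure.  Likelihood-ratio
comparisons use ML log-likelihoods throughout; REML comparison is invalid
across nested fixed effects, and one consistent rule is simpler to verify.

Fixed-effect p-values use t statistics with approximate df = n_persons - q
(q = number of fixed effects); the df method is recorded in the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from traitchange.core_io import LongPanel
from traitchange.errors import FitError, UsageError


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of two nested (ML-fitted) models."""

    chi2: float
    df: int
    p: float
    p_mixture: float | None = None  # 50:50 chi2(df-1)/chi2(df) boundary mix

    def significant(self, alpha: float = 0.01) -> bool:
        return self.p < alpha


@dataclass
class GrowthFit:
    """Summary of one fitted growth model."""

    trait: str
    rater_role: str
    model_form: str  # "linear" | "quadratic"
    random_slope: bool
    fixed_effects: pd.DataFrame  # term, estimate, se, t, approx_df, p
    variance_components: dict[str, float]
    loglik_ml: float | None
    loglik_reml: float | None
    n_obs: int
    n_persons: int
    person_slopes: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    df_method: str = "n_persons - q"
    notes: list[str] = field(default_factory=list)

    @property
    def slope(self) -> float:
        return float(
            self.fixed_effects.set_index("term").loc["month", "estimate"]
        )

    @property
    def slope_se(self) -> float:
        return float(self.fixed_effects.set_index("term").loc["month", "se"])

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        df = self.n_persons - len(self.fixed_effects)
        half = stats.t.ppf(0.5 + level / 2, df) * self.slope_se
        return self.slope - half, self.slope + half


def _prepare(
    scores: LongPanel, trait: str, rater_role: str
) -> pd.DataFrame:
    df = scores.data
    df = df[(df["variable"] == trait) & (df["rater_role"] == rater_role)]
    if df.empty:
        raise UsageError(f"no observations for trait={trait!r}, rater={rater_role!r}")
    out = df[["person_id", "wave", "month", "value"]].dropna(subset=["value"])
    return out.reset_index(drop=True)


def _fit_mixedlm(
    data: pd.DataFrame,
    quadratic: bool,
    random_slope: bool,
    reml: bool,
    time_scale: float = 1.0,
):
    d = data.copy()
    d["t"] = d["month"] / time_scale
    formula = "value ~ t + I(t**2)" if quadratic else "value ~ t"
    re_formula = "~t" if random_slope else "~1"
    model = MixedLM.from_formula(
        formula, groups="person_id", re_formula=re_formula, data=d
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method="lbfgs", maxiter=500)
    return res


def fit_growth(
    scores: LongPanel,
    trait: str,
    rater_role: str = "self",
    model_form: str = "linear",
    random_slope: bool = True,
    likelihood: str = "both",
) -> GrowthFit:
    """Fit a linear or quadratic mixed-effects growth model for one trait.

    Parameters
    ----------
    scores
        Scale-level panel.
    model_form
        ``"linear"`` (fixed intercept + month) or ``"quadratic"`` (adds a
        fixed month^2 term; random effects stay intercept + linear slope).
    random_slope
        Include the per-person random month slope (with unstructured
        intercept-slope covariance) in addition to the random intercept.
    likelihood
        ``"ml"``, ``"reml"``, or ``"both"``.  LRT helpers need ML.

    Non-convergence triggers one retry on a months/10 time scale (estimates
    mapped back to per-month units); a fit that still fails is returned
    flagged, never silently replaced.
    """
    if model_form not in ("linear", "quadratic"):
        raise UsageError(f"unknown model_form {model_form!r}")
    data = _prepare(scores, trait, rater_role)
    if model_form == "quadratic" and data["month"].nunique() < 3:
        raise FitError("quadratic curvature needs >=3 distinct time points")
    quadratic = model_form == "quadratic"

    notes: list[str] = []
    res_ml = res_reml = None
    # rescale time to the observation span: keeps the random-slope variance
    # on the same order as the intercept variance, which the optimizer needs
    base_scale = float(data["month"].max()) or 1.0
    time_scale = base_scale
    need_ml = likelihood in ("ml", "both")
    need_reml = likelihood in ("reml", "both")
    for scale in (base_scale, base_scale * 10.0):
        try:
            res_ml = (
                _fit_mixedlm(data, quadratic, random_slope, reml=False, time_scale=scale)
                if need_ml
                else None
            )
            res_reml = (
                _fit_mixedlm(data, quadratic, random_slope, reml=True, time_scale=scale)
                if need_reml
                else None
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            notes.append(f"fit failed at time scale {scale}: {exc}")
            continue
        primary = res_ml if res_ml is not None else res_reml
        if primary is not None and primary.converged:
            time_scale = scale
            if scale != base_scale:
                notes.append(f"converged after rescaling time by 1/{scale:g}")
            break
        notes.append(f"non-convergence at time scale {scale}")
        time_scale = scale
    primary = res_ml if res_ml is not None else res_reml
    if primary is None:
        raise FitError(f"growth model failed for {trait}/{rater_role}: {notes}")
    converged = bool(primary.converged)

    n_persons = data["person_id"].nunique()
    q = 3 if quadratic else 2
    approx_df = max(n_persons - q, 1)

    terms = ["Intercept", "month"] + (["month2"] if quadratic else [])
    raw_terms = ["Intercept", "t"] + (["I(t ** 2)"] if quadratic else [])
    # undo the time rescaling: coefficient on (month/s)^p is slope * s^p
    scale_back = {"Intercept": 1.0, "t": 1.0 / time_scale, "I(t ** 2)": 1.0 / time_scale**2}
    fe_rows = []
    for term, raw in zip(terms, raw_terms):
        est = float(primary.fe_params[raw]) * scale_back[raw]
        se = float(primary.bse_fe[raw]) * scale_back[raw]
        tval = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tval), approx_df) if np.isfinite(tval) else np.nan
        fe_rows.append(
            {"term": term, "estimate": est, "se": se, "t": tval,
             "approx_df": approx_df, "p": p}
        )
    fixed_effects = pd.DataFrame(fe_rows)

    cov_re = np.asarray(primary.cov_re)
    sigma2 = float(primary.scale)
    vc = {"residual_var": sigma2}
    vc["intercept_var"] = float(cov_re[0, 0])
    if random_slope:
        vc["slope_var"] = float(cov_re[1, 1]) / time_scale**2
        vc["intercept_slope_cov"] = float(cov_re[0, 1]) / time_scale
    else:
        vc["slope_var"] = 0.0
        vc["intercept_slope_cov"] = 0.0

    person_slopes: dict[str, float] = {}
    if random_slope and not quadratic and res_ml is not None:
        fixed = float(res_ml.fe_params["t"]) / time_scale
        for pid, re in res_ml.random_effects.items():
            person_slopes[str(pid)] = fixed + float(re["t"]) / time_scale
    elif not random_slope and not quadratic:
        fixed = float(primary.fe_params["t"]) / time_scale
        person_slopes = {str(p): fixed for p in data["person_id"].unique()}

    return GrowthFit(
        trait=trait,
        rater_role=rater_role,
        model_form=model_form,
        random_slope=random_slope,
        fixed_effects=fixed_effects,
        variance_components=vc,
        loglik_ml=float(res_ml.llf) if res_ml is not None else None,
        loglik_reml=float(res_reml.llf) if res_reml is not None else None,
        n_obs=len(data),
        n_persons=n_persons,
        person_slopes=person_slopes,
        converged=converged,
        notes=notes,
    )


def _check_nested(a: GrowthFit, b: GrowthFit) -> None:
    if (a.trait, a.rater_role) != (b.trait, b.rater_role):
        raise UsageError(
            "LRT requires fits of the same trait and rater role; got "
            f"{(a.trait, a.rater_role)} vs {(b.trait, b.rater_role)}"
        )
    if a.n_obs != b.n_obs or a.n_persons != b.n_persons:
        raise UsageError("LRT requires fits on identical data")
    if a.loglik_ml is None or b.loglik_ml is None:
        raise UsageError("LRT requires ML log-likelihoods (likelihood='ml'/'both')")


def compare_linear_quadratic(fit_lin: GrowthFit, fit_quad: GrowthFit) -> LRTResult:
    """LRT of the fixed quadratic term: chi2 = 2*(ll_quad - ll_lin), df = 1."""
    _check_nested(fit_lin, fit_quad)
    if fit_lin.model_form != "linear" or fit_quad.model_form != "quadratic":
        raise UsageError("pass (linear fit, quadratic fit) in that order")
    chi2 = max(0.0, 2.0 * (fit_quad.loglik_ml - fit_lin.loglik_ml))
    p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return LRTResult(chi2=chi2, df=1, p=p)


def test_random_slopes(
    scores: LongPanel, trait: str, rater_role: str = "self"
) -> LRTResult:
    """Individual differences in change: random-intercept-only vs random
    intercept + slope, df = 2 (slope variance + covariance).

    The naive chi2(2) reference is conservative because the slope variance
    sits on the boundary under the null; the 50:50 chi2(1)/chi2(2) mixture
    p-value is reported alongside.
    """
    fit0 = fit_growth(
        scores, trait, rater_role, "linear", random_slope=False, likelihood="ml"
    )
    fit1 = fit_growth(
        scores, trait, rater_role, "linear", random_slope=True, likelihood="ml"
    )
    chi2 = max(0.0, 2.0 * (fit1.loglik_ml - fit0.loglik_ml))
    p = float(stats.chi2.sf(chi2, 2)) if chi2 > 0 else 1.0
    p_mix = (
        float(0.5 * stats.chi2.sf(chi2, 1) + 0.5 * stats.chi2.sf(chi2, 2))
        if chi2 > 0
        else 1.0
    )
    return LRTResult(chi2=chi2, df=2, p=p, p_mixture=p_mix)


def extract_slopes(fit: GrowthFit) -> pd.DataFrame:
    """Predicted individual slopes (fixed + BLUP random deviation).

    Returns a tidy table with columns person_id, rater_role, trait, slope.
    """
    if fit.model_form != "linear":
        raise UsageError("slopes are extracted from linear fits")
    if not fit.person_slopes:
        raise UsageError("fit carries no per-person slopes (needs ML linear fit)")
    return pd.DataFrame(
        {
            "person_id": list(fit.person_slopes),
            "rater_role": fit.rater_role,
            "trait": fit.trait,
            "slope": list(fit.person_slopes.values()),
        }
    )
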