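"""Linear mixed-model engine used by all analyses.

Thin, opinionated wrapper around :class:`statsmodels` ``MixedLM``:

* ML (not REML) by default, so that nested fits are comparable by
  likelihood-ratio test and AIC;
* parameter counting that includes random-effect variances/covariances and
  the residual variance, matching the bookkeeping of lme4's ``anova``
  (e.g. adding a correlated random slope to a random-intercept model costs
  one fixed + two covariance parameters);
* conditional (group-level) coefficients — fixed effect plus BLUP
  deviations — with conditional standard errors;
* an optional robust refit that winsorizes large standardized residuals
  and refits to convergence, limiting the leverage of heavy-tailed noise;
* automatic fallback to a diagonal random-effects covariance when the full
  covariance fails to converge or is singular (flagged on the result).

Wald fixed-effect p-values use the normal approximation; with the group
counts used here this is close to Kenward–Roger/Satterthwaite-corrected
tests for all but the smallest designs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLMParams

logger = logging.getLogger(__name__)

__all__ = ["LmmFit", "LrtResult", "fit_lmm", "likelihood_ratio_test"]

#: winsorization threshold (standardized residuals) for the robust refit
ROBUST_C = 2.5


@dataclass
class LmmFit:
    """A fitted mixed model and its comparison-ready summaries."""

    name: str
    formula: str
    fixed: pd.DataFrame  # index=term; estimate, se, ci_lo, ci_hi, p
    loglik: float
    n_params: int  # fixed + random (co)variances + residual variance
    aic: float
    n_obs: int
    converged: bool
    reml: bool
    robust: bool
    result: object = field(repr=False)  # statsmodels MixedLMResults
    robust_weights: np.ndarray | None = field(default=None, repr=False)

    @property
    def random_effects(self) -> dict:
        """Per-group BLUP deviations (statsmodels ``random_effects``)."""
        return self.result.random_effects

    @property
    def random_effects_cov(self) -> dict:
        """Per-group conditional covariance of the BLUP deviations."""
        return self.result.random_effects_cov


def _wald_table(res) -> pd.DataFrame:
    est = res.fe_params
    se = res.bse_fe
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    ci = 1.959963984540054 * se
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_lo": est - ci,
            "ci_hi": est + ci,
            "p": p,
        }
    )


def _count_params(res) -> int:
    model = res.model
    k_fe = model.k_fe
    k_re = model.k_re
    if getattr(model, "_freepat", None) is not None:
        k_cov = int(np.sum(np.tril(model._freepat.cov_re) != 0))
    else:
        k_cov = k_re * (k_re + 1) // 2
    k_vc = model.k_vc
    return k_fe + k_cov + k_vc + 1  # +1 residual variance


def _diag_free(model) -> MixedLMParams:
    """Free-parameter pattern constraining the random covariance to be
    diagonal (the non-convergence fallback)."""
    return MixedLMParams.from_components(
        fe_params=np.ones(model.k_fe),
        cov_re=np.eye(model.k_re) if model.k_re else np.empty((0, 0)),
        vcomp=np.ones(model.k_vc),
    )


def _fit_once(model, reml: bool, free=None, start_params=None,
              exhaustive: bool = False):
    """Fit trying a sequence of optimizers.

    Returns the first healthy result (or, with ``exhaustive``, the
    best-likelihood healthy result across all optimizers — needed when
    likelihoods of separately fitted models are differenced, where a
    loosely converged optimum would bias the test statistic).
    """
    best_healthy = None
    best_any = None
    for method in ("lbfgs", "powell", "bfgs"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=reml, free=free, method=method,
                                start_params=start_params, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):
                continue
        if _is_healthy(res):
            if not exhaustive:
                return res
            if best_healthy is None or res.llf > best_healthy.llf:
                best_healthy = res
        if np.isfinite(res.llf) and (best_any is None or res.llf > best_any.llf):
            best_any = res
    if best_healthy is not None:
        return best_healthy
    if best_any is None:
        raise RuntimeError("mixed model optimization failed for all methods")
    return best_any


def _warm_start(model, prev: "LmmFit") -> MixedLMParams | None:
    """Starting values for ``model`` taken from a nested fit with the same
    random structure: matching fixed effects copied (new ones start at 0),
    covariance parameters copied verbatim."""
    prev_res = prev.result
    if (model.k_re != prev_res.model.k_re
            or model.k_vc != prev_res.model.k_vc):
        return None
    fe = np.zeros(model.k_fe)
    prev_names = list(prev_res.model.exog_names)
    prev_fe = np.asarray(prev_res.fe_params, float)
    for i, name in enumerate(model.exog_names):
        if name in prev_names:
            fe[i] = prev_fe[prev_names.index(name)]
    scale = max(prev_res.scale, 1e-12)
    cov_re = (np.asarray(prev_res.cov_re, float) / scale
              if model.k_re else np.empty((0, 0)))
    vcomp = np.asarray(prev_res.vcomp, float) / scale if model.k_vc else np.empty(0)
    return MixedLMParams.from_components(
        fe_params=fe, cov_re=cov_re, vcomp=vcomp
    )


def _is_healthy(res) -> bool:
    if not res.converged or not np.isfinite(res.llf):
        return False
    if res.model.k_re:
        eig = np.linalg.eigvalsh(np.asarray(res.cov_re, float))
        if np.any(eig < -1e-8):
            return False
    if not np.all(np.isfinite(res.bse_fe)):
        return False
    return True


def fit_lmm(
    formula: str,
    data: pd.DataFrame,
    groups: str,
    re_formula: str = "1",
    vc_formula: dict[str, str] | None = None,
    *,
    name: str = "",
    robust: bool = False,
    reml: bool = False,
    start_from: "LmmFit | None" = None,
    multi_start: bool = False,
) -> LmmFit:
    """Fit a linear mixed model from a Wilkinson formula.

    Parameters
    ----------
    formula, re_formula, vc_formula
        Fixed-effect formula, random-effect formula within ``groups``, and
        optional variance components (e.g. nested channel-level intercepts
        and slopes, each with its own variance and no cross-covariance).
    groups
        Column naming the top grouping factor (subject).
    robust
        Iteratively winsorize standardized residuals at ±2.5 and refit, so
        a handful of extreme observations cannot dominate the fit. Weights
        (winsorized / raw residual magnitude) are recorded.
    reml
        Use REML instead of ML. Leave False whenever fits are compared by
        LRT or AIC.
    start_from
        A nested fit with the same random structure used as warm start —
        guarantees the richer model's likelihood does not fall below its
        null's through optimizer failure.
    multi_start
        Take the best likelihood over all optimizers instead of the first
        converged one; use for fits entering likelihood-ratio tests so
        that null and full model get the same optimization effort.
    """
    model_data = data.dropna(
        subset=[c for c in data.columns if c in _vars_in(formula, re_formula, vc_formula)]
    )
    if model_data[groups].nunique() < 2:
        raise ValueError("need at least 2 groups for a mixed model")

    model = sm.MixedLM.from_formula(
        formula, model_data, groups=model_data[groups],
        re_formula=re_formula, vc_formula=vc_formula,
    )
    start = _warm_start(model, start_from) if start_from is not None else None
    res = _fit_once(model, reml, start_params=start, exhaustive=multi_start)
    if start_from is not None:
        # the warm start guards against landing below the null's optimum;
        # a cold fit guards against terminating prematurely right at it
        cold = _fit_once(model, reml, exhaustive=multi_start)
        if cold.llf > res.llf or (
            not _is_healthy(res) and _is_healthy(cold)
        ):
            res = cold
    converged = _is_healthy(res)
    if not converged and model.k_re > 1:
        logger.warning(
            "mixed model %s did not converge with full random covariance; "
            "falling back to diagonal", name or formula
        )
        res = _fit_once(model, reml, free=_diag_free(model))
        converged = _is_healthy(res)

    weights = None
    if robust:
        res, weights = _robust_refit(formula, model_data, groups,
                                     re_formula, vc_formula, res, reml)

    loglik = float(res.llf)
    n_params = _count_params(res)
    return LmmFit(
        name=name or formula,
        formula=formula,
        fixed=_wald_table(res),
        loglik=loglik,
        n_params=n_params,
        aic=2.0 * n_params - 2.0 * loglik,
        n_obs=int(res.model.nobs),
        converged=bool(converged),
        reml=reml,
        robust=robust,
        result=res,
        robust_weights=weights,
    )


def _vars_in(formula, re_formula, vc_formula) -> set[str]:
    import re as _re

    text = " ".join(
        [formula, re_formula or ""] + list((vc_formula or {}).values())
    )
    return set(_re.findall(r"[A-Za-z_][A-Za-z0-9_]*", text))


def _robust_refit(formula, data, groups, re_formula, vc_formula, res, reml,
                  max_iter: int = 10, tol: float = 1e-6):
    """Huber-type robustification by response winsorization.

    Standardized marginal residuals beyond ``ROBUST_C`` are clipped and the
    model refit on the adjusted response until the coefficients stabilize.
    On clean Gaussian data almost no residual is clipped and the fit matches
    the ordinary one.
    """
    response = formula.split("~")[0].strip()
    work = data.copy()
    y = work[response].to_numpy(float).copy()
    prev = np.asarray(res.fe_params, float)
    for _ in range(max_iter):
        fitted = np.asarray(res.fittedvalues, float)
        resid = y - fitted
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale <= 0:
            break
        clipped = np.clip(resid, -ROBUST_C * scale, ROBUST_C * scale)
        work[response] = fitted + clipped
        model = sm.MixedLM.from_formula(
            formula, work, groups=work[groups],
            re_formula=re_formula, vc_formula=vc_formula,
        )
        res = _fit_once(model, reml)
        cur = np.asarray(res.fe_params, float)
        if np.max(np.abs(cur - prev)) < tol:
            break
        prev = cur
    resid = y - np.asarray(res.fittedvalues, float)
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.minimum(1.0, ROBUST_C * scale / np.abs(resid))
    w[~np.isfinite(w)] = 1.0
    return res, w


@dataclass(frozen=True)
class LrtResult:
    """One-sided likelihood-ratio test between nested ML fits."""

    df: int
    chi2: float
    p: float


def likelihood_ratio_test(fit_null: LmmFit, fit_full: LmmFit) -> LrtResult:
    """chi2 = 2·(LL_full − LL_null); df = difference in total parameter
    count (fixed + random covariance parameters)."""
    if fit_null.reml or fit_full.reml:
        raise ValueError("LRT requires ML fits")
    if fit_null.n_obs != fit_full.n_obs:
        raise ValueError("LRT requires fits on identical rows")
    df = fit_full.n_params - fit_null.n_params
    if df < 1:
        raise ValueError("models are not nested in the expected direction")
    chi2 = 2.0 * (fit_full.loglik - fit_null.loglik)
    if chi2 < -1e-6:
        warnings.warn(
            "nested fit has lower likelihood than its null "
            f"(chi2={chi2:.3g}); check convergence", RuntimeWarning
        )
    chi2 = max(chi2, 0.0)
    return LrtResult(df=df, chi2=float(chi2), p=float(stats.chi2.sf(chi2, df)))
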