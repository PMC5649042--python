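"""Population-level linear mixed-effects models of daily well-being.

Daily mood or energy is regressed on the five standardized daily measures
(day of study, weekday, sleep duration, daytime activity, nighttime
stillness) with participant-level random effects. Fitting starts from the
*maximal* structure — every fixed predictor gets a correlated random slope
plus a random intercept — and, when that fails to converge, repeatedly
removes the random term with the smallest estimated variance (never the
intercept) and refits, which is the standard data-driven reduction for
maximal structures.

All fits use maximum likelihood (not REML) so log-likelihoods are
comparable across fixed-effects structures; model fit is assessed with a
chi-square ladder: random-intercept-only -> fixed effects + random
intercept -> the reduced-maximal model, with degrees of freedom equal to
the difference in parameter counts.

A fit counts as converged when the optimizer reports success and the
largest per-observation score component is below 1e-3. Fixed-effect t
tests use residual degrees of freedom and are descriptive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: fixed-effect terms (besides the intercept), in canonical order
FIXED_TERMS = (
    "day_of_study",
    "weekday",
    "sleep_duration",
    "daytime_activity",
    "nighttime_stillness",
)
#: analysis-table column for each term
TERM_COLUMNS = {
    "day_of_study": "day_s",
    "weekday": "weekday_s",
    "sleep_duration": "sleep_z",
    "daytime_activity": "activity_z",
    "nighttime_stillness": "stillness_z",
}
#: tie-break preference when two random terms have equal variance
DROP_PREFERENCE = (
    "nighttime_stillness",
    "weekday",
    "day_of_study",
    "sleep_duration",
    "daytime_activity",
)
#: per-observation score tolerance for declaring convergence
GRAD_TOL = 1e-3


@dataclass(frozen=True)
class LmmSpec:
    """A mixed-model specification: outcome, fixed terms, random terms.

    The intercept is always present in both parts; ``random`` must be a
    subset of ``fixed``. Random effects are grouped by participant with a
    fully correlated (unstructured) covariance.
    """

    outcome: str
    fixed: tuple = FIXED_TERMS
    random: tuple = FIXED_TERMS

    def __post_init__(self):
        if not set(self.random) <= set(self.fixed):
            raise ValueError("random terms must be a subset of fixed terms")

    def n_parameters(self) -> int:
        """Fixed effects + random covariance entries + residual variance."""
        q = 1 + len(self.random)
        return (1 + len(self.fixed)) + q * (q + 1) // 2 + 1


@dataclass
class LmmFit:
    """Result of one mixed-model fit."""

    spec: LmmSpec
    estimates: pd.Series
    stderr: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: float
    cov_re: pd.DataFrame
    scale: float
    llf: float
    aic: float
    bic: float
    converged: bool
    n_obs: int
    n_groups: int
    notes: list = field(default_factory=list)


def _design(table: pd.DataFrame, spec: LmmSpec):
    cols = [TERM_COLUMNS[t] for t in spec.fixed]
    re_cols = [TERM_COLUMNS[t] for t in spec.random]
    data = table.dropna(subset=[spec.outcome, *cols]).copy()
    y = data[spec.outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols])
    Z = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in re_cols])
    groups = data["participant_id"].to_numpy()
    names = ["intercept", *spec.fixed]
    re_names = ["intercept", *spec.random]
    return y, X, Z, groups, names, re_names


def _degenerate_fit(spec, y, X, groups, names, re_names, note) -> LmmFit:
    """Exact-fit / zero-variance shortcut: plain least squares with a floored scale."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    scale = max(float(resid @ resid) / n, 1e-12)
    llf = -0.5 * n * (np.log(2 * np.pi * scale) + 1.0)
    k = spec.n_parameters()
    q = len(re_names)
    zeros = pd.Series(0.0, index=names)
    return LmmFit(
        spec=spec,
        estimates=pd.Series(beta, index=names),
        stderr=zeros.copy(),
        tvalues=zeros.copy(),
        pvalues=pd.Series(1.0, index=names),
        df_resid=float(n - X.shape[1]),
        cov_re=pd.DataFrame(np.zeros((q, q)), index=re_names, columns=re_names),
        scale=scale,
        llf=float(llf),
        aic=float(2 * k - 2 * llf),
        bic=float(k * np.log(n) - 2 * llf),
        converged=True,
        n_obs=n,
        n_groups=int(len(np.unique(groups))),
        notes=[note],
    )


def fit_lmm(table: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """Maximum-likelihood mixed-model fit for the given specification.

    Singular or non-converged optimizations return a flagged fit
    (``converged=False``) with diagnostics in ``notes`` rather than
    raising.
    """
    y, X, Z, groups, names, re_names = _design(table, spec)
    if len(np.unique(groups)) < 2:
        raise ValueError("mixed model needs >= 2 participants")

    # degenerate data shortcut: (near-)exact linear fit or constant outcome,
    # where the profiled residual variance collapses to zero
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    if float(np.var(y - X @ beta_ols)) < 1e-10:
        return _degenerate_fit(spec, y, X, groups, names, re_names, "degenerate: exact linear fit")

    model = sm.MixedLM(y, X, groups=groups, exog_re=Z)
    notes: list[str] = []
    res = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # lbfgs occasionally claims convergence at a singular boundary with
        # an infinite likelihood; fall through to slower but sturdier methods
        for method in ("lbfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=1000, disp=False)
            except Exception as exc:  # singular/ill-conditioned: flag, don't raise
                logger.warning("mixed model fit failed (%s): %s", method, exc)
                notes.append(f"fit error ({method}): {exc}")
                continue
            res = cand
            if np.isfinite(cand.llf):
                break
        notes.extend(sorted({str(w.message) for w in caught}))
    if res is None:
        fit = _degenerate_fit(spec, y, X, groups, names, re_names, "; ".join(notes))
        fit.converged = False
        return fit

    grad_ok = True
    try:
        score = model.score(res.params_object)
        grad_ok = bool(np.max(np.abs(score)) / len(y) < GRAD_TOL)
    except Exception:
        pass
    converged = bool(res.converged) and np.isfinite(res.llf) and grad_ok

    k = spec.n_parameters()
    nfe = X.shape[1]
    est = pd.Series(np.asarray(res.fe_params, dtype=float), index=names)
    se = pd.Series(np.asarray(res.bse_fe, dtype=float), index=names)
    tval = est / se.replace(0.0, np.nan)
    df_resid = float(len(y) - nfe)
    pval = pd.Series(2 * stats.t.sf(np.abs(tval.to_numpy()), df_resid), index=names)
    cov_re = pd.DataFrame(np.asarray(res.cov_re, dtype=float), index=re_names, columns=re_names)
    return LmmFit(
        spec=spec,
        estimates=est,
        stderr=se,
        tvalues=tval,
        pvalues=pval,
        df_resid=df_resid,
        cov_re=cov_re,
        scale=float(res.scale),
        llf=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        bic=float(k * np.log(len(y)) - 2 * res.llf),
        converged=converged,
        n_obs=len(y),
        n_groups=int(len(np.unique(groups))),
        notes=notes,
    )


def maximal_with_fallback(
    table: pd.DataFrame, outcome: str, fixed: tuple = FIXED_TERMS
) -> tuple[LmmFit, list[str]]:
    """Fit the maximal random-effects structure, reducing on non-convergence.

    While the fit has not converged and more than the random intercept
    remains, the random term with the smallest estimated variance in the
    partial fit is removed (ties broken by a fixed preference order) and
    the model refit. Returns the final fit and the ordered dropped terms.
    The loop runs at most once per removable term, so it terminates in
    <= len(fixed) reductions; a model that never converges is returned
    flagged.
    """
    spec = LmmSpec(outcome=outcome, fixed=fixed, random=fixed)
    dropped: list[str] = []
    fit = fit_lmm(table, spec)
    while not fit.converged and len(spec.random) > 0:
        variances = fit.cov_re.to_numpy().diagonal()
        candidates = list(spec.random)  # never the intercept (index 0 of cov_re)
        pref = {t: i for i, t in enumerate(DROP_PREFERENCE)}
        scored = sorted(
            candidates,
            key=lambda t: (variances[1 + list(spec.random).index(t)], pref.get(t, 99)),
        )
        victim = scored[0]
        dropped.append(victim)
        logger.info("fallback: dropping random slope %s (min variance)", victim)
        spec = LmmSpec(
            outcome=outcome, fixed=fixed, random=tuple(t for t in spec.random if t != victim)
        )
        fit = fit_lmm(table, spec)
    return fit, dropped


def fit_ladder(table: pd.DataFrame, outcome: str, final_spec: LmmSpec) -> pd.DataFrame:
    """Chi-square model-fit ladder.

    Fits (a) random-intercept-only with no fixed predictors, (b) the fixed
    effects with a random intercept, and (c) the final reduced-maximal
    specification, reporting AIC, BIC, log-likelihood and likelihood-ratio
    chi-square with df equal to the difference in parameter counts.
    """
    spec_a = LmmSpec(outcome=outcome, fixed=(), random=())
    spec_b = LmmSpec(outcome=outcome, fixed=final_spec.fixed, random=())
    if not set(spec_b.fixed) <= set(final_spec.fixed) or not set(final_spec.random) <= set(
        final_spec.fixed
    ):
        raise ValueError("ladder specs must be nested")
    rows = []
    prev = None
    for name, spec in (
        ("random_intercept_only", spec_a),
        ("fixed_random_intercept", spec_b),
        ("reduced_maximal", final_spec),
    ):
        fit = fit_lmm(table, spec)
        row = {
            "model": name,
            "aic": fit.aic,
            "bic": fit.bic,
            "loglik": fit.llf,
            "chisq": np.nan,
            "df": np.nan,
            "p": np.nan,
            "converged": fit.converged,
        }
        if prev is not None:
            chisq = 2.0 * (fit.llf - prev[1].llf)
            df = spec.n_parameters() - prev[0].n_parameters()
            row["chisq"] = chisq
            row["df"] = df
            row["p"] = float(stats.chi2.sf(max(chisq, 0.0), df))
        rows.append(row)
        prev = (spec, fit)
    return pd.DataFrame(rows)


def fit_to_dict(fit: LmmFit, dropped: list[str] | None = None) -> dict:
    """JSON-serializable summary mirroring the estimate/SE/t/p table layout."""
    return {
        "outcome": fit.spec.outcome,
        "fixed_terms": list(fit.spec.fixed),
        "random_terms": list(fit.spec.random),
        "dropped_random_terms": dropped or [],
        "estimates": fit.estimates.to_dict(),
        "stderr": fit.stderr.to_dict(),
        "tvalues": fit.tvalues.to_dict(),
        "pvalues": fit.pvalues.to_dict(),
        "cov_re": fit.cov_re.to_numpy().tolist(),
        "scale": fit.scale,
        "loglik": fit.llf,
        "aic": fit.aic,
        "bic": fit.bic,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
    }
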