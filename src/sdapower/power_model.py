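"""Statistical summaries of assignment-power grids.

Logistic models of the probability that a simulated disperser's status is
correctly identified, as a function of panel size, PIC ranking direction,
placement and pairwise differentiation; Nakagawa-Schielzeth marginal and
conditional coefficients of determination for logit models; and the plain
mean/SD summaries used for literature tables.  The guaranteed core is the
fixed-effects maximum-likelihood fit (IRLS via statsmodels); random
intercepts (treatment, individual) are delegated to statsmodels'
variational-Bayes mixed GLM when requested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .sda_engine import CORRECT_OUTCOMES, SDAGrid

LOGIT_DISTRIBUTION_VARIANCE = math.pi**2 / 3.0


@dataclass
class PowerModelFit:
    """Coefficient table, predictions, and variance decomposition of one
    fitted model."""

    coefficients: pd.DataFrame  # columns: name, estimate, se, z
    predict: Callable[[pd.DataFrame], np.ndarray]
    r2_marginal: float
    r2_conditional: float
    random_effect_variances: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    separation_flagged: bool = False
    deviance: float = float("nan")
    linear_predictor: np.ndarray | None = None


def _check_rank(exog: pd.DataFrame) -> None:
    x = np.asarray(exog, dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the aliased columns: those whose removal restores full rank
        aliased = []
        for j, name in enumerate(exog.columns):
            reduced = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                aliased.append(str(name))
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def r2_nakagawa(
    sigma2_fixed: float,
    sigma2_random: float = 0.0,
    distribution_variance: float = LOGIT_DISTRIBUTION_VARIANCE,
) -> tuple[float, float]:
    """Marginal and conditional R2 for a (G)LMM from variance components.

    ``R2_m = s2_f / (s2_f + s2_u + s2_d)``; the conditional version adds
    the random-effect variance ``s2_u`` to the numerator.  For a logit
    link the distribution-specific variance is ``pi^2 / 3``.
    """
    total = sigma2_fixed + sigma2_random + distribution_variance
    if total <= 0:
        raise ValueError("zero total variance")
    return sigma2_fixed / total, (sigma2_fixed + sigma2_random) / total


def fit_logistic(
    data: pd.DataFrame,
    formula: str,
    random_effects: Sequence[str] = (),
) -> PowerModelFit:
    """Logistic (binomial, logit link) model of a binary response.

    ``formula`` is a patsy formula such as
    ``"correct ~ panel_size + C(direction)"``.  With ``random_effects``
    naming grouping columns, random intercepts are fitted through
    statsmodels' Bayesian mixed GLM; otherwise a plain IRLS GLM.  Complete
    separation is flagged (estimates still returned with a warning);
    rank-deficient designs raise, naming the aliased columns.
    """
    if not random_effects:
        return _fit_glm(data, formula)
    vc = {g: f"0 + C({g})" for g in random_effects}
    model = sm.BinomialBayesMixedGLM.from_formula(formula, vc, data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit_vb()
    k = len(model.exog_names)
    est = fit.fe_mean
    se = fit.fe_sd
    coef = pd.DataFrame(
        {
            "name": model.exog_names,
            "estimate": est,
            "se": se,
            "z": est / se,
        }
    )
    linpred = np.asarray(model.exog) @ est
    re_var = {
        name: float(np.exp(2.0 * m))  # vcp params are log-SDs
        for name, m in zip(model.vcp_names, fit.vcp_mean)
    }
    s2f = float(np.var(linpred))
    r2m, r2c = r2_nakagawa(s2f, sum(re_var.values()))
    return PowerModelFit(
        coefficients=coef,
        predict=lambda newdata: np.asarray(fit.predict(exog=newdata)),
        r2_marginal=r2m,
        r2_conditional=r2c,
        random_effect_variances=re_var,
        converged=True,
        linear_predictor=linpred,
    )


def _fit_glm(data: pd.DataFrame, formula: str) -> PowerModelFit:
    model = smf.glm(formula, data=data, family=sm.families.Binomial())
    _check_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    separation = False
    response = np.asarray(model.endog, dtype=float)
    if np.all(response == response[0]):
        # constant response: intercept-only fit, no slopes estimable
        p = float(response.mean())
        eta = 50.0 if p >= 1 else (-50.0 if p <= 0 else math.log(p / (1 - p)))
        coef = pd.DataFrame(
            {"name": ["Intercept"], "estimate": [eta], "se": [float("nan")],
             "z": [float("nan")]}
        )
        const = np.full(len(data), eta)
        r2m, r2c = r2_nakagawa(0.0, 0.0)
        return PowerModelFit(
            coefficients=coef,
            predict=lambda newdata: np.full(len(newdata), p),
            r2_marginal=r2m,
            r2_conditional=r2c,
            converged=True,
            linear_predictor=const,
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = model.fit(maxiter=200)
        except Exception:
            separation = True
            fit = model.fit_regularized(alpha=1e-6, maxiter=500)
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
    if separation:
        warnings.warn("possible complete separation; estimates unstable")
    est = np.asarray(fit.params)
    se = np.asarray(getattr(fit, "bse", np.full(len(est), np.nan)))
    coef = pd.DataFrame(
        {
            "name": model.exog_names,
            "estimate": est,
            "se": se,
            "z": est / se,
        }
    )
    linpred = np.asarray(model.exog) @ est
    s2f = float(np.var(linpred))
    r2m, r2c = r2_nakagawa(s2f, 0.0)
    return PowerModelFit(
        coefficients=coef,
        predict=lambda newdata: np.asarray(fit.predict(newdata)),
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=bool(getattr(fit, "converged", True)),
        separation_flagged=separation,
        deviance=float(getattr(fit, "deviance", float("nan"))),
        linear_predictor=linpred,
    )


def r2_glmm(fit: PowerModelFit) -> tuple[float, float]:
    """Recompute (marginal, conditional) R2 from the fit's stored linear
    predictor and random-effect variances."""
    if fit.linear_predictor is None:
        raise ValueError("fit has no linear predictor")
    s2f = float(np.var(fit.linear_predictor))
    return r2_nakagawa(s2f, sum(fit.random_effect_variances.values()))


# ---------------------------------------------------------------------------
# grid -> model frame


def model_frame_from_grid(
    grid: SDAGrid, differentiation: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flatten an SDA grid into a modelling frame.

    One row per (treatment, disperser, direction, panel) cell with the
    binary response ``correct``, panel size, ranking-direction indicator,
    placement, and (when a pairwise differentiation table is supplied) the
    mutual information between home and placement; identity placements get
    I = 0 and are retained.
    """
    df = grid.records[grid.records["outcome"] != "error"].copy()
    df["correct"] = df["outcome"].isin(CORRECT_OUTCOMES).astype(int)
    df["moved"] = (df["home"] != df["placed_in"]).astype(int)
    if differentiation is not None:
        lookup: dict[tuple[str, str], float] = {}
        for _, row in differentiation.iterrows():
            v = float(row["mutual_information"])
            lookup[(row["pop_a"], row["pop_b"])] = v
            lookup[(row["pop_b"], row["pop_a"])] = v
        df["pairwise_I"] = [
            0.0 if h == p else lookup[(h, p)]
            for h, p in zip(df["home"], df["placed_in"])
        ]
    return df


# ---------------------------------------------------------------------------
# literature-table summaries


def summarize_table(values) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and count of the non-missing
    entries of a numeric column; SD is NaN for a single value."""
    x = pd.to_numeric(pd.Series(values), errors="coerce").dropna()
    if x.empty:
        raise ValueError("no non-missing values")
    n = len(x)
    sd = float(x.std(ddof=1)) if n > 1 else float("nan")
    return float(x.mean()), sd, n


def fit_loci_vs_fst(records: pd.DataFrame) -> PowerModelFit:
    """Poisson (log link) GLM of the number of loci used against global
    F_ST across published studies."""
    df = records.dropna(subset=["loci", "fst"])
    if len(df) < 3:
        raise ValueError("need at least 3 complete records")
    if (df["loci"] <= 0).any():
        raise ValueError("loci counts must be positive")
    model = smf.glm("loci ~ fst", data=df, family=sm.families.Poisson())
    fit = model.fit()
    est = np.asarray(fit.params)
    se = np.asarray(fit.bse)
    coef = pd.DataFrame(
        {"name": model.exog_names, "estimate": est, "se": se, "z": est / se}
    )
    linpred = np.asarray(model.exog) @ est
    return PowerModelFit(
        coefficients=coef,
        predict=lambda newdata: np.asarray(fit.predict(newdata)),
        r2_marginal=float("nan"),
        r2_conditional=float("nan"),
        converged=bool(fit.converged),
        deviance=float(fit.deviance),
        linear_predictor=linpred,
    )
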