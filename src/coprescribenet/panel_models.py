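"""Between/within-person panel models of opioid outcomes on prominence.

A time-varying prominence metric x_it (e.g. PageRank percentile) is
decomposed into a between-person component BP_i = mean_t(x_it)/10 and a
within-person component WP_it = (x_it - mean_t(x_it))/10, both scaled
per 10 percentile points.  BP compares patients to each other; WP
compares a patient to their own average and is analogous to a
fixed-effects estimate.  Outcomes are regressed on BP, WP and controls
in random-intercept GLMMs (negative binomial for the prescription
count, logit for the binary outcomes) with state fixed effects;
coefficients are reported exponentiated (IRR / OR) with Wald CIs,
alongside the random-intercept variance, latent-scale ICC and BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._glmm import FitError, GLMMFit, fit_random_intercept_glmm

__all__ = [
    "DEFAULT_COVARIATES",
    "ModelSpec",
    "ModelResult",
    "decompose",
    "fit_glmm",
    "icc",
    "margins",
    "run_model_suite",
]

#: fixed effects of the main specification, in reporting order
DEFAULT_COVARIATES = [
    "female", "age_10yr", "ins_POS", "ins_HMO",
    "state_KY", "state_VA", "state_TN", "state_OH", "state_NC", "state_GA",
    "cancer_dx", "n_prescribers",
]

OUTCOME_FAMILY = {
    "n_rx": "negbin",
    "mme_gt90": "logit",
    "overdose_any": "logit",
    "oud": "logit",
}


def decompose(
    panel: pd.DataFrame,
    column: str = "pr_pct",
    group: str = "patient_id",
    scale: float = 10.0,
) -> pd.DataFrame:
    """Add ``bp`` and ``wp`` columns for a prominence column.

    bp_i = person mean of the column over the patient's panel quarters,
    divided by ``scale``; wp_it = (x_it - person mean)/scale.  Identity:
    scale*(bp + wp) reconstructs the column exactly, and the per-patient
    mean of wp is 0 (up to float rounding).
    """
    out = panel.copy()
    pmean = out.groupby(group)[column].transform("mean")
    out["bp"] = pmean / scale
    out["wp"] = (out[column] - pmean) / scale
    return out


@dataclass
class ModelSpec:
    """One model cell: outcome, prominence metric, sample, covariates."""

    outcome: str
    metric: str = "pr_pct"
    sample: str = "main"              # 'main' or 'highrisk'
    family: str | None = None         # inferred from outcome when None
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    scale: float = 10.0               # metric units per reported coefficient

    def resolved_family(self) -> str:
        fam = self.family or OUTCOME_FAMILY.get(self.outcome)
        if fam is None:
            raise ValueError(
                f"no default family for outcome {self.outcome!r}; pass family="
            )
        return fam


@dataclass
class ModelResult:
    """Fitted cell with reporting helpers.

    ``fit`` is the underlying :class:`GLMMFit`; ``dropped`` lists
    covariates removed because they were constant in the sample (e.g. a
    state with no patients — degenerate cells are dropped, not imputed).
    """

    spec: ModelSpec
    fit: GLMMFit
    exog_names: list
    dropped: list = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.params, index=self.exog_names)

    @property
    def se(self) -> pd.Series:
        return pd.Series(self.fit.se, index=self.exog_names)

    @property
    def sigma_u2(self) -> float:
        return self.fit.sigma_u2

    @property
    def bic(self) -> float:
        return self.fit.bic

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        """Exponentiated coefficients (IRR for counts, OR for binary) + CIs."""
        ci = np.clip(self.fit.conf_int(level), -700.0, 700.0)  # avoid exp overflow
        lab = "IRR" if self.fit.family in ("negbin", "poisson") else "OR"
        return pd.DataFrame(
            {
                "coef": self.fit.params,
                "se": self.fit.se,
                lab: np.exp(self.fit.params),
                "ci_low": np.exp(ci[:, 0]),
                "ci_high": np.exp(ci[:, 1]),
            },
            index=self.exog_names,
        )


def _build_design(panel: pd.DataFrame, covariates, add_const=True):
    cols, names, dropped = [], [], []
    if add_const:
        cols.append(np.ones(len(panel)))
        names.append("const")
    for c in covariates:
        v = panel[c].to_numpy(dtype=float)
        if np.nanstd(v) == 0.0:
            dropped.append(c)       # degenerate cell: constant column
            continue
        cols.append(v)
        names.append(c)
    X = np.column_stack(cols)
    return X, names, dropped


def fit_glmm(
    panel: pd.DataFrame,
    spec: ModelSpec | None = None,
    outcome: str | None = None,
    group: str = "patient_id",
    n_quad: int = 21,
    fix_sigma: float | None = None,
    **spec_kwargs,
) -> ModelResult:
    """Fit one random-intercept panel model.

    Either pass a :class:`ModelSpec`, or an outcome name plus keyword
    overrides (``metric=``, ``covariates=``, ``family=``).  The metric
    column is decomposed into bp/wp here if those columns are absent.
    """
    if spec is None:
        if outcome is None:
            raise ValueError("pass a ModelSpec or an outcome name")
        spec = ModelSpec(outcome=outcome, **spec_kwargs)
    family = spec.resolved_family()

    df = panel
    if "bp" not in df.columns or "wp" not in df.columns:
        df = decompose(df, column=spec.metric, group=group, scale=spec.scale)
    covs = [c for c in spec.covariates if c in df.columns] + ["bp", "wp"]
    X, names, dropped = _build_design(df, covs)
    y = df[spec.outcome].to_numpy(dtype=float)
    fit = fit_random_intercept_glmm(
        y, X, df[group].to_numpy(), family=family,
        exog_names=names, n_quad=n_quad, fix_sigma=fix_sigma,
    )
    return ModelResult(spec=spec, fit=fit, exog_names=names, dropped=dropped)


def icc(result: ModelResult | GLMMFit, mean_count: float | None = None) -> float:
    """Latent-scale intraclass correlation of the random intercept.

    Logit models: sigma_u^2 / (sigma_u^2 + pi^2/3), the share of latent
    outcome variance due to stable between-patient differences.  Count
    models use the lognormal-Poisson latent-scale approximation
    sigma_u^2 / (sigma_u^2 + ln(1 + 1/mu + alpha)) with mu the marginal
    mean count — an approximation, labelled as such, since no exact
    latent-variance decomposition exists for the NB family.
    """
    fit = result.fit if isinstance(result, ModelResult) else result
    s2 = fit.sigma_u2
    if fit.family == "logit":
        return s2 / (s2 + math.pi ** 2 / 3.0)
    alpha = fit.alpha if fit.alpha is not None else 0.0
    if mean_count is None:
        mean_count = getattr(fit, "mean_count", 1.0)
    resid = math.log(1.0 + 1.0 / max(mean_count, 1e-12) + alpha)
    return s2 / (s2 + resid)


def _pop_average_prediction(fit: GLMMFit, x_row: np.ndarray, theta=None, n_quad=31):
    """E[y | x], averaged over the random intercept by Gauss–Hermite."""
    p = len(fit.params)
    if theta is None:
        beta, sigma = fit.params, fit.sigma_u
    else:
        beta = theta[:p]
        k = p + (1 if fit.alpha is not None else 0)
        sigma = np.exp(theta[k]) if not fit.sigma_fixed else fit.sigma_u
    eta0 = float(x_row @ beta)
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    u = np.sqrt(2.0) * sigma * z
    wn = w / np.sqrt(np.pi)
    if fit.family == "logit":
        return float(np.sum(wn * expit(eta0 + u)))
    return float(np.sum(wn * np.exp(eta0 + u)))


def _internal_theta(fit: GLMMFit) -> np.ndarray:
    theta = list(fit.params)
    if fit.alpha is not None:
        theta.append(np.log(fit.alpha))
    if not fit.sigma_fixed:
        theta.append(np.log(max(fit.sigma_u, 1e-12)))
    return np.asarray(theta)


def margins(
    result: ModelResult,
    panel: pd.DataFrame,
    term: str = "bp",
    grid: np.ndarray | None = None,
    n_points: int = 9,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted outcome over a grid of one prominence term.

    Other covariates are held at their sample means (binary covariates at
    their observed proportions); the prediction is population-averaged
    over the random intercept by quadrature.  The default grid spans
    ±1 SD of the term around its mean.  CIs are delta-method over the
    full parameter vector.
    """
    fit = result.fit
    names = result.exog_names
    if term not in names:
        raise ValueError(f"term {term!r} not in the fitted design {names}")
    df = panel
    if "bp" not in df.columns or "wp" not in df.columns:
        df = decompose(df, column=result.spec.metric, scale=result.spec.scale)
    means = {c: float(df[c].mean()) for c in names if c != "const"}
    if grid is None:
        mu, sd = means[term], float(df[term].std())
        grid = np.linspace(mu - sd, mu + sd, n_points)
        if grid[0] < df[term].min() or grid[-1] > df[term].max():
            import warnings

            warnings.warn(f"margins grid for {term!r} extends beyond data support")

    theta_hat = _internal_theta(fit)
    dim = len(theta_hat)
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for g in grid:
        x = np.array(
            [1.0 if c == "const" else (g if c == term else means[c]) for c in names]
        )
        pred = _pop_average_prediction(fit, x)
        # delta method: numeric gradient of the prediction in theta
        gvec = np.zeros(dim)
        h = 1e-5 * np.maximum(np.abs(theta_hat), 1.0)
        for j in range(dim):
            tp = theta_hat.copy(); tp[j] += h[j]
            tm = theta_hat.copy(); tm[j] -= h[j]
            gvec[j] = (
                _pop_average_prediction(fit, x, tp) - _pop_average_prediction(fit, x, tm)
            ) / (2.0 * h[j])
        var = float(gvec @ fit.cov @ gvec)
        se = math.sqrt(max(var, 0.0))
        rows.append({"grid": g, "predicted": pred, "ci_low": pred - z * se,
                     "ci_high": pred + z * se})
    return pd.DataFrame(rows)


def run_model_suite(
    panel: pd.DataFrame,
    outcomes=("n_rx", "mme_gt90", "overdose_any", "oud"),
    metrics=("pr_pct", "bip_pr_pct", "pr_std", "degree_log"),
    samples=("main", "highrisk"),
    covariates=None,
    group: str = "patient_id",
    n_quad: int = 21,
) -> pd.DataFrame:
    """Fit the full grid of outcome x metric x sample cells.

    Mirrors the main-table layout plus the sensitivity variants
    (high-risk subsample, bipartite prominence, standardized PageRank,
    logged degree).  z-score and log-degree metrics are entered on their
    own scale (per 1 unit); percentile metrics per 10 points.  Fit
    failures are recorded per cell, never abort the suite.
    """
    from .outcomes import restrict_high_risk

    covariates = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    rows = []
    frames = {"main": panel}
    if "highrisk" in samples:
        frames["highrisk"] = restrict_high_risk(panel)
    for sample in samples:
        df0 = frames[sample]
        for metric in metrics:
            scale = 10.0 if metric.endswith("_pct") else 1.0
            df = decompose(df0, column=metric, group=group, scale=scale)
            for outcome in outcomes:
                spec = ModelSpec(
                    outcome=outcome, metric=metric, sample=sample,
                    covariates=covariates, scale=scale,
                )
                row = {"sample": sample, "metric": metric, "outcome": outcome}
                try:
                    res = fit_glmm(df, spec=spec, group=group, n_quad=n_quad)
                    sf = res.summary_frame()
                    eff = sf.columns[2]  # 'IRR' or 'OR'
                    mean_count = float(df[outcome].mean())
                    row.update(
                        {
                            "family": res.fit.family,
                            "exp_bp": sf.loc["bp", eff],
                            "bp_ci_low": sf.loc["bp", "ci_low"],
                            "bp_ci_high": sf.loc["bp", "ci_high"],
                            "exp_wp": sf.loc["wp", eff],
                            "wp_ci_low": sf.loc["wp", "ci_low"],
                            "wp_ci_high": sf.loc["wp", "ci_high"],
                            "sigma_u2": res.sigma_u2,
                            "icc": icc(res, mean_count=mean_count),
                            "bic": res.bic,
                            "nobs": res.fit.nobs,
                            "ngroups": res.fit.ngroups,
                            "dropped": ";".join(res.dropped),
                            "error": "",
                        }
                    )
                except (FitError, ValueError, np.linalg.LinAlgError) as exc:
                    row.update({"error": f"{type(exc).__name__}: {exc}"})
                rows.append(row)
    return pd.DataFrame(rows)
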