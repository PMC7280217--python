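"""Binomial logit GLMMs with a per-chick random intercept.

The analysis model for the wariness trials: a binary response (approached,
eaten, or eaten restricted to approached rows), fixed experimental factors
(trial, pattern class, contrast level, batch), and a Normal(0, sigma^2)
random intercept per chick.  The marginal likelihood

    L(beta, sigma) = prod_i  E_b[ prod_j Bernoulli(y_ij | logistic(x_ij' beta + b)) ]

is maximized directly, with the one-dimensional per-chick integral
evaluated by Gauss-Hermite quadrature (31 nodes by default; one node
reduces to the Laplace-at-zero approximation).  Maximum likelihood — not
quasi-likelihood — so AIC is well defined and usable for the model-
reduction rules:

1. drop the batch factor if its Wald test is non-significant (alpha=0.05);
2. drop the trial x pattern x contrast three-way interaction iff doing so
   lowers AIC (otherwise it is retained).

Per-term tests are Wald chi-square (multi-df terms tested as coefficient
blocks); F-statistics with software-specific denominator df conventions
are deliberately not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import chi2

__all__ = [
    "ModelSpec",
    "GlmmFit",
    "full_factorial_spec",
    "fit_glmm",
    "reduce_model",
    "analysis_report",
]

RESPONSES = ("approached", "eaten", "eaten_given_approached")

BATCH_TERM = "C(batch)"
THREE_WAY_TERM = "C(trial):C(pattern_class):C(contrast_level)"

_FACTORIAL_TERMS = [
    "C(trial)",
    "C(pattern_class)",
    "C(contrast_level)",
    "C(trial):C(pattern_class)",
    "C(trial):C(contrast_level)",
    "C(pattern_class):C(contrast_level)",
    THREE_WAY_TERM,
]


@dataclass(frozen=True)
class ModelSpec:
    """One GLMM: response, fixed-effect terms, chick random intercept."""

    response: str
    fixed_terms: tuple[str, ...]
    group_col: str = "chick_id"

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")

    @property
    def formula_rhs(self) -> str:
        return "1 + " + " + ".join(self.fixed_terms) if self.fixed_terms else "1"

    def without(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise ValueError(f"term {term!r} not in model")
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))


def full_factorial_spec(response: str, include_batch: bool = True) -> ModelSpec:
    """Full factorial trial x pattern x contrast model (trial categorical),
    plus a batch main effect, mirroring the study's starting model."""
    terms = list(_FACTORIAL_TERMS)
    if include_batch:
        terms.append(BATCH_TERM)
    return ModelSpec(response=response, fixed_terms=tuple(terms))


@dataclass(frozen=True)
class GlmmFit:
    """Fitted model: ML estimates, per-term Wald tests, AIC."""

    coefficients: pd.DataFrame  # index term-coefficient name: estimate, se
    tests: pd.DataFrame  # index term: wald_chi2, df, p_value
    sigma_chick: float
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_groups: int
    model_spec: ModelSpec
    cov: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> pd.Series:
        return self.coefficients["estimate"]


def _prepare(records: pd.DataFrame, spec: ModelSpec):
    df = records.copy()
    if spec.response == "eaten_given_approached":
        df = df[df["approached"] == 1]
        y_col = "eaten"
    else:
        y_col = spec.response
    if df.empty:
        raise ValueError("no rows left for this response")
    y = df[y_col].to_numpy(float)
    X = patsy.dmatrix(spec.formula_rhs, df, return_type="dataframe")
    design_info = X.design_info
    Xm = np.asarray(X, dtype=float)
    # detect aliased (collinear) columns up front
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        raise ValueError(
            f"design matrix is singular (rank {rank} < {Xm.shape[1]} columns); "
            f"check for aliased factors among {list(design_info.term_names)}"
        )
    groups, group_idx = np.unique(df[spec.group_col].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 chicks")
    order = np.argsort(group_idx, kind="stable")
    return y[order], Xm[order], group_idx[order], len(groups), design_info


class _MarginalNLL:
    """Negative marginal log-likelihood and analytic gradient.

    Rows must be sorted by group; per-group sums use ``reduceat``.
    """

    def __init__(self, y, X, group_idx, n_groups, n_quad=31):
        self.y, self.X = y, X
        self.n_groups = n_groups
        self.starts = np.searchsorted(group_idx, np.arange(n_groups))
        self.col_group = group_idx
        nodes, weights = hermgauss(n_quad)
        self.nodes = nodes  # b = sqrt(2) * sigma * node
        self.logw = np.log(weights / np.sqrt(np.pi))

    def value_grad(self, theta):
        beta, logsig = theta[:-1], theta[-1]
        sigma = np.exp(logsig)
        b = np.sqrt(2.0) * sigma * self.nodes  # (K,)
        eta = self.X @ beta + b[:, None]  # (K, n)
        # log Bernoulli pmf, numerically stable
        ll_rows = self.y * eta - np.logaddexp(0.0, eta)
        S = np.add.reduceat(ll_rows, self.starts, axis=1)  # (K, G)
        lse = logsumexp(self.logw[:, None] + S, axis=0)  # (G,)
        nll = -float(lse.sum())
        # responsibilities of quadrature nodes per group
        R = np.exp(self.logw[:, None] + S - lse[None, :])  # (K, G)
        resid = self.y - 1.0 / (1.0 + np.exp(-eta))  # (K, n)
        w_rows = R[:, self.col_group]  # (K, n)
        m = (w_rows * resid).sum(axis=0)  # (n,)
        grad_beta = -(self.X.T @ m)
        grad_logsig = -float(((w_rows * resid).sum(axis=1) * b).sum())
        return nll, np.append(grad_beta, grad_logsig)


def _start_values(y, X):
    """A few damped IRLS-style Newton steps on the plain GLM for warm start."""
    beta = np.zeros(X.shape[1])
    for _ in range(8):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = np.clip(p * (1 - p), 1e-6, None)
        try:
            step = np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -3, 3)
        beta = beta + step
        if np.abs(step).max() < 1e-6:
            break
    return np.clip(beta, -10, 10)


_LOGSIG_LO = -8.0  # sigma ~ 3e-4: numerically a plain GLM


def fit_glmm(records: pd.DataFrame, spec: ModelSpec, n_quad: int = 31) -> GlmmFit:
    """Fit by direct maximization of the Gauss-Hermite marginal likelihood.

    Returns ML estimates, per-term Wald chi-square tests from the inverse
    observed-information covariance, and AIC counting the random-intercept
    variance as one parameter.  A fit that fails the optimizer's own
    convergence test is returned flagged, never raised.
    """
    y, X, gidx, n_groups, design_info = _prepare(records, spec)
    nll = _MarginalNLL(y, X, gidx, n_groups, n_quad=n_quad)
    x0 = np.append(_start_values(y, X), np.log(0.5))
    bounds = [(None, None)] * X.shape[1] + [(_LOGSIG_LO, 3.0)]
    res = optimize.minimize(
        nll.value_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = res.x
    p = X.shape[1]
    sigma = float(np.exp(theta[-1]))
    at_floor = theta[-1] <= _LOGSIG_LO + 1e-6

    # observed information: central finite differences of the analytic gradient
    n_par = p + 1
    H = np.empty((n_par, n_par))
    h = 1e-5 * (1.0 + np.abs(theta))
    for j in range(n_par):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        gp = nll.value_grad(tp)[1]
        gm = nll.value_grad(tm)[1]
        H[:, j] = (gp - gm) / (2.0 * h[j])
    H = 0.5 * (H + H.T)
    if at_floor:
        # variance on the boundary: profile it out, covariance from the beta block
        cov_beta = np.linalg.pinv(H[:p, :p])
        cov = np.zeros((n_par, n_par))
        cov[:p, :p] = cov_beta
    else:
        cov = np.linalg.pinv(H)
        cov_beta = cov[:p, :p]

    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    coef = pd.DataFrame(
        {"estimate": theta[:p], "se": se}, index=design_info.column_names
    )

    rows = {}
    for term, sl in design_info.term_name_slices.items():
        b = theta[:p][sl]
        V = cov_beta[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        df_t = b.size
        rows[term] = {
            "wald_chi2": stat,
            "df": df_t,
            "p_value": float(chi2.sf(stat, df_t)) if np.isfinite(stat) else np.nan,
        }
    tests = pd.DataFrame(rows).T
    tests["df"] = tests["df"].astype(int)

    loglik = -res.fun
    aic = 2.0 * res.fun + 2.0 * (p + 1)
    return GlmmFit(
        coefficients=coef,
        tests=tests,
        sigma_chick=sigma,
        loglik=float(loglik),
        aic=float(aic),
        converged=bool(res.success),
        n_obs=len(y),
        n_groups=n_groups,
        model_spec=spec,
        cov=cov,
    )


def _term_p(fit: GlmmFit, term: str) -> float:
    return float(fit.tests.loc[term, "p_value"])


def reduce_model(
    records: pd.DataFrame,
    full_spec: ModelSpec | None = None,
    response: str | None = None,
    alpha: float = 0.05,
    n_quad: int = 31,
) -> tuple[GlmmFit, list[dict]]:
    """Apply the study's two model-reduction rules in order.

    1. Fit the full factorial model with batch; if the batch term is not
       significant at ``alpha``, pool over batches (drop the term).
    2. Refit without the trial x pattern x contrast three-way interaction;
       keep the reduced model iff its AIC is lower, otherwise retain the
       interaction.

    Any non-convergent candidate fit defers the decision (the richer
    model is kept) and is logged.  Returns the final fit and the
    reduction log (one entry per candidate decision).
    """
    if full_spec is None:
        if response is None:
            raise ValueError("give either full_spec or response")
        full_spec = full_factorial_spec(response)
    log: list[dict] = []
    current = fit_glmm(records, full_spec, n_quad=n_quad)

    # rule 1: batch pooling
    if BATCH_TERM in full_spec.fixed_terms:
        entry = {"rule": "batch_pooling", "term": BATCH_TERM,
                 "aic_with": current.aic, "aic_without": None}
        if not current.converged:
            entry.update(decision="deferred: full model did not converge", dropped=False)
            log.append(entry)
        else:
            p_batch = _term_p(current, BATCH_TERM)
            entry["p_value"] = p_batch
            if p_batch >= alpha:
                cand = fit_glmm(records, current.model_spec.without(BATCH_TERM), n_quad=n_quad)
                if cand.converged:
                    entry.update(aic_without=cand.aic, dropped=True,
                                 decision=f"batch non-significant (p={p_batch:.3f}); pooled")
                    current = cand
                else:
                    entry.update(dropped=False,
                                 decision="deferred: reduced model did not converge")
            else:
                entry.update(dropped=False,
                             decision=f"batch significant (p={p_batch:.3f}); retained")
            log.append(entry)

    # rule 2: three-way interaction, by AIC
    if THREE_WAY_TERM in current.model_spec.fixed_terms:
        cand = fit_glmm(records, current.model_spec.without(THREE_WAY_TERM), n_quad=n_quad)
        entry = {"rule": "three_way_interaction", "term": THREE_WAY_TERM,
                 "aic_with": current.aic, "aic_without": cand.aic}
        if not cand.converged:
            entry.update(dropped=False, decision="deferred: reduced model did not converge")
        elif cand.aic < current.aic:
            entry.update(dropped=True,
                         decision=f"AIC improved ({current.aic:.1f} -> {cand.aic:.1f}); removed")
            current = cand
        else:
            entry.update(dropped=False,
                         decision=f"AIC did not improve ({current.aic:.1f} -> {cand.aic:.1f}); retained")
        log.append(entry)

    return current, log


def analysis_report(records: pd.DataFrame, n_quad: int = 31) -> dict:
    """Run the full analysis: reduced GLMM per response plus proportion
    tables ready for the per-group-per-trial figures."""
    from .behavior import summarize_proportions

    report: dict = {"responses": {}, "proportions": None}
    for response in RESPONSES:
        fit, log = reduce_model(records, response=response, n_quad=n_quad)
        report["responses"][response] = {
            "final_terms": list(fit.model_spec.fixed_terms),
            "coefficients": fit.coefficients,
            "tests": fit.tests,
            "sigma_chick": fit.sigma_chick,
            "aic": fit.aic,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "reduction_log": log,
        }
    report["proportions"] = summarize_proportions(records)
    return report


def report_to_text(report: dict) -> str:
    """Human-readable rendering of an analysis report."""
    lines = []
    for response, r in report["responses"].items():
        lines.append(f"== Response: {response} ==")
        lines.append(f"final fixed terms: {', '.join(r['final_terms'])}")
        lines.append(
            f"sigma_chick={r['sigma_chick']:.3f}  AIC={r['aic']:.1f}  "
            f"logLik={r['loglik']:.1f}  n={r['n_obs']}  converged={r['converged']}"
        )
        lines.append("per-term Wald tests:")
        lines.append(r["tests"].to_string(float_format=lambda v: f"{v:.4f}"))
        for e in r["reduction_log"]:
            lines.append(f"  [{e['rule']}] {e['decision']}")
        lines.append("")
    lines.append("== Proportions (per group x trial) ==")
    lines.append(report["proportions"].to_string(index=False))
    return "\n".join(lines)
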