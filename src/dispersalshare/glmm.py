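"""Binomial random-intercept GLMM and the forward-selection protocol.

The response is (successes k, trials n) per observation — the shared ASV
count over the human sample's richness.  The model is binomial with a logit
link, a subject-level random intercept, and timepoint always included as a
fixed effect (except in per-timepoint refits).  Estimation maximizes the
Laplace-approximated marginal likelihood; an adaptive Gauss-Hermite option
is available (1 quadrature point = Laplace).

Selection protocol: each candidate is first screened one-by-one for a
candidate x timepoint interaction (likelihood-ratio test of the interaction
block, rows complete for that candidate only).  The first variable entering
is the one with the lowest Wald p below 0.05; subsequent additions are
AIC-gated (accept only if AIC drops by >= 3) on rows complete for all
candidates; the final model is refit on rows complete for the selected
variables only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

TIMEPOINT_ORDER = ("S", "A", "W")

#: the seven explanatory variables and how they enter the linear predictor
COVARIATE_KINDS = {
    "built": "continuous",
    "outdoor": "continuous",
    "gardening": "binary",  # 1 = at_least_monthly
    "pets": "binary",  # 1 = yes
    "handwashing": "binary",  # 1 = many_times_a_day
    "number_of_persons": "continuous",
    "real_mat_days": "continuous",
}

_BINARY_CODING = {
    "gardening": {"rarely": 0.0, "at_least_monthly": 1.0},
    "pets": {"no": 0.0, "yes": 1.0},
    "handwashing": {"max_once_a_day": 0.0, "many_times_a_day": 1.0},
}


# ---------------------------------------------------------------------------
# model data assembly
# ---------------------------------------------------------------------------


def assemble_model_data(
    shared_records,
    covariates,
    human_type: str,
    exclude_antibiotics: bool = True,
) -> pd.DataFrame:
    """Build the modeling frame for one human sample type.

    One row per (subject, timepoint) observation with successes ``k``,
    trials ``n``, and numerically coded covariates (NaN = missing).
    Observations flagged for antibiotic use within 6 months are excluded by
    default.
    """
    cov_by_subject = {c.subject_id: c for c in covariates}
    rows = []
    for rec in shared_records:
        if rec.human_type != human_type:
            continue
        cov = cov_by_subject.get(rec.subject_id)
        if cov is None:
            continue
        ab = cov.antibiotics_last_6mo.get(rec.timepoint)
        if exclude_antibiotics and ab:
            continue
        row = {
            "subject": rec.subject_id,
            "timepoint": rec.timepoint,
            "k": rec.shared_count,
            "n": rec.human_richness,
            "built": np.nan if cov.built is None else float(cov.built),
            "outdoor": np.nan if cov.outdoor is None else float(cov.outdoor),
            "number_of_persons": (
                np.nan if cov.number_of_persons is None else float(cov.number_of_persons)
            ),
            "real_mat_days": (
                np.nan
                if rec.timepoint not in cov.real_mat_days
                else float(cov.real_mat_days[rec.timepoint])
            ),
        }
        for name, coding in _BINARY_CODING.items():
            val = getattr(cov, name)
            row[name] = np.nan if val is None else coding[val]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Fixed-effect structure; the subject random intercept is implicit."""

    terms: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()  # covariates crossed with timepoint
    include_timepoint: bool = True

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        self.interactions = tuple(self.interactions)
        for c in self.interactions:
            if c not in self.terms:
                raise ValueError(
                    f"interaction {c!r} x timepoint requires {c!r} as a main effect"
                )
        if self.interactions and not self.include_timepoint:
            raise ValueError("timepoint interactions require the timepoint main effect")

    def with_term(self, term: str, interaction: bool = False) -> "ModelSpec":
        terms = self.terms if term in self.terms else self.terms + (term,)
        inter = (
            self.interactions + (term,)
            if interaction and term not in self.interactions
            else self.interactions
        )
        return ModelSpec(terms, inter, self.include_timepoint)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept, timepoint dummies (reference = first
    timepoint present in S,A,W order), covariates and covariate x timepoint
    interaction columns."""
    n_obs = len(data)
    cols: list[np.ndarray] = [np.ones(n_obs)]
    names: list[str] = ["(Intercept)"]
    tp_dummies: dict[str, np.ndarray] = {}
    if spec.include_timepoint:
        present = [t for t in TIMEPOINT_ORDER if t in set(data["timepoint"])]
        for tp in present[1:]:
            dummy = (data["timepoint"] == tp).to_numpy(dtype=float)
            tp_dummies[tp] = dummy
            cols.append(dummy)
            names.append(f"timepoint{tp}")
    for term in spec.terms:
        vals = data[term].to_numpy(dtype=float)
        cols.append(vals)
        names.append(term)
    for term in spec.interactions:
        vals = data[term].to_numpy(dtype=float)
        for tp, dummy in tp_dummies.items():
            cols.append(vals * dummy)
            names.append(f"{term}:timepoint{tp}")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify dependent columns incrementally
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            kept.append(j)
        else:
            bad.append(names[j])
    raise ValueError(f"rank-deficient design; collinear terms: {bad}")


# ---------------------------------------------------------------------------
# Laplace / adaptive Gauss-Hermite marginal likelihood
# ---------------------------------------------------------------------------


def _binom_constant(k: np.ndarray, n: np.ndarray) -> float:
    return float(
        (special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)).sum()
    )


def _glm_loglik(beta: np.ndarray, X: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    eta = X @ beta
    return float((k * eta - n * np.logaddexp(0.0, eta)).sum())


def _posterior_modes(
    eta_fixed: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    groups: np.ndarray,
    m: int,
    sigma: float,
    b0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject modes of the random-intercept posterior (vectorized Newton).

    The objective is strictly concave in each b, so undamped Newton with a
    step cap converges; returns (b_hat, curvature w = -d2/db2 at the mode).
    """
    inv_s2 = 1.0 / (sigma * sigma)
    b = b0.copy()
    for _ in range(100):
        eta = eta_fixed + b[groups]
        mu = special.expit(eta)
        grad = np.bincount(groups, weights=k - n * mu, minlength=m) - b * inv_s2
        w = np.bincount(groups, weights=n * mu * (1.0 - mu), minlength=m) + inv_s2
        step = np.clip(grad / w, -4.0, 4.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-11:
            break
    eta = eta_fixed + b[groups]
    mu = special.expit(eta)
    w = np.bincount(groups, weights=n * mu * (1.0 - mu), minlength=m) + inv_s2
    return b, w


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def marginal_loglik(
    beta: np.ndarray,
    sigma: float,
    X: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    groups: np.ndarray,
    m: int,
    b0: np.ndarray | None = None,
    nagq: int = 1,
) -> tuple[float, np.ndarray]:
    """Marginal log-likelihood (without the binomial constant) and the
    posterior modes.  ``sigma == 0`` gives the exact independent binomial
    log-likelihood."""
    eta_fixed = X @ beta
    if sigma < 1e-8:
        ll = float((k * eta_fixed - n * np.logaddexp(0.0, eta_fixed)).sum())
        return ll, np.zeros(m)
    if b0 is None:
        b0 = np.zeros(m)
    b, w = _posterior_modes(eta_fixed, k, n, groups, m, sigma, b0)
    inv_s2 = 1.0 / (sigma * sigma)
    eta = eta_fixed + b[groups]
    data_ll = np.bincount(
        groups, weights=k * eta - n * np.logaddexp(0.0, eta), minlength=m
    )
    if nagq <= 1:
        # Laplace: g(b_hat) + 0.5*log(2*pi) - 0.5*log(w); prior terms explicit
        per_group = (
            data_ll - 0.5 * b * b * inv_s2 - np.log(sigma) - 0.5 * np.log(w)
        )
        return float(per_group.sum()), b
    if nagq not in _GH_CACHE:
        nodes, weights = np.polynomial.hermite.hermgauss(nagq)
        _GH_CACHE[nagq] = (nodes, weights)
    nodes, weights = _GH_CACHE[nagq]
    sd = 1.0 / np.sqrt(w)  # m
    bq = b[:, None] + np.sqrt(2.0) * sd[:, None] * nodes[None, :]  # m x q
    eta_q = eta_fixed[:, None] + bq[groups]  # obs x q
    data_ll_q = np.zeros((m, nagq))
    contrib = k[:, None] * eta_q - n[:, None] * np.logaddexp(0.0, eta_q)
    for q in range(nagq):
        data_ll_q[:, q] = np.bincount(groups, weights=contrib[:, q], minlength=m)
    log_prior = -0.5 * bq**2 * inv_s2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    log_integrand = data_ll_q + log_prior + nodes[None, :] ** 2 + np.log(weights)[None, :]
    log_integrand += 0.5 * np.log(2.0) + np.log(sd)[:, None]
    per_group = special.logsumexp(log_integrand, axis=1)
    return float(per_group.sum()), b


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    spec: ModelSpec
    coefficient_names: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    random_intercept_sd: float
    loglik: float
    aic: float
    n_obs: int
    n_subjects: int
    converged: bool
    optimizer: str
    separation_flag: bool = False
    # design payload retained for simulation-based diagnostics
    X: np.ndarray | None = None
    k: np.ndarray | None = None
    n: np.ndarray | None = None
    group_codes: np.ndarray | None = None
    subject_labels: list[str] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return len(self.estimates) + 1  # fixed effects + random-intercept SD

    @property
    def coefficients(self) -> dict[str, tuple[float, float, float, float]]:
        return {
            name: (float(e), float(s), float(z), float(p))
            for name, e, s, z, p in zip(
                self.coefficient_names,
                self.estimates,
                self.standard_errors,
                self.z_values,
                self.p_values,
            )
        }

    def wald_p(self, name: str) -> float:
        return self.coefficients[name][3]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.coefficient_names,
                "estimate": self.estimates,
                "se": self.standard_errors,
                "z": self.z_values,
                "p": self.p_values,
            }
        )


def _irls_start(X: np.ndarray, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """A few IRLS steps of the plain binomial GLM for starting values."""
    p_obs = (k + 0.5) / (n + 1.0)
    beta = np.zeros(X.shape[1])
    beta[0] = special.logit(np.clip(p_obs.mean(), 1e-6, 1 - 1e-6))
    for _ in range(8):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(n * mu * (1 - mu), 1e-10, None)
        z = eta + (k - n * mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta_new)):
            break
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = np.clip(beta_new, -30, 30)
    return beta


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    nagq: int = 1,
    max_sigma: float = 25.0,
    fix_sigma: float | None = None,
) -> FitResult:
    """Fit the binomial-logit random-intercept model by (adaptive) Laplace ML.

    Retries with a derivative-free optimizer if the gradient-based one fails
    to converge.  Complete separation is flagged on the result, not raised.
    """
    needed = ["subject", "timepoint", "k", "n", *spec.terms]
    sub = data[needed]
    if sub.isna().any().any():
        bad = [c for c in needed if sub[c].isna().any()]
        raise ValueError(f"missing values in model terms: {bad}; drop rows first")
    subjects = list(dict.fromkeys(data["subject"]))
    if len(subjects) < 2:
        raise ValueError("GLMM requires at least 2 subjects")
    X, names = build_design(data, spec)
    _check_rank(X, names)
    k = data["k"].to_numpy(dtype=float)
    n = data["n"].to_numpy(dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    groups = np.array([subjects.index(s) for s in data["subject"]])
    m = len(subjects)
    const = _binom_constant(k, n)

    cache = {"b": np.zeros(m)}

    def nll(theta: np.ndarray) -> float:
        beta, sigma = theta[:-1], abs(theta[-1])
        ll, b = marginal_loglik(
            beta, sigma, X, k, n, groups, m, b0=cache["b"], nagq=nagq
        )
        cache["b"] = b
        return -ll

    beta0 = _irls_start(X, k, n)
    if fix_sigma is not None:
        theta0 = np.append(beta0, fix_sigma)
        bounds = [(None, None)] * X.shape[1] + [(fix_sigma, fix_sigma)]
    else:
        theta0 = np.append(beta0, 0.5)
        bounds = [(None, None)] * X.shape[1] + [(0.0, max_sigma)]
    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6, "eps": 1e-6},
    )
    optimizer = "L-BFGS-B"
    if not res.success:
        if fix_sigma is None:
            res2 = optimize.minimize(
                nll,
                res.x,
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
        else:
            res2 = optimize.minimize(
                lambda b: nll(np.append(b, fix_sigma)),
                res.x[:-1],
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
            res2.x = np.append(res2.x, fix_sigma)
        if res2.fun <= res.fun:
            res = res2
            res.x[-1] = np.clip(abs(res.x[-1]), 0.0, max_sigma)
        optimizer = "Nelder-Mead (derivative-free retry)"
    theta_hat = res.x
    beta_hat, sigma_hat = theta_hat[:-1], float(max(theta_hat[-1], 0.0))
    loglik = -nll(np.append(beta_hat, sigma_hat)) + const

    # Wald covariance: beta-block Hessian at the fitted variance parameter
    p = X.shape[1]
    h = 1e-5 * (1.0 + np.abs(beta_hat))
    H = np.zeros((p, p))
    f0 = nll(theta_hat)

    def nll_beta(b: np.ndarray) -> float:
        return nll(np.append(b, sigma_hat))

    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (
                    nll_beta(beta_hat + ei) - 2 * f0 + nll_beta(beta_hat - ei)
                ) / (h[i] * h[i])
            else:
                val = (
                    nll_beta(beta_hat + ei + ej)
                    - nll_beta(beta_hat + ei - ej)
                    - nll_beta(beta_hat - ei + ej)
                    + nll_beta(beta_hat - ei - ej)
                ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    separation = False
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        separation = True
    if np.any(~np.isfinite(se)) or np.any(se == 0):
        se = np.where(np.isfinite(se) & (se > 0), se, np.inf)
    if np.any(np.abs(beta_hat) > 12) or np.any(se > 50):
        separation = True
    z = np.where(se > 0, beta_hat / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    n_params = p + 1
    aic = 2.0 * n_params - 2.0 * loglik
    return FitResult(
        spec=spec,
        coefficient_names=names,
        estimates=beta_hat,
        standard_errors=se,
        z_values=z,
        p_values=pvals,
        random_intercept_sd=sigma_hat,
        loglik=loglik,
        aic=aic,
        n_obs=len(data),
        n_subjects=m,
        converged=bool(res.success or np.isfinite(res.fun)),
        optimizer=optimizer,
        separation_flag=separation,
        X=X,
        k=k.astype(np.int64),
        n=n.astype(np.int64),
        group_codes=groups,
        subject_labels=subjects,
    )


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """(statistic, df, p) for nested fits on identical data."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("LRT requires fits on identical observations")
    df = len(full.estimates) - len(reduced.estimates)
    if df <= 0:
        raise ValueError("full model must have more parameters")
    lr = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return lr, df, float(stats.chi2.sf(lr, df))


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    candidate: str
    keep_interaction: bool
    model: FitResult
    interaction_p: float | None
    entry_p_wald: float
    entry_p_lrt: float
    n_rows: int


def _complete_rows(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = ["subject", "timepoint", "k", "n", *terms]
    return data.dropna(subset=cols).reset_index(drop=True)


def screen_interaction(
    candidate: str,
    data: pd.DataFrame,
    include_timepoint: bool = True,
    alpha: float = 0.05,
    min_rows: int = 10,
    nagq: int = 1,
) -> ScreenResult:
    """One-candidate screen: test the candidate x timepoint interaction block
    by LRT; fall back to the main-effects model when it is not significant."""
    rows = _complete_rows(data, [candidate])
    if len(rows) < min_rows:
        raise ValueError(
            f"candidate {candidate!r}: only {len(rows)} complete rows (< {min_rows})"
        )
    base_spec = ModelSpec((candidate,), (), include_timepoint)
    null_spec = ModelSpec((), (), include_timepoint)
    if include_timepoint:
        if rows["timepoint"].nunique() < 2:
            raise ValueError(
                f"candidate {candidate!r}: degenerate design — a single timepoint "
                "cannot estimate a timepoint interaction"
            )
        int_spec = ModelSpec((candidate,), (candidate,), True)
        fit_int = fit_glmm(int_spec, rows, nagq=nagq)
        fit_main = fit_glmm(base_spec, rows, nagq=nagq)
        _, _, p_int = likelihood_ratio_test(fit_int, fit_main)
        keep = p_int < alpha and fit_int.converged and not fit_int.separation_flag
        model = fit_int if keep else fit_main
    else:
        fit_main = fit_glmm(base_spec, rows, nagq=nagq)
        p_int = None
        keep = False
        model = fit_main
    fit_null = fit_glmm(null_spec, rows, nagq=nagq)
    _, _, p_lrt = likelihood_ratio_test(model, fit_null)
    return ScreenResult(
        candidate=candidate,
        keep_interaction=keep,
        model=model,
        interaction_p=p_int,
        entry_p_wald=model.wald_p(candidate),
        entry_p_lrt=p_lrt,
        n_rows=len(rows),
    )


@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    interactions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "selected": list(self.selected),
            "interactions": list(self.interactions),
        }


def forward_select(
    candidates: Sequence[str],
    data: pd.DataFrame,
    include_timepoint: bool = True,
    alpha: float = 0.05,
    aic_threshold: float = 3.0,
    nagq: int = 1,
) -> tuple[FitResult, SelectionTrace]:
    """The full selection protocol.

    Step 1 uses rows complete for each candidate separately and gates entry
    on the candidate's Wald p (< alpha).  Later steps use rows complete for
    all candidates and accept the lowest-AIC addition only when AIC drops by
    at least ``aic_threshold``.  The final model is refit on rows complete
    for the selected variables only.  AIC ties break toward fewer
    parameters, then candidate input order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    trace = SelectionTrace()

    # --- step 1: per-candidate screen on candidate-complete rows ---------
    screens: dict[str, ScreenResult] = {}
    step1: list[dict] = []
    for c in candidates:
        try:
            scr = screen_interaction(
                c, data, include_timepoint=include_timepoint, alpha=alpha, nagq=nagq
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            step1.append({"candidate": c, "error": str(exc)})
            continue
        screens[c] = scr
        step1.append(
            {
                "candidate": c,
                "n_rows": scr.n_rows,
                "interaction_p": scr.interaction_p,
                "keep_interaction": scr.keep_interaction,
                "entry_p_wald": scr.entry_p_wald,
                "entry_p_lrt": scr.entry_p_lrt,
            }
        )
    eligible = {c: s for c, s in screens.items() if s.entry_p_wald < alpha}
    if not eligible:
        base = fit_glmm(
            ModelSpec((), (), include_timepoint), _complete_rows(data, []), nagq=nagq
        )
        trace.steps.append(
            {"step": 1, "kind": "p_gate", "candidates": step1, "decision": "none entered"}
        )
        return base, trace
    first = min(eligible, key=lambda c: eligible[c].entry_p_wald)
    trace.steps.append(
        {"step": 1, "kind": "p_gate", "candidates": step1, "decision": f"enter {first}"}
    )
    trace.selected.append(first)
    if screens[first].keep_interaction:
        trace.interactions.append(first)

    # --- steps >= 2: AIC-gated additions on all-candidate-complete rows --
    data_cc = _complete_rows(data, candidates)
    spec = ModelSpec(
        (first,), (first,) if first in trace.interactions else (), include_timepoint
    )
    current = fit_glmm(spec, data_cc, nagq=nagq)
    remaining = [c for c in candidates if c not in trace.selected]
    step_no = 2
    while remaining:
        trials: list[dict] = []
        best = None  # (aic, n_params, order, candidate, fit, spec)
        for order, c in enumerate(remaining):
            cand_spec = spec.with_term(
                c, interaction=c in screens and screens[c].keep_interaction
            )
            try:
                fit_c = fit_glmm(cand_spec, data_cc, nagq=nagq)
            except (ValueError, np.linalg.LinAlgError) as exc:
                trials.append({"candidate": c, "error": str(exc)})
                continue
            trials.append({"candidate": c, "aic": fit_c.aic, "n_params": fit_c.n_parameters})
            key = (round(fit_c.aic, 10), fit_c.n_parameters, order)
            if best is None or key < best[0]:
                best = (key, c, fit_c, cand_spec)
        if best is None:
            trace.steps.append(
                {"step": step_no, "kind": "aic_gate", "candidates": trials,
                 "decision": "stop (no fittable candidate)"}
            )
            break
        _, c_best, fit_best, spec_best = best
        delta = current.aic - fit_best.aic
        if delta >= aic_threshold:
            trace.steps.append(
                {"step": step_no, "kind": "aic_gate", "candidates": trials,
                 "current_aic": current.aic, "decision": f"enter {c_best}",
                 "delta_aic": delta}
            )
            trace.selected.append(c_best)
            if c_best in screens and screens[c_best].keep_interaction:
                trace.interactions.append(c_best)
            spec = spec_best
            current = fit_best
            remaining.remove(c_best)
            step_no += 1
        else:
            trace.steps.append(
                {"step": step_no, "kind": "aic_gate", "candidates": trials,
                 "current_aic": current.aic, "decision": "stop", "delta_aic": delta}
            )
            break

    # --- final refit on rows complete for the selected variables only ----
    final_rows = _complete_rows(data, trace.selected)
    final = fit_glmm(spec, final_rows, nagq=nagq)
    trace.steps.append(
        {"step": step_no + 1, "kind": "final_refit", "n_rows": len(final_rows),
         "terms": list(spec.terms), "interactions": list(spec.interactions)}
    )
    return final, trace


def per_timepoint_models(
    candidates: Sequence[str],
    data: pd.DataFrame,
    min_obs: int = 15,
    alpha: float = 0.05,
    aic_threshold: float = 3.0,
    nagq: int = 1,
) -> tuple[dict[str, tuple[FitResult, SelectionTrace]], dict[str, str]]:
    """Re-run the selection within each timepoint (timepoint term removed,
    random intercept retained).  Small strata are skipped with a reason."""
    results: dict[str, tuple[FitResult, SelectionTrace]] = {}
    skipped: dict[str, str] = {}
    for tp in TIMEPOINT_ORDER:
        sub = data[data["timepoint"] == tp].reset_index(drop=True)
        if len(sub) == 0:
            continue
        if len(sub) < min_obs:
            skipped[tp] = f"only {len(sub)} observations (< {min_obs})"
            continue
        if sub["subject"].nunique() < 2:
            skipped[tp] = "fewer than 2 subjects"
            continue
        try:
            results[tp] = forward_select(
                candidates,
                sub,
                include_timepoint=False,
                alpha=alpha,
                aic_threshold=aic_threshold,
                nagq=nagq,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            skipped[tp] = f"selection failed: {exc}"
    return results, skipped


# ---------------------------------------------------------------------------
# simulation-based residual diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ResidualDiagnostics:
    scaled_residuals: np.ndarray
    ks_statistic: float
    ks_p: float
    dispersion_ratio: float
    dispersion_p: float
    n_simulations: int
    seed: int


def simulate_response(fit: FitResult, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw response vectors from the fitted model: new random intercepts
    from the fitted SD, then binomial noise.  Shape (size, n_obs)."""
    if fit.X is None:
        raise ValueError("fit carries no design payload")
    m = fit.n_subjects
    b = rng.normal(0.0, fit.random_intercept_sd, size=(size, m))
    eta = fit.X @ fit.estimates + b[:, fit.group_codes]
    mu = special.expit(eta)
    return rng.binomial(fit.n[None, :].repeat(size, axis=0), mu)


def simulate_residuals(
    fit: FitResult, n_sim: int = 250, seed: int = 0
) -> ResidualDiagnostics:
    """DHARMa-style scaled quantile residuals plus uniformity and dispersion
    tests against the fitted model's simulation distribution."""
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if not fit.converged:
        raise ValueError("cannot simulate residuals from a non-converged fit")
    rng = np.random.default_rng(seed)
    sims = simulate_response(fit, rng, size=n_sim)  # n_sim x n_obs
    obs = fit.k
    below = (sims < obs[None, :]).sum(axis=0)
    equal = (sims == obs[None, :]).sum(axis=0)
    u = rng.uniform(size=len(obs))
    scaled = (below + u * (equal + 1)) / (n_sim + 1.0)
    ks_stat, ks_p = stats.kstest(scaled, "uniform")
    mu_marginal = special.expit(fit.X @ fit.estimates)
    denom = np.sqrt(np.clip(fit.n * mu_marginal * (1 - mu_marginal), 1e-12, None))
    pearson_obs = (obs - fit.n * mu_marginal) / denom
    pearson_sim = (sims - fit.n[None, :] * mu_marginal[None, :]) / denom[None, :]
    var_obs = pearson_obs.var(ddof=1)
    var_sim = pearson_sim.var(axis=1, ddof=1)
    ratio = var_obs / var_sim.mean()
    p_hi = (1 + (var_sim >= var_obs).sum()) / (n_sim + 1.0)
    p_lo = (1 + (var_sim <= var_obs).sum()) / (n_sim + 1.0)
    dispersion_p = min(1.0, 2.0 * min(p_hi, p_lo))
    return ResidualDiagnostics(
        scaled_residuals=scaled,
        ks_statistic=float(ks_stat),
        ks_p=float(ks_p),
        dispersion_ratio=float(ratio),
        dispersion_p=float(dispersion_p),
        n_simulations=n_sim,
        seed=seed,
    )
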