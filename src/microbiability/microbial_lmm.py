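"""Microbial mixed linear model: REML variance components and microbiability.

The model is

    y = Xb + m + e,    m ~ N(0, sigma2_m * M),    e_l ~ N(0, sigma2_e_l * I_l)

where y holds the (transformed) trait records, Xb the fixed effects (line,
and the run x pen combination when significant), m the random microbial
animal effect with the microbial relationship matrix M as covariance kernel,
and e residuals with a separate variance per selection line (heterogeneous
residuals). Microbiability per line is

    m2_l = sigma2_m / (sigma2_m + sigma2_e_l),

the fraction of the line's phenotypic variance explained by the microbial
variance — the microbiome analogue of heritability.

Estimation is restricted maximum likelihood via average-information (AI)
updates with an expectation-maximization fallback when an AI proposal leaves
the parameter space or fails to improve the restricted likelihood. A variance
component whose estimate pins at the lower boundary for three consecutive
iterations is "fixed at the boundary": it stays there, its standard error is
reported as missing, and the likelihood-ratio test against the model without
m degenerates to D = 0 and p = 1.

The significance of the microbial effect is tested with

    D = 2 [logL(full) - logL(reduced)],   D ~ chi2(1) under the null,

matching the convention used with ASReml-style software. Because the null
pins sigma2_m at the boundary, the asymptotically correct reference is a
50:50 mixture of chi2(0) and chi2(1); that mixture p-value is reported as a
diagnostic alongside the chi2(1) one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .mrm import MicrobialRelationshipMatrix

MAX_ITER = 200
TOL_LOGL = 1e-8
TOL_THETA = 1e-6
BOUNDARY_PATIENCE = 3


class ConvergenceError(RuntimeError):
    """REML did not converge; carries the iteration trajectory."""

    def __init__(self, message: str, trajectory: list | None = None):
        super().__init__(message)
        self.trajectory = trajectory or []


class DesignError(ValueError):
    """Rank-deficient or otherwise invalid fixed-effects design."""


class OptimizationError(RuntimeError):
    """Inconsistent likelihoods between nested fits."""


# ---------------------------------------------------------------------------
# fixed-effects design
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Fixed-effect structure and residual grouping for one trait fit."""

    trait: str
    include_line: bool = True
    include_run_pen: bool = False
    screen_pvalue: float | None = None

    def describe(self) -> str:
        terms = ["intercept"]
        if self.include_line:
            terms.append("line")
        if self.include_run_pen:
            terms.append("run:pen")
        return " + ".join(terms)


def _dummy_code(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Reference-level dummy coding; first level (sorted) is the reference."""
    levels = sorted(pd.unique(labels))
    cols = [(labels == lv).astype(float) for lv in levels[1:]]
    names = [str(lv) for lv in levels[1:]]
    if not cols:
        return np.empty((len(labels), 0)), []
    return np.column_stack(cols), names


def build_design(
    metadata: pd.DataFrame,
    include_line: bool = True,
    include_run_pen: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed-effects design matrix from sample metadata.

    Raises DesignError naming the offending columns when dummy columns are
    confounded (e.g., a run x pen cell nested entirely within one line).
    """
    n = len(metadata)
    X = np.ones((n, 1))
    names = ["intercept"]
    if include_line:
        d, lv = _dummy_code(metadata["line"].to_numpy())
        X = np.hstack([X, d])
        names += [f"line[{v}]" for v in lv]
    if include_run_pen:
        combo = (
            metadata["run"].astype(str) + ":" + metadata["pen"].astype(str)
        ).to_numpy()
        d, lv = _dummy_code(combo)
        X = np.hstack([X, d])
        names += [f"run:pen[{v}]" for v in lv]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not add rank
        bad = []
        kept = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.hstack([kept, X[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = cand
        raise DesignError(f"rank-deficient design; confounded columns: {bad}")
    return X, names


def fixed_effect_screen(
    y: np.ndarray,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> ModelSpec:
    """Decide whether the run x pen combination enters the fixed effects.

    A joint F-test of the run:pen dummies in the fixed-effects-only (OLS)
    model with the line effect; the factor is included when p < alpha.
    Levels confounded with line are dropped with a warning rather than
    failing the screen.
    """
    y = np.asarray(y, dtype=float)
    combo = (metadata["run"].astype(str) + ":" + metadata["pen"].astype(str)).to_numpy()
    spec = ModelSpec(trait="", include_line=True)
    if len(pd.unique(combo)) < 2:
        spec.screen_pvalue = 1.0
        return spec
    X0, _ = build_design(metadata, include_line=True, include_run_pen=False)
    try:
        X1, _ = build_design(metadata, include_line=True, include_run_pen=True)
    except DesignError as exc:
        warnings.warn(f"run:pen confounded with line; factor dropped ({exc})",
                      stacklevel=2)
        spec.screen_pvalue = np.nan
        return spec
    n = len(y)
    rss0 = float(np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
    df1 = X1.shape[1] - X0.shape[1]
    df2 = n - X1.shape[1]
    if df2 <= 0 or rss1 <= 0:
        spec.screen_pvalue = np.nan
        return spec
    f_stat = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    spec.screen_pvalue = p
    spec.include_run_pen = p < alpha
    return spec


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def reml_loglik(
    theta: np.ndarray, y: np.ndarray, X: np.ndarray, kernels: list[np.ndarray]
) -> float:
    """Restricted log-likelihood at variance components ``theta``.

    l_R = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ] - (n-p)/2 log(2*pi)
    with V = sum_i theta_i K_i and P the REML projection matrix.
    """
    n, p = X.shape
    V = np.zeros((n, n))
    for t, K in zip(theta, kernels):
        V += t * K
    c, low = scipy.linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vinv_y = scipy.linalg.cho_solve((c, low), y)
    vinv_x = scipy.linalg.cho_solve((c, low), X)
    xtvx = X.T @ vinv_x
    c2 = scipy.linalg.cholesky(xtvx, lower=True)
    logdet_x = 2.0 * np.sum(np.log(np.diag(c2)))
    beta = scipy.linalg.cho_solve((c2, True), X.T @ vinv_y)
    quad = float(y @ vinv_y - (X.T @ vinv_y) @ beta)
    return float(
        -0.5 * (logdet_v + logdet_x + quad) - 0.5 * (n - p) * np.log(2 * np.pi)
    )


def _reml_state(theta, y, X, kernels):
    """Log-likelihood plus the pieces AI/EM updates need (P, Py)."""
    n, p = X.shape
    V = np.zeros((n, n))
    for t, K in zip(theta, kernels):
        V += t * K
    try:
        c, low = scipy.linalg.cho_factor(V, lower=True)
    except scipy.linalg.LinAlgError:
        return None
    eye = np.eye(n)
    vinv = scipy.linalg.cho_solve((c, low), eye)
    vinv_x = vinv @ X
    xtvx = X.T @ vinv_x
    try:
        c2 = scipy.linalg.cholesky(xtvx, lower=True)
    except scipy.linalg.LinAlgError:
        return None
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    logdet_x = 2.0 * np.sum(np.log(np.diag(c2)))
    tmp = scipy.linalg.cho_solve((c2, True), vinv_x.T)
    P = vinv - vinv_x @ tmp
    Py = P @ y
    logl = float(
        -0.5 * (logdet_v + logdet_x + float(y @ Py))
        - 0.5 * (n - p) * np.log(2 * np.pi)
    )
    return {"logl": logl, "P": P, "Py": Py}


@dataclass
class REMLFit:
    """Raw optimizer output: components in kernel order plus diagnostics."""

    theta: np.ndarray
    names: list[str]
    se: np.ndarray
    boundary: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    grad_norm: float
    trajectory: list = field(default_factory=list)


def _ai_reml(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    names: list[str],
    q_em: np.ndarray,
    start: np.ndarray,
    eps_b: float,
    max_iter: int = MAX_ITER,
) -> REMLFit:
    """Average-information REML with EM fallback and boundary fixing."""
    theta = np.maximum(np.asarray(start, dtype=float), eps_b)
    k = len(kernels)
    fixed = np.zeros(k, dtype=bool)
    bound_count = np.zeros(k, dtype=int)
    traj: list = []

    state = _reml_state(theta, y, X, kernels)
    if state is None:
        raise ConvergenceError("covariance matrix not positive definite at start")
    prev_logl = -np.inf
    prev_theta = theta.copy()
    grad = np.zeros(k)
    ai = np.eye(k)
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        P, Py = state["P"], state["Py"]
        KPy = [K @ Py for K in kernels]
        grad = np.array(
            [-0.5 * (np.sum(P * K) - float(Py @ kpy))
             for K, kpy in zip(kernels, KPy)]
        )
        ai = 0.5 * np.array(
            [[float(KPy[i] @ P @ KPy[j]) for j in range(k)] for i in range(k)]
        )
        traj.append({"iter": it, "theta": theta.copy(), "logl": state["logl"]})

        free = ~fixed
        rel_change = np.max(
            np.abs(theta - prev_theta) / np.maximum(np.abs(prev_theta), eps_b)
        )
        if it > 1 and abs(state["logl"] - prev_logl) < TOL_LOGL and rel_change < TOL_THETA:
            converged = True
            break
        prev_logl = state["logl"]
        prev_theta = theta.copy()
        if not free.any():
            converged = True
            break

        # AI proposal with step halving; EM fallback
        ai_free = ai[np.ix_(free, free)]
        try:
            delta = np.linalg.solve(ai_free, grad[free])
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(ai_free, grad[free], rcond=None)[0]
        accepted = None
        step = 1.0
        for _ in range(6):
            prop = theta.copy()
            prop[free] = np.maximum(theta[free] + step * delta, eps_b)
            trial = _reml_state(prop, y, X, kernels)
            if trial is not None and trial["logl"] >= state["logl"] - 1e-10:
                accepted = (prop, trial)
                break
            step *= 0.5
        if accepted is None:
            # EM-REML update: sigma_i^2 <- sigma_i^2 + sigma_i^4 (y'PK_iPy - tr(PK_i)) / q_i
            prop = theta.copy()
            for i in np.where(free)[0]:
                upd = theta[i] + theta[i] ** 2 * (
                    float(Py @ KPy[i]) - np.sum(P * kernels[i])
                ) / q_em[i]
                prop[i] = max(upd, eps_b)
            trial = _reml_state(prop, y, X, kernels)
            if trial is None:
                raise ConvergenceError(
                    "EM fallback produced an indefinite covariance", traj
                )
            accepted = (prop, trial)
        theta, state = accepted

        at_bound = theta <= eps_b * (1.0 + 1e-9)
        bound_count = np.where(at_bound, bound_count + 1, 0)
        newly_fixed = (bound_count >= BOUNDARY_PATIENCE) & ~fixed
        if newly_fixed.any():
            fixed |= newly_fixed
            theta[fixed] = eps_b

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", traj
        )

    # standard errors from the inverse AI matrix over free components
    se = np.full(k, np.nan)
    free = ~fixed
    if free.any():
        ai_free = ai[np.ix_(free, free)]
        try:
            cov = np.linalg.inv(ai_free)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            se[free] = np.sqrt(d)
        except np.linalg.LinAlgError:
            pass
    return REMLFit(
        theta=theta,
        names=list(names),
        se=se,
        boundary=fixed,
        loglik=state["logl"],
        n_iter=it,
        converged=converged,
        grad_norm=float(np.linalg.norm(grad[~fixed])) if (~fixed).any() else 0.0,
        trajectory=traj,
    )


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """REML variance components with SEs and boundary flags.

    ``sigma2_m`` is None for the reduced (no microbial effect) model. SEs of
    components fixed at the boundary are NaN ("NA").
    """

    sigma2_m: float | None
    sigma2_e: dict[str, float]
    se_m: float
    se_e: dict[str, float]
    boundary: dict[str, bool]
    loglik: float
    n_iter: int
    grad_norm: float

    def as_dict(self) -> dict:
        out = {
            "sigma2_m": self.sigma2_m,
            "se_m": None if np.isnan(self.se_m) else self.se_m,
            "sigma2_e": dict(self.sigma2_e),
            "se_e": {
                l: (None if np.isnan(v) else v) for l, v in self.se_e.items()
            },
            "boundary": dict(self.boundary),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
        }
        return out


def _align(y, metadata, M):
    y = np.asarray(y, dtype=float)
    if len(y) != len(metadata):
        raise ValueError("y and metadata length mismatch")
    if M is not None:
        ids = list(metadata["animal_id"].astype(str))
        if list(M.sample_ids) != ids:
            M = M.reorder(ids)
    return y, M


def reml_fit(
    y: np.ndarray,
    metadata: pd.DataFrame,
    M: MicrobialRelationshipMatrix | None,
    spec: ModelSpec | None = None,
    homogeneous_residuals: bool = False,
) -> tuple[VarianceComponents, REMLFit]:
    """Fit the microbial mixed model (or the reduced model when M is None).

    Residuals are heterogeneous across lines by default; each line needs at
    least 2 animals. Returns the packaged variance components and the raw
    optimizer output.
    """
    if spec is None:
        spec = ModelSpec(trait="", include_line=True)
    y, M = _align(y, metadata, M)
    n = len(y)
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("trait has zero variance")
    eps_b = 1e-6 * vary

    X, _ = build_design(
        metadata, include_line=spec.include_line, include_run_pen=spec.include_run_pen
    )

    lines = metadata["line"].astype(str).to_numpy()
    groups = ["all"] if homogeneous_residuals else sorted(pd.unique(lines))
    kernels: list[np.ndarray] = []
    names: list[str] = []
    q_em: list[float] = []
    starts: list[float] = []
    if M is not None:
        kernels.append(M.matrix)
        names.append("sigma2_m")
        q_em.append(float(n))
        starts.append(0.1 * vary)
    for g in groups:
        mask = np.ones(n, bool) if g == "all" else (lines == g)
        if mask.sum() < 2:
            raise ValueError(f"line {g!r} has fewer than 2 animals")
        kernels.append(np.diag(mask.astype(float)))
        names.append(f"sigma2_e[{g}]")
        q_em.append(float(mask.sum()))
        starts.append((0.9 if M is not None else 1.0) * float(np.var(y[mask])))

    fit = _ai_reml(
        y, X, kernels, names, np.asarray(q_em), np.asarray(starts), eps_b
    )

    offset = 1 if M is not None else 0
    sigma2_e = {g: float(fit.theta[offset + i]) for i, g in enumerate(groups)}
    se_e = {g: float(fit.se[offset + i]) for i, g in enumerate(groups)}
    boundary = {names[i]: bool(fit.boundary[i]) for i in range(len(names))}
    vc = VarianceComponents(
        sigma2_m=float(fit.theta[0]) if M is not None else None,
        sigma2_e=sigma2_e,
        se_m=float(fit.se[0]) if M is not None else np.nan,
        se_e=se_e,
        boundary=boundary,
        loglik=fit.loglik,
        n_iter=fit.n_iter,
        grad_norm=fit.grad_norm,
    )
    return vc, fit


def microbiability(vc: VarianceComponents) -> dict[str, float]:
    """m2_l = sigma2_m / (sigma2_m + sigma2_e_l) per residual group."""
    if vc.sigma2_m is None:
        raise ValueError("reduced model has no microbial variance")
    return {
        l: vc.sigma2_m / (vc.sigma2_m + s2) for l, s2 in vc.sigma2_e.items()
    }


def lrt_microbial_effect(
    logl_full: float, logl_reduced: float
) -> tuple[float, float]:
    """Likelihood-ratio test of the microbial effect: D = 2(logL2 - logL1).

    D is referred to a chi-squared distribution with one degree of freedom.
    D is clipped below at zero (a boundary estimate makes the two restricted
    likelihoods coincide, giving D = 0 and p = 1).
    """
    if logl_reduced > logl_full + 1e-4:
        raise OptimizationError(
            f"reduced logL {logl_reduced:.6f} exceeds full logL {logl_full:.6f}"
        )
    d = max(0.0, 2.0 * (logl_full - logl_reduced))
    p = float(stats.chi2.sf(d, df=1))
    return d, p


def mixture_pvalue(d: float) -> float:
    """Boundary-corrected p-value from the 50:50 chi2(0):chi2(1) mixture."""
    if d <= 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(d, df=1))


@dataclass
class MicrobiabilityResult:
    """Full vs reduced model comparison for one trait in one subset."""

    trait: str
    m2: dict[str, float]
    components: VarianceComponents
    components_reduced: VarianceComponents
    logl_full: float
    logl_reduced: float
    d_statistic: float
    p_value: float
    p_value_mixture: float
    spec: ModelSpec
    n_animals: int

    def as_dict(self) -> dict:
        return {
            "trait": self.trait,
            "n_animals": self.n_animals,
            "fixed_effects": self.spec.describe(),
            "run_pen_screen_pvalue": self.spec.screen_pvalue,
            "m2": {k: float(v) for k, v in self.m2.items()},
            "full": self.components.as_dict(),
            "reduced": self.components_reduced.as_dict(),
            "D": self.d_statistic,
            "p_value": self.p_value,
            "p_value_mixture": self.p_value_mixture,
        }


def fit_microbiability(
    y: np.ndarray,
    metadata: pd.DataFrame,
    M: MicrobialRelationshipMatrix,
    trait: str = "",
    include_run_pen: bool | str = "auto",
    alpha: float = 0.05,
) -> MicrobiabilityResult:
    """Fit full and reduced models for one trait; return microbiabilities + LRT.

    ``include_run_pen="auto"`` screens the run x pen combination with a joint
    F-test at level ``alpha`` and includes it only when significant.
    """
    y = np.asarray(y, dtype=float)
    if include_run_pen == "auto":
        spec = fixed_effect_screen(y, metadata, alpha=alpha)
        spec.trait = trait
    else:
        spec = ModelSpec(trait=trait, include_run_pen=bool(include_run_pen))
    vc_full, _ = reml_fit(y, metadata, M, spec=spec)
    vc_red, _ = reml_fit(y, metadata, None, spec=spec)
    d, p = lrt_microbial_effect(vc_full.loglik, vc_red.loglik)
    if vc_full.boundary.get("sigma2_m", False):
        # boundary estimate: full and reduced models coincide
        d, p = 0.0, 1.0
    return MicrobiabilityResult(
        trait=trait,
        m2=microbiability(vc_full),
        components=vc_full,
        components_reduced=vc_red,
        logl_full=vc_full.loglik,
        logl_reduced=vc_red.loglik,
        d_statistic=d,
        p_value=p,
        p_value_mixture=mixture_pvalue(d),
        spec=spec,
        n_animals=len(y),
    )
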