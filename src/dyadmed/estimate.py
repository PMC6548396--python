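"""Fitting the Actor-Partner Interdependence Mediation Model (APIMeM).

The model for a distinguishable dyad observes six variables per dyad,
``(x1, x2, m1, m2, y1, y2)`` -- predictor (perceived social support), mediator
(family health) and outcome (family functioning) for the patient (1) and the
nearest relative (2) -- and posits twelve directed paths:

    m1 = alpha_m1 + a_A1*x1 + a_P1*x2 + e1
    m2 = alpha_m2 + a_A2*x2 + a_P2*x1 + e2
    y1 = alpha_y1 + cp_A1*x1 + cp_P1*x2 + b_A1*m1 + b_P1*m2 + e3
    y2 = alpha_y2 + cp_A2*x2 + cp_P2*x1 + b_A2*m2 + b_P2*m1 + e4

``A`` marks actor paths, ``P`` partner paths; the numeric subscript is the
role *receiving* the path (a_P1 is the relative's support acting on the
patient's health).  (x1, x2) covary freely (C1); so do the two mediator
errors (C2) and the two outcome errors (C3); mediator and outcome errors are
uncorrelated.

Because the two mediator equations share the regressor set (1, x1, x2) and
the two outcome equations share (1, x1, x2, m1, m2), and the model is
saturated (21 covariance parameters for 21 moments), per-equation ordinary
least squares *is* the maximum-likelihood SEM solution: ``fit_saturated``
exploits this closed form.  ``fit_constrained`` minimises the multivariate
normal ML discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - 6

subject to path-equality constraints; chi2 = (n - 1) * F_min with df equal to
the number of independent constraints.  For fixed paths the block-diagonal
residual covariance has a closed-form ML update, so the optimisation is
concentrated onto the free path parameters only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .dyads import DyadDataset, to_wide
from .errors import ConvergenceError, EstimationError, UndefinedStatisticError

PATH_NAMES = (
    "a_A1", "a_P1", "a_A2", "a_P2",
    "b_A1", "b_P1", "b_A2", "b_P2",
    "cp_A1", "cp_P1", "cp_A2", "cp_P2",
)

#: the six patient/relative equalities of the empirical distinguishability test
ROLE_EQUALITY_CONSTRAINTS = (
    ("a_A1", "a_A2"), ("a_P1", "a_P2"),
    ("b_A1", "b_A2"), ("b_P1", "b_P2"),
    ("cp_A1", "cp_A2"), ("cp_P1", "cp_P2"),
)

_VAR_ORDER = ("x1", "x2", "m1", "m2", "y1", "y2")
# (row, col) of each path in the 6x6 structural matrix A, v = A v + alpha + u
_PATH_POSITIONS = {
    "a_A1": (2, 0), "a_P1": (2, 1), "a_A2": (3, 1), "a_P2": (3, 0),
    "cp_A1": (4, 0), "cp_P1": (4, 1), "b_A1": (4, 2), "b_P1": (4, 3),
    "cp_A2": (5, 1), "cp_P2": (5, 0), "b_A2": (5, 3), "b_P2": (5, 2),
}


@dataclass
class PathCoefficients:
    """The twelve structural paths plus the four endogenous intercepts."""

    a_A1: float
    a_P1: float
    a_A2: float
    a_P2: float
    b_A1: float
    b_P1: float
    b_A2: float
    b_P2: float
    cp_A1: float
    cp_P1: float
    cp_A2: float
    cp_P2: float
    alpha_m1: float = 0.0
    alpha_m2: float = 0.0
    alpha_y1: float = 0.0
    alpha_y2: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "PathCoefficients":
        missing = [p for p in PATH_NAMES if p not in d]
        if missing:
            raise KeyError(f"missing path coefficient(s): {missing}")
        return cls(**{k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__})

    def structural_matrix(self) -> np.ndarray:
        """6x6 matrix A with A[i, j] the path from variable j to variable i."""
        A = np.zeros((6, 6))
        d = self.as_dict()
        for name, (i, j) in _PATH_POSITIONS.items():
            A[i, j] = d[name]
        return A


@dataclass
class ResidualStructure:
    """Second moments of the error terms and the exogenous block."""

    mediator_cov: np.ndarray   # 2x2 for (e1, e2): houses C2
    outcome_cov: np.ndarray    # 2x2 for (e3, e4): houses C3
    exog_mean: np.ndarray      # means of (x1, x2)
    exog_cov: np.ndarray       # 2x2 sample covariance of (x1, x2): houses C1


@dataclass
class FitStats:
    """Likelihood-ratio fit of a constrained model against the saturated one."""

    chi2: float
    df: int
    p: float
    rmsea: float


@dataclass
class ApimemFit:
    paths: PathCoefficients
    se: dict
    resid: ResidualStructure
    r2_per_equation: dict
    r2_overall: float
    n: int
    coef_cov: np.ndarray | None = None   # 12x12 covariance of the path estimates
    log: list = field(default_factory=list)


def _as_wide(data) -> np.ndarray:
    if isinstance(data, DyadDataset):
        wide, _ = to_wide(data)
        return wide
    wide = np.asarray(data, dtype=float)
    if wide.ndim != 2 or wide.shape[1] != 6:
        raise EstimationError(f"expected (n, 6) data, got shape {wide.shape}")
    return wide


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        sds = X.std(axis=0)
        flat = [names[i] for i in range(1, X.shape[1]) if sds[i] == 0]
        what = f"constant column(s) {flat}" if flat else "collinear regressors"
        raise EstimationError(f"rank-deficient design: {what}")


def solve_paths(wide: np.ndarray) -> PathCoefficients:
    """Closed-form (OLS) path estimates only -- the fast inner kernel used by
    the bootstrap.  No standard errors, no checks beyond solvability."""
    n = wide.shape[0]
    ones = np.ones((n, 1))
    x = wide[:, 0:2]
    m = wide[:, 2:4]
    y = wide[:, 4:6]
    Xm = np.hstack([ones, x])
    Bm = np.linalg.solve(Xm.T @ Xm, Xm.T @ m)      # (3, 2)
    Xo = np.hstack([ones, x, m])
    Bo = np.linalg.solve(Xo.T @ Xo, Xo.T @ y)      # (5, 2)
    return PathCoefficients(
        a_A1=Bm[1, 0], a_P1=Bm[2, 0], a_A2=Bm[2, 1], a_P2=Bm[1, 1],
        cp_A1=Bo[1, 0], cp_P1=Bo[2, 0], b_A1=Bo[3, 0], b_P1=Bo[4, 0],
        cp_A2=Bo[2, 1], cp_P2=Bo[1, 1], b_A2=Bo[4, 1], b_P2=Bo[3, 1],
        alpha_m1=Bm[0, 0], alpha_m2=Bm[0, 1],
        alpha_y1=Bo[0, 0], alpha_y2=Bo[0, 1],
    )


# mapping from (equation, regressor index) to path name, per equation column
_MED_COEF_NAMES = {0: {1: "a_A1", 2: "a_P1"}, 1: {1: "a_P2", 2: "a_A2"}}
_OUT_COEF_NAMES = {
    0: {1: "cp_A1", 2: "cp_P1", 3: "b_A1", 4: "b_P1"},
    1: {1: "cp_P2", 2: "cp_A2", 3: "b_P2", 4: "b_A2"},
}


def fit_saturated(data) -> ApimemFit:
    """Fit the saturated APIMeM by per-equation least squares.

    The saturated path model reproduces the sample covariance exactly
    (chi2 = 0, df = 0), so these estimates coincide with the SEM maximum
    likelihood solution.  Standard errors are normal-theory per-equation OLS
    errors; the joint covariance of the twelve path estimates accounts for
    the correlated errors within the mediator pair and within the outcome
    pair (cross-pair covariances are exactly zero in sample because the
    outcome residuals are orthogonal to the mediators).
    """
    wide = _as_wide(data)
    n = wide.shape[0]
    if n < 7:
        raise EstimationError(f"need more dyads than parameters per equation: n={n} < 7")
    ones = np.ones((n, 1))
    x, m, y = wide[:, 0:2], wide[:, 2:4], wide[:, 4:6]
    Xm = np.hstack([ones, x])
    Xo = np.hstack([ones, x, m])
    _check_design(Xm, ("const", "x1", "x2"))
    _check_design(Xo, ("const", "x1", "x2", "m1", "m2"))

    XmtXm_inv = np.linalg.inv(Xm.T @ Xm)
    XotXo_inv = np.linalg.inv(Xo.T @ Xo)
    Bm = XmtXm_inv @ Xm.T @ m
    Bo = XotXo_inv @ Xo.T @ y
    Em = m - Xm @ Bm                       # residuals e1, e2
    Eo = y - Xo @ Bo                       # residuals e3, e4

    paths = PathCoefficients(
        a_A1=Bm[1, 0], a_P1=Bm[2, 0], a_A2=Bm[2, 1], a_P2=Bm[1, 1],
        cp_A1=Bo[1, 0], cp_P1=Bo[2, 0], b_A1=Bo[3, 0], b_P1=Bo[4, 0],
        cp_A2=Bo[2, 1], cp_P2=Bo[1, 1], b_A2=Bo[4, 1], b_P2=Bo[3, 1],
        alpha_m1=Bm[0, 0], alpha_m2=Bm[0, 1],
        alpha_y1=Bo[0, 0], alpha_y2=Bo[0, 1],
    )

    # normal-theory standard errors, per equation (n - p denominator)
    se: dict[str, float] = {}
    # clip guards zero-noise data where roundoff makes the RSS tiny-negative
    s2_m = np.clip((Em ** 2).sum(axis=0) / (n - Xm.shape[1]), 0.0, None)
    s2_o = np.clip((Eo ** 2).sum(axis=0) / (n - Xo.shape[1]), 0.0, None)
    for eq, names in _MED_COEF_NAMES.items():
        for idx, name in names.items():
            se[name] = math.sqrt(s2_m[eq] * XmtXm_inv[idx, idx])
    for eq, names in _OUT_COEF_NAMES.items():
        for idx, name in names.items():
            se[name] = math.sqrt(s2_o[eq] * XotXo_inv[idx, idx])

    # joint covariance of the 12 path estimates (order = PATH_NAMES);
    # within a pair sharing design X:  Cov(beta_g, beta_h) = sigma_gh (X'X)^-1
    sig_m = Em.T @ Em / (n - Xm.shape[1])
    sig_o = Eo.T @ Eo / (n - Xo.shape[1])
    coef_cov = np.zeros((12, 12))
    pidx = {name: k for k, name in enumerate(PATH_NAMES)}
    for eq_g, names_g in _MED_COEF_NAMES.items():
        for eq_h, names_h in _MED_COEF_NAMES.items():
            for ig, ng in names_g.items():
                for ih, nh in names_h.items():
                    coef_cov[pidx[ng], pidx[nh]] = sig_m[eq_g, eq_h] * XmtXm_inv[ig, ih]
    for eq_g, names_g in _OUT_COEF_NAMES.items():
        for eq_h, names_h in _OUT_COEF_NAMES.items():
            for ig, ng in names_g.items():
                for ih, nh in names_h.items():
                    coef_cov[pidx[ng], pidx[nh]] = sig_o[eq_g, eq_h] * XotXo_inv[ig, ih]

    resid = ResidualStructure(
        mediator_cov=Em.T @ Em / (n - 1),
        outcome_cov=Eo.T @ Eo / (n - 1),
        exog_mean=x.mean(axis=0),
        exog_cov=np.cov(x, rowvar=False, ddof=1).reshape(2, 2),
    )

    endo = np.hstack([m, y])
    r2_eq = {}
    for k, name in enumerate(("m1", "m2", "y1", "y2")):
        res = Em[:, k] if k < 2 else Eo[:, k - 2]
        tot = endo[:, k] - endo[:, k].mean()
        r2_eq[name] = 1.0 - (res @ res) / (tot @ tot)

    resid4 = np.hstack([Em, Eo])
    S_endo = np.cov(endo, rowvar=False, ddof=1)
    S_res = np.cov(resid4, rowvar=False, ddof=1)
    det_endo = np.linalg.det(S_endo)
    if det_endo <= 0:
        raise EstimationError("singular marginal covariance of the endogenous block")
    r2_all = 1.0 - np.linalg.det(S_res) / det_endo

    return ApimemFit(
        paths=paths, se=se, resid=resid,
        r2_per_equation=r2_eq, r2_overall=float(r2_all),
        n=n, coef_cov=coef_cov,
    )


def overall_r2(fit: ApimemFit) -> float:
    """Generalised (determinant-based) R^2 over the four endogenous variables:
    1 - |residual covariance| / |marginal covariance|."""
    return fit.r2_overall


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root-mean-square error of approximation:
    sqrt(max(chi2 - df, 0) / (df * (n - 1)))."""
    if df <= 0:
        raise UndefinedStatisticError("RMSEA is undefined at df = 0")
    if n <= 1:
        raise UndefinedStatisticError("RMSEA requires n > 1")
    return math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))


def _equivalence_classes(constraints: Sequence[tuple]) -> list[list[str]]:
    """Union-find over path names; returns the classes covering all 12 paths."""
    parent = {p: p for p in PATH_NAMES}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for pair in constraints:
        names = list(pair)
        for nm in names:
            if nm not in parent:
                raise EstimationError(f"unknown path name in constraints: {nm!r}")
        for other in names[1:]:
            ra, rb = find(names[0]), find(other)
            if ra != rb:
                parent[rb] = ra
    classes: dict[str, list[str]] = {}
    for p in PATH_NAMES:
        classes.setdefault(find(p), []).append(p)
    return list(classes.values())


def _implied_sigma(A: np.ndarray, psi: np.ndarray) -> np.ndarray:
    T = np.eye(6) - A
    Tinv = np.linalg.inv(T)
    return Tinv @ psi @ Tinv.T


def fit_constrained(
    data,
    constraints: Sequence[tuple] = ROLE_EQUALITY_CONSTRAINTS,
    gtol: float = 1e-9,
    max_restarts: int = 3,
) -> tuple[ApimemFit, FitStats]:
    """ML fit under path-equality constraints, with the likelihood-ratio test
    against the saturated model.

    The discrepancy is concentrated: for a fixed structural matrix A the
    block-diagonal error covariance maximising the likelihood is the
    corresponding block of (I - A) S (I - A)', so the optimiser searches only
    the free path parameters.  ``chi2 = (n - 1) F_min``; df equals the number
    of independent equality constraints.  An empty constraint list recovers
    the saturated model (chi2 = 0, df = 0).
    """
    wide = _as_wide(data)
    n = wide.shape[0]
    if n < 7:
        raise EstimationError(f"too few dyads: n={n}")
    S = np.cov(wide, rowvar=False, ddof=1)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise EstimationError("sample covariance is singular")

    classes = _equivalence_classes(constraints)
    df = len(PATH_NAMES) - len(classes)

    sat = fit_saturated(wide)
    sat_vals = sat.paths.as_dict()
    theta0 = np.array([np.mean([sat_vals[p] for p in cls]) for cls in classes])

    def build_A(theta: np.ndarray) -> np.ndarray:
        A = np.zeros((6, 6))
        for val, cls in zip(theta, classes):
            for name in cls:
                i, j = _PATH_POSITIONS[name]
                A[i, j] = val
        return A

    def discrepancy(theta: np.ndarray) -> float:
        T = np.eye(6) - build_A(theta)
        G = T @ S @ T.T
        _, ld_x = np.linalg.slogdet(G[:2, :2])
        s_m, ld_m = np.linalg.slogdet(G[2:4, 2:4])
        s_y, ld_y = np.linalg.slogdet(G[4:6, 4:6])
        if s_m <= 0 or s_y <= 0:
            return np.inf
        return ld_x + ld_m + ld_y - logdet_S

    rng = np.random.default_rng(0)
    best = None
    start = theta0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(discrepancy, start, method="BFGS",
                                options={"gtol": gtol, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        grad_norm = float(np.linalg.norm(res.jac))
        if res.fun < np.inf and grad_norm < 1e-5:
            break
        start = theta0 * (1 + 0.05 * rng.standard_normal(theta0.size))
    else:
        raise ConvergenceError(
            "constrained APIMeM fit did not converge",
            best_discrepancy=float(best.fun),
            grad_norm=float(np.linalg.norm(best.jac)),
        )

    theta = best.x
    A = build_A(theta)
    T = np.eye(6) - A
    G = T @ S @ T.T
    psi = np.zeros((6, 6))
    psi[:2, :2], psi[2:4, 2:4], psi[4:6, 4:6] = G[:2, :2], G[2:4, 2:4], G[4:6, 4:6]
    sigma = _implied_sigma(A, psi)

    # intercepts so implied means equal the sample means
    mu = wide.mean(axis=0)
    alpha = T @ mu
    vals = {}
    for val, cls in zip(theta, classes):
        for name in cls:
            vals[name] = float(val)
    paths = PathCoefficients(
        **vals,
        alpha_m1=alpha[2], alpha_m2=alpha[3], alpha_y1=alpha[4], alpha_y2=alpha[5],
    )

    # approximate SEs from the curvature of (n-1)/2 * F at the optimum,
    # mapped back from class parameters to every member path
    se: dict[str, float] = {}
    try:
        H = _num_hessian(discrepancy, theta)
        cov_theta = np.linalg.inv(0.5 * (n - 1) * H)
        sds = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
        for sd, cls in zip(sds, classes):
            for name in cls:
                se[name] = float(sd)
    except np.linalg.LinAlgError:
        se = {name: float("nan") for name in PATH_NAMES}

    r2_eq = {}
    for k, name in zip(range(2, 6), ("m1", "m2", "y1", "y2")):
        r2_eq[name] = 1.0 - psi[k, k] / sigma[k, k]
    det_endo = np.linalg.det(sigma[2:, 2:])
    r2_all = 1.0 - np.linalg.det(psi[2:, 2:]) / det_endo

    resid = ResidualStructure(
        mediator_cov=psi[2:4, 2:4], outcome_cov=psi[4:6, 4:6],
        exog_mean=mu[:2], exog_cov=psi[:2, :2],
    )
    fit = ApimemFit(paths=paths, se=se, resid=resid,
                    r2_per_equation=r2_eq, r2_overall=float(r2_all), n=n,
                    log=[f"discrepancy={best.fun:.3e}", f"grad_norm={np.linalg.norm(best.jac):.2e}"])

    chi2 = max(float((n - 1) * best.fun), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rm = rmsea(chi2, df, n) if df > 0 else 0.0
    return fit, FitStats(chi2=chi2, df=df, p=p, rmsea=rm)


def _num_hessian(f, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian (small, smooth problems only)."""
    k = x0.size
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H
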