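"""Penalized function-on-scalar regression of articulator trajectories.

Model, per articulation site, on the common median-frame grid t = 0..T*-1:

    y_ij(t) = beta0(t) + x_i * beta1(t) + b_i(t) + eps_ij(t)

where i indexes speakers, j repetitions, x_i = 1 for AWS and 0 for FS
(difference coding: with two groups the "ordinal factor" reduces to it, and
the test of beta1 = 0 is a test for a difference in the mean course), and
b_i(t) is a smooth random speaker curve capturing the repeated measurements.
All curves are expanded in a cubic B-spline basis; beta0 and beta1 carry
second-order difference penalties, the speaker curves a ridge penalty on
their basis coefficients.  Smoothing parameters are chosen by Gaussian REML
on the mixed-model representation.  Effective degrees of freedom (edf) per
term are the trace of the term-wise hat matrix.

Inference on the group effect is available two ways: an approximate Wald
test built from the penalized fit's Bayesian covariance, and a permutation
test that re-fits under speaker-level permutations of the group labels (the
calibrated primary option, since edf-based p-values are approximations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .errors import ConfigurationError, ModelError
from .prep import TrajectorySet


@dataclass
class FosrSpec:
    """Configuration of the penalized functional regression."""

    n_basis: int | None = None  # default min(25, max(T*//4, 8))
    spline_order: int = 4  # cubic
    penalty_order: int = 2
    smoothing: str = "REML"
    reference_group: str = "FS"
    #: optional fixed (lambda_beta0, lambda_beta1, lambda_subject); skips REML
    fixed_lambdas: tuple[float, float, float] | None = None

    def resolve_n_basis(self, t_star: int) -> int:
        k = self.n_basis if self.n_basis is not None else min(25, max(t_star // 4, 8))
        if k < self.spline_order + 2:
            raise ConfigurationError(
                f"n_basis={k} must be >= spline order + 2 = {self.spline_order + 2}"
            )
        if self.penalty_order >= k:
            raise ConfigurationError("penalty order must be below n_basis")
        return k


@dataclass
class FosrFit:
    """Fitted penalized function-on-scalar regression for one site."""

    site: str
    spec: FosrSpec
    t_star: int
    basis: np.ndarray  # (T*, K)
    beta0: np.ndarray  # (K,)
    beta1: np.ndarray  # (K,) group difference (AWS - FS with default coding)
    b: np.ndarray  # (n_subjects, K) speaker random curves
    subjects: list
    subject_groups: list[str]
    lambdas: tuple[float, float, float]
    edf: dict[str, float]
    sigma2: float
    reml: float
    # internals retained for prediction and permutation refits
    _X: np.ndarray = field(repr=False, default=None)
    _Ytil: np.ndarray = field(repr=False, default=None)
    _G: np.ndarray = field(repr=False, default=None)
    _P: np.ndarray = field(repr=False, default=None)
    _y_sumsq: float = 0.0
    _n_obs: int = 0
    _subj_idx: np.ndarray = field(repr=False, default=None)

    @property
    def intercept_curve(self) -> np.ndarray:
        return self.basis @ self.beta0

    @property
    def group_effect_curve(self) -> np.ndarray:
        return self.basis @ self.beta1

    def subject_curve(self, i: int) -> np.ndarray:
        x = 1.0 if self.subject_groups[i] != self.spec.reference_group else 0.0
        return self.basis @ (self.beta0 + x * self.beta1 + self.b[i])


def bspline_basis(t_star: int, n_basis: int, order: int = 4) -> np.ndarray:
    """B-spline design matrix on the integer frame grid 0..t_star-1."""
    k = order - 1  # polynomial degree
    n_interior = n_basis - order
    if n_interior < 0:
        raise ConfigurationError("n_basis below spline order")
    interior = np.linspace(0, t_star - 1, n_interior + 2)[1:-1]
    knots = np.concatenate(
        (np.full(order, 0.0), interior, np.full(order, float(t_star - 1)))
    )
    t = np.arange(t_star, dtype=float)
    B = BSpline.design_matrix(t, knots, k, extrapolate=False).toarray()
    return B


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def _design(ts: TrajectorySet, site: str, reference: str):
    wide = ts.curves(site)
    if wide.isna().any().any():
        raise ModelError(f"site {site!r} has incomplete curves")
    idx = wide.index
    groups = idx.get_level_values("group")
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ModelError(f"need exactly 2 groups, found {levels}")
    if reference not in levels:
        raise ConfigurationError(f"reference group {reference!r} not in {levels}")
    subj_order: list = []
    subj_groups: list[str] = []
    for s, g in zip(idx.get_level_values("subject"), groups):
        if s not in subj_order:
            subj_order.append(s)
            subj_groups.append(g)
    for g in levels:
        if sum(1 for x in subj_groups if x == g) < 2:
            raise ModelError(f"need >= 2 subjects per group, group {g!r} too small")
    subj_idx = np.array([subj_order.index(s) for s in idx.get_level_values("subject")])
    x = np.array([0.0 if g == reference else 1.0 for g in groups])
    Y = wide.to_numpy(dtype=float)
    return Y, x, subj_idx, subj_order, subj_groups


def _trial_design_matrix(x: np.ndarray, subj_idx: np.ndarray, n_subj: int) -> np.ndarray:
    n = x.size
    X = np.zeros((n, 2 + n_subj))
    X[:, 0] = 1.0
    X[:, 1] = x
    X[np.arange(n), 2 + subj_idx] = 1.0
    return X


class _PenalizedSolver:
    """Normal-equation machinery shared by the REML search and refits.

    With theta = [beta0; beta1; b_1..b_S] (K coefficients per block) and the
    trial design X (n_trials x (2+S)), the Gram matrix is kron(X'X, B'B) and
    the right-hand side vec(X' Y B).
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, B: np.ndarray, P: np.ndarray):
        self.B = B
        self.P = P
        self.K = B.shape[1]
        self.n_terms = X.shape[1]
        self.G = B.T @ B
        self.X = X
        self.XtX = X.T @ X
        self.Ytil = Y @ B
        self.Cty = (X.T @ self.Ytil).ravel()
        self.y_sumsq = float(np.sum(Y * Y))
        self.n_obs = Y.size

    def penalty(self, lambdas: tuple[float, float, float]) -> np.ndarray:
        l0, l1, lb = lambdas
        K, S = self.K, self.n_terms - 2
        M = np.zeros((self.n_terms * K, self.n_terms * K))
        M[:K, :K] = l0 * self.P
        M[K:2 * K, K:2 * K] = l1 * self.P
        M[2 * K:, 2 * K:] = lb * np.eye(S * K)
        return M

    def solve(self, lambdas):
        A = np.kron(self.XtX, self.G)
        M = A + self.penalty(lambdas)
        try:
            cf = cho_factor(M, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - singular design
            raise ModelError(f"singular penalized system: {exc}") from exc
        theta = cho_solve(cf, self.Cty)
        rss = self.y_sumsq - 2.0 * float(theta @ self.Cty) + float(theta @ (A @ theta))
        pen = float(theta @ (self.penalty(lambdas) @ theta))
        return theta, A, cf, max(rss, 1e-12), max(pen, 0.0)

    def reml_score(self, log_lambdas: np.ndarray) -> float:
        lambdas = tuple(np.exp(np.clip(log_lambdas, -30, 30)))
        theta, A, cf, rss, pen = self.solve(lambdas)
        K, S = self.K, self.n_terms - 2
        mp = 2 * 2  # null-space dimension of the two difference penalties
        n_eff = self.n_obs - mp
        sigma2 = (rss + pen) / n_eff
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        rank_p = K - 2
        logdet_S = (
            rank_p * (math.log(lambdas[0]) + math.log(lambdas[1]))
            + S * K * math.log(lambdas[2])
        )
        return n_eff * math.log(sigma2) + logdet_M - logdet_S

    def edf_blocks(self, lambdas) -> tuple[dict[str, float], float]:
        theta, A, cf, rss, pen = self.solve(lambdas)
        F = cho_solve(cf, A)
        d = np.diag(F)
        K = self.K
        edf = {
            "beta0": float(d[:K].sum()),
            "beta1": float(d[K:2 * K].sum()),
            "subjects": float(d[2 * K:].sum()),
        }
        return edf, float(d.sum())


def fit_fosr(ts: TrajectorySet, site: str, spec: FosrSpec | None = None) -> FosrFit:
    """Fit the penalized function-on-scalar regression for one site."""
    spec = spec or FosrSpec()
    K = spec.resolve_n_basis(ts.t_star)
    Y, x, subj_idx, subjects, subj_groups = _design(ts, site, spec.reference_group)
    B = bspline_basis(ts.t_star, K, spec.spline_order)
    P = difference_penalty(K, spec.penalty_order)
    X = _trial_design_matrix(x, subj_idx, len(subjects))
    solver = _PenalizedSolver(Y, X, B, P)

    if spec.fixed_lambdas is not None:
        lambdas = tuple(float(v) for v in spec.fixed_lambdas)
        reml = solver.reml_score(np.log(np.asarray(lambdas)))
    else:
        # Nelder-Mead from a few fixed starts; the REML surface can be
        # multimodal in the three log smoothing parameters.
        best = None
        for x0 in ((0.0, 0.0, 0.0), (5.0, 5.0, 5.0), (-5.0, -5.0, 0.0), (0.0, -8.0, 0.0)):
            res = optimize.minimize(
                solver.reml_score,
                x0=np.asarray(x0),
                method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-5},
            )
            if best is None or res.fun < best.fun:
                best = res
        lambdas = tuple(np.exp(np.clip(best.x, -30, 30)))
        reml = float(best.fun)

    theta, A, cf, rss, pen = solver.solve(lambdas)
    edf, edf_total = solver.edf_blocks(lambdas)
    mp = 4
    sigma2 = (rss + pen) / (solver.n_obs - mp)
    S = len(subjects)
    return FosrFit(
        site=site,
        spec=spec,
        t_star=ts.t_star,
        basis=B,
        beta0=theta[:K].copy(),
        beta1=theta[K:2 * K].copy(),
        b=theta[2 * K:].reshape(S, K).copy(),
        subjects=subjects,
        subject_groups=subj_groups,
        lambdas=lambdas,
        edf=edf,
        sigma2=float(sigma2),
        reml=float(reml),
        _X=X,
        _Ytil=solver.Ytil,
        _G=solver.G,
        _P=P,
        _y_sumsq=solver.y_sumsq,
        _n_obs=solver.n_obs,
        _subj_idx=subj_idx,
    )


def _wald_from_solver(solver: _PenalizedSolver, lambdas) -> tuple[float, float, float]:
    """(edf1, statistic, p) of the Wald-type test of beta1 = 0."""
    theta, A, cf, rss, pen = solver.solve(lambdas)
    edf, _ = solver.edf_blocks(lambdas)
    K = solver.K
    mp = 4
    sigma2 = (rss + pen) / (solver.n_obs - mp)
    Minv_block = cho_solve(cf, np.eye(solver.n_terms * K)[:, K:2 * K])[K:2 * K, :]
    V1 = sigma2 * Minv_block
    b1 = theta[K:2 * K]
    evals, evecs = np.linalg.eigh((V1 + V1.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r = int(min(K, max(1, round(edf["beta1"]))))
    z = evecs.T @ b1
    stat = float(np.sum(z[:r] ** 2 / np.maximum(evals[:r], 1e-300)))
    p = float(chi2.sf(stat, r))
    return edf["beta1"], stat, p


def test_group_effect(
    fit: FosrFit,
    method: str = "permutation",
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Test beta1(t) = 0; returns (edf of the group term, statistic, p).

    method="wald": approximate chi-square test on the penalized fit's
    Bayesian covariance at rank round(edf).  method="permutation": speaker
    level permutation of the group labels, re-fitting the coefficients at the
    observed smoothing parameters; p = (1 + #{perm stat >= observed}) /
    (1 + n_perm).
    """
    solver = _rebuild_solver(fit)
    edf1, stat, p_wald = _wald_from_solver(solver, fit.lambdas)
    if method == "wald":
        return edf1, stat, p_wald
    if method != "permutation":
        raise ConfigurationError(f"unknown method {method!r}")
    if n_perm < 19:
        raise ConfigurationError("permutation test needs n_perm >= 19")
    rng = np.random.default_rng(seed)
    subj_x = np.array(
        [0.0 if g == fit.spec.reference_group else 1.0 for g in fit.subject_groups]
    )
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(subj_x)
        Xp = fit._X.copy()
        Xp[:, 1] = perm[fit._subj_idx]
        solver.XtX = Xp.T @ Xp
        solver.Cty = (Xp.T @ solver.Ytil).ravel()
        _, stat_p, _ = _wald_from_solver(solver, fit.lambdas)
        if stat_p >= stat:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return edf1, stat, float(p)


def _rebuild_solver(fit: FosrFit) -> _PenalizedSolver:
    solver = _PenalizedSolver.__new__(_PenalizedSolver)
    solver.B = fit.basis
    solver.P = fit._P
    solver.K = fit.basis.shape[1]
    solver.n_terms = fit._X.shape[1]
    solver.X = fit._X
    solver.XtX = fit._X.T @ fit._X
    solver.Ytil = fit._Ytil
    solver.Cty = (fit._X.T @ fit._Ytil).ravel()
    solver.y_sumsq = fit._y_sumsq
    solver.n_obs = fit._n_obs
    solver.G = fit._G
    return solver


def predict_curves(fit: FosrFit, level: str = "group") -> pd.DataFrame:
    """Model-predicted curves as a tidy table (site, level, unit, frame, value).

    level="group": the reference-group curve beta0 and the non-reference
    curve beta0 + beta1.  level="subject": beta0 + x_i beta1 + b_i per
    speaker.
    """
    rows = []
    frames = np.arange(fit.t_star)
    if level == "group":
        ref = fit.spec.reference_group
        other = next(g for g in sorted(set(fit.subject_groups)) if g != ref)
        rows.append((ref, fit.basis @ fit.beta0))
        rows.append((other, fit.basis @ (fit.beta0 + fit.beta1)))
    elif level == "subject":
        for i, s in enumerate(fit.subjects):
            rows.append((s, fit.subject_curve(i)))
    else:
        raise ConfigurationError(f"unknown prediction level {level!r}")
    return pd.concat(
        [
            pd.DataFrame(
                {"site": fit.site, "level": level, "unit": unit, "frame": frames,
                 "value": curve}
            )
            for unit, curve in rows
        ],
        ignore_index=True,
    )


def fit_all_sites(
    ts: TrajectorySet,
    spec: FosrSpec | None = None,
    test: str = "wald",
    n_perm: int = 199,
    seed: int = 0,
) -> dict[str, dict]:
    """Fit every site and summarize edf and group-effect tests."""
    out = {}
    for site in ts.sites:
        fit = fit_fosr(ts, site, spec)
        edf1, stat, p = test_group_effect(fit, method=test, n_perm=n_perm, seed=seed)
        out[site] = {
            "edf_group": edf1,
            "edf_subjects": fit.edf["subjects"],
            "statistic": stat,
            "p": p,
            "lambdas": list(fit.lambdas),
            "fit": fit,
        }
    return out
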