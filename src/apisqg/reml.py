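"""REML animal models on dense relationship matrices.

The model is the single-record animal model

    y = X b + a + e,    a ~ N(0, sigma2_a A),    e ~ N(0, sigma2_e I)

with a week-of-year class as the only fixed effect and one record per queen
(Z = I).  Variance components maximise the restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y + (n - p) log 2 pi ]

with V = sigma2_a A + sigma2_e I and P the usual REML projection.  The
univariate fit diagonalises A once (A = U L U'), which turns every
likelihood evaluation into O(n p^2); the bivariate fit uses the analogous
2x2-block diagonalisation when both traits are complete and falls back to a
dense Cholesky of V over the observed (queen, trait) cells when records are
missing on one trait.

Parameterisation enforces positive definiteness: log-variances in the
univariate case, unconstrained Cholesky factors of G and R (log-diagonal)
in the bivariate case, with a floor of 1e-8 x phenotypic variance and a
boundary flag.  Standard errors come from the observed information —
central finite differences of l_R with relative step 1e-4, taken with
respect to the variance-scale parameters — and the usual first-order delta
method for heritability and the genetic / phenotypic correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize

from .relationship import RelationshipMatrix, phenotyped_submatrix

__all__ = [
    "ModelSpec",
    "ModelError",
    "SingularDesignError",
    "UnivariateFit",
    "BivariateFit",
    "Correlations",
    "fit_univariate",
    "fit_bivariate",
    "heritability",
    "correlations",
    "univariate_loglik",
    "bivariate_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_FLOOR_FRAC = 1e-8  # variance floor as a fraction of phenotypic variance
_FD_REL_STEP = 1e-4  # relative step of the observed-information differences
_COND_LIMIT = 1e8  # information condition number beyond which the fit is flagged
MAX_ITER = 200


class ModelError(ValueError):
    """Invalid model input (missing columns, too few records, ...)."""


class SingularDesignError(ModelError):
    """The fixed-effect design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Trait selection and fixed-effect structure of an animal-model fit."""

    traits: tuple[str, ...]
    fixed_effect: str = "week"
    id_col: str = "queen_id"

    def __post_init__(self) -> None:
        if len(self.traits) not in (1, 2):
            raise ModelError("ModelSpec supports one or two traits")


@dataclass
class UnivariateFit:
    trait: str
    sigma2_a: float
    sigma2_e: float
    loglik: float
    param_cov: np.ndarray  # 2x2 over (sigma2_a, sigma2_e)
    converged: bool
    boundary: bool
    identifiable: bool
    n_used: int
    n_fixed: int
    message: str = ""

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_e


@dataclass
class BivariateFit:
    traits: tuple[str, str]
    G: np.ndarray  # 2x2 genetic covariance
    R: np.ndarray  # 2x2 residual covariance
    loglik: float
    param_cov: np.ndarray  # 6x6 over (g11, g12, g22, r11, r12, r22)
    converged: bool
    boundary: bool
    identifiable: bool
    n_used: dict[str, int]
    n_fixed: int
    message: str = ""


@dataclass
class Correlations:
    r_g: float
    se_g: float
    r_p: float
    se_p: float
    r_g_clamped: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# shared helpers


def _design_matrix(classes: Sequence) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded class indicators (first sorted level dropped).

    With fewer than two observed levels the design degenerates to an
    intercept-only model.  The restricted likelihood depends only on the
    column space, so the choice of reference level is immaterial.
    """
    labels = [str(c) for c in classes]
    levels = sorted(set(labels))
    n = len(labels)
    X = np.ones((n, len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = [1.0 if lab == lev else 0.0 for lab in labels]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("collinear week-class design")
    return X, levels


def _prepare(pheno: pd.DataFrame, trait: str, spec: ModelSpec) -> pd.DataFrame:
    for col in (spec.id_col, spec.fixed_effect, trait):
        if col not in pheno.columns:
            raise ModelError(f"phenotype table lacks column {col!r}")
    sub = pheno[[spec.id_col, spec.fixed_effect, trait]].dropna(subset=[trait])
    if sub[spec.fixed_effect].isna().any():
        raise ModelError("every phenotyped queen needs a week class")
    return sub


def _fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, scale: float) -> np.ndarray:
    """Central-difference Hessian; steps relative to |x_i| with floor ``scale``."""
    k = len(x)
    h = _FD_REL_STEP * np.maximum(np.abs(x), scale)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _cov_from_information(H: np.ndarray) -> tuple[np.ndarray, bool]:
    """(parameter covariance, identifiable) from the loglik Hessian."""
    info = -H
    if not np.all(np.isfinite(info)):
        return np.full_like(info, np.nan), False
    ev = np.linalg.eigvalsh((info + info.T) / 2.0)
    identifiable = ev.min() > 0 and ev.max() / ev.min() < _COND_LIMIT
    if not identifiable:
        return np.full_like(info, np.nan), False
    return np.linalg.inv(info), True


# ---------------------------------------------------------------------------
# univariate


class _UnivariateLik:
    """Restricted likelihood of (sigma2_a, sigma2_e) in the eigenbasis of A."""

    def __init__(self, y: np.ndarray, X: np.ndarray, A: np.ndarray) -> None:
        lam, U = np.linalg.eigh((A + A.T) / 2.0)
        self.lam = np.clip(lam, 0.0, None)
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n, self.p = X.shape

    def loglik(self, s2a: float, s2e: float) -> float:
        return self.loglik_grad(s2a, s2e)[0]

    def loglik_grad(self, s2a: float, s2e: float) -> tuple[float, np.ndarray]:
        """l_R and its gradient wrt (sigma2_a, sigma2_e).

        Uses the standard REML score -1/2 [tr(P V_k) - y' P V_k P y] with
        V_a = diag(lam) and V_e = I in the eigenbasis.
        """
        d = s2a * self.lam + s2e
        if np.any(d <= 0.0) or not np.all(np.isfinite(d)):
            return -np.inf, np.array([np.nan, np.nan])
        w = 1.0 / d
        Xw = self.Xt * w[:, None]
        XtWX = self.Xt.T @ Xw
        XtWy = self.Xt.T @ (w * self.yt)
        try:
            c, low = sla.cho_factor(XtWX)
        except (sla.LinAlgError, ValueError):
            return -np.inf, np.array([np.nan, np.nan])
        beta = sla.cho_solve((c, low), XtWy)
        quad = float(w @ (self.yt * self.yt) - XtWy @ beta)
        logdet_xwx = 2.0 * float(np.sum(np.log(np.diag(c))))
        logdet_v = float(np.sum(np.log(d)))
        ll = -0.5 * (logdet_v + logdet_xwx + quad + (self.n - self.p) * _LOG2PI)

        py = w * (self.yt - self.Xt @ beta)
        Minv_XtW = sla.cho_solve((c, low), Xw.T)  # (p, n)
        # tr(P V_k) = sum_i v_ki / d_i - sum_i v_ki * [X_w M^-1 X_w']_ii
        diag_proj = np.einsum("ij,ji->i", Xw, Minv_XtW)
        g = np.empty(2)
        for k, v in enumerate((self.lam, np.ones_like(self.lam))):
            tr_pv = float(v @ w) - float(v @ diag_proj)
            g[k] = -0.5 * (tr_pv - float(v @ (py * py)))
        return ll, g


def fit_univariate(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    spec: ModelSpec | str,
) -> UnivariateFit:
    """Fit the univariate animal model by REML for one trait.

    ``pheno`` needs columns ``queen_id``, the fixed-effect class and the
    trait (NaN = missing, rows dropped).  ``A`` may cover more queens than
    are phenotyped; the principal submatrix is used.
    """
    if isinstance(spec, str):
        spec = ModelSpec((spec,))
    trait = spec.traits[0]
    sub = _prepare(pheno, trait, spec)
    if len(sub) < 10:
        raise ModelError(f"trait {trait!r}: need >= 10 records, got {len(sub)}")
    ids = sub[spec.id_col].astype(str).tolist()
    y = sub[trait].to_numpy(dtype=float)
    X, _ = _design_matrix(sub[spec.fixed_effect])
    Asub = phenotyped_submatrix(A, ids)
    lik = _UnivariateLik(y, X, Asub.values)

    # scale-free starting point: split the OLS residual variance in half
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    var_p = float(np.var(y - X @ beta0, ddof=X.shape[1]))
    if var_p <= 0.0:
        raise ModelError(f"trait {trait!r} has zero phenotypic variance")
    floor = _FLOOR_FRAC * var_p
    lo, hi = np.log(floor), np.log(1e4 * var_p)

    def neg(theta: np.ndarray) -> tuple[float, np.ndarray]:
        s = np.exp(theta)
        ll, g = lik.loglik_grad(*s)
        if not np.isfinite(ll):
            return np.inf, np.zeros(2)
        return -ll, -g * s  # chain rule to the log scale

    res = optimize.minimize(
        neg,
        x0=np.log([0.5 * var_p, 0.5 * var_p]),
        method="L-BFGS-B",
        jac=True,
        bounds=[(lo, hi), (lo, hi)],
        options={"maxiter": MAX_ITER, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        # line-search hiccups near the optimum: polish derivative-free
        polish = optimize.minimize(
            lambda t: neg(np.clip(t, lo, hi))[0],
            res.x,
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-8, "fatol": 1e-10},
        )
        if polish.fun <= res.fun:
            res = polish
            res.x = np.clip(res.x, lo, hi)
    s2a, s2e = np.exp(res.x)
    boundary = bool(np.any(res.x < lo + 1e-6))
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"REML for {trait!r} did not converge: {res.message}")

    H = _fd_hessian(lambda p: lik.loglik(p[0], p[1]), np.array([s2a, s2e]), 1e-3 * var_p)
    param_cov, identifiable = _cov_from_information(H)
    msg = "" if identifiable else "flat or boundary likelihood direction; SEs unavailable"
    return UnivariateFit(
        trait=trait,
        sigma2_a=float(s2a),
        sigma2_e=float(s2e),
        loglik=float(-res.fun),
        param_cov=param_cov,
        converged=converged,
        boundary=boundary,
        identifiable=identifiable,
        n_used=len(sub),
        n_fixed=X.shape[1],
        message=msg or str(res.message),
    )


def univariate_loglik(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    spec: ModelSpec | str,
    sigma2_a: float,
    sigma2_e: float,
) -> float:
    """Restricted log-likelihood at given variance components (no fitting)."""
    if isinstance(spec, str):
        spec = ModelSpec((spec,))
    trait = spec.traits[0]
    sub = _prepare(pheno, trait, spec)
    ids = sub[spec.id_col].astype(str).tolist()
    X, _ = _design_matrix(sub[spec.fixed_effect])
    lik = _UnivariateLik(sub[trait].to_numpy(dtype=float), X, phenotyped_submatrix(A, ids).values)
    return lik.loglik(sigma2_a, sigma2_e)


# ---------------------------------------------------------------------------
# bivariate


def _chol2(theta: np.ndarray) -> np.ndarray:
    """Lower-triangular 2x2 factor from (log d1, off, log d2)."""
    return np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])


class _BivarComplete:
    """Block-diagonal restricted likelihood when both traits are complete.

    In the eigenbasis of A the covariance of the i-th component pair is the
    2x2 matrix ``G lam_i + R``, so the likelihood is a sum of n cheap terms.
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, A: np.ndarray) -> None:
        lam, U = np.linalg.eigh((A + A.T) / 2.0)
        self.lam = np.clip(lam, 0.0, None)
        self.Yt = U.T @ Y  # (n, 2)
        self.Xt = U.T @ X  # (n, p)
        self.n, self.p = X.shape

    def loglik(self, G: np.ndarray, R: np.ndarray) -> float:
        lam = self.lam
        v11 = G[0, 0] * lam + R[0, 0]
        v12 = G[0, 1] * lam + R[0, 1]
        v22 = G[1, 1] * lam + R[1, 1]
        det = v11 * v22 - v12 * v12
        if np.any(det <= 0.0) or np.any(v11 <= 0.0):
            return -np.inf
        i11, i12, i22 = v22 / det, -v12 / det, v11 / det
        y1, y2 = self.Yt[:, 0], self.Yt[:, 1]
        yvy = float(np.sum(i11 * y1 * y1 + 2.0 * i12 * y1 * y2 + i22 * y2 * y2))
        Xt = self.Xt
        B11 = Xt.T @ (Xt * i11[:, None])
        B12 = Xt.T @ (Xt * i12[:, None])
        B22 = Xt.T @ (Xt * i22[:, None])
        M = np.block([[B11, B12], [B12, B22]])
        u = np.concatenate([Xt.T @ (i11 * y1 + i12 * y2), Xt.T @ (i12 * y1 + i22 * y2)])
        try:
            c, low = sla.cho_factor(M)
        except (sla.LinAlgError, ValueError):
            return -np.inf
        beta = sla.cho_solve((c, low), u)
        quad = yvy - float(u @ beta)
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(c))))
        logdet_v = float(np.sum(np.log(det)))
        npar = 2 * self.n - 2 * self.p
        return -0.5 * (logdet_v + logdet_m + quad + npar * _LOG2PI)


class _BivarMissing:
    """Dense restricted likelihood over the observed (queen, trait) cells."""

    def __init__(
        self,
        y_parts: list[np.ndarray],
        X_parts: list[np.ndarray],
        A_blocks: list[list[np.ndarray]],
        same_queen: np.ndarray,
    ) -> None:
        self.y = np.concatenate(y_parts)
        self.X = sla.block_diag(*X_parts)
        self.A11, self.A12, self.A22 = A_blocks[0][0], A_blocks[0][1], A_blocks[1][1]
        self.same = same_queen  # (n1, n2) indicator: same queen on both traits
        self.n = len(self.y)
        self.p = self.X.shape[1]

    def loglik(self, G: np.ndarray, R: np.ndarray) -> float:
        n1 = self.A11.shape[0]
        V = np.empty((self.n, self.n))
        V[:n1, :n1] = G[0, 0] * self.A11 + R[0, 0] * np.eye(n1)
        V12 = G[0, 1] * self.A12 + R[0, 1] * self.same
        V[:n1, n1:] = V12
        V[n1:, :n1] = V12.T
        V[n1:, n1:] = G[1, 1] * self.A22 + R[1, 1] * np.eye(self.n - n1)
        try:
            c, low = sla.cho_factor(V)
        except (sla.LinAlgError, ValueError):
            return -np.inf
        Vy = sla.cho_solve((c, low), self.y)
        VX = sla.cho_solve((c, low), self.X)
        M = self.X.T @ VX
        u = self.X.T @ Vy
        try:
            cm, lowm = sla.cho_factor(M)
        except (sla.LinAlgError, ValueError):
            return -np.inf
        beta = sla.cho_solve((cm, lowm), u)
        quad = float(self.y @ Vy - u @ beta)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(cm))))
        return -0.5 * (logdet_v + logdet_m + quad + (self.n - self.p) * _LOG2PI)


def _build_bivar_lik(
    pheno: pd.DataFrame, A: RelationshipMatrix, spec: ModelSpec
) -> tuple[object, dict[str, int], int, list[float]]:
    t1, t2 = spec.traits
    subs = [_prepare(pheno, t, spec) for t in (t1, t2)]
    n_used = {t: len(s) for t, s in zip((t1, t2), subs)}
    for t, s in zip((t1, t2), subs):
        if len(s) < 10:
            raise ModelError(f"trait {t!r}: need >= 10 records, got {len(s)}")
    var_p = []
    for t, s in zip((t1, t2), subs):
        X, _ = _design_matrix(s[spec.fixed_effect])
        yv = s[t].to_numpy(dtype=float)
        b0, *_ = np.linalg.lstsq(X, yv, rcond=None)
        var_p.append(float(np.var(yv - X @ b0, ddof=X.shape[1])))

    ids1 = subs[0][spec.id_col].astype(str).tolist()
    ids2 = subs[1][spec.id_col].astype(str).tolist()
    if ids1 == ids2:
        Y = np.column_stack([s.iloc[:, 2].to_numpy(dtype=float) for s in subs])
        X, _ = _design_matrix(subs[0][spec.fixed_effect])
        lik = _BivarComplete(Y, X, phenotyped_submatrix(A, ids1).values)
        return lik, n_used, X.shape[1] * 2, var_p

    idx = A.index
    sel1 = np.array([idx[q] for q in ids1])
    sel2 = np.array([idx[q] for q in ids2])
    A11 = A.values[np.ix_(sel1, sel1)]
    A12 = A.values[np.ix_(sel1, sel2)]
    A22 = A.values[np.ix_(sel2, sel2)]
    same = (np.array(ids1)[:, None] == np.array(ids2)[None, :]).astype(float)
    y_parts, X_parts = [], []
    p_tot = 0
    for t, s in zip((t1, t2), subs):
        X, _ = _design_matrix(s[spec.fixed_effect])
        p_tot += X.shape[1]
        y_parts.append(s[t].to_numpy(dtype=float))
        X_parts.append(X)
    lik = _BivarMissing(y_parts, X_parts, [[A11, A12], [None, A22]], same)
    return lik, n_used, p_tot, var_p


def fit_bivariate(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    spec: ModelSpec | tuple[str, str],
) -> BivariateFit:
    """Fit the bivariate animal model by REML over 6 covariance parameters.

    Records missing on one trait contribute their observed cell only
    (cell-level deletion; queens missing both traits drop out entirely).
    Starting values come from the two univariate fits plus the sample
    correlation of the traits.
    """
    if not isinstance(spec, ModelSpec):
        spec = ModelSpec(tuple(spec))
    t1, t2 = spec.traits
    lik, n_used, p_tot, var_p = _build_bivar_lik(pheno, A, spec)

    uni = [fit_univariate(pheno, A, ModelSpec((t,), spec.fixed_effect, spec.id_col)) for t in (t1, t2)]
    both = pheno.dropna(subset=[t1, t2])
    r0 = float(np.clip(both[t1].corr(both[t2]), -0.8, 0.8)) if len(both) > 2 else 0.0
    if not np.isfinite(r0):
        r0 = 0.0
    floor = _FLOOR_FRAC * min(var_p)
    g11, g22 = max(uni[0].sigma2_a, floor * 10), max(uni[1].sigma2_a, floor * 10)
    e11, e22 = max(uni[0].sigma2_e, floor * 10), max(uni[1].sigma2_e, floor * 10)
    G0 = np.array([[g11, 0.5 * r0 * np.sqrt(g11 * g22)], [0.5 * r0 * np.sqrt(g11 * g22), g22]])
    R0 = np.array([[e11, 0.5 * r0 * np.sqrt(e11 * e22)], [0.5 * r0 * np.sqrt(e11 * e22), e22]])

    def pack(M: np.ndarray) -> np.ndarray:
        L = np.linalg.cholesky(M)
        return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Lg, Lr = _chol2(theta[:3]), _chol2(theta[3:])
        return Lg @ Lg.T, Lr @ Lr.T

    def neg(theta: np.ndarray) -> float:
        # large finite penalty (not inf) keeps finite-difference gradients sane
        G, R = unpack(theta)
        if min(G[0, 0], G[1, 1], R[0, 0], R[1, 1]) < floor:
            return 1e10
        ll = lik.loglik(G, R)
        return 1e10 if not np.isfinite(ll) else -ll

    x0 = np.concatenate([pack(G0), pack(R0)])
    res = optimize.minimize(
        neg, x0, method="L-BFGS-B",
        options={"maxiter": MAX_ITER, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not res.success:
        polish = optimize.minimize(
            neg, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if polish.fun <= res.fun:
            res = polish
    G, R = unpack(res.x)
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"bivariate REML for ({t1!r}, {t2!r}) did not converge: {res.message}")
    boundary = bool(min(G[0, 0], G[1, 1], R[0, 0], R[1, 1]) < 2.0 * floor * 10)

    def ll_nat(p6: np.ndarray) -> float:
        Gn = np.array([[p6[0], p6[1]], [p6[1], p6[2]]])
        Rn = np.array([[p6[3], p6[4]], [p6[4], p6[5]]])
        return lik.loglik(Gn, Rn)

    nat = np.array([G[0, 0], G[0, 1], G[1, 1], R[0, 0], R[0, 1], R[1, 1]])
    H = _fd_hessian(ll_nat, nat, 1e-3 * min(var_p))
    param_cov, identifiable = _cov_from_information(H)
    msg = "" if identifiable else "flat or boundary likelihood direction; SEs unavailable"
    return BivariateFit(
        traits=(t1, t2),
        G=G,
        R=R,
        loglik=float(-res.fun),
        param_cov=param_cov,
        converged=converged,
        boundary=boundary,
        identifiable=identifiable,
        n_used=n_used,
        n_fixed=p_tot,
        message=msg or str(res.message),
    )


def bivariate_loglik(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    spec: ModelSpec | tuple[str, str],
    G: np.ndarray,
    R: np.ndarray,
) -> float:
    """Bivariate restricted log-likelihood at given (G, R) (no fitting)."""
    if not isinstance(spec, ModelSpec):
        spec = ModelSpec(tuple(spec))
    lik, *_ = _build_bivar_lik(pheno, A, spec)
    return lik.loglik(np.asarray(G, dtype=float), np.asarray(R, dtype=float))


# ---------------------------------------------------------------------------
# derived genetic parameters


def heritability(fit: UnivariateFit) -> tuple[float, float]:
    """h2 = sigma2_a / (sigma2_a + sigma2_e) with its delta-method SE."""
    s = fit.sigma2_p
    if s <= 0.0:
        raise ModelError("zero total variance; heritability undefined")
    h2 = fit.sigma2_a / s
    grad = np.array([fit.sigma2_e, -fit.sigma2_a]) / s**2
    if np.all(np.isfinite(fit.param_cov)):
        se = float(np.sqrt(max(grad @ fit.param_cov @ grad, 0.0)))
    else:
        se = float("nan")
    return float(h2), se


def correlations(fit: BivariateFit) -> Correlations:
    """Genetic and phenotypic correlations with delta-method SEs.

    r_g = g12 / sqrt(g11 g22) (clamped to [-1, 1] with a flag);
    r_p = (g12 + r12) / sqrt((g11 + r11)(g22 + r22)).  If either genetic
    variance is at the zero boundary r_g is undefined and reported as NaN.
    """
    g11, g12, g22 = fit.G[0, 0], fit.G[0, 1], fit.G[1, 1]
    r11, r12, r22 = fit.R[0, 0], fit.R[0, 1], fit.R[1, 1]
    C = fit.param_cov
    have_cov = np.all(np.isfinite(C))

    t1v, t2v = g11 + r11, g22 + r22
    r_p = (g12 + r12) / np.sqrt(t1v * t2v)
    gp = np.array(
        [-r_p / (2 * t1v), 1.0 / np.sqrt(t1v * t2v), -r_p / (2 * t2v)] * 2
    )
    se_p = float(np.sqrt(max(gp @ C @ gp, 0.0))) if have_cov else float("nan")

    # genetic variance at (or below) the boundary makes the ratio meaningless
    tiny = 1e-6 * min(t1v, t2v)
    if g11 <= tiny or g22 <= tiny:
        return Correlations(
            r_g=float("nan"), se_g=float("nan"), r_p=float(r_p), se_p=se_p,
            message="genetic variance at zero boundary; r_g undefined",
        )
    r_g = g12 / np.sqrt(g11 * g22)
    gg = np.array([-r_g / (2 * g11), 1.0 / np.sqrt(g11 * g22), -r_g / (2 * g22), 0, 0, 0])
    se_g = float(np.sqrt(max(gg @ C @ gg, 0.0))) if have_cov else float("nan")
    clamped = bool(abs(r_g) > 1.0)
    msg = "r_g clamped to [-1, 1]" if clamped else ""
    return Correlations(
        r_g=float(np.clip(r_g, -1.0, 1.0)), se_g=se_g,
        r_p=float(r_p), se_p=se_p, r_g_clamped=clamped, message=msg,
    )
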