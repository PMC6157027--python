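"""Maximum-likelihood variance-component linear mixed models.

The phenotypic covariance is modeled as

    Omega = sigma2_total * (2*Phi * h_r^2  +  E * h_meth^2  +  I * e^2),

where 2*Phi is the additive relationship matrix from the pedigree, E the
gene-specific methylation kernel, I the identity, and the non-negative
fractions h_r^2 (residual polygenic), h_meth^2 (gene-methylation) and
e^2 = 1 - h_r^2 - h_meth^2 (environmental) partition the total variance.
With unit-diagonal structuring kernels the fractions are directly
interpretable as proportions of phenotypic variance.  (The literal
"2 * E" weighting, which sacrifices that interpretation, is available via
``strict_omega=True``.)

Fitting maximizes the exact multivariate-normal likelihood over the
fraction simplex {f_k >= 0, sum f_k <= 1}.  Fixed effects are profiled out
by GLS and sigma2_total in closed form at every covariance evaluation, so
the optimizer works in only one or two dimensions; gradients are analytic
(envelope theorem).  Boundary solutions — in particular h_meth^2 = 0, the
point mass of the association LRT's null distribution — are reachable
exactly because the optimizer operates on the bounded simplex directly.
Multi-start (default 5 starts, including the boundary and a null-model warm
start) guards against local optima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize

__all__ = ["VarCompModel", "VarCompFit", "LMMError", "loglikelihood", "fit_ml",
           "fit_null_and_full", "PolygenicScanner"]

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
#: fractions below this are reported as exactly 0 (boundary snap)
SNAP_TOL = 1e-6
#: diagonal ridge applied only when a covariance factorization fails
DEFAULT_RIDGE = 1e-8


class LMMError(RuntimeError):
    """Numerical failure in mixed-model fitting (singular covariance etc.)."""


@dataclass
class VarCompModel:
    """Aligned trait, fixed-effect design and structuring kernels.

    ``kernels`` is an ordered list of (name, symmetric PSD samples x samples
    matrix); ``[("polygenic", 2*Phi)]`` for the null model,
    ``[("polygenic", 2*Phi), ("methylation", E)]`` for the full model.  All
    parts must already be aligned to the same sample ordering.
    """

    y: np.ndarray
    X: np.ndarray
    kernels: list[tuple[str, np.ndarray]]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError(f"X has {self.X.shape[0]} rows for {n} samples")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        for name, K in self.kernels:
            K = np.asarray(K, dtype=float)
            if K.shape != (n, n):
                raise ValueError(f"kernel {name!r} has shape {K.shape}, expected ({n}, {n})")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class VarCompFit:
    """ML estimates for one :class:`VarCompModel`."""

    sigma2_total: float
    fractions: dict[str, float]
    e2: float
    betas: np.ndarray
    loglik: float
    converged: bool
    n_restarts_used: int = 0

    def fraction(self, name: str) -> float:
        return self.fractions.get(name, 0.0)


def loglikelihood(
    model: VarCompModel,
    fractions: np.ndarray | list[float],
    sigma2: float,
    betas: np.ndarray | list[float],
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Exact multivariate-normal log-density at explicit parameter values.

    Evaluates the density of ``y - X @ betas`` under covariance
    ``sigma2 * (sum_k f_k K_k + (1 - sum f) I)`` via a Cholesky
    factorization.  A ridge of ``ridge`` is added to the diagonal only if
    the factorization fails, with a warning.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size != len(model.kernels):
        raise ValueError("one fraction per kernel required")
    if (f < 0).any() or f.sum() > 1.0 + 1e-12:
        raise ValueError("fractions must be >= 0 with sum <= 1")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    n = model.n
    V = np.eye(n) * (1.0 - f.sum())
    for fk, (_, K) in zip(f, model.kernels):
        V += fk * K
    V *= sigma2
    c, _ = _chol(V, ridge)
    r = model.y - model.X @ np.asarray(betas, dtype=float)
    alpha = cho_solve(c, r)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    return -0.5 * (n * _LOG2PI + logdet + r @ alpha)


def _chol(V: np.ndarray, ridge: float):
    try:
        return cho_factor(V, lower=True), 0.0
    except np.linalg.LinAlgError:
        pass
    log.debug("covariance factorization failed; retrying with ridge %g", ridge)
    try:
        return cho_factor(V + ridge * np.eye(V.shape[0]), lower=True), ridge
    except np.linalg.LinAlgError as err:
        raise LMMError("covariance numerically singular even after ridge; "
                       "consider increasing the ridge") from err


class _Profile:
    """Profiled log-likelihood over variance fractions (dense Cholesky path).

    At each fraction vector f the fixed effects are solved by GLS and
    sigma2 in closed form, giving

        ll(f) = -n/2 [log 2pi + 1 + log(r' V^-1 r / n)] - 1/2 log|V|,

    with V = sum f_k K_k + (1 - sum f) I.  The gradient follows from the
    envelope theorem: d ll / d f_k =
        -1/2 tr(V^-1 (K_k - I)) + n/2 * (a' (K_k - I) a) / (r' a),
    a = V^-1 r.
    """

    def __init__(self, y, X, kernels, ridge=DEFAULT_RIDGE):
        self.y, self.X = y, X
        self.Ks = [np.asarray(K, float) for _, K in kernels]
        self.n = y.size
        self.ridge = ridge

    def value_grad_state(self, f):
        f = np.asarray(f, float)
        n = self.n
        V = np.eye(n) * max(1.0 - f.sum(), 0.0)
        for fk, K in zip(f, self.Ks):
            V += fk * K
        c, _ = _chol(V, self.ridge)
        Vinv = cho_solve(c, np.eye(n))
        Wx = Vinv @ self.X
        A = self.X.T @ Wx
        beta = np.linalg.solve(A, self.X.T @ (Vinv @ self.y))
        r = self.y - self.X @ beta
        a = Vinv @ r
        rss = float(r @ a)
        if rss <= 0:
            raise LMMError("non-positive weighted residual sum of squares")
        sigma2 = rss / n
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        ll = -0.5 * (n * _LOG2PI + n + n * np.log(sigma2) + logdet)
        grad = np.empty(f.size)
        tr_vinv = np.trace(Vinv)
        for k, K in enumerate(self.Ks):
            tr = float(np.sum(Vinv * K)) - tr_vinv
            quad = float(a @ (K @ a)) - float(a @ a)
            grad[k] = -0.5 * tr + 0.5 * n * quad / rss
        return ll, grad, beta, sigma2

    def value(self, f):
        return self.value_grad_state(f)[0]


class _RotatedProfile:
    """Single-kernel fast path: simultaneous diagonalization.

    With one kernel K = U diag(lam) U', V(f) = U diag(f*lam + 1 - f) U';
    rotating y and X by U' once makes every likelihood evaluation O(n p^2).
    """

    def __init__(self, y, X, K):
        lam, U = eigh(np.asarray(K, float))
        self.lam = np.clip(lam, 0.0, None)
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n = y.size
        self.U = U

    @classmethod
    def from_rotated(cls, lam, yt, Xt):
        prof = cls.__new__(cls)
        prof.lam, prof.yt, prof.Xt, prof.n, prof.U = lam, yt, Xt, yt.size, None
        return prof

    def value_grad_state(self, f):
        f = float(np.asarray(f).ravel()[0])
        n = self.n
        w = f * self.lam + (1.0 - f)
        w = np.maximum(w, 1e-12)
        Xw = self.Xt / w[:, None]
        A = self.Xt.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ self.yt)
        r = self.yt - self.Xt @ beta
        a = r / w
        rss = float(r @ a)
        if rss <= 0:
            raise LMMError("non-positive weighted residual sum of squares")
        sigma2 = rss / n
        ll = -0.5 * (n * _LOG2PI + n + n * np.log(sigma2) + np.sum(np.log(w)))
        dlam = self.lam - 1.0
        tr = float(np.sum(dlam / w))
        quad = float(np.sum(dlam * a * a))
        grad = np.array([-0.5 * tr + 0.5 * n * quad / rss])
        return ll, grad, beta, sigma2

    def value(self, f):
        return self.value_grad_state(f)[0]


def _default_starts(m: int) -> list[np.ndarray]:
    if m == 1:
        pts = [[0.0], [0.1], [0.25], [0.5], [0.9]]
    elif m == 2:
        pts = [[0.5, 0.0], [0.25, 0.25], [0.0, 0.5], [0.1, 0.1]]
    else:
        pts = [[0.0] * m, [1.0 / (m + 1)] * m]
    return [np.asarray(p, float) for p in pts]


def _ols_fit(y, X) -> VarCompFit:
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sigma2 = float(r @ r) / n
    ll = -0.5 * n * (_LOG2PI + 1.0 + np.log(sigma2))
    return VarCompFit(sigma2, {}, 1.0, beta, float(ll), True, 0)


def fit_ml(
    model: VarCompModel,
    starts: list | None = None,
    tol: float = 1e-8,
    ridge: float = DEFAULT_RIDGE,
    snap: float = SNAP_TOL,
) -> VarCompFit:
    """Maximize the profiled likelihood over the fraction simplex.

    Every start point and every optimizer endpoint is kept as a candidate
    and the best evaluated point wins, so a warm start at a nested model's
    solution guarantees the nesting inequality by construction.  Fractions
    below ``snap`` are reported as exactly 0.
    """
    m = len(model.kernels)
    if m == 0:
        return _ols_fit(model.y, model.X)
    if model.n < 4:
        raise ValueError("need at least 4 samples to fit variance components")
    prof = (_RotatedProfile(model.y, model.X, model.kernels[0][1]) if m == 1
            else _Profile(model.y, model.X, model.kernels, ridge))
    start_pts = [np.asarray(s, float).ravel() for s in (starts or _default_starts(m))]

    def neg(f):
        ll, grad, *_ = prof.value_grad_state(f)
        return -ll, -grad

    candidates: list[tuple[float, np.ndarray]] = []
    any_success = False
    for x0 in start_pts:
        x0 = np.clip(x0, 0.0, 1.0)
        if x0.sum() > 1.0:
            x0 = x0 / (x0.sum() + 1e-9)
        try:
            candidates.append((prof.value(x0), x0))
        except LMMError:
            continue
        if m == 1:
            res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                           bounds=[(0.0, 1.0)], options={"ftol": tol, "gtol": 1e-10})
        else:
            res = minimize(
                neg, x0, jac=True, method="SLSQP",
                bounds=[(0.0, 1.0)] * m,
                constraints=[{"type": "ineq",
                              "fun": lambda f: 1.0 - f.sum(),
                              "jac": lambda f: -np.ones_like(f)}],
                options={"ftol": tol, "maxiter": 200},
            )
        xf = np.clip(res.x, 0.0, 1.0)
        if xf.sum() > 1.0:
            xf = xf / xf.sum()
        try:
            candidates.append((prof.value(xf), xf))
            any_success = any_success or bool(res.success)
        except LMMError:
            continue
    if not candidates:
        raise LMMError("all optimization starts failed")
    best_ll, best_f = max(candidates, key=lambda c: c[0])
    snapped = np.where(best_f < snap, 0.0, best_f)
    if not np.array_equal(snapped, best_f):
        try:
            ll_s = prof.value(snapped)
            if ll_s >= best_ll - 1e-9:
                best_ll, best_f = ll_s, snapped
        except LMMError:
            pass
    ll, _, beta, sigma2 = prof.value_grad_state(best_f)
    fractions = {name: float(fk) for (name, _), fk in zip(model.kernels, best_f)}
    return VarCompFit(
        sigma2_total=float(sigma2),
        fractions=fractions,
        e2=float(1.0 - best_f.sum()),
        betas=np.asarray(beta),
        loglik=float(ll),
        converged=any_success,
        n_restarts_used=len(start_pts),
    )


def fit_null_and_full(
    y: np.ndarray,
    X: np.ndarray,
    phi2: np.ndarray,
    E: np.ndarray,
    strict_omega: bool = False,
    sample_ids: list[str] | None = None,
    **fit_kwargs,
) -> tuple[VarCompFit, VarCompFit]:
    """Fit the polygenic null and the polygenic + methylation full model.

    ``phi2`` is the additive relationship matrix 2*Phi and ``E`` the
    gene-specific methylation kernel (already sample-aligned).  With
    ``strict_omega`` the methylation kernel enters as ``2 * E``.  The full
    fit is warm-started at the null solution, so its maximized
    log-likelihood is never below the null's and the LRT is non-negative.
    """
    y = np.asarray(y, float).ravel()
    Emat = 2.0 * np.asarray(E, float) if strict_omega else np.asarray(E, float)
    full_starts = fit_kwargs.pop("full_starts", None)
    null_model = VarCompModel(y, X, [("polygenic", np.asarray(phi2, float))], sample_ids)
    null_fit = fit_ml(null_model, **fit_kwargs)
    full_model = VarCompModel(
        y, X, [("polygenic", np.asarray(phi2, float)), ("methylation", Emat)], sample_ids
    )
    warm = np.array([null_fit.fraction("polygenic"), 0.0])
    starts = list(full_starts) if full_starts is not None else _default_starts(2)
    starts = starts + [warm]
    full_fit = fit_ml(full_model, starts=starts, **fit_kwargs)
    if full_fit.loglik < null_fit.loglik:
        # the null point is inside the full model's parameter space; tiny
        # cross-path rounding can put the evaluated warm start below the
        # null optimum, in which case the null solution itself is the MLE
        full_fit = VarCompFit(
            sigma2_total=null_fit.sigma2_total,
            fractions={"polygenic": null_fit.fraction("polygenic"), "methylation": 0.0},
            e2=null_fit.e2,
            betas=null_fit.betas,
            loglik=null_fit.loglik,
            converged=full_fit.converged,
            n_restarts_used=full_fit.n_restarts_used,
        )
    return null_fit, full_fit


class PolygenicScanner:
    """Repeated single-kernel fits sharing one eigendecomposition.

    Used for per-site heritability scans: the additive relationship matrix
    and the fixed-effect design are rotated once, after which each site's
    polygenic fit costs O(n p^2) per likelihood evaluation.
    """

    def __init__(self, phi2: np.ndarray, X: np.ndarray):
        phi2 = np.asarray(phi2, float)
        self.X = np.atleast_2d(np.asarray(X, float))
        lam, U = eigh(phi2)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.Xt = U.T @ self.X
        self.n = phi2.shape[0]

    def fit(self, y: np.ndarray, starts=(0.0, 0.1, 0.3, 0.6, 0.9),
            tol: float = 1e-8, snap: float = SNAP_TOL) -> tuple[VarCompFit, VarCompFit]:
        """Return (polygenic fit, sporadic/no-kernel fit) for one trait vector."""
        y = np.asarray(y, float).ravel()
        yt = self.U.T @ y
        prof = _RotatedProfile.from_rotated(self.lam, yt, self.Xt)

        def neg(f):
            ll, grad, *_ = prof.value_grad_state(f)
            return -ll, -grad

        candidates = []
        any_success = False
        for s in starts:
            x0 = np.array([s])
            candidates.append((prof.value(x0), x0))
            res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                           bounds=[(0.0, 1.0)], options={"ftol": tol, "gtol": 1e-10})
            xf = np.clip(res.x, 0.0, 1.0)
            candidates.append((prof.value(xf), xf))
            any_success = any_success or bool(res.success)
        best_ll, best_f = max(candidates, key=lambda c: c[0])
        if 0.0 < best_f[0] < snap:
            best_f = np.array([0.0])
        ll, _, beta, sigma2 = prof.value_grad_state(best_f)
        poly = VarCompFit(float(sigma2), {"polygenic": float(best_f[0])},
                          float(1.0 - best_f[0]), np.asarray(beta), float(ll),
                          any_success, len(starts))
        sporadic = _ols_fit(y, self.X)
        if poly.loglik < sporadic.loglik:
            poly = VarCompFit(sporadic.sigma2_total, {"polygenic": 0.0}, 1.0,
                              sporadic.betas, sporadic.loglik, any_success, len(starts))
        return poly, sporadic
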