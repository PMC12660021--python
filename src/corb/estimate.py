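"""Marginal maximum likelihood estimation for oblique bifactor Rasch models.

The fitting routine is an EM algorithm for the marginal likelihood with a
multivariate normal latent density:

* **E-step** — posterior weights of each person over a fixed set of
  standard-normal base nodes, mapped through the current ``mu + L z``
  transform (``L`` the Cholesky factor of the current covariance), giving
  posterior moments of the latent vector.
* **M-step** — Newton updates of the reduced item parameters (a weighted
  logistic regression, separable through the design matrix) and a
  pattern-constrained update of the latent covariance matrix.

Latent means are estimated freely whenever the design matrix is reduced
and are folded back into the reported item difficulties, so all reported
quantities live on the conventional zero-latent-mean scale.

Numerical integration uses a product Gauss-Hermite rule for up to three
dimensions and scrambled-Sobol quasi Monte Carlo above that, where product
rules become too expensive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp, ndtri

from .model_core import (
    CovariancePattern,
    ModelSpec,
    ResponseData,
    _loglik_matrix,
    gsm_implied_full_covariance,
    n_free_params,
)

__all__ = [
    "IntegrationConfig",
    "FitResult",
    "EAPTable",
    "GsmGatherResult",
    "fit",
    "fit_hierarchy",
    "constrained_sigma_update",
    "eap_scores",
    "eap_reliability",
    "lrt",
    "gsm_gather",
]


@dataclass
class IntegrationConfig:
    """Numerical integration settings for the latent-space integrals.

    ``scheme`` is ``"auto"`` (Gauss-Hermite product up to 3 dimensions,
    quasi Monte Carlo above), ``"gauss_hermite_product"`` or ``"qmc"``.
    QMC uses scrambled Sobol points mapped through the normal quantile
    function; the scramble is seeded, so results are reproducible.
    """

    scheme: str = "auto"
    nodes_per_dim: int = 15
    n_points: int = 2048
    seed: int = 0
    adaptive: bool = True

    def resolve(self, D: int) -> tuple[np.ndarray, np.ndarray]:
        """Standard-normal base nodes ``z`` (Q, D) and log-weights (Q,)."""
        scheme = self.scheme
        if scheme == "auto":
            scheme = "gauss_hermite_product" if D <= 3 else "qmc"
        if scheme == "gauss_hermite_product":
            if D > 4:
                raise ValueError(
                    "product quadrature is limited to D <= 4; use the qmc scheme"
                )
            x, w = np.polynomial.hermite_e.hermegauss(self.nodes_per_dim)
            logw1 = np.log(w) - 0.5 * np.log(2.0 * np.pi)
            grids = np.meshgrid(*([x] * D), indexing="ij")
            z = np.stack([g.ravel() for g in grids], axis=1)
            lw = np.meshgrid(*([logw1] * D), indexing="ij")
            logw = np.add.reduce([g.ravel() for g in lw])
            return z, logw
        if scheme == "qmc":
            sob = stats.qmc.Sobol(d=D, scramble=True, seed=self.seed)
            n = int(self.n_points)
            if n & (n - 1) == 0:
                u = sob.random_base2(int(np.log2(n)))
            else:  # pragma: no cover - non-power-of-two request
                u = sob.random(n)
            eps = np.finfo(float).tiny
            z = ndtri(np.clip(u, eps, 1.0 - eps))
            logw = np.full(n, -np.log(n))
            return z, logw
        raise ValueError(f"unknown integration scheme {scheme!r}")

    def describe(self, D: int) -> dict:
        scheme = self.scheme
        if scheme == "auto":
            scheme = "gauss_hermite_product" if D <= 3 else "qmc"
        out = {"scheme": scheme, "seed": int(self.seed)}
        if scheme == "gauss_hermite_product":
            out["nodes_per_dim"] = int(self.nodes_per_dim)
        else:
            out["n_points"] = int(self.n_points)
        return out


def _sigma_from_params(s: np.ndarray, groups, D: int) -> np.ndarray:
    Sigma = np.zeros((D, D))
    for val, g in zip(s, groups):
        for i, j in g:
            Sigma[i, j] = Sigma[j, i] = val
    return Sigma


def _floor_pd(Sigma: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(Sigma)
    if vals.min() >= floor:
        return Sigma, False
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T, True


def constrained_sigma_update(
    M: np.ndarray,
    pattern: CovariancePattern,
    floor: float = 1e-6,
    return_info: bool = False,
):
    """Pattern-constrained MLE of a normal covariance given the average
    posterior second-moment matrix ``M``.

    A fully free pattern returns ``M`` itself; a diagonal pattern returns
    ``diag(M)``.  Mixed patterns (and tied parameters) are solved by Fisher
    scoring on the expected complete-data normal log-likelihood
    ``-(log|Sigma| + tr(Sigma^-1 M)) / 2`` over the free entries, with the
    constrained entries held at zero.  The result is eigenvalue-floored at
    ``floor`` to stay positive definite.
    """
    M = np.asarray(M, dtype=float)
    D = pattern.D
    floored = False
    if pattern.free.all() and pattern.ties is None:
        Sigma, floored = _floor_pd(M, floor)
    elif pattern.n_free_offdiag == 0 and pattern.ties is None:
        d = np.diag(M)
        floored = bool((d < floor).any())
        Sigma = np.diag(np.maximum(d, floor))
    else:
        groups = pattern.parameter_groups()
        start = pattern.project(M)
        start[np.diag_indices_from(start)] = np.maximum(
            np.diag(start), max(floor, 1e-4)
        )

        def pack_groups(Sig):
            return np.array([np.mean([Sig[i, j] for i, j in g]) for g in groups])

        def objective(svec):
            Sig = _sigma_from_params(svec, groups, D)
            try:
                L = np.linalg.cholesky(Sig)
            except np.linalg.LinAlgError:
                return -np.inf, None
            logdet = 2.0 * np.log(np.diag(L)).sum()
            R = np.linalg.inv(Sig)
            return -0.5 * (logdet + np.trace(R @ M)), R

        # shrink the off-diagonal start toward the (always valid) diagonal
        # until the pattern-projected matrix is positive definite
        diag_part = np.diag(np.diag(start))
        for lam in (1.0, 0.7, 0.4, 0.2, 0.0):
            s = pack_groups(lam * start + (1.0 - lam) * diag_part)
            obj, R = objective(s)
            if np.isfinite(obj):
                break
        for _ in range(200):
            U = 0.5 * (R @ M @ R - R)
            g = np.array(
                [sum((2.0 if i != j else 1.0) * U[i, j] for i, j in grp)
                 for grp in groups]
            )
            if np.abs(g).max() < 1e-11:
                break
            # Fisher information: I_kl = tr(R E_k R E_l) / 2
            RE = []
            for grp in groups:
                E = np.zeros((D, D))
                for i, j in grp:
                    E[i, j] = E[j, i] = 1.0
                RE.append(R @ E)
            K = len(groups)
            info = np.empty((K, K))
            for a in range(K):
                for b in range(a, K):
                    info[a, b] = info[b, a] = 0.5 * np.einsum(
                        "ij,ji->", RE[a], RE[b]
                    )
            try:
                step = np.linalg.solve(info, g)
            except np.linalg.LinAlgError:
                step = g
            t = 1.0
            for _ in range(40):
                obj_new, R_new = objective(s + t * step)
                if obj_new > obj - 1e-12:
                    break
                t *= 0.5
            else:
                break
            if obj_new - obj < 1e-13:
                s, obj, R = s + t * step, obj_new, R_new
                break
            s, obj, R = s + t * step, obj_new, R_new
        Sigma = _sigma_from_params(s, groups, D)
        Sigma, floored = _floor_pd(Sigma, floor)
        Sigma = pattern.project(Sigma)

    if return_info:
        return Sigma, {"floored": floored}
    return Sigma


@dataclass
class FitResult:
    """Result of a marginal maximum likelihood fit."""

    spec: ModelSpec
    beta_hat: np.ndarray          # per-item difficulties, zero-latent-mean scale
    beta_reduced: np.ndarray      # raw reduced parameters (A columns)
    mu_hat: np.ndarray            # estimated latent means (zero if A is full)
    Sigma_hat: np.ndarray
    loglik: float
    n_free: int
    n_persons: int
    converged: bool
    n_iter: int
    history: list[float] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)
    integration: dict = field(default_factory=dict)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.n_free

    @property
    def bic(self) -> float:
        return self.deviance + self.n_free * np.log(self.n_persons)


def _init_params(data: ResponseData, spec: ModelSpec):
    pbar = np.nanmean(data.X, axis=0)
    d0 = -np.log(np.clip(pbar, 0.02, 0.98) / (1.0 - np.clip(pbar, 0.02, 0.98)))
    A, B = spec.A.A, spec.B.B
    if spec.estimate_means:
        # solve A beta - B mu ~= d0 so the start matches observed item means
        Z = np.hstack([A, -B])
        sol, *_ = np.linalg.lstsq(Z, d0, rcond=None)
        beta, mu = sol[: A.shape[1]], sol[A.shape[1]:]
    else:
        beta, mu = d0.copy(), np.zeros(spec.D)
    Sigma = pattern_start = spec.pattern.project(np.eye(spec.D))
    return beta, mu, pattern_start


class _EMEngine:
    """Precomputed quantities and the EM map for one (data, spec) pair.

    Parameters are packed into one flat vector: reduced item parameters,
    latent means (when estimated) and the free covariance entries (one
    value per parameter group, honoring ties).
    """

    def __init__(self, data: ResponseData, spec: ModelSpec, z, logw):
        self.spec = spec
        self.z, self.logw = z, logw
        self.A, self.B = spec.A.A, spec.B.B
        self.X = data.X
        self.has_missing = bool(np.isnan(self.X).any())
        self.Mobs = (~np.isnan(self.X)).astype(float) if self.has_missing else None
        self.n1 = np.nansum(self.X, axis=0)
        self.N = data.n_persons
        self.groups = spec.pattern.parameter_groups()
        self.P = spec.A.n_params
        self.D = spec.D
        self.est_mu = spec.estimate_means
        self.warns: list[str] = []

    # --- packing -----------------------------------------------------
    def pack(self, beta, mu, Sigma) -> np.ndarray:
        s = [np.mean([Sigma[i, j] for i, j in g]) for g in self.groups]
        parts = [beta] + ([mu] if self.est_mu else []) + [np.asarray(s)]
        return np.concatenate(parts)

    def unpack(self, x):
        beta = x[: self.P]
        off = self.P
        if self.est_mu:
            mu = x[off: off + self.D]
            off += self.D
        else:
            mu = np.zeros(self.D)
        Sigma = _sigma_from_params(x[off:], self.groups, self.D)
        return beta, mu, Sigma

    def sanitize(self, x) -> np.ndarray:
        """Project the covariance part back to a valid PD pattern matrix."""
        beta, mu, Sigma = self.unpack(x)
        Sigma, floored = _floor_pd(Sigma, 1e-6)
        if floored:
            Sigma = self.spec.pattern.project(Sigma)
            Sigma, _ = _floor_pd(Sigma, 1e-6)
            Sigma = self.spec.pattern.project(Sigma)
            self._warn("covariance floored")
        return self.pack(beta, mu, Sigma)

    def _warn(self, msg):
        if msg not in self.warns:
            self.warns.append(msg)

    # --- EM map ------------------------------------------------------
    def estep(self, x):
        """Log-likelihood at ``x`` and posterior node weights."""
        beta, mu, Sigma = self.unpack(x)
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        theta = mu + self.z @ L.T                       # (Q, D)
        Btheta = self.B @ theta.T                       # (I, Q)
        eta = Btheta - (self.A @ beta)[:, None]
        ll_mat = _loglik_matrix(self.X, eta)
        ll_mat += self.logw
        # fused log-sum-exp and posterior weights: one exp pass over (N, Q)
        m = ll_mat.max(axis=1)
        np.subtract(ll_mat, m[:, None], out=ll_mat)
        w = np.exp(ll_mat, out=ll_mat)
        s = w.sum(axis=1)
        loglik = float((m + np.log(s)).sum())
        if not np.isfinite(loglik):
            return -np.inf, None, None
        w /= s[:, None]
        return loglik, w, (theta, Btheta)

    def em_step(self, x):
        """One EM iteration: returns (loglik at x, updated parameters)."""
        loglik, w, aux = self.estep(x)
        if w is None:
            return loglik, x
        theta, Btheta = aux
        beta, mu, Sigma = self.unpack(x)
        Wq = w.sum(axis=0)
        Wobs = self.Mobs.T @ w if self.has_missing else None

        # item parameters: Newton ascent on the expected complete loglik
        A = self.A
        for _ in range(25):
            p = expit(Btheta - (A @ beta)[:, None])
            if self.has_missing:
                grad_d = (Wobs * p).sum(axis=1) - self.n1
                h = (Wobs * p * (1.0 - p)).sum(axis=1)
            else:
                grad_d = p @ Wq - self.n1
                h = (p * (1.0 - p)) @ Wq
            grad_b = A.T @ grad_d
            if np.abs(grad_b).max() < 1e-9:
                break
            H = (A.T * h) @ A
            try:
                step = np.linalg.solve(H, grad_b)
            except np.linalg.LinAlgError:
                step = grad_b / np.maximum(h.mean(), 1e-8)
            np.clip(step, -2.0, 2.0, out=step)
            beta = beta + step  # H is the negated (positive definite) Hessian

        # latent means and pattern-constrained covariance
        m1 = (Wq @ theta) / self.N
        M2 = (theta.T * Wq) @ theta / self.N
        if self.est_mu:
            mu = m1
            Mc = M2 - np.outer(mu, mu)
        else:
            Mc = M2
        Sigma, info = constrained_sigma_update(
            Mc, self.spec.pattern, floor=1e-6, return_info=True
        )
        if info["floored"]:
            self._warn("covariance floored")
        return loglik, self.pack(beta, mu, Sigma)


def fit(
    data: ResponseData,
    spec: ModelSpec,
    integration: IntegrationConfig | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
    seed: int = 0,
    param_tol: float = 1e-4,
    start: dict | None = None,
    accelerate: bool = True,
    warmup: bool = True,
) -> FitResult:
    """Fit a model by EM marginal maximum likelihood.

    The E-step computes posterior node weights per person; the M-step
    performs a Newton update of the reduced item parameters and a
    pattern-constrained covariance update.  With ``accelerate=True``
    (default) plain EM steps are interleaved with safeguarded SQUAREM
    extrapolations of the EM map — any extrapolated point that does not
    improve the log-likelihood is discarded in favor of the plain step,
    so the accepted iterates remain monotone up to integration noise.

    Stops when a plain EM step improves the log-likelihood by less than
    ``tol`` with largest parameter change below ``param_tol``, or at
    ``max_iter`` EM-map evaluations.  Estimation failures (non-finite
    likelihood, covariance degeneracies after the safeguard) yield
    ``converged=False`` rather than an exception.  The fit is
    deterministic given ``seed`` and the integration configuration.
    """
    from .identify import check_identification

    if data.n_items != spec.n_items:
        raise ValueError("data and spec disagree on the number of items")
    if spec.family != "RTM":
        if not check_identification(spec.B).identified:
            raise ValueError(
                f"the {spec.family} model is not identified for this scoring "
                "matrix; run the identification module on the structure first"
            )

    if integration is None:
        integration = IntegrationConfig(seed=seed)

    # two-stage integration: refine a coarse-grid solution on the full grid
    # (QMC prefixes and smaller product rules are valid rules themselves)
    coarse = None
    if warmup and accelerate:
        desc = integration.describe(spec.D)
        if desc["scheme"] == "qmc" and integration.n_points >= 1024:
            coarse = IntegrationConfig(
                scheme="qmc", n_points=max(256, integration.n_points // 8),
                seed=integration.seed,
            )
        elif desc["scheme"] == "gauss_hermite_product" and \
                integration.nodes_per_dim > 9 and spec.D >= 3:
            coarse = IntegrationConfig(
                scheme="gauss_hermite_product", nodes_per_dim=7,
                seed=integration.seed,
            )
    if coarse is not None:
        rough = fit(
            data, spec, integration=coarse, tol=max(tol * 100, 1e-3),
            max_iter=min(200, max_iter), seed=seed,
            param_tol=max(param_tol * 100, 1e-2), start=start,
            accelerate=accelerate, warmup=False,
        )
        start = {
            "beta": rough.beta_reduced,
            "mu": rough.mu_hat,
            "Sigma": rough.Sigma_hat,
        }

    z, logw = integration.resolve(spec.D)
    eng = _EMEngine(data, spec, z, logw)

    beta, mu, Sigma = _init_params(data, spec)
    if start is not None:
        beta = np.asarray(start.get("beta", beta), dtype=float).copy()
        mu = np.asarray(start.get("mu", mu), dtype=float).copy()
        Sigma = spec.pattern.project(
            np.asarray(start.get("Sigma", Sigma), dtype=float)
        )
    x = eng.sanitize(eng.pack(beta, mu, Sigma))

    history: list[float] = []
    converged = False
    n_eval = 0
    failed = False
    stall = 30  # evals without a tol-sized improvement before stopping
    best_ll, best_x, last_improve = -np.inf, x, 0

    def _track(ll, point):
        """Keep the best iterate seen; quadrature-approximate EM can drift
        slightly downhill along flat ridges, so the best point (not the
        last) is the maximum-likelihood estimate at grid resolution."""
        nonlocal best_ll, best_x, last_improve
        if ll > best_ll:
            if ll > best_ll + tol:
                last_improve = n_eval
            best_ll, best_x = ll, point

    while n_eval < max_iter:
        ll0, x1 = eng.em_step(x)
        n_eval += 1
        history.append(ll0)
        if not np.isfinite(ll0):
            failed = True
            break
        _track(ll0, x)
        if len(history) > 1 and abs(ll0 - history[-2]) < tol and \
                np.abs(x1 - x).max() < param_tol:
            converged = True  # ll0 was computed at x; keep x as the solution
            best_ll, best_x = ll0, x
            break
        if n_eval - last_improve >= stall:
            eng._warn("stopped on log-likelihood plateau")
            converged = True
            break
        if not accelerate or n_eval + 2 > max_iter:
            x = x1
            continue
        ll1, x2 = eng.em_step(x1)
        n_eval += 1
        history.append(ll1)
        if not np.isfinite(ll1):
            failed = True
            break
        _track(ll1, x1)
        if abs(ll1 - ll0) < tol and np.abs(x2 - x1).max() < param_tol:
            converged = True
            best_ll, best_x = ll1, x1
            break
        r = x1 - x
        v = (x2 - x1) - r
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            x = x2
            continue
        alpha = min(-np.linalg.norm(r) / nv, -1.0)
        xp = eng.sanitize(x - 2.0 * alpha * r + alpha**2 * v)
        llp, xs = eng.em_step(xp)
        n_eval += 1
        if np.isfinite(llp) and llp >= ll1 - 1e-8:
            history.append(llp)
            _track(llp, xp)
            x = xs
        else:
            x = x2

    if not failed and not converged and n_eval >= max_iter:
        # max_iter reached: evaluate the likelihood at the final point
        ll_final, _, _ = eng.estep(x)
        if np.isfinite(ll_final):
            history.append(ll_final)
            _track(ll_final, x)

    x = best_x if np.isfinite(best_ll) else x
    beta, mu, Sigma = eng.unpack(x)
    if failed:
        eng._warn("non-finite log-likelihood; stopping")
    loglik = best_ll if np.isfinite(best_ll) else (
        history[-1] if history else -np.inf
    )
    beta_hat = spec.A.A @ beta - spec.B.B @ mu
    return FitResult(
        spec=spec,
        beta_hat=beta_hat,
        beta_reduced=beta,
        mu_hat=mu,
        Sigma_hat=Sigma,
        loglik=loglik,
        n_free=n_free_params(spec),
        n_persons=eng.N,
        converged=converged,
        n_iter=n_eval,
        history=history,
        warnings_=eng.warns,
        integration=integration.describe(spec.D),
    )


def _start_from(res: FitResult) -> dict:
    return {
        "beta": res.beta_reduced,
        "mu": res.mu_hat,
        "Sigma": res.Sigma_hat,
    }


def fit_hierarchy(
    data: ResponseData,
    specs: dict[str, ModelSpec],
    integration: IntegrationConfig | None = None,
    strategy: str = "warm",
    **fit_kwargs,
) -> dict[str, FitResult]:
    """Fit nested families ordered from most constrained to most general
    (e.g. RTM, ETM, CORB).

    ``strategy="warm"`` starts each model from the previous solution,
    which is fast and keeps deviances consistent with the nesting
    hierarchy by construction.  ``strategy="cold_fallback"`` fits every
    model from its own default start — on flat likelihoods a constrained
    warm start can park the general model far along a likelihood ridge,
    which distorts covariance recovery — and refits from the nested
    solution only when the fitted deviances invert the hierarchy, keeping
    whichever fit has the higher likelihood.
    """
    out: dict[str, FitResult] = {}
    prev: FitResult | None = None
    for name, spec in specs.items():
        if strategy == "warm":
            start = _start_from(prev) if prev is not None else None
            res = fit(data, spec, integration=integration, start=start,
                      **fit_kwargs)
        elif strategy == "cold_fallback":
            res = fit(data, spec, integration=integration, **fit_kwargs)
            if prev is not None and res.loglik < prev.loglik:
                refit = fit(data, spec, integration=integration,
                            start=_start_from(prev), **fit_kwargs)
                if refit.loglik > res.loglik:
                    res = refit
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        out[name] = res
        prev = res
    return out


@dataclass
class EAPTable:
    """Expected a posteriori scores, posterior SDs and reliabilities."""

    eap: np.ndarray               # (N, D), zero-latent-mean scale
    psd: np.ndarray               # (N, D) posterior standard deviations
    reliability: np.ndarray       # (D,)
    dimension_names: list[str] = field(default_factory=list)


def eap_scores(
    data: ResponseData, fit_result: FitResult, integration: IntegrationConfig | None = None
) -> EAPTable:
    """Posterior mean and SD of each latent dimension for every person.

    Scores are reported on the zero-latent-mean scale.  Because the
    posterior is taken under the full fitted covariance matrix, correlated
    dimensions reinforce one another: information about one factor sharpens
    the posterior of the others.
    """
    spec = fit_result.spec
    if integration is None:
        integration = IntegrationConfig(**{
            k: v for k, v in fit_result.integration.items() if k != "scheme"
        }, scheme=fit_result.integration.get("scheme", "auto"))
    z, logw = integration.resolve(spec.D)
    Sigma, _ = _floor_pd(fit_result.Sigma_hat, 1e-10)
    L = np.linalg.cholesky(Sigma)
    theta = fit_result.mu_hat + z @ L.T
    eta = spec.B.B @ theta.T - (spec.A.A @ fit_result.beta_reduced)[:, None]
    ll_mat = _loglik_matrix(data.X, eta) + logw
    lse = logsumexp(ll_mat, axis=1)
    w = np.exp(ll_mat - lse[:, None])
    m = w @ theta
    second = w @ (theta**2)
    var = np.maximum(second - m**2, 0.0)
    eap = m - fit_result.mu_hat
    rel = eap_reliability_from_variances(var, np.diag(fit_result.Sigma_hat))
    return EAPTable(
        eap=eap,
        psd=np.sqrt(var),
        reliability=rel,
        dimension_names=list(spec.B.dimension_names),
    )


def eap_reliability_from_variances(
    posterior_var: np.ndarray, sigma2: np.ndarray
) -> np.ndarray:
    """``1 - mean(posterior variance) / latent variance`` per dimension,
    clipped to [0, 1]."""
    sigma2 = np.asarray(sigma2, dtype=float)
    mean_pv = np.asarray(posterior_var, dtype=float).mean(axis=0)
    rel = np.zeros_like(sigma2)
    zero = sigma2 <= 0
    if zero.any():
        warnings.warn(
            "zero latent variance: reliability set to 0", UserWarning, stacklevel=2
        )
    nz = ~zero
    rel[nz] = 1.0 - mean_pv[nz] / sigma2[nz]
    return np.clip(rel, 0.0, 1.0)


def eap_reliability(table: EAPTable, Sigma_hat: np.ndarray) -> np.ndarray:
    """Per-dimension EAP reliability from an EAP table and fitted variances."""
    return eap_reliability_from_variances(table.psd**2, np.diag(Sigma_hat))


def lrt(fit_general: FitResult, fit_nested: FitResult, tol: float = 1e-3):
    """Likelihood-ratio test of a nested covariance pattern.

    Requires the two fits to share the scoring and design matrices and the
    nested pattern's free entries to be a subset of the general one (the
    RTM - ETM - CORB hierarchy).  Models with different scoring matrices
    (the subdimension family) are not nested in this hierarchy and can only
    be compared by information criteria.
    """
    gs, ns = fit_general.spec, fit_nested.spec
    if gs.B.B.shape != ns.B.B.shape or not np.allclose(gs.B.B, ns.B.B):
        raise ValueError(
            "models with different scoring matrices are not nested; "
            "compare them with information criteria (AIC/BIC) instead"
        )
    if not np.allclose(gs.A.A, ns.A.A):
        raise ValueError("nested comparison requires the same design matrix")
    if (ns.pattern.free & ~gs.pattern.free).any():
        raise ValueError("the nested model's free entries must be a subset")
    if fit_general.loglik < fit_nested.loglik - tol:
        raise ValueError(
            "general model has lower likelihood than the nested model; "
            "check convergence"
        )
    chi2 = max(fit_nested.deviance - fit_general.deviance, 0.0)
    df = fit_general.n_free - fit_nested.n_free
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 <= tol else 0.0)
    return chi2, df, p


@dataclass
class GsmGatherResult:
    """Specific-factor covariance matrix assembled from several
    subdimension-model reparameterizations."""

    Sigma: np.ndarray                 # (S+1, S+1) gathered covariance
    n_specific: int
    max_duplicate_discrepancy: float
    max_implied_discrepancy: float
    entry_counts: np.ndarray


def gsm_gather(fits: list[FitResult]) -> GsmGatherResult:
    """Assemble the full latent covariance from >= 3 subdimension fits.

    Each reparameterization directly estimates the variances and pairwise
    covariances of its retained specific factors (and the general-factor
    variance); entries estimated by several fits are averaged.  All pairs
    of specific factors must be covered by at least one fit.  Diagnostics
    report the largest disagreement between duplicate estimates and between
    the gathered matrix and the zero-sum-implied completion of each fit.
    """
    if len(fits) < 2:
        raise ValueError("gathering needs at least two reparameterizations")
    S = fits[0].spec.D  # reduced dimensionality equals the number of specifics
    excls = [f.spec.gsm_excluded for f in fits]
    if any(f.spec.family not in ("GSM", "SRM") for f in fits):
        raise ValueError("all fits must be subdimension-family fits")
    if len(set(excls)) != len(excls):
        raise ValueError("reparameterizations must exclude distinct factors")
    pairs_needed = {
        (a, b) for a in range(1, S + 1) for b in range(a + 1, S + 1)
    }
    covered = set()
    for f in fits:
        retained = [k for k in range(1, S + 1) if k != f.spec.gsm_excluded]
        covered |= {
            (a, b) for i, a in enumerate(retained) for b in retained[i + 1:]
        }
    missing = pairs_needed - covered
    if missing:
        raise ValueError(
            f"specific-factor pair(s) not covered by any reparameterization: "
            f"{sorted(missing)}"
        )

    sums = np.zeros((S + 1, S + 1))
    counts = np.zeros((S + 1, S + 1))
    mins = np.full((S + 1, S + 1), np.inf)
    maxs = np.full((S + 1, S + 1), -np.inf)

    def add(i, j, v):
        sums[i, j] += v
        counts[i, j] += 1
        mins[i, j] = min(mins[i, j], v)
        maxs[i, j] = max(maxs[i, j], v)
        if i != j:
            sums[j, i], counts[j, i] = sums[i, j], counts[i, j]
            mins[j, i], maxs[j, i] = mins[i, j], maxs[i, j]

    for f in fits:
        retained = [k for k in range(1, S + 1) if k != f.spec.gsm_excluded]
        Sr = f.Sigma_hat  # (S, S): index 0 = general, 1..S-1 = retained specifics
        add(0, 0, Sr[0, 0])
        for a in range(1, S):
            for b in range(a, S):
                add(retained[a - 1], retained[b - 1], Sr[a, b])

    with np.errstate(invalid="ignore"):
        Sigma = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    dup = float(np.max(np.where(counts > 1, maxs - mins, 0.0)))

    implied_disc = 0.0
    est_mask = counts > 0
    for f in fits:
        imp = gsm_implied_full_covariance(f.Sigma_hat, f.spec.gsm_excluded)
        implied_disc = max(implied_disc, float(np.abs((imp - Sigma)[est_mask]).max()))
    return GsmGatherResult(
        Sigma=Sigma,
        n_specific=S,
        max_duplicate_discrepancy=dup,
        max_implied_discrepancy=implied_disc,
        entry_counts=counts,
    )
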