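"""Dichotomous multidimensional Rasch likelihood and covariance patterns.

The probability of a correct response to item ``i`` given the latent
vector ``theta`` is ``logistic(B_i . theta - d_i)`` where ``d = A beta``
composes the item difficulties from the (possibly reduced) design matrix.
Latent abilities follow a multivariate normal with mean zero — when a
reduced design matrix is used the latent means are estimated freely during
fitting and folded back into the reported difficulties, which is the
likelihood-preserving shift that the reduced parameterization exists to
pin down.

Model families differ only in the scoring matrix and in which entries of
the latent covariance matrix are free:

========  =========================================  ==================
family    covariance pattern                          scoring matrix
========  =========================================  ==================
CORB      all entries free                            loading pattern
RTM       diagonal (orthogonal bifactor)              loading pattern
ETM       general-specific free, specifics diagonal   loading pattern
SORB      general orthogonal, specific block free     loading pattern
GSM       general orthogonal, retained block free     zero-sum reduced
SRM       GSM + equal retained specific variances     zero-sum reduced
========  =========================================  ==================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from .structures import DesignMatrix, ScoringMatrix

__all__ = [
    "FAMILIES",
    "build_spec",
    "CovariancePattern",
    "ModelSpec",
    "ResponseData",
    "make_pattern",
    "n_free_params",
    "linear_predictor",
    "response_probability",
    "marginal_loglik",
    "gsm_implied_full_covariance",
]

FAMILIES = ("RTM", "ETM", "CORB", "SORB", "GSM", "SRM")


@dataclass
class CovariancePattern:
    """Which entries of the D-by-D latent covariance matrix are free.

    ``free`` is a symmetric boolean matrix; the diagonal is always free.
    ``ties`` optionally groups free entries that share one parameter
    (used for the equal-specific-variance constraint of the SRM): entries
    with the same positive integer label are equated, 0 means untied.
    """

    D: int
    free: np.ndarray
    ties: np.ndarray | None = None

    def __post_init__(self):
        self.free = np.asarray(self.free, dtype=bool)
        if self.free.shape != (self.D, self.D):
            raise ValueError("pattern shape mismatch")
        if not (self.free == self.free.T).all():
            raise ValueError("pattern must be symmetric")
        if not self.free.diagonal().all():
            raise ValueError("diagonal variances are always free")
        if self.ties is not None:
            self.ties = np.asarray(self.ties, dtype=int)
            if self.ties.shape != (self.D, self.D) or not (self.ties == self.ties.T).all():
                raise ValueError("ties must be a symmetric integer matrix")
            if ((self.ties != 0) & ~self.free).any():
                raise ValueError("tied entries must be free")

    def parameter_groups(self) -> list[list[tuple[int, int]]]:
        """Upper-triangle (i <= j) index groups, one group per free parameter."""
        groups: dict = {}
        singles = []
        for i in range(self.D):
            for j in range(i, self.D):
                if not self.free[i, j]:
                    continue
                lab = int(self.ties[i, j]) if self.ties is not None else 0
                if lab:
                    groups.setdefault(lab, []).append((i, j))
                else:
                    singles.append([(i, j)])
        return singles + [groups[k] for k in sorted(groups)]

    @property
    def n_free(self) -> int:
        return len(self.parameter_groups())

    @property
    def n_free_offdiag(self) -> int:
        return int(np.triu(self.free, 1).sum())

    def conforms(self, Sigma: np.ndarray, tol: float = 1e-10) -> bool:
        Sigma = np.asarray(Sigma)
        ok = np.abs(Sigma[~self.free]).max(initial=0.0) <= tol
        if ok and self.ties is not None:
            for g in self.parameter_groups():
                vals = [Sigma[i, j] for i, j in g]
                ok = ok and (np.ptp(vals) <= tol)
        return bool(ok)

    def project(self, Sigma: np.ndarray) -> np.ndarray:
        """Zero constrained entries and average tied groups."""
        out = np.where(self.free, np.asarray(Sigma, dtype=float), 0.0)
        if self.ties is not None:
            for g in self.parameter_groups():
                if len(g) > 1:
                    m = np.mean([out[i, j] for i, j in g])
                    for i, j in g:
                        out[i, j] = out[j, i] = m
        return out


def make_pattern(family: str, D: int) -> CovariancePattern:
    """Covariance pattern of a model family in a D-dimensional latent space.

    For GSM/SRM, D is the *reduced* dimensionality (general factor plus the
    retained specific factors).
    """
    fam = family.upper()
    if D < 2:
        raise ValueError("D must be at least 2")
    free = np.eye(D, dtype=bool)
    if fam == "CORB":
        free[:] = True
    elif fam == "RTM":
        pass
    elif fam == "ETM":
        free[0, :] = True
        free[:, 0] = True
    elif fam in ("SORB", "GSM", "SRM"):
        free[1:, 1:] = True
    else:
        raise ValueError(f"unknown family {family!r}")
    ties = None
    if fam == "SRM":
        ties = np.zeros((D, D), dtype=int)
        for k in range(1, D):
            ties[k, k] = 1
    return CovariancePattern(D, free, ties)


@dataclass
class ModelSpec:
    """Scoring matrix, design matrix and covariance pattern of one model.

    ``mu`` is fixed at zero by convention: reported difficulties are always
    on the zero-latent-mean scale.  When ``A`` is a reduced design matrix
    the latent means are profiled during estimation (``estimate_means``).
    """

    family: str
    B: ScoringMatrix
    A: DesignMatrix
    pattern: CovariancePattern
    gsm_excluded: int | None = None
    srm_equal_specific_variances: bool = False

    def __post_init__(self):
        self.family = self.family.upper()
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.B.n_items != self.A.n_items:
            raise ValueError("B and A disagree on the number of items")
        if self.pattern.D != self.B.n_dims:
            raise ValueError("pattern dimension does not match B")
        if self.family in ("GSM", "SRM") and self.gsm_excluded is None:
            raise ValueError("GSM/SRM specs need gsm_excluded")
        if self.family == "SRM":
            self.srm_equal_specific_variances = True

    @property
    def n_items(self) -> int:
        return self.B.n_items

    @property
    def D(self) -> int:
        return self.B.n_dims

    @property
    def estimate_means(self) -> bool:
        return self.A.is_reduced


@dataclass
class ResponseData:
    """Person-by-item dichotomous responses; NaN marks a missing response."""

    X: np.ndarray
    person_ids: list = field(default_factory=list)
    item_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D person-by-item matrix")
        obs = ~np.isnan(self.X)
        vals = self.X[obs]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("observed responses must be 0 or 1")
        if not obs.any(axis=1).all():
            raise ValueError("every person needs at least one observed response")
        if not obs.any(axis=0).all():
            raise ValueError("every item needs at least one observed response")
        if not self.person_ids:
            self.person_ids = [f"p{i + 1}" for i in range(self.X.shape[0])]
        if not self.item_ids:
            self.item_ids = [f"item{j + 1}" for j in range(self.X.shape[1])]

    @property
    def n_persons(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.X).sum())


def linear_predictor(theta, item: int, beta, spec: ModelSpec) -> float:
    """``B_i . theta - (A beta)_i`` for a single item."""
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if theta.shape[-1] != spec.D:
        raise ValueError(f"theta has {theta.shape[-1]} dims; expected {spec.D}")
    if beta.shape[-1] != spec.A.n_params:
        raise ValueError(
            f"beta has {beta.shape[-1]} entries; expected {spec.A.n_params}"
        )
    d_i = float(spec.A.A[item] @ beta)
    return float(spec.B.B[item] @ theta) - d_i


def response_probability(theta, item: int, beta, spec: ModelSpec) -> float:
    """Probability of a correct response under the logistic link."""
    return float(expit(linear_predictor(theta, item, beta, spec)))


def _loglik_matrix(X: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Person-by-node log-likelihood: sum over observed items of the
    Bernoulli log-probability.  ``eta`` is items-by-nodes."""
    lp1 = log_expit(eta)        # log P(x=1)
    lp0 = log_expit(-eta)       # log P(x=0)
    if np.isnan(X).any():
        X1 = np.nan_to_num(X)
        M = (~np.isnan(X)).astype(float)
        return X1 @ lp1 + (M - X1) @ lp0
    return X @ (lp1 - lp0) + lp0.sum(axis=0)


def marginal_loglik(
    data: ResponseData,
    beta,
    Sigma,
    spec: ModelSpec,
    integration=None,
    mu=None,
) -> float:
    """Marginal log-likelihood: sum over persons of the log integral of the
    response likelihood against the N(mu, Sigma) latent density.

    ``Sigma`` must be positive definite and conform to the spec's pattern.
    Missing responses are skipped (missing at random).
    """
    from .estimate import IntegrationConfig  # lazy: avoid module cycle

    from scipy.special import logsumexp

    beta = np.asarray(beta, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if not spec.pattern.conforms(Sigma, tol=1e-8):
        raise ValueError("Sigma violates the model family's covariance pattern")
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as e:
        raise ValueError("Sigma must be positive definite") from e
    if integration is None:
        integration = IntegrationConfig()
    z, logw = integration.resolve(spec.D)
    mu = np.zeros(spec.D) if mu is None else np.asarray(mu, dtype=float)
    theta = mu + z @ L.T
    d = spec.A.A @ beta
    eta = spec.B.B @ theta.T - d[:, None]
    ll = _loglik_matrix(data.X, eta)
    return float(logsumexp(ll + logw, axis=1).sum())


def n_free_params(spec: ModelSpec) -> int:
    """Free-parameter count: design-matrix columns plus free covariance
    entries (tied entries count once)."""
    return spec.A.n_params + spec.pattern.n_free


def build_spec(
    structure,
    family: str,
    partition=None,
    excluded: int | None = None,
    reduced: bool | None = None,
) -> ModelSpec:
    """Build a :class:`ModelSpec` for a loading structure and model family.

    For the oblique families (CORB/ETM/SORB) the structure must pass the
    identification check; a witness partition is found automatically unless
    one is supplied.  The orthogonal RTM accepts either a reduced design
    matrix (when the structure identifies one) or the full identity design
    with zero latent means (``reduced=False``, the only option on clear
    structures).  GSM/SRM use the zero-sum scoring matrix for the given
    excluded factor.

    Raises ``IdentificationError`` for oblique families on structures that
    are not analytically identified.
    """
    from .identify import (
        IdentificationError,
        check_identification,
        reduced_design_matrix,
    )
    from .structures import full_design_matrix, gsm_scoring_matrix, scoring_matrix

    fam = family.upper()
    if fam in ("GSM", "SRM"):
        if excluded is None:
            excluded = structure.n_specific
        B = gsm_scoring_matrix(structure, excluded)
    else:
        B = scoring_matrix(structure)
        excluded = None
    report = check_identification(B)
    if reduced is None:
        reduced = report.identified
    if fam in ("CORB", "ETM", "SORB", "GSM", "SRM") and not report.identified:
        raise IdentificationError(
            f"the {fam} model is not analytically identified for this structure "
            f"({report.reason}); a G- or S-structure is required"
        )
    if reduced:
        if not report.identified:
            raise IdentificationError(
                f"no reduced design matrix exists: {report.reason}"
            )
        if partition is not None:
            A = reduced_design_matrix(B, partition)
        else:
            A = report.A_reduced
    else:
        A = full_design_matrix(B.n_items)
    return ModelSpec(fam, B, A, make_pattern(fam, B.n_dims), gsm_excluded=excluded)


def gsm_implied_full_covariance(Sigma_reduced, excluded_factor: int) -> np.ndarray:
    """Complete a subdimension-model covariance matrix to all S+1 dimensions.

    ``Sigma_reduced`` is the fitted (S)-dimensional matrix over (general,
    retained specifics).  The excluded factor's row and column follow from
    the per-person zero-sum constraint on specific scores:
    ``cov(th_k, th_j) = -sum_{i != k} cov(th_i, th_j)`` and
    ``var(th_k) = sum_{i, j != k} cov(th_i, th_j)``.

    With S = 2 the implied correlation between the two specific factors is
    exactly -1 for any positive variance.
    """
    Sr = np.asarray(Sigma_reduced, dtype=float)
    D = Sr.shape[0]
    S = D  # reduced space: general + (S - 1) retained specifics
    k = int(excluded_factor)
    if not (1 <= k <= S):
        raise ValueError(f"excluded_factor must be in 1..{S}")
    retained = [j for j in range(1, S + 1) if j != k]
    full = np.zeros((S + 1, S + 1))
    full[0, 0] = Sr[0, 0]
    for a, ja in enumerate(retained, start=1):
        full[0, ja] = full[ja, 0] = Sr[0, a]
        for b, jb in enumerate(retained, start=1):
            full[ja, jb] = Sr[a, b]
    spec_block = Sr[1:, 1:]
    for b, jb in enumerate(retained, start=1):
        full[k, jb] = full[jb, k] = -spec_block[:, b - 1].sum()
    full[k, k] = spec_block.sum()
    full[k, 0] = full[0, k] = -Sr[0, 1:].sum()
    return full
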