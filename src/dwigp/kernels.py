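"""Covariance functions on the (multi-shell) sphere and kernel assembly.

The diffusion-weighted signal in a voxel is modelled as a Gaussian process
over measurement points x = (g, b), with g a unit gradient direction and b
the diffusion weighting.  Because the signal is antipodally symmetric
(S(g) = S(-g)), angular distance is measured as theta = arccos(|g . g'|),
i.e. the smaller of the two angles obtained when either vector is extended
in the negative direction.

Two stationary angular covariance models are supported:

* exponential:  C(theta) = exp(-theta / a)
* spherical:    C(theta) = 1 - 3 theta/(2a) + theta^3/(2 a^3)  for theta <= a,
                and exactly 0 beyond the cutoff a.

For multi-shell data the kernel is a product of the angular covariance and a
squared-exponential in log b-value distance,
C_b(b, b') = exp(-(log b - log b')^2 / (2 l^2)), giving the block kernel

    K = [ lam*C(Theta_11) + s1^2 I      lam*C(Theta_12)*C_b(b1,b2) ]
        [ lam*C(Theta_21)*C_b(b2,b1)    lam*C(Theta_22) + s2^2 I   ]

with one noise variance per shell and hyperparameters (lam, a, l, s_1^2 ...
s_N^2), i.e. 3 + N free parameters for N shells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .exceptions import (
    InvalidHyperparameterError,
    InvalidInputError,
    NumericalConditioningError,
)
from .gradients import GradientScheme

ANGULAR_MODELS = ("spherical", "exponential")

_UNIT_NORM_TOL = 1e-6
_JITTER_SCALE = 1e-10


def _check_unit(G: np.ndarray, label: str) -> np.ndarray:
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.ndim != 2 or G.shape[1] != 3:
        raise InvalidInputError(f"{label} must be an (n, 3) array of 3-vectors")
    norms = np.linalg.norm(G, axis=1)
    bad = np.flatnonzero(np.abs(norms - 1.0) > _UNIT_NORM_TOL)
    if bad.size:
        i = int(bad[0])
        raise InvalidInputError(
            f"{label}[{i}] has norm {norms[i]:.6g}, expected unit length"
        )
    return G


def compute_angles(G: np.ndarray, G_prime: np.ndarray | None = None) -> np.ndarray:
    """Axially symmetric angles between two sets of unit directions.

    theta_ij = arccos(|g_i . g'_j|) in [0, pi/2]; the absolute value makes
    antipodal directions equivalent.  The dot products are clipped to [-1, 1]
    before the arccos to guard against rounding.  With ``G_prime`` omitted the
    matrix is exactly symmetric with a zero diagonal.
    """
    G = _check_unit(G, "G")
    symmetric = G_prime is None
    Gp = G if symmetric else _check_unit(G_prime, "G_prime")
    dots = np.abs(np.clip(G @ Gp.T, -1.0, 1.0))
    theta = np.arccos(dots)
    if symmetric:
        theta = 0.5 * (theta + theta.T)
        np.fill_diagonal(theta, 0.0)
    return theta


def _check_scale(a: float, name: str = "a") -> float:
    a = float(a)
    if not a > 0:
        raise InvalidHyperparameterError(f"scale {name} must be positive, got {a}")
    return a


def exponential_cov(theta, a: float):
    """Exponential covariance exp(-theta/a); equals 1 at zero separation."""
    a = _check_scale(a)
    return np.exp(-np.asarray(theta, dtype=float) / a)


def spherical_cov(theta, a: float):
    """Spherical covariance: piecewise cubic reaching exactly 0 at theta = a."""
    a = _check_scale(a)
    t = np.asarray(theta, dtype=float)
    r = t / a
    c = 1.0 - 1.5 * r + 0.5 * r**3
    return np.where(t > a, 0.0, c)


def log_b_cov(b, b_prime, ell: float):
    """Squared-exponential covariance in log b-value distance."""
    ell = _check_scale(ell, "ell")
    b = np.asarray(b, dtype=float)
    bp = np.asarray(b_prime, dtype=float)
    if np.any(b <= 0) or np.any(bp <= 0):
        raise InvalidInputError(
            "b-values must be positive for the log-b covariance "
            "(b0 volumes are filtered upstream)"
        )
    d = np.log(b) - np.log(bp)
    return np.exp(-(d * d) / (2.0 * ell * ell))


def angular_cov(theta, a: float, model: str):
    """Dispatch to the requested angular covariance model."""
    if model == "spherical":
        return spherical_cov(theta, a)
    if model == "exponential":
        return exponential_cov(theta, a)
    raise InvalidHyperparameterError(
        f"unknown angular model {model!r}; expected one of {ANGULAR_MODELS}"
    )


@dataclass(frozen=True)
class Hyperparameters:
    """The hyperparameter vector beta of a covariance model.

    Parameters
    ----------
    model : {"spherical", "exponential"}
        Angular covariance family.
    lam : float
        Signal-variance scale lambda (signal units squared); diag(K) = lam.
    a : float
        Angular length scale in radians.
    sigma2 : sequence of float
        One measurement-noise variance per shell (signal units squared).
        May be zero for noise-free synthetic work; the optimiser itself works
        in log coordinates and therefore always keeps them positive.
    ell : float, optional
        Log-b length scale; required iff there is more than one shell.
    """

    model: str
    lam: float
    a: float
    sigma2: tuple
    ell: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ANGULAR_MODELS:
            raise InvalidHyperparameterError(
                f"unknown angular model {self.model!r}; expected one of {ANGULAR_MODELS}"
            )
        object.__setattr__(self, "sigma2", tuple(float(s) for s in np.atleast_1d(self.sigma2)))
        for name in ("lam", "a"):
            if not float(getattr(self, name)) > 0:
                raise InvalidHyperparameterError(f"{name} must be positive")
        object.__setattr__(self, "lam", float(self.lam))
        object.__setattr__(self, "a", float(self.a))
        if any(s < 0 for s in self.sigma2):
            raise InvalidHyperparameterError("noise variances must be non-negative")
        multi = len(self.sigma2) > 1
        if multi and self.ell is None:
            raise InvalidHyperparameterError("multi-shell model requires ell")
        if not multi and self.ell is not None:
            raise InvalidHyperparameterError("single-shell model takes no ell")
        if self.ell is not None:
            object.__setattr__(self, "ell", _check_scale(self.ell, "ell"))

    @property
    def n_shells(self) -> int:
        return len(self.sigma2)

    @property
    def n_params(self) -> int:
        """Free-parameter count: 3 single shell, 3 + N for N shells."""
        return 2 + len(self.sigma2) + (1 if self.ell is not None else 0)

    # -- unconstrained log coordinates used by the optimiser ---------------

    def to_vector(self) -> np.ndarray:
        """Unconstrained coordinates [log lam, log a, (log ell), log sigma2_s...]."""
        head = [self.lam, self.a] + ([self.ell] if self.ell is not None else [])
        return np.log(np.asarray(head + list(self.sigma2), dtype=float))

    @classmethod
    def from_vector(cls, u: np.ndarray, model: str, n_shells: int) -> "Hyperparameters":
        u = np.asarray(u, dtype=float).ravel()
        expected = (3 if n_shells == 1 else 3 + n_shells)
        if len(u) != expected:
            raise InvalidHyperparameterError(
                f"expected {expected} unconstrained parameters for {n_shells} "
                f"shell(s), got {len(u)}"
            )
        v = np.exp(u)
        if n_shells == 1:
            return cls(model=model, lam=v[0], a=v[1], sigma2=(v[2],))
        return cls(model=model, lam=v[0], a=v[1], ell=v[2], sigma2=tuple(v[3:]))

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "lambda": self.lam,
            "a": self.a,
            "ell": self.ell,
            "sigma2": list(self.sigma2),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        return cls(model=d["model"], lam=d["lambda"], a=d["a"],
                   ell=d.get("ell"), sigma2=tuple(d["sigma2"]))


@dataclass
class KernelMatrix:
    """An assembled covariance matrix with its noise-augmented factorisation.

    ``K`` is the noise-free n x n prior covariance, ``K_y = K + noise`` the
    observation covariance, ``factor`` its cached Cholesky factor and
    ``log_det`` = log|K_y|.
    """

    K: np.ndarray
    K_y: np.ndarray
    factor: tuple
    log_det: float
    scheme: GradientScheme
    hyper: Hyperparameters
    _inverse: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def solve(self, b: np.ndarray) -> np.ndarray:
        """K_y^{-1} b via the cached triangular factor."""
        return cho_solve(self.factor, np.asarray(b, dtype=float))

    def inverse(self) -> np.ndarray:
        """Explicit K_y^{-1} (cached); used by the leave-one-out identities."""
        if self._inverse is None:
            self._inverse = cho_solve(self.factor, np.eye(self.n))
        return self._inverse


def _factorise(K_y: np.ndarray):
    """Cholesky with a single documented jitter retry."""
    try:
        return cho_factor(K_y, lower=True), K_y
    except LinAlgError:
        jitter = _JITTER_SCALE * float(np.mean(np.diag(K_y)))
        warnings.warn(
            f"Cholesky factorisation failed; retrying with jitter {jitter:.3g} "
            "on the diagonal",
            stacklevel=3,
        )
        K_j = K_y + jitter * np.eye(K_y.shape[0])
        try:
            return cho_factor(K_j, lower=True), K_j
        except LinAlgError:
            smallest = float(np.linalg.eigvalsh(K_y)[0])
            raise NumericalConditioningError(
                "covariance matrix is not positive definite even after jitter "
                f"(smallest eigenvalue ~ {smallest:.3g})"
            ) from None


def _rep_bvalues(scheme: GradientScheme) -> np.ndarray:
    """Representative shell b-value of every measurement."""
    return scheme.shell_bvalues[scheme.shell_ids]


def assemble_K(scheme: GradientScheme, hyper: Hyperparameters) -> KernelMatrix:
    """Assemble K and the factorised K_y for a diffusion-weighted scheme.

    Single shell: K_ij = lam * C(theta_ij; a) and K_y = K + sigma^2 I.
    Multi-shell: the angular kernel is multiplied by the log-b covariance
    evaluated on representative shell b-values (so within-shell blocks are
    purely angular) and each shell contributes its own noise variance on the
    diagonal.
    """
    if np.any(scheme.is_b0):
        raise InvalidInputError(
            "scheme contains b0 volumes; pass scheme.dwi (b0 entries are "
            "excluded from GP training)"
        )
    if len(scheme) < 1:
        raise InvalidInputError("scheme must contain at least one measurement")
    if hyper.n_shells != scheme.n_shells:
        raise InvalidInputError(
            f"hyperparameters describe {hyper.n_shells} shell(s) but the "
            f"scheme has {scheme.n_shells}"
        )
    theta = compute_angles(scheme.directions)
    K = hyper.lam * angular_cov(theta, hyper.a, hyper.model)
    if scheme.n_shells > 1:
        b = _rep_bvalues(scheme)
        K = K * log_b_cov(b[:, None], b[None, :], hyper.ell)
    noise = np.asarray(hyper.sigma2, dtype=float)[scheme.shell_ids]
    K_y = K + np.diag(noise)
    factor, K_y = _factorise(K_y)
    log_det = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    return KernelMatrix(K=K, K_y=K_y, factor=factor, log_det=log_det,
                        scheme=scheme, hyper=hyper)


def cross_covariance(
    scheme: GradientScheme,
    hyper: Hyperparameters,
    query_directions: np.ndarray,
    query_bvalues: np.ndarray | None = None,
) -> np.ndarray:
    """k(x*, x): (m, n) covariances between query points and a training scheme.

    ``query_bvalues`` defaults to the training scheme's representative shell
    b-values mapped by nearest shell; for multi-shell kernels they enter the
    log-b factor directly.
    """
    Q = _check_unit(query_directions, "query_directions")
    theta = compute_angles(Q, scheme.directions)
    k = hyper.lam * angular_cov(theta, hyper.a, hyper.model)
    if scheme.n_shells > 1:
        if query_bvalues is None:
            raise InvalidInputError("multi-shell queries require b-values")
        qb = np.asarray(query_bvalues, dtype=float).ravel()
        if np.any(qb <= 0):
            raise InvalidInputError("query b-values must be positive")
        b = _rep_bvalues(scheme)
        k = k * log_b_cov(qb[:, None], b[None, :], hyper.ell)
    return k
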