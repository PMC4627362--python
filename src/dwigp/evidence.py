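"""Laplace-approximated model evidence and Bayes factors.

The evidence p(y | M) = integral of p(y | beta, M) p(beta | M) d(beta) is
approximated by Laplace's method around the type-II ML optimum beta_0 in the
unconstrained log-parameter coordinates, with a flat (improper) prior over
those coordinates so that the MAP point coincides with the ML point:

    log p(y | M) ~= L(beta_0) + (d/2) log 2pi - 1/2 log |-H|

where L is the summed log marginal likelihood and H its Hessian at beta_0,
estimated by central finite differences.  The approximation is exact when L
is quadratic, and improves as the posterior sharpens (more voxels).

Bayes factors are ratios of two models' evidences computed on the identical
voxel set; values above 1 favour the first model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidComparisonError, InvalidInputError
from .kernels import Hyperparameters

_LOG_2PI = float(np.log(2.0 * np.pi))


def finite_difference_hessian(objective, beta_hat: np.ndarray,
                              rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian, symmetrised as (H + H^T) / 2.

    Per-coordinate step h_k = rel_step * max(|beta_hat_k|, 1).  Raises if the
    objective is non-finite anywhere on the stencil, naming the coordinate.
    """
    x = np.asarray(beta_hat, dtype=float).ravel()
    d = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)

    cache: dict[tuple, float] = {}

    def f(z, coords):
        key = tuple(z)
        if key not in cache:
            val = float(objective(z))
            if not np.isfinite(val):
                raise InvalidInputError(
                    f"objective non-finite at a finite-difference stencil point "
                    f"(perturbed coordinate(s) {coords})"
                )
            cache[key] = val
        return cache[key]

    f0 = f(x, ())
    H = np.empty((d, d))
    for k in range(d):
        ek = np.zeros(d); ek[k] = h[k]
        H[k, k] = (f(x + ek, (k,)) - 2.0 * f0 + f(x - ek, (k,))) / h[k] ** 2
    for k in range(d):
        ek = np.zeros(d); ek[k] = h[k]
        for l in range(k + 1, d):
            el = np.zeros(d); el[l] = h[l]
            H[k, l] = H[l, k] = (
                f(x + ek + el, (k, l)) - f(x + ek - el, (k, l))
                - f(x - ek + el, (k, l)) + f(x - ek - el, (k, l))
            ) / (4.0 * h[k] * h[l])
    return 0.5 * (H + H.T)


@dataclass(frozen=True)
class EvidenceResult:
    """Laplace evidence for one covariance model on one voxel population."""

    model: str
    log_evidence: float
    beta_hat: Hyperparameters
    hessian: np.ndarray
    n_voxels: int
    valid: bool
    eigenvalues: np.ndarray
    data_fingerprint: str = ""


def laplace_evidence_from_objective(objective, beta_hat: np.ndarray,
                                    rel_step: float = 1e-3):
    """Core Laplace computation for an arbitrary (maximised) log objective.

    Returns (log_evidence, hessian, eigenvalues, valid); ``valid`` is False
    when -H is not positive definite, in which case the log evidence is nan.
    """
    x = np.asarray(beta_hat, dtype=float).ravel()
    H = finite_difference_hessian(objective, x, rel_step)
    eigs = np.linalg.eigvalsh(-H)
    valid = bool(np.all(eigs > 0))
    if valid:
        log_ev = float(objective(x)) + 0.5 * len(x) * _LOG_2PI \
            - 0.5 * float(np.sum(np.log(eigs)))
    else:
        log_ev = float("nan")
    return log_ev, H, eigs, valid


def laplace_log_evidence(results, rel_step: float = 1e-3) -> EvidenceResult:
    """Laplace evidence of a fitted :class:`~dwigp.model.DiffusionGPResults`.

    The fit must use the marginal-likelihood criterion (the evidence
    integrates the likelihood, not a predictive score).
    """
    if results.criterion != "ml":
        raise InvalidInputError(
            "Laplace evidence requires a marginal-likelihood ('ml') fit, "
            f"got criterion {results.criterion!r}"
        )
    if not results.converged:
        raise InvalidInputError("fit did not converge; refusing to compute evidence")
    model = results.model
    idx = results.voxel_indices

    def f(u):
        return model.objective_from_vector(u, "ml", idx)

    log_ev, H, eigs, valid = laplace_evidence_from_objective(
        f, results.params.to_vector(), rel_step)
    return EvidenceResult(
        model=results.params.model, log_evidence=log_ev,
        beta_hat=results.params, hessian=H, n_voxels=len(idx),
        valid=valid, eigenvalues=eigs,
        data_fingerprint=_fingerprint(model.endog[idx]),
    )


def bayes_factor(e1: EvidenceResult, e2: EvidenceResult) -> float:
    """exp(log_evidence_1 - log_evidence_2); > 1 favours the first model."""
    for e in (e1, e2):
        if not e.valid:
            raise InvalidInputError(
                f"evidence for model {e.model!r} is flagged invalid "
                "(Hessian not negative definite)"
            )
    if e1.n_voxels != e2.n_voxels or e1.data_fingerprint != e2.data_fingerprint:
        raise InvalidComparisonError(
            "evidences were computed on different voxel sets and are not comparable"
        )
    return float(np.exp(e1.log_evidence - e2.log_evidence))


def _fingerprint(values: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(values, dtype=float).tobytes()).hexdigest()
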