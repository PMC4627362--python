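"""Shared fixtures and independent oracles for the dwigp test suite.

The oracle helpers deliberately re-derive everything with explicit formulas
and dense inverses (no reuse of the package's factorised solve paths), so
they can certify the fast implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from dwigp import GradientScheme, Hyperparameters


def random_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_scheme(rng: np.random.Generator, n_per_shell, shell_bvalues) -> GradientScheme:
    """A b0-free scheme with the given shell layout and random directions."""
    dirs, bvals, ids = [], [], []
    for s, (n, b) in enumerate(zip(n_per_shell, shell_bvalues)):
        dirs.append(random_directions(n, rng))
        bvals.append(np.full(n, float(b)))
        ids.append(np.full(n, s, dtype=int))
    return GradientScheme(np.concatenate(dirs), np.concatenate(bvals),
                          np.concatenate(ids), np.asarray(shell_bvalues, float))


def random_hyper(rng: np.random.Generator, n_shells: int,
                 model: str | None = None, sigma2_scale: float = 0.1) -> Hyperparameters:
    model = model or rng.choice(["spherical", "exponential"])
    lam = float(rng.uniform(0.5, 3.0))
    return Hyperparameters(
        model=str(model),
        lam=lam,
        a=float(rng.uniform(0.4, 1.5)),
        ell=float(rng.uniform(0.5, 2.0)) if n_shells > 1 else None,
        sigma2=tuple(rng.uniform(0.2, 1.0, n_shells) * sigma2_scale * lam),
    )


# -- brute-force covariance assembly (independent of dwigp.kernels) ---------

def oracle_cov_element(x1, b1, s1, x2, b2, s2, hyper, shell_bvalues) -> float:
    """Covariance between two measurement points, written out longhand."""
    ct = float(np.clip(abs(float(np.dot(x1, x2))), -1.0, 1.0))
    theta = np.arccos(ct)
    if hyper.model == "spherical":
        C = 1.0 - 1.5 * theta / hyper.a + 0.5 * theta**3 / hyper.a**3 \
            if theta <= hyper.a else 0.0
    else:
        C = np.exp(-theta / hyper.a)
    k = hyper.lam * C
    if hyper.ell is not None:
        rb1, rb2 = shell_bvalues[s1], shell_bvalues[s2]
        k *= np.exp(-((np.log(rb1) - np.log(rb2)) ** 2) / (2.0 * hyper.ell**2))
    return float(k)


def oracle_K(scheme: GradientScheme, hyper: Hyperparameters,
             with_noise: bool = True) -> np.ndarray:
    n = len(scheme)
    K = np.empty((n, n))
    for i in range(n):
        # at zero separation both kernel factors are 1 by definition; going
        # through acos(dot) would inject ~1e-8 of pure rounding error
        K[i, i] = hyper.lam
        for j in range(n):
            if i == j:
                continue
            K[i, j] = oracle_cov_element(
                scheme.directions[i], scheme.bvalues[i], scheme.shell_ids[i],
                scheme.directions[j], scheme.bvalues[j], scheme.shell_ids[j],
                hyper, scheme.shell_bvalues)
    if with_noise:
        K = K + np.diag(np.asarray(hyper.sigma2)[scheme.shell_ids])
    return K


def oracle_conditional(scheme, hyper, y_demeaned, query_dirs, query_shells):
    """Direct MVN conditioning with explicit inverses on the demeaned signal.

    ``query_shells`` gives the shell index of each query (its representative
    b-value enters the log-b factor).  Returns (mean_demeaned, variance).
    """
    K_y = oracle_K(scheme, hyper, with_noise=True)
    m = len(query_shells)
    n = len(scheme)
    kq = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            kq[i, j] = oracle_cov_element(
                query_dirs[i], scheme.shell_bvalues[query_shells[i]], query_shells[i],
                scheme.directions[j], scheme.bvalues[j], scheme.shell_ids[j],
                hyper, scheme.shell_bvalues)
    mean = kq @ np.linalg.solve(K_y, y_demeaned)
    var = hyper.lam - np.sum(np.linalg.solve(K_y, kq.T).T * kq, axis=1)
    return mean, var


def oracle_loo(scheme, hyper, y_demeaned):
    """Leave-one-out CV and GPP by literally refitting without each point."""
    K = oracle_K(scheme, hyper, with_noise=False)
    noise = np.asarray(hyper.sigma2)[scheme.shell_ids]
    K_y = K + np.diag(noise)
    n = len(scheme)
    sq_resid, log_dens = [], []
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        Kinv = np.linalg.inv(K_y[np.ix_(rest, rest)])
        mean = K[i, rest] @ Kinv @ y_demeaned[rest]
        var = K[i, i] + noise[i] - K[i, rest] @ Kinv @ K[rest, i]
        r = y_demeaned[i] - mean
        sq_resid.append(r**2)
        log_dens.append(-0.5 * np.log(2 * np.pi * var) - r**2 / (2 * var))
    return float(np.mean(sq_resid)), float(np.mean(log_dens))


def tensor_lls_predict(scheme, train_values, train_idx, query_idx) -> np.ndarray:
    """Log-linear least-squares single-tensor fit as a prediction baseline.

    Fits ln S = c - b g^T D g on the training subset and evaluates the model
    at the query volumes.  All indices refer to the (b0-free) scheme.
    """
    def design(idx):
        g = scheme.directions[idx]
        b = scheme.bvalues[idx]
        return np.column_stack([
            np.ones(len(idx)),
            -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ])

    coef, *_ = np.linalg.lstsq(design(train_idx), np.log(train_values), rcond=None)
    return np.exp(design(query_idx) @ coef)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
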