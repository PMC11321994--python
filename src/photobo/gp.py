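"""Gaussian-process surrogates for both optimization campaigns.

Two kernels are supported:

* a Matérn kernel (nu in {1/2, 3/2, 5/2}) on z-scored molecular descriptors,
  used for the catalyst-discovery campaign;
* a custom formulation RBF kernel over reaction-condition pairs,

      K(P_i, P_j) = alpha * exp(-(theta1*D_EA^2 + theta2*D_fps(M)^2
                                  + theta3*D_fps(L)^2 + theta4*D_C^2)),

  whose four component distances come from the condition space's frozen
  normalizers.  The theta weights regulate the relative importance of the
  electronic, catalyst-structure, ligand-structure and loading channels and
  are tuned by marginal likelihood along with alpha and the noise variance.

Targets (yields in %) are standardized internally; predictions are reported
back on the % scale.  Because an RBF over Tanimoto distances is not
guaranteed positive semi-definite, Cholesky factorization escalates a
diagonal jitter from ``jitter`` up to 1e-4, warning on escalation and failing
hard (with the offending minimum eigenvalue) beyond the cap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .conditions import ConditionSpace, ReactionCondition
from .errors import DimensionError, PSDError, ValidationError

JITTER_CAP = 1e-4
LOG_BOUND = (math.log(1e-4), math.log(1e4))


@dataclass
class KernelSpec:
    """Kernel family plus initial hyperparameters for marginal-likelihood fitting."""

    kind: str = "matern_descriptor"  # or "formulation_rbf"
    nu: float = 2.5
    ard: bool = False
    lengthscale: float = 1.0
    signal_var: float = 1.0
    alpha: float = 1.0                      # formulation signal scale
    thetas: tuple = (1.0, 1.0, 1.0, 1.0)    # formulation component weights
    noise_var: float = 1e-2
    noise_floor: float = 1e-6
    jitter: float = 1e-10
    n_restarts: int = 8

    def __post_init__(self):
        if self.kind not in ("matern_descriptor", "formulation_rbf"):
            raise ValidationError(f"unknown kernel kind {self.kind!r}")
        if self.nu not in (0.5, 1.5, 2.5):
            raise ValidationError("Matern smoothness nu must be one of 0.5, 1.5, 2.5")
        for v, name in ((self.signal_var, "signal_var"), (self.alpha, "alpha"),
                        (self.noise_var, "noise_var"), (self.lengthscale, "lengthscale")):
            if np.any(np.asarray(v) <= 0):
                raise ValidationError(f"{name} must be positive")
        if any(t < 0 for t in self.thetas):
            raise ValidationError("theta weights must be non-negative")


def _matern_corr(r: np.ndarray, nu: float) -> np.ndarray:
    """Matern correlation as a function of scaled distance r = d / lengthscale."""
    if nu == 0.5:
        return np.exp(-r)
    if nu == 1.5:
        s = math.sqrt(3.0) * r
        return (1.0 + s) * np.exp(-s)
    s = math.sqrt(5.0) * r
    return (1.0 + s + s * s / 3.0) * np.exp(-s)


class MaternKernel:
    """Matern covariance on a Euclidean feature space (shared or ARD lengthscales)."""

    def __init__(self, nu: float, lengthscales: np.ndarray, signal_var: float):
        self.nu = nu
        self.lengthscales = np.atleast_1d(np.asarray(lengthscales, dtype=float))
        self.signal_var = float(signal_var)

    def __call__(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        r = cdist(X1 / self.lengthscales, X2 / self.lengthscales)
        return self.signal_var * _matern_corr(r, self.nu)

    def diag(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.signal_var)


class FormulationKernel:
    """The combined-distance RBF kernel over reaction-condition indices."""

    def __init__(self, space: ConditionSpace, alpha: float, thetas: Sequence[float]):
        if any(t < 0 for t in thetas):
            raise ValidationError("theta weights must be non-negative")
        self.space = space
        self.alpha = float(alpha)
        self.thetas = np.asarray(thetas, dtype=float)

    def __call__(self, I, J) -> np.ndarray:
        D = self.space.component_dists(I, J)  # (4, n, m), normalized
        expo = np.tensordot(self.thetas, D * D, axes=1)
        return self.alpha * np.exp(-expo)

    def diag(self, I) -> np.ndarray:
        return np.full(len(np.atleast_1d(I)), self.alpha)


def formulation_kernel(
    p: ReactionCondition, q: ReactionCondition, spec: KernelSpec, space: ConditionSpace
) -> float:
    """Evaluate the formulation kernel between two single conditions."""
    if spec.kind != "formulation_rbf":
        raise ValidationError("spec.kind must be 'formulation_rbf'")
    k = FormulationKernel(space, spec.alpha, spec.thetas)
    return float(k([space.index_of(p)], [space.index_of(q)])[0, 0])


def chol_with_jitter(K: np.ndarray, jitter: float) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of K + jI, escalating j tenfold up to the cap."""
    n = K.shape[0]
    j = jitter
    first = True
    while j <= JITTER_CAP:
        try:
            L = cholesky(K + j * np.eye(n), lower=True)
            if not first:
                warnings.warn(f"kernel matrix required jitter escalation to {j:.1e}")
            return L, j
        except np.linalg.LinAlgError:
            first = False
            j *= 10.0
    min_eig = float(np.linalg.eigvalsh(K).min())
    raise PSDError(min_eig)


@dataclass
class GPModel:
    """A fitted GP exposing the posterior mean and uncertainty on the % yield scale."""

    spec: KernelSpec
    kernel: object
    X: np.ndarray            # descriptor rows, or condition indices
    y: np.ndarray            # raw targets (%)
    noise_var: float         # on the standardized scale
    y_mean: float
    y_std: float
    L: np.ndarray = field(repr=False)
    alpha_vec: np.ndarray = field(repr=False)
    jitter_used: float = 0.0
    log_marginal_likelihood: float = float("nan")
    log_marginal_likelihood_init: float = float("nan")
    x_mean: np.ndarray | None = None  # descriptor scaler, persisted with the model
    x_std: np.ndarray | None = None

    def _encode(self, Xs) -> np.ndarray:
        if self.spec.kind == "matern_descriptor":
            Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
            if Xs.shape[1] != self.X.shape[1]:
                raise DimensionError(
                    f"query has {Xs.shape[1]} features, model trained on {self.X.shape[1]}"
                )
            return (Xs - self.x_mean) / self.x_std
        return np.asarray(Xs, dtype=int)

    def predict(self, Xs) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation (latent, noise-free) at queries."""
        Q = self._encode(Xs)
        Ks = self.kernel(self._Xe, Q) if self.spec.kind == "matern_descriptor" else self.kernel(self.X, Q)
        mu_std = Ks.T @ self.alpha_vec
        v = solve_triangular(self.L, Ks, lower=True)
        var = self.kernel.diag(Q) - np.einsum("ij,ij->j", v, v)
        var = np.clip(var, 0.0, None)
        mu = self.y_mean + self.y_std * mu_std
        sigma = self.y_std * np.sqrt(var)
        return mu, sigma

    @property
    def _Xe(self) -> np.ndarray:
        if self.spec.kind == "matern_descriptor":
            return (self.X - self.x_mean) / self.x_std
        return self.X


def _build_kernel(spec: KernelSpec, log_params: np.ndarray, ndim: int, space=None):
    """Instantiate a kernel (and noise variance) from a log-parameter vector."""
    p = np.exp(log_params)
    if spec.kind == "matern_descriptor":
        nl = ndim if spec.ard else 1
        signal, ls, noise = p[0], p[1 : 1 + nl], p[1 + nl]
        return MaternKernel(spec.nu, ls, signal), float(noise)
    alpha, thetas, noise = p[0], p[1:5], p[5]
    return FormulationKernel(space, alpha, thetas), float(noise)


def _init_log_params(spec: KernelSpec, y_var: float, ndim: int) -> np.ndarray:
    if spec.kind == "matern_descriptor":
        nl = ndim if spec.ard else 1
        return np.log(np.concatenate([
            [max(spec.signal_var, 1e-4)],
            np.full(nl, spec.lengthscale),
            [max(spec.noise_var, spec.noise_floor)],
        ]))
    return np.log(np.concatenate([
        [max(spec.alpha, 1e-4)], np.asarray(np.maximum(spec.thetas, 1e-4), dtype=float),
        [max(spec.noise_var, spec.noise_floor)],
    ]))


def _neg_lml(log_params, spec, Xe, y_std_targets, ndim, space, jitter):
    kernel, noise = _build_kernel(spec, log_params, ndim, space)
    n = len(y_std_targets)
    K = kernel(Xe, Xe) + noise * np.eye(n)
    try:
        # trial points explored by the optimizer may be near-degenerate;
        # only the final factorization in fit_gp surfaces escalation warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            L, _ = chol_with_jitter(K, jitter)
    except PSDError:
        return 1e25
    a = solve_triangular(L, y_std_targets, lower=True)
    lml = -0.5 * a @ a - np.log(np.diag(L)).sum() - 0.5 * n * math.log(2 * math.pi)
    return -lml if np.isfinite(lml) else 1e25


def fit_gp(
    X,
    y,
    spec: KernelSpec,
    seed: int = 0,
    space: ConditionSpace | None = None,
    optimize: bool = True,
) -> GPModel:
    """Fit a GP by multi-restart maximization of the log marginal likelihood.

    ``X`` is an (n, d) descriptor matrix for the Matern kernel, or a length-n
    sequence of condition indices for the formulation kernel (``space``
    required).  Deterministic given (X, y, spec, seed).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValidationError("need at least two observations")
    if not np.all(np.isfinite(y)):
        raise ValidationError("targets must be finite")

    if spec.kind == "matern_descriptor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(X) != len(y):
            raise ValidationError("X and y length mismatch")
        x_mean = X.mean(axis=0)
        x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xe = (X - x_mean) / x_std
        ndim = X.shape[1]
    else:
        if space is None:
            raise ValidationError("formulation kernel requires the condition space")
        X = np.asarray(X, dtype=int)
        if len(X) != len(y):
            raise ValidationError("X and y length mismatch")
        Xe, x_mean, x_std, ndim = X, None, None, 4

    y_mean = float(y.mean())
    y_std = float(y.std())
    if y_std == 0.0:
        y_std = 1.0
    t = (y - y_mean) / y_std

    theta0 = _init_log_params(spec, t.var(), ndim)
    nparam = len(theta0)
    lo, hi = LOG_BOUND
    noise_lo = math.log(spec.noise_floor)
    bounds = [(lo, hi)] * nparam
    bounds[-1] = (noise_lo, hi)
    theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

    nll0 = _neg_lml(theta0, spec, Xe, t, ndim, space, spec.jitter)
    best_theta, best_nll = theta0, nll0
    if optimize:
        rng = np.random.default_rng(seed)
        starts = [theta0] + [
            rng.uniform([b[0] for b in bounds], [b[1] for b in bounds])
            for _ in range(max(spec.n_restarts - 1, 0))
        ]
        for s in starts:
            res = minimize(
                _neg_lml, s, args=(spec, Xe, t, ndim, space, spec.jitter),
                method="L-BFGS-B", bounds=bounds,
            )
            if res.fun < best_nll:
                best_theta, best_nll = res.x, res.fun

    kernel, noise = _build_kernel(spec, best_theta, ndim, space)
    n = len(t)
    K = kernel(Xe, Xe) + noise * np.eye(n)
    L, j_used = chol_with_jitter(K, spec.jitter)
    alpha_vec = cho_solve((L, True), t)
    return GPModel(
        spec=spec, kernel=kernel, X=X, y=y, noise_var=noise,
        y_mean=y_mean, y_std=y_std, L=L, alpha_vec=alpha_vec,
        jitter_used=j_used,
        log_marginal_likelihood=-best_nll,
        log_marginal_likelihood_init=-nll0,
        x_mean=x_mean, x_std=x_std,
    )


def predict_posterior(model: GPModel, Xs) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mu, sigma) at queries; thin functional wrapper over the model."""
    return model.predict(Xs)
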