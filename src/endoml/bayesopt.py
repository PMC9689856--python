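"""Gaussian-process Bayesian optimization with expected improvement.

Everything is written against the minimization convention: the
surrogate models g(y), the incumbent is the smallest observed value,
and expected improvement is

    EI(y) = sigma(y) * [gamma * Phi(gamma) + phi(gamma)],
    gamma  = (g_best - mu(y)) / sigma(y),

i.e. the posterior expectation of max(g_best - Y, 0). The surrogate
is a Matern-5/2 GP with per-dimension length scales whose
hyperparameters are set by multi-start marginal-likelihood
maximization; dimensions flagged log-scale are searched in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.stats import norm, qmc

__all__ = [
    "SearchBox",
    "GPModel",
    "gp_fit",
    "gp_predict",
    "expected_improvement",
    "optimize_ei",
    "BayesianOptimizer",
]

_JITTER = 1e-12  # escalated multiplicatively if the factorization fails


@dataclass
class SearchBox:
    """Axis-aligned search domain with optional per-dimension log scale."""

    lower: np.ndarray
    upper: np.ndarray
    log_scale: np.ndarray | None = None

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound shapes differ")
        if np.any(self.lower >= self.upper):
            raise ValueError("need lower < upper in every dimension")
        if self.log_scale is None:
            self.log_scale = np.zeros(self.lower.size, dtype=bool)
        else:
            self.log_scale = np.asarray(self.log_scale, dtype=bool)
        if self.log_scale.any() and np.any(self.lower[self.log_scale] <= 0):
            raise ValueError("log-scale dimensions need positive lower bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    def to_unit(self, y: np.ndarray) -> np.ndarray:
        """Map a point in the box to [0, 1]^K (log dims in log space)."""
        y = np.asarray(y, dtype=float)
        lo, hi = self.lower.copy(), self.upper.copy()
        yt = y.astype(float).copy()
        ls = self.log_scale
        yt[..., ls] = np.log(yt[..., ls])
        lo[ls], hi[ls] = np.log(lo[ls]), np.log(hi[ls])
        return (yt - lo) / (hi - lo)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        lo, hi = self.lower.copy(), self.upper.copy()
        ls = self.log_scale
        lo[ls], hi[ls] = np.log(lo[ls]), np.log(hi[ls])
        y = lo + u * (hi - lo)
        y[..., ls] = np.exp(y[..., ls])
        return np.clip(y, self.lower, self.upper)


def _matern52(x1: np.ndarray, x2: np.ndarray, signal_var: float, lengths: np.ndarray) -> np.ndarray:
    d = (x1[:, None, :] - x2[None, :, :]) / lengths[None, None, :]
    r = np.sqrt(np.maximum((d * d).sum(axis=-1), 0.0))
    s5r = np.sqrt(5.0) * r
    return signal_var * (1.0 + s5r + 5.0 * r * r / 3.0) * np.exp(-s5r)


@dataclass
class GPModel:
    """Fitted GP posterior over the unit-cube coordinates of a SearchBox."""

    x: np.ndarray                  # (N, K) training inputs (unit cube)
    y: np.ndarray                  # (N,) observations, internally centered
    signal_var: float
    lengths: np.ndarray
    noise_var: float
    y_mean: float = 0.0
    chol: np.ndarray | None = None
    alpha: np.ndarray | None = None

    def _factorize(self):
        k = _matern52(self.x, self.x, self.signal_var, self.lengths)
        jitter = _JITTER
        while True:  # escalate jitter only as far as positive-definiteness needs
            try:
                kj = k.copy()
                kj[np.diag_indices_from(kj)] += self.noise_var + jitter
                self.chol = linalg.cholesky(kj, lower=True)
                break
            except linalg.LinAlgError:
                jitter *= 100.0
                if jitter > 1e-2:
                    raise
        self.alpha = linalg.cho_solve((self.chol, True), self.y - self.y_mean)


def _neg_log_marginal(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    sv, noise = np.exp(theta[0]), np.exp(theta[-1])
    lengths = np.exp(theta[1:-1])
    k = _matern52(x, x, sv, lengths)
    k[np.diag_indices_from(k)] += noise + _JITTER
    try:
        chol = linalg.cholesky(k, lower=True)
    except linalg.LinAlgError:
        return 1e25
    alpha = linalg.cho_solve((chol, True), y)
    return float(0.5 * y @ alpha + np.log(np.diag(chol)).sum()
                 + 0.5 * len(y) * np.log(2 * np.pi))


def gp_fit(x: np.ndarray, y: np.ndarray, n_restarts: int = 4, seed: int = 0,
           fixed_theta: tuple | None = None) -> GPModel:
    """Fit a Matern-5/2 GP by multi-start marginal-likelihood maximization.

    ``fixed_theta = (signal_var, lengths, noise_var)`` skips the
    hyperparameter search (used by oracles and tests).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 2:
        raise ValueError("need at least two observations")
    if not np.isfinite(y).all() or not np.isfinite(x).all():
        raise ValueError("non-finite observation")
    if len(np.unique(x, axis=0)) < len(x):
        warnings.warn("duplicate input points; relying on noise/jitter", stacklevel=2)
    y_mean = float(y.mean())
    yc = y - y_mean
    if fixed_theta is not None:
        sv, lengths, noise = fixed_theta
        model = GPModel(x, y, float(sv), np.asarray(lengths, dtype=float),
                        float(noise), y_mean)
        model._factorize()
        return model
    k = x.shape[1]
    yvar = max(yc.var(), 1e-12)
    rng = np.random.default_rng(seed)
    best, best_val = None, np.inf
    starts = [np.concatenate([[np.log(yvar)], np.zeros(k) + np.log(0.3),
                              [np.log(yvar * 1e-4 + 1e-10)]])]
    noise_hi = np.log(yvar + 1e-10)
    noise_lo = min(np.log(1e-8), noise_hi - 1.0)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.concatenate([
            [np.log(yvar) + rng.normal(0, 1)],
            rng.uniform(np.log(0.05), np.log(2.0), size=k),
            [rng.uniform(noise_lo, noise_hi)],
        ]))
    bounds = ([(np.log(yvar * 1e-4 + 1e-12), np.log(yvar * 1e4 + 1e-6))]
              + [(np.log(1e-3), np.log(1e2))] * k
              + [(np.log(1e-12), np.log(yvar + 1e-8))])
    for theta0 in starts:
        res = optimize.minimize(_neg_log_marginal, theta0, args=(x, yc),
                                method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    model = GPModel(x, y, float(np.exp(best[0])), np.exp(best[1:-1]),
                    float(np.exp(best[-1])), y_mean)
    model._factorize()
    return model


def gp_predict(model: GPModel, y_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and sd of the latent function at query points."""
    q = np.atleast_2d(np.asarray(y_points, dtype=float))
    ks = _matern52(q, model.x, model.signal_var, model.lengths)
    mu = model.y_mean + ks @ model.alpha
    v = linalg.solve_triangular(model.chol, ks.T, lower=True)
    var = model.signal_var - (v * v).sum(axis=0)
    sd = np.sqrt(np.maximum(var, 0.0))
    return mu, sd


def expected_improvement(model: GPModel, y_points: np.ndarray, best_value: float) -> np.ndarray:
    """Closed-form EI for minimization; zero wherever sigma is zero."""
    mu, sd = gp_predict(model, y_points)
    ei = np.zeros_like(mu)
    pos = sd > 1e-12
    gamma = (best_value - mu[pos]) / sd[pos]
    ei[pos] = sd[pos] * (gamma * norm.cdf(gamma) + norm.pdf(gamma))
    return np.maximum(ei, 0.0)


@dataclass
class _HistoryEntry:
    point: np.ndarray
    value: float
    incumbent: float


def optimize_ei(objective, box: SearchBox, n_init: int = 5, n_iter: int = 15,
                seed: int = 0, n_candidates: int = 256, n_refine: int = 5):
    """Full BO loop: LHS design, GP refits, multi-start EI maximization.

    Returns ``(best_point, best_value, history)`` where history is a
    list of dicts with keys point/value/incumbent, one per evaluation
    (length ``n_init + n_iter``).
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=box.dim, seed=rng.integers(2**31))
    xs = list(sampler.random(n_init))
    values, history = [], []

    def _eval(u):
        point = box.from_unit(np.asarray(u))
        val = objective(point if box.dim > 1 else float(point[0]))
        val = float(val)
        if not np.isfinite(val):
            warnings.warn("non-finite objective value; penalized", stacklevel=2)
            finite = [v for v in values if np.isfinite(v)]
            val = (max(finite) + 1.0) if finite else 1e6
        values.append(val)
        inc = min(values)
        history.append({"point": point, "value": val, "incumbent": inc})
        return val

    for u in xs:
        _eval(u)
    for it in range(n_iter):
        x_obs = np.vstack(xs)
        model = gp_fit(x_obs, np.asarray(values), seed=int(rng.integers(2**31)))
        best = min(values)
        cands = rng.random((n_candidates, box.dim))
        ei = expected_improvement(model, cands, best)
        order = np.argsort(-ei)[:n_refine]
        best_u, best_ei = cands[order[0]], ei[order[0]]
        for idx in order:
            res = optimize.minimize(
                lambda u: -expected_improvement(model, u[None, :], best)[0],
                cands[idx], method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * box.dim)
            if -res.fun > best_ei:
                best_ei, best_u = -res.fun, res.x
        xs.append(np.asarray(best_u, dtype=float))
        _eval(xs[-1])
    values_arr = np.asarray(values)
    i_best = int(values_arr.argmin())
    return history[i_best]["point"], float(values_arr[i_best]), history


class BayesianOptimizer:
    """Object wrapper holding a box and budget; ``minimize`` runs the loop."""

    def __init__(self, box: SearchBox, n_init: int = 5, n_iter: int = 15, seed: int = 0):
        self.box = box
        self.n_init = n_init
        self.n_iter = n_iter
        self.seed = seed

    def minimize(self, objective):
        best_point, best_value, history = optimize_ei(
            objective, self.box, self.n_init, self.n_iter, self.seed)
        self.best_point_ = best_point
        self.best_value_ = best_value
        self.history_ = history
        return best_point, best_value, history
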