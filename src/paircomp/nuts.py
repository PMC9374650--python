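"""No-U-Turn Hamiltonian Monte Carlo sampler.

A self-contained NUTS implementation (slice variant with doubling, as in
Hoffman & Gelman) over a caller-supplied ``logp_grad`` function:

* leapfrog integration with a diagonal or dense metric (a dense metric
  decorrelates posteriors that are only soft-identified up to a common
  shift, which is the typical geometry of ability parameters);
* dual-averaging step-size adaptation toward a target acceptance
  statistic during warmup;
* a two-phase warmup: the first three quarters run on the unit metric and
  the draws from its second half estimate the metric (regularized toward
  unity), after which the step size is re-tuned on the new metric;
* per-iteration sampler statistics: divergence flag (energy error > 1000),
  tree depth, the Hamiltonian after momentum refresh (for E-BFMI), and the
  mean acceptance statistic.

The sampler is deterministic given a ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DIVERGENCE_THRESHOLD = 1000.0  # energy error that flags a divergent transition


class Metric:
    """Kinetic-energy metric: diagonal or dense inverse mass matrix.

    ``inv_mass`` approximates the posterior covariance.  The dense variant
    decorrelates strongly coupled parameters (e.g. abilities identified
    only up to a common shift), at an O(dim^2) cost per leapfrog step.
    """

    def __init__(self, inv_mass):
        inv_mass = np.asarray(inv_mass, dtype=float)
        self.dense = inv_mass.ndim == 2
        self.inv_mass = inv_mass
        if self.dense:
            # Sigma = L L^T ; momentum ~ N(0, Sigma^-1) via L^-T xi
            self._chol = np.linalg.cholesky(inv_mass)
        else:
            self._sqrt_mass = 1.0 / np.sqrt(inv_mass)

    @classmethod
    def unit(cls, dim):
        return cls(np.ones(dim))

    def sample_momentum(self, rng):
        if self.dense:
            xi = rng.standard_normal(self.inv_mass.shape[0])
            from scipy.linalg import solve_triangular

            return solve_triangular(self._chol.T, xi, lower=False)
        return rng.standard_normal(self.inv_mass.size) * self._sqrt_mass

    def velocity(self, p):
        """M^-1 p, the position update direction."""
        if self.dense:
            return self.inv_mass @ p
        return self.inv_mass * p

    def kinetic(self, p):
        return 0.5 * float(np.dot(p, self.velocity(p)))


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_retained, dim), unconstrained scale
    divergent: np.ndarray      # (n_retained,) bool
    treedepth: np.ndarray      # (n_retained,) int
    energy: np.ndarray         # (n_retained,) Hamiltonian after refresh
    accept_stat: np.ndarray    # (n_retained,) mean leapfrog acceptance
    step_size: float
    metric: Metric


class _Tree:
    """State threaded through the recursive doubling procedure."""

    __slots__ = ("logp_grad", "eps", "metric", "logu", "h0", "rng",
                 "alpha_sum", "n_alpha", "divergent")

    def __init__(self, logp_grad, eps, metric, logu, h0, rng):
        self.logp_grad = logp_grad
        self.eps = eps
        self.metric = metric
        self.logu = logu
        self.h0 = h0
        self.rng = rng
        self.alpha_sum = 0.0
        self.n_alpha = 0
        self.divergent = False


def _leapfrog(logp_grad, x, p, grad, eps, metric):
    p = p + 0.5 * eps * grad
    x = x + eps * metric.velocity(p)
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _no_uturn(x_minus, x_plus, p_minus, p_plus, metric):
    dx = x_plus - x_minus
    return (np.dot(dx, metric.velocity(p_minus)) >= 0.0
            and np.dot(dx, metric.velocity(p_plus)) >= 0.0)


def _build_tree(tree: _Tree, x, p, grad, v, depth):
    """Returns (x-, p-, g-, x+, p+, g+, x', lp', g', n', s')."""
    if depth == 0:
        x1, p1, lp1, g1 = _leapfrog(tree.logp_grad, x, p, grad,
                                    v * tree.eps, tree.metric)
        h1 = -lp1 + tree.metric.kinetic(p1) if np.isfinite(lp1) else np.inf
        n1 = 1 if tree.logu <= -h1 else 0
        diverged = (tree.logu - DIVERGENCE_THRESHOLD) > -h1
        if diverged:
            tree.divergent = True
        tree.alpha_sum += min(1.0, math.exp(min(0.0, tree.h0 - h1)))
        tree.n_alpha += 1
        return x1, p1, g1, x1, p1, g1, x1, lp1, g1, n1, (not diverged)
    # inner subtree
    (xm, pm, gm, xp, pp, gp,
     x1, lp1, g1, n1, s1) = _build_tree(tree, x, p, grad, v, depth - 1)
    if s1:
        if v == -1:
            (xm, pm, gm, _, _, _,
             x2, lp2, g2, n2, s2) = _build_tree(tree, xm, pm, gm, v, depth - 1)
        else:
            (_, _, _, xp, pp, gp,
             x2, lp2, g2, n2, s2) = _build_tree(tree, xp, pp, gp, v, depth - 1)
        if n2 and tree.rng.uniform() < n2 / max(n1 + n2, 1):
            x1, lp1, g1 = x2, lp2, g2
        n1 += n2
        s1 = s2 and _no_uturn(xm, xp, pm, pp, tree.metric)
    return xm, pm, gm, xp, pp, gp, x1, lp1, g1, n1, s1


def _nuts_transition(logp_grad, x, lp, grad, eps, metric, rng, max_treedepth):
    p0 = metric.sample_momentum(rng)
    h0 = -lp + metric.kinetic(p0)
    logu = math.log(rng.uniform()) - h0
    tree = _Tree(logp_grad, eps, metric, logu, h0, rng)

    xm = xp = x
    pm = pp = p0
    gm = gp = grad
    x_new, lp_new, g_new = x, lp, grad
    n = 1
    depth = 0
    s = True
    while s and depth < max_treedepth:
        v = 1 if rng.uniform() < 0.5 else -1
        if v == -1:
            (xm, pm, gm, _, _, _,
             x1, lp1, g1, n1, s1) = _build_tree(tree, xm, pm, gm, v, depth)
        else:
            (_, _, _, xp, pp, gp,
             x1, lp1, g1, n1, s1) = _build_tree(tree, xp, pp, gp, v, depth)
        if s1 and n1 and rng.uniform() < n1 / n:
            x_new, lp_new, g_new = x1, lp1, g1
        n += n1
        s = s1 and _no_uturn(xm, xp, pm, pp, metric)
        depth += 1
    alpha = tree.alpha_sum / max(tree.n_alpha, 1)
    return x_new, lp_new, g_new, tree.divergent, depth, alpha, h0


def _find_reasonable_epsilon(logp_grad, x, lp, grad, metric, rng):
    eps = 1.0
    p = metric.sample_momentum(rng)
    h0 = -lp + metric.kinetic(p)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, metric)
    h1 = -lp1 + metric.kinetic(p1) if np.isfinite(lp1) else np.inf
    log_ratio = h0 - h1
    a = 1.0 if log_ratio > math.log(0.5) else -1.0
    for _ in range(64):
        if a * log_ratio <= -a * math.log(2.0):
            break
        eps *= 2.0**a
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, metric)
        h1 = -lp1 + metric.kinetic(p1) if np.isfinite(lp1) else np.inf
        log_ratio = h0 - h1
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log(step size)."""

    def __init__(self, eps0, target_accept, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target_accept
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.m = 0
        self.h_bar = 0.0
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0

    def update(self, alpha):
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - alpha)
        self.log_eps = self.mu - math.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self):
        return math.exp(self.log_eps_bar)


def _estimate_metric(window: np.ndarray, kind: str) -> Metric:
    """Regularized covariance of warmup draws, shrunk toward the unit
    metric (more shrinkage for fewer draws)."""
    n_w, dim = window.shape
    shrink = n_w / (n_w + 5.0)
    if kind == "dense":
        cov = np.cov(window, rowvar=False).reshape(dim, dim)
        reg = shrink * cov + (1.0 - shrink) * 1e-3 * np.eye(dim)
        reg += 1e-10 * np.eye(dim)
        return Metric(reg)
    var = window.var(axis=0, ddof=1)
    return Metric(np.maximum(shrink * var + (1.0 - shrink) * 1e-3, 1e-10))


def sample_chain(
    logp_grad,
    x0: np.ndarray,
    rng: np.random.Generator,
    n_iterations: int,
    warmup: int,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
    metric_kind: str = "auto",
) -> ChainResult:
    """Run one NUTS chain; retains the ``n_iterations - warmup`` final draws.

    ``metric_kind`` selects the adapted metric: "diag", "dense", or "auto"
    (dense for dimension <= 32, where the full posterior covariance is
    cheap and well estimated from warmup draws, else diagonal).
    """
    x = np.asarray(x0, dtype=float).copy()
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    dim = x.size
    if metric_kind == "auto":
        metric_kind = "dense" if dim <= 32 else "diag"
    if metric_kind not in ("diag", "dense"):
        raise ValueError("metric_kind must be 'auto', 'diag' or 'dense'")

    metric = Metric.unit(dim)
    eps = _find_reasonable_epsilon(logp_grad, x, lp, grad, metric, rng)
    da = _DualAveraging(eps, target_accept)

    metric_switch = (3 * warmup) // 4 if warmup >= 40 else warmup
    collect_from = warmup // 4
    window: list = []

    n_keep = n_iterations - warmup
    draws = np.empty((n_keep, dim))
    divergent = np.zeros(n_keep, dtype=bool)
    treedepth = np.zeros(n_keep, dtype=np.int64)
    energy = np.empty(n_keep)
    accept = np.empty(n_keep)

    for m in range(n_iterations):
        x, lp, grad, div, depth, alpha, h0 = _nuts_transition(
            logp_grad, x, lp, grad, eps, metric, rng, max_treedepth)
        if m < warmup:
            eps = da.update(alpha)
            if collect_from <= m < metric_switch:
                window.append(x.copy())
            if m == metric_switch - 1 and metric_switch < warmup \
                    and len(window) >= 10:
                metric = _estimate_metric(np.asarray(window), metric_kind)
                eps = _find_reasonable_epsilon(logp_grad, x, lp, grad,
                                               metric, rng)
                da = _DualAveraging(eps, target_accept)
            if m == warmup - 1:
                eps = da.adapted
        else:
            k = m - warmup
            draws[k] = x
            divergent[k] = div
            treedepth[k] = depth
            energy[k] = h0
            accept[k] = alpha

    return ChainResult(draws=draws, divergent=divergent, treedepth=treedepth,
                       energy=energy, accept_stat=accept, step_size=eps,
                       metric=metric)
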