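"""Hamiltonian Monte Carlo for the marginal posterior over model parameters.

The sampler works on an unconstrained vector ``z``:

* ``z[0] = log C``, ``z[1] = log r``, ``z[2] = logit rho``,
* ``z[3 : 3+n_p-1]`` and the remainder parameterize the abundance simplexes
  through a centered softmax (last logit pinned at zero).

The target is the marginal log posterior plus the log Jacobian of the
transform, so the stationary distribution on the constrained scale matches
the model exactly.  Gradients are analytic; adaptation follows the usual
recipe of dual-averaged step size (Nesterov/Hoffman-Gelman) with a diagonal
mass matrix re-estimated over doubling warmup windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["Potential", "run_chain", "constrain", "unconstrain"]

_MAX_ENERGY_ERROR = 1000.0  # divergence guard


def _softmax_padded(z: np.ndarray) -> np.ndarray:
    """Softmax of ``(z, 0)``: maps R^(n-1) to the interior of the n-simplex."""
    full = np.concatenate([z, [0.0]])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def constrain(z: np.ndarray, n_p: int, n_a: int):
    """Map an unconstrained vector to ``(C, r, rho, sigma, tau)``."""
    C = float(np.exp(z[0]))
    r = float(np.exp(z[1]))
    rho = float(expit(z[2]))
    sigma = _softmax_padded(z[3 : 3 + n_p - 1])
    tau = _softmax_padded(z[3 + n_p - 1 :])
    return C, r, rho, sigma, tau


def unconstrain(C: float, r: float, rho: float, sigma: np.ndarray, tau: np.ndarray) -> np.ndarray:
    eps = 1e-300
    z_sigma = np.log(sigma[:-1] + eps) - np.log(sigma[-1] + eps)
    z_tau = np.log(tau[:-1] + eps) - np.log(tau[-1] + eps)
    rho = min(max(rho, 1e-12), 1 - 1e-12)
    return np.concatenate(
        [[np.log(max(C, eps)), np.log(max(r, eps)), np.log(rho / (1 - rho))], z_sigma, z_tau]
    )


class Potential:
    """Log density and gradient of the transformed marginal posterior.

    Precomputes the count matrix and its margins; each call costs a handful
    of vectorized operations on ``(n_p, n_a)`` arrays.
    """

    def __init__(self, counts: np.ndarray, lambda_r: float = 0.01, c_upper: float | None = None):
        self.m = np.asarray(counts, dtype=float)
        self.n_p, self.n_a = self.m.shape
        self.m_total = float(self.m.sum())
        self.row_sums = self.m.sum(axis=1)
        self.col_sums = self.m.sum(axis=0)
        self.lambda_r = float(lambda_r)
        self.c_upper = c_upper
        self.dim = 3 + (self.n_p - 1) + (self.n_a - 1)

    def __call__(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._evaluate(z)

    def _evaluate(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        n_p, n_a = self.n_p, self.n_a
        C, r, rho, sigma, tau = constrain(z, n_p, n_a)
        if not np.isfinite(C) or (self.c_upper is not None and C > self.c_upper):
            return -np.inf, np.zeros_like(z)
        if not np.isfinite(r):
            return -np.inf, np.zeros_like(z)

        s = np.outer(sigma, tau)
        log_x = (
            self.m_total * np.log(C)
            + self.row_sums @ np.log(sigma)
            + self.col_sums @ np.log(tau)
        )
        a = np.log1p(-rho)
        b = np.log(rho) + self.m * np.log1p(r) - C * r * s
        y = np.logaddexp(a, b)
        logp = -C + np.log(self.lambda_r) - self.lambda_r * r + log_x + y.sum()
        # Jacobian of (exp, exp, logistic, softmax, softmax)
        log_jac = (
            z[0]
            + z[1]
            + np.log(rho)
            + np.log1p(-rho)
            + np.log(sigma).sum()
            + np.log(tau).sum()
        )
        logq = logp + log_jac
        if not np.isfinite(logq):
            return -np.inf, np.zeros_like(z)

        q = expit(b - a)  # P(B_ij = 1 | M, theta)
        qs = q * s
        d_C = -1.0 + self.m_total / C - r * qs.sum()
        d_r = (q * (self.m / (1.0 + r) - C * s)).sum() - self.lambda_r
        d_rho = q.sum() / rho - (1.0 - q).sum() / (1.0 - rho)
        g_sigma = self.row_sums / sigma - C * r * (q @ tau)
        g_tau = self.col_sums / tau - C * r * (q.T @ sigma)

        grad = np.empty_like(z)
        grad[0] = C * d_C + 1.0
        grad[1] = r * d_r + 1.0
        grad[2] = rho * (1.0 - rho) * d_rho + 1.0 - 2.0 * rho
        gs_dot = sigma @ g_sigma
        gt_dot = tau @ g_tau
        grad[3 : 3 + n_p - 1] = (
            sigma[:-1] * (g_sigma[:-1] - gs_dot) + 1.0 - n_p * sigma[:-1]
        )
        grad[3 + n_p - 1 :] = tau[:-1] * (g_tau[:-1] - gt_dot) + 1.0 - n_a * tau[:-1]
        if not np.isfinite(grad).all():
            return -np.inf, np.zeros_like(z)
        return float(logq), grad


def _leapfrog(potential, z, p, grad, eps, inv_mass, n_steps):
    z = z.copy()
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        z = z + eps * inv_mass * p
        logq, grad = potential(z)
        if not np.isfinite(logq):
            return z, p, logq, grad
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return z, p, logq, grad


@dataclass
class _DualAveraging:
    """Step-size adaptation targeting a fixed Metropolis acceptance statistic."""

    target: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75

    def start(self, eps0: float) -> None:
        self.mu = np.log(10.0 * eps0)
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _find_initial_step_size(potential, z, logq, grad, inv_mass, rng) -> float:
    """Crude bracketing of a step size with acceptance near one half."""
    eps = 0.1
    p = rng.standard_normal(z.size) / np.sqrt(inv_mass)
    h0 = logq - 0.5 * (p * p * inv_mass).sum()
    z1, p1, logq1, _ = _leapfrog(potential, z, p, grad, eps, inv_mass, 1)
    h1 = logq1 - 0.5 * (p1 * p1 * inv_mass).sum() if np.isfinite(logq1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        z1, p1, logq1, _ = _leapfrog(potential, z, p, grad, eps, inv_mass, 1)
        h1 = logq1 - 0.5 * (p1 * p1 * inv_mass).sum() if np.isfinite(logq1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return max(eps, 1e-8)


def run_chain(
    potential: Potential,
    z0: np.ndarray,
    rng: np.random.Generator,
    n_warmup: int,
    n_draws: int,
    target_accept: float = 0.8,
    max_leapfrog: int = 32,
):
    """Run one adaptive HMC chain; returns draws, log posteriors and diagnostics.

    The number of leapfrog steps per iteration is drawn uniformly from
    ``1..max_leapfrog`` (trajectory jittering avoids resonances of static HMC).
    """
    dim = z0.size
    z = z0.copy()
    logq, grad = potential(z)
    if not np.isfinite(logq):
        raise ValueError("non-finite log posterior at the chain's initial state")

    inv_mass = np.ones(dim)
    eps = _find_initial_step_size(potential, z, logq, grad, inv_mass, rng)
    averager = _DualAveraging(target=target_accept)
    averager.start(eps)

    # warmup layout: step-size-only head and tail around mass-matrix windows
    head = max(1, int(0.15 * n_warmup))
    tail = max(1, int(0.10 * n_warmup))
    window_start = head
    window_len = 25
    window_buf: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    lps = np.empty(n_draws)
    n_accept = 0
    n_divergent = 0

    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logq - 0.5 * (p * p * inv_mass).sum()
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        z_new, p_new, logq_new, grad_new = _leapfrog(
            potential, z, p, grad, eps, inv_mass, n_steps
        )
        if np.isfinite(logq_new):
            h1 = logq_new - 0.5 * (p_new * p_new * inv_mass).sum()
            delta = h1 - h0
        else:
            delta = -np.inf
        if delta < -_MAX_ENERGY_ERROR:
            n_divergent += 1
        accept_prob = min(1.0, float(np.exp(min(delta, 0.0))))
        if np.log(rng.random()) < delta:
            z, logq, grad = z_new, logq_new, grad_new
            if not warming:
                n_accept += 1

        if warming:
            eps = averager.update(accept_prob)
            in_window = head <= it < n_warmup - tail
            if in_window:
                window_buf.append(z.copy())
                end_of_window = (it + 1 - window_start) >= window_len
                last_window = it + 1 >= n_warmup - tail
                if end_of_window or last_window:
                    if len(window_buf) >= 10:
                        var = np.var(np.asarray(window_buf), axis=0)
                        n = len(window_buf)
                        # regularize toward unit scale as Stan does
                        inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                        inv_mass = np.maximum(inv_mass, 1e-10)
                        eps = _find_initial_step_size(potential, z, logq, grad, inv_mass, rng)
                        averager.start(eps)
                    window_buf = []
                    window_start = it + 1
                    window_len *= 2
            if it == n_warmup - 1:
                eps = averager.adapted
        else:
            k = it - n_warmup
            draws[k] = z
            lps[k] = logq

    info = {
        "step_size": float(eps),
        "inv_mass": inv_mass.copy(),
        "accept_rate": n_accept / max(n_draws, 1),
        "n_divergent": n_divergent,
    }
    return draws, lps, info
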