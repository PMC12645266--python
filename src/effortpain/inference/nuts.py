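"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained implementation of NUTS (the slice-sampling variant of
Hoffman & Gelman, 2014) with a Stan-style three-phase warmup: an initial
step-size-only buffer, a sequence of doubling covariance-estimation windows
that update the diagonal inverse mass matrix, and a terminal step-size
buffer.  Only the model's log density and gradient are required.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

__all__ = ["NutsConfig", "nuts_sample"]

_MAX_TREEDEPTH = 10
_DELTA_MAX = 1000.0  # divergence threshold on energy error


@dataclasses.dataclass
class NutsConfig:
    n_warmup: int = 1000
    n_samples: int = 1000
    target_accept: float = 0.8
    max_treedepth: int = _MAX_TREEDEPTH
    init_buffer: int = 75
    term_buffer: int = 50
    base_window: int = 25


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman, 2014)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w2 = self.count ** (-self.kappa)
        self.log_eps_bar = w2 * self.log_eps + (1.0 - w2) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _find_initial_step(logp_grad, theta, inv_mass, rng) -> float:
    """Heuristic: double/halve eps until the one-step acceptance crosses 0.5."""
    eps = 1.0
    lp, grad = logp_grad(theta)
    r = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(r**2 * inv_mass)
    _, rn, lpn, _, hn = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    if not np.isfinite(hn):
        hn = -np.inf
    direction = 1.0 if (hn - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, rn, lpn, _, hn = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        if not np.isfinite(hn):
            hn = -np.inf
        if direction * (hn - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    # overflow in a diverging trajectory just yields h = -inf, handled upstream
    with np.errstate(over="ignore", invalid="ignore"):
        r = r + 0.5 * eps * grad
        theta = theta + eps * inv_mass * r
        lp, grad = logp_grad(theta)
        r = r + 0.5 * eps * grad
        h = lp - 0.5 * np.sum(r**2 * inv_mass)
    return theta, r, lp, grad, h


class _Tree:
    __slots__ = ("theta_m", "r_m", "g_m", "theta_p", "r_p", "g_p",
                 "theta_prop", "n", "stop", "divergent", "alpha", "n_alpha")


def _build_tree(logp_grad, theta, r, grad, log_u, v, depth, eps, inv_mass, h0, rng):
    if depth == 0:
        theta1, r1, lp1, g1, h1 = _leapfrog(logp_grad, theta, r, grad, v * eps, inv_mass)
        t = _Tree()
        if not np.isfinite(h1):
            h1 = -np.inf
        t.theta_m = t.theta_p = t.theta_prop = theta1
        t.r_m = t.r_p = r1
        t.g_m = t.g_p = g1
        t.n = int(log_u <= h1 - h0)
        t.divergent = (log_u - (h1 - h0)) > _DELTA_MAX
        t.stop = t.divergent
        t.alpha = min(1.0, np.exp(min(0.0, h1 - h0)))
        t.n_alpha = 1
        return t
    t = _build_tree(logp_grad, theta, r, grad, log_u, v, depth - 1, eps, inv_mass, h0, rng)
    if not t.stop:
        if v == -1:
            t2 = _build_tree(logp_grad, t.theta_m, t.r_m, t.g_m, log_u, v,
                             depth - 1, eps, inv_mass, h0, rng)
            t.theta_m, t.r_m, t.g_m = t2.theta_m, t2.r_m, t2.g_m
        else:
            t2 = _build_tree(logp_grad, t.theta_p, t.r_p, t.g_p, log_u, v,
                             depth - 1, eps, inv_mass, h0, rng)
            t.theta_p, t.r_p, t.g_p = t2.theta_p, t2.r_p, t2.g_p
        if t2.n > 0 and rng.random() < t2.n / max(t.n + t2.n, 1):
            t.theta_prop = t2.theta_prop
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.n += t2.n
        t.divergent = t.divergent or t2.divergent
        t.stop = t2.stop or _uturn(t.theta_m, t.theta_p, t.r_m, t.r_p, inv_mass)
    return t


def _uturn(theta_m, theta_p, r_m, r_p, inv_mass):
    d = theta_p - theta_m
    return (np.dot(d, inv_mass * r_m) < 0.0) or (np.dot(d, inv_mass * r_p) < 0.0)


def _mass_windows(n_warmup: int, cfg: NutsConfig):
    """Stan-like adaptation schedule: list of (start, end) slow windows."""
    if n_warmup < cfg.init_buffer + cfg.term_buffer + cfg.base_window:
        # short warmup: single window over the middle half
        a, b = n_warmup // 4, 3 * n_warmup // 4
        return [(a, b)] if b > a + 1 else []
    windows = []
    start = cfg.init_buffer
    size = cfg.base_window
    end_slow = n_warmup - cfg.term_buffer
    while start < end_slow:
        end = min(start + size, end_slow)
        if end_slow - end < size:  # absorb the remainder into the last window
            end = end_slow
        windows.append((start, end))
        start = end
        size *= 2
    return windows


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    config: NutsConfig,
    rng: np.random.Generator,
) -> dict:
    """Run one NUTS chain; returns draws and per-draw diagnostics.

    Returns a dict with ``draws`` (n_samples x dim, post-warmup),
    ``step_size``, ``inv_mass``, ``accept_rate``, ``n_divergent`` and
    ``treedepth`` statistics.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
    da = _DualAveraging(eps, config.target_accept)
    windows = _mass_windows(config.n_warmup, config)
    win_idx = 0
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    n_total = config.n_warmup + config.n_samples
    draws = np.empty((config.n_samples, dim))
    accepts = []
    depths = []
    n_div = 0

    for it in range(n_total):
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(r0**2 * inv_mass)
        log_u = np.log(rng.random())  # slice variable: u ~ U(0, exp(h0))
        theta_m = theta_p = theta
        r_m = r_p = r0
        g_m = g_p = grad
        theta_new = theta
        n = 1
        stop = False
        divergent = False
        depth = 0
        alpha_sum, n_alpha = 0.0, 0
        while not stop and depth < config.max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                t = _build_tree(logp_grad, theta_m, r_m, g_m, log_u, v, depth,
                                eps, inv_mass, h0, rng)
                theta_m, r_m, g_m = t.theta_m, t.r_m, t.g_m
            else:
                t = _build_tree(logp_grad, theta_p, r_p, g_p, log_u, v, depth,
                                eps, inv_mass, h0, rng)
                theta_p, r_p, g_p = t.theta_p, t.r_p, t.g_p
            if not t.stop and t.n > 0 and rng.random() < min(1.0, t.n / n):
                theta_new = t.theta_prop
            n += t.n
            alpha_sum += t.alpha
            n_alpha += t.n_alpha
            divergent = divergent or t.divergent
            stop = t.stop or _uturn(theta_m, theta_p, r_m, r_p, inv_mass)
            depth += 1
        accept_stat = alpha_sum / max(n_alpha, 1)
        if not np.array_equal(theta_new, theta):
            theta = theta_new
            lp, grad = logp_grad(theta)
        depths.append(depth)

        warmup = it < config.n_warmup
        if warmup:
            eps = da.update(accept_stat)
            if win_idx < len(windows):
                a, b = windows[win_idx]
                if a <= it < b:
                    welford_n += 1
                    delta = theta - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (theta - welford_mean)
                if it == b - 1:
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        # Stan-style regularization toward unit scale
                        w = welford_n / (welford_n + 5.0)
                        inv_mass = w * var + (1.0 - w) * 1e-3
                        inv_mass = np.maximum(inv_mass, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    win_idx += 1
                    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
                    da = _DualAveraging(eps, config.target_accept)
            if it == config.n_warmup - 1:
                eps = da.adapted
        else:
            draws[it - config.n_warmup] = theta
            accepts.append(accept_stat)
            if divergent:
                n_div += 1

    return {
        "draws": draws,
        "step_size": float(eps),
        "inv_mass": inv_mass,
        "accept_rate": float(np.mean(accepts)) if accepts else float("nan"),
        "mean_treedepth": float(np.mean(depths)),
        "n_divergent": n_div,
    }
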