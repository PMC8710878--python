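"""No-U-turn sampler (NUTS) over a differentiable log density.

A self-contained Hamiltonian Monte Carlo implementation: the classic
recursive tree-doubling NUTS with slice sampling of trajectory states,
dual-averaging step-size adaptation toward a target acceptance statistic,
and windowed diagonal mass-matrix estimation during warmup (short initial
buffer, doubling estimation windows, terminal step-size buffer).

The target is supplied as a callable ``logp_grad(theta) -> (logp, grad)``
over an unconstrained parameter vector; constraint transforms and their
Jacobians are the caller's responsibility.  Everything is driven by a
``numpy.random.Generator``, so runs are exactly reproducible under a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["nuts", "NUTSStats"]

_MAX_DELTA_H = 1000.0  # divergence threshold on energy error


@dataclass
class NUTSStats:
    """Per-draw sampler diagnostics for one chain."""

    accept_prob: np.ndarray
    divergent: np.ndarray
    treedepth: np.ndarray
    energy: np.ndarray
    step_size: float


class _Tree:
    """State bundle for one subtree of the NUTS trajectory."""

    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "lp_prop", "grad_prop",
        "n", "cont", "alpha", "n_alpha", "divergent",
    )


def _kinetic(r, inv_mass):
    return 0.5 * float(np.dot(r, inv_mass * r))


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    lp1, g1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * g1
    return theta1, r1, lp1, g1


def _no_uturn(theta_plus, theta_minus, r_plus, r_minus, inv_mass):
    d = theta_plus - theta_minus
    return (
        np.dot(d, inv_mass * r_minus) >= 0
        and np.dot(d, inv_mass * r_plus) >= 0
    )


def _build_tree(
    logp_grad, theta, r, grad, logu, direction, depth, eps, joint0,
    inv_mass, rng,
):
    t = _Tree()
    if depth == 0:
        theta1, r1, lp1, g1 = _leapfrog(
            logp_grad, theta, r, grad, direction * eps, inv_mass
        )
        if np.isfinite(lp1) and np.all(np.isfinite(r1)):
            joint = lp1 - _kinetic(r1, inv_mass)
        else:
            joint = -np.inf
        if not np.isfinite(joint):
            joint = -np.inf
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.r_minus = t.r_plus = r1
        t.grad_minus = t.grad_plus = t.grad_prop = g1
        t.lp_prop = lp1
        t.n = int(logu <= joint)
        t.divergent = (logu - _MAX_DELTA_H) >= joint
        t.cont = not t.divergent
        t.alpha = min(1.0, math.exp(min(0.0, joint - joint0)))
        t.n_alpha = 1
        return t

    t = _build_tree(
        logp_grad, theta, r, grad, logu, direction, depth - 1, eps, joint0,
        inv_mass, rng,
    )
    if t.cont:
        if direction == -1:
            t2 = _build_tree(
                logp_grad, t.theta_minus, t.r_minus, t.grad_minus, logu,
                direction, depth - 1, eps, joint0, inv_mass, rng,
            )
            t.theta_minus = t2.theta_minus
            t.r_minus = t2.r_minus
            t.grad_minus = t2.grad_minus
        else:
            t2 = _build_tree(
                logp_grad, t.theta_plus, t.r_plus, t.grad_plus, logu,
                direction, depth - 1, eps, joint0, inv_mass, rng,
            )
            t.theta_plus = t2.theta_plus
            t.r_plus = t2.r_plus
            t.grad_plus = t2.grad_plus
        total = t.n + t2.n
        if t2.n > 0 and rng.random() < t2.n / total:
            t.theta_prop = t2.theta_prop
            t.lp_prop = t2.lp_prop
            t.grad_prop = t2.grad_prop
        t.n = total
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.divergent = t.divergent or t2.divergent
        t.cont = (
            t2.cont
            and not t2.divergent
            and _no_uturn(
                t.theta_plus, t.theta_minus, t.r_plus, t.r_minus, inv_mass
            )
        )
    return t


def _transition(logp_grad, theta, lp, grad, eps, inv_mass, max_treedepth, rng):
    """One NUTS draw; returns (theta, lp, grad, accept_stat, divergent, depth, energy)."""
    dim = theta.shape[0]
    r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    joint0 = lp - _kinetic(r0, inv_mass)
    logu = joint0 - rng.exponential()

    theta_minus = theta_plus = theta
    r_minus = r_plus = r0
    grad_minus = grad_plus = grad
    prop_theta, prop_lp, prop_grad = theta, lp, grad
    n = 1
    depth = 0
    alpha_sum = 0.0
    n_alpha_sum = 0
    divergent = False
    cont = True

    while cont and depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            t = _build_tree(
                logp_grad, theta_minus, r_minus, grad_minus, logu, direction,
                depth, eps, joint0, inv_mass, rng,
            )
            theta_minus, r_minus, grad_minus = t.theta_minus, t.r_minus, t.grad_minus
        else:
            t = _build_tree(
                logp_grad, theta_plus, r_plus, grad_plus, logu, direction,
                depth, eps, joint0, inv_mass, rng,
            )
            theta_plus, r_plus, grad_plus = t.theta_plus, t.r_plus, t.grad_plus

        alpha_sum += t.alpha
        n_alpha_sum += t.n_alpha
        divergent = divergent or t.divergent
        if t.cont and t.n > 0 and rng.random() < min(1.0, t.n / n):
            prop_theta, prop_lp, prop_grad = t.theta_prop, t.lp_prop, t.grad_prop
        n += t.n
        cont = t.cont and _no_uturn(
            theta_plus, theta_minus, r_plus, r_minus, inv_mass
        )
        depth += 1

    accept = alpha_sum / max(n_alpha_sum, 1)
    energy = -joint0
    return prop_theta, prop_lp, prop_grad, accept, divergent, depth, energy


def _find_reasonable_epsilon(logp_grad, theta, lp, grad, inv_mass, rng):
    eps = 1.0
    dim = theta.shape[0]
    r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    joint0 = lp - _kinetic(r0, inv_mass)
    _, r1, lp1, _ = _leapfrog(logp_grad, theta, r0, grad, eps, inv_mass)
    joint1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (joint1 - joint0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, lp1, _ = _leapfrog(logp_grad, theta, r0, grad, eps, inv_mass)
        joint1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
        if direction * (joint1 - joint0) < direction * math.log(0.5):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size (gamma=0.05, t0=10, kappa=0.75)."""

    def __init__(self, eps0, target):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept):
        self.count += 1
        m = self.count
        w = 1.0 / (m + 10.0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept)
        self.log_eps = self.mu - math.sqrt(m) / 0.05 * self.h_bar
        step = m**-0.75
        self.log_eps_bar = step * self.log_eps + (1 - step) * self.log_eps_bar

    @property
    def eps(self):
        return math.exp(self.log_eps)

    @property
    def eps_final(self):
        return math.exp(self.log_eps_bar)


def _adaptation_windows(n_warmup):
    """Stan-style (init_buffer, mass windows, term_buffer) boundaries."""
    if n_warmup < 40:
        return []  # too short for mass adaptation
    init = max(1, int(round(n_warmup * 0.075)))
    term = max(1, int(round(n_warmup * 0.10)))
    if n_warmup >= 150:
        init, term = 75, 50
    boundaries = []
    pos = init
    size = 25 if n_warmup >= 150 else max(5, (n_warmup - init - term) // 4)
    while pos + size < n_warmup - term:
        next_pos = pos + size
        # merge the final window if doubling again would overshoot
        if next_pos + 2 * size >= n_warmup - term:
            next_pos = n_warmup - term
        boundaries.append((pos, next_pos))
        pos = next_pos
        size *= 2
    if not boundaries:
        boundaries.append((init, n_warmup - term))
    return boundaries


def nuts(
    logp_grad,
    theta0: np.ndarray,
    *,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    adapt_mass: bool = True,
):
    """Run one NUTS chain.

    Returns ``(draws, stats)`` with ``draws`` of shape ``(n_draws, dim)``
    and ``stats`` a :class:`NUTSStats` (post-warmup diagnostics only).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    dim = theta.shape[0]
    inv_mass = np.ones(dim)
    eps = _find_reasonable_epsilon(logp_grad, theta, lp, grad, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)

    windows = _adaptation_windows(n_warmup) if adapt_mass else []
    window_iter = iter(windows)
    window = next(window_iter, None)
    buffer: list[np.ndarray] = []

    for i in range(n_warmup):
        theta, lp, grad, accept, _, _, _ = _transition(
            logp_grad, theta, lp, grad, da.eps, inv_mass, max_treedepth, rng
        )
        da.update(accept)
        if window is not None and window[0] <= i < window[1]:
            buffer.append(theta)
        if window is not None and i == window[1] - 1:
            if len(buffer) >= 5:
                var = np.var(np.asarray(buffer), axis=0, ddof=1)
                n = len(buffer)
                w = n / (n + 5.0)
                inv_mass = w * var + (1 - w) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-10)
                eps = _find_reasonable_epsilon(
                    logp_grad, theta, lp, grad, inv_mass, rng
                )
                da = _DualAveraging(eps, target_accept)
            buffer = []
            window = next(window_iter, None)

    eps = da.eps_final if n_warmup > 0 else da.eps

    draws = np.empty((n_draws, dim))
    accept_prob = np.empty(n_draws)
    divergent = np.zeros(n_draws, dtype=bool)
    treedepth = np.zeros(n_draws, dtype=int)
    energy = np.empty(n_draws)
    for i in range(n_draws):
        theta, lp, grad, accept, div, depth, en = _transition(
            logp_grad, theta, lp, grad, eps, inv_mass, max_treedepth, rng
        )
        draws[i] = theta
        accept_prob[i] = accept
        divergent[i] = div
        treedepth[i] = depth
        energy[i] = en

    stats = NUTSStats(
        accept_prob=accept_prob,
        divergent=divergent,
        treedepth=treedepth,
        energy=energy,
        step_size=eps,
    )
    return draws, stats
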