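"""No-U-Turn Hamiltonian Monte Carlo with warmup adaptation.

A self-contained NUTS implementation over a user-supplied log-density and
gradient: multinomial trajectory sampling, dual-averaging step-size
adaptation toward a target acceptance statistic, and windowed diagonal
mass-matrix estimation during warmup (initial step-size buffer, doubling
variance-estimation windows, terminal step-size buffer).  Deterministic
given the seed.

The model modules pose unconstrained parameterizations (log-transformed
scales with Jacobian terms, non-centered random intercepts), so no
constraint handling is needed here.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "sample_nuts", "sample_chains"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclasses.dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim)
    step_size: float
    mean_accept: float
    n_divergent: int
    mean_treedepth: float


@dataclasses.dataclass
class _State:
    x: np.ndarray
    p: np.ndarray
    grad: np.ndarray
    lp: float


def _leapfrog(logp_grad, state: _State, eps: float, inv_mass) -> _State:
    p = state.p + 0.5 * eps * state.grad
    x = state.x + eps * inv_mass * p
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return _State(x=x, p=p, grad=grad, lp=lp)


def _hamiltonian(state: _State, inv_mass) -> float:
    # overflow in the kinetic term (huge trial step sizes) maps to -inf
    with np.errstate(over="ignore", invalid="ignore"):
        h = state.lp - 0.5 * float(np.sum(state.p * state.p * inv_mass))
    return h if np.isfinite(h) else -np.inf


def _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng) -> float:
    """Heuristic doubling/halving to land near 50% acceptance."""
    eps = 1.0
    p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    start = _State(x=x, p=p, grad=grad, lp=lp)
    h0 = _hamiltonian(start, inv_mass)
    h1 = _hamiltonian(_leapfrog(logp_grad, start, eps, inv_mass), inv_mass)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        h1 = _hamiltonian(_leapfrog(logp_grad, start, eps, inv_mass), inv_mass)
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return eps


def _build_tree(logp_grad, state: _State, direction, depth, eps, inv_mass, h0, rng):
    """Doubling recursion.

    Returns (left_edge, right_edge, proposal, log_weight, momentum_sum,
    valid, accept_sum, accept_count, diverged); the proposal is drawn
    multinomially (weight exp(H - H0)) from the subtree's leaves, and the
    U-turn criterion compares the momentum sum against both edge momenta.
    """
    if depth == 0:
        leaf = _leapfrog(logp_grad, state, direction * eps, inv_mass)
        delta_h = _hamiltonian(leaf, inv_mass) - h0
        diverged = delta_h < -_MAX_DELTA_H
        alpha = min(1.0, float(np.exp(min(delta_h, 0.0))))
        return (
            leaf, leaf, leaf,
            delta_h, leaf.p.copy(), not diverged, alpha, 1, diverged,
        )

    left, right, prop, log_w, sum_p, ok, a_sum, a_n, div = _build_tree(
        logp_grad, state, direction, depth - 1, eps, inv_mass, h0, rng
    )
    if not ok:
        return left, right, prop, log_w, sum_p, False, a_sum, a_n, div
    inner = right if direction > 0 else left
    left2, right2, prop2, log_w2, sum_p2, ok2, a_sum2, a_n2, div2 = _build_tree(
        logp_grad, inner, direction, depth - 1, eps, inv_mass, h0, rng
    )
    if direction > 0:
        right = right2
    else:
        left = left2
    a_sum += a_sum2
    a_n += a_n2
    if not ok2:
        return left, right, prop, log_w, sum_p, False, a_sum, a_n, div2
    log_w_all = np.logaddexp(log_w, log_w2)
    if np.log(rng.random() + 1e-300) < log_w2 - log_w_all:
        prop = prop2
    sum_p = sum_p + sum_p2
    ok = (
        float(np.sum(sum_p * inv_mass * left.p)) > 0
        and float(np.sum(sum_p * inv_mass * right.p)) > 0
    )
    return left, right, prop, log_w_all, sum_p, ok, a_sum, a_n, False


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    init_inv_mass: np.ndarray | None = None,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws only.

    ``init_inv_mass`` seeds the diagonal inverse mass (per-coordinate
    posterior-variance guess, e.g. inverse Fisher information); warmup
    re-estimates it from the chain.
    """
    x = np.asarray(x0, float).copy()
    dim = x.size
    inv_mass = (
        np.ones(dim) if init_inv_mass is None else np.asarray(init_inv_mass, float)
    )
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = np.log(eps), 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # mass-adaptation window boundaries within warmup
    if n_warmup >= 120:
        first = max(int(0.15 * n_warmup), 20)
        last = max(int(0.10 * n_warmup), 20)
        boundaries = []
        size = max(25, (n_warmup - first - last) // 7)
        pos = first
        while pos + size < n_warmup - last:
            pos += size
            boundaries.append(pos)
            size *= 2
        boundaries.append(n_warmup - last)
    else:
        first = min(n_warmup, max(10, n_warmup // 3))
        boundaries = [max(n_warmup - 10, first)] if n_warmup > first + 10 else []
    window_start = first
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    accept_sum = 0.0
    n_div = 0
    depth_sum = 0

    for it in range(n_warmup + n_draws):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        state = _State(x=x, p=p0, grad=grad, lp=lp)
        h0 = _hamiltonian(state, inv_mass)
        left = right = state
        prop = state
        log_sum_w = 0.0  # weight of the initial point
        sum_p = p0.copy()
        alpha_sum, alpha_n = 0.0, 0
        depth = 0

        while depth < max_treedepth:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            edge = right if direction > 0 else left
            l2, r2, prop_sub, log_w_sub, sum_p_sub, ok, a_sum, a_n, div = _build_tree(
                logp_grad, edge, direction, depth, eps, inv_mass, h0, rng
            )
            alpha_sum += a_sum
            alpha_n += a_n
            n_div += int(div and it >= n_warmup)
            if not ok:
                break
            if direction > 0:
                right = r2
            else:
                left = l2
            if np.log(rng.random() + 1e-300) < log_w_sub - log_sum_w:
                prop = prop_sub
            log_sum_w = np.logaddexp(log_sum_w, log_w_sub)
            sum_p += sum_p_sub
            depth += 1
            if (
                float(np.sum(sum_p * inv_mass * left.p)) <= 0
                or float(np.sum(sum_p * inv_mass * right.p)) <= 0
            ):
                break

        x, lp, grad = prop.x, prop.lp, prop.grad
        depth_sum += depth
        accept_stat = alpha_sum / max(alpha_n, 1)

        if it < n_warmup:
            da_count += 1
            h_bar = (1 - 1 / (da_count + t0)) * h_bar + (
                target_accept - accept_stat
            ) / (da_count + t0)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))

            if it >= window_start:
                welford_n += 1
                delta = x - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (x - welford_mean)
            if boundaries and it + 1 == boundaries[0]:
                boundaries.pop(0)
                if welford_n > 4:
                    var = welford_m2 / (welford_n - 1)
                    inv_mass = var * welford_n / (welford_n + 5.0) + 1e-3 * (
                        5.0 / (welford_n + 5.0)
                    )
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = np.log(eps), 0.0, 0
                window_start = it + 1
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x
            accept_sum += accept_stat

    return NutsResult(
        draws=draws,
        step_size=eps,
        mean_accept=accept_sum / max(n_draws, 1),
        n_divergent=n_div,
        mean_treedepth=depth_sum / (n_warmup + n_draws),
    )


def sample_chains(
    logp_grad,
    init: np.ndarray | Callable[[np.random.Generator], np.ndarray],
    dim: int,
    chains: int,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    jitter: float = 0.5,
    init_inv_mass: np.ndarray | None = None,
) -> tuple[np.ndarray, list[NutsResult]]:
    """Run ``chains`` independent NUTS chains (sequentially).

    Returns draws of shape (chains, n_draws, dim) and per-chain stats.
    ``init`` is either a base point that gets uniform jitter per chain or a
    callable producing a chain-specific start.
    """
    streams = np.random.SeedSequence(seed).spawn(chains)
    all_draws = np.empty((chains, n_draws, dim))
    results = []
    for c in range(chains):
        rng = np.random.default_rng(streams[c])
        if callable(init):
            x0 = np.asarray(init(rng), float)
        else:
            x0 = np.asarray(init, float) + rng.uniform(-jitter, jitter, dim)
        res = sample_nuts(
            logp_grad,
            x0,
            n_warmup,
            n_draws,
            rng,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
            init_inv_mass=init_inv_mass,
        )
        all_draws[c] = res.draws
        results.append(res)
    return all_draws, results
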