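"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC backend for the hierarchical models.
The target is supplied as a callback ``logp_grad(theta) -> (logp, grad)``
on an unconstrained parameter vector; models handle their own constraining
transforms (log for scales, ordered via log-increments for cutpoints) and
include the Jacobian terms in ``logp``.

Warm-up follows the usual three-phase schedule: an initial step-size-only
phase, a sequence of doubling windows that estimate a diagonal mass matrix
from the warm-up draws, and a final step-size-only phase.  Post-warm-up
draws are returned per chain so split-R-hat and effective sample size can
be computed downstream.  Sampling is fully deterministic given the seed:
chains draw from independent streams spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["McmcConfig", "SampleResult", "nuts_sample"]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log density


@dataclass
class McmcConfig:
    """MCMC run configuration.

    ``iterations`` counts all iterations per chain; the first
    ``warmup_fraction`` of them are warm-up and discarded.  The default
    4 chains x 5,000 iterations with half warm-up retains 10,000 draws.
    """

    chains: int = 4
    iterations: int = 5000
    warmup_fraction: float = 0.5
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ConfigurationError("chains must be >= 1")
        if self.iterations < 2 or self.iterations % 2:
            raise ConfigurationError("iterations must be a positive even number")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ConfigurationError("warmup_fraction must be in (0, 1)")
        if not 0.0 < self.target_accept < 1.0:
            raise ConfigurationError("target_accept must be in (0, 1)")

    @property
    def n_warmup(self) -> int:
        return int(round(self.iterations * self.warmup_fraction))

    @property
    def n_kept(self) -> int:
        return self.iterations - self.n_warmup

    @property
    def n_draws(self) -> int:
        return self.chains * self.n_kept


@dataclass
class SampleResult:
    """Post-warm-up draws (chains, kept, dim) plus sampler statistics."""

    draws: np.ndarray
    step_size: np.ndarray  # final adapted step size per chain
    divergences: int
    mean_accept: float

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def _find_reasonable_epsilon(logp_grad, theta, logp, grad, inv_mass, rng) -> float:
    eps = 1.0
    r = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
    joint0 = logp - 0.5 * np.dot(r * r, inv_mass)
    _, _, _, logp1, r1 = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    joint1 = logp1 - 0.5 * np.dot(r1 * r1, inv_mass)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, _, _, logp1, r1 = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        joint1 = logp1 - 0.5 * np.dot(r1 * r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, grad1, None, logp1, r1


class _Tree:
    """Recursive NUTS tree builder (slice variant) for one iteration."""

    __slots__ = ("f", "eps", "inv_mass", "rng", "log_u", "joint0", "alpha", "n_alpha", "divergent")

    def __init__(self, f, eps, inv_mass, rng, log_u, joint0):
        self.f = f
        self.eps = eps
        self.inv_mass = inv_mass
        self.rng = rng
        self.log_u = log_u
        self.joint0 = joint0
        self.alpha = 0.0
        self.n_alpha = 0
        self.divergent = False

    def build(self, theta, r, grad, direction, depth):
        if depth == 0:
            theta1, grad1, _, logp1, r1 = _leapfrog(
                self.f, theta, r, grad, direction * self.eps, self.inv_mass
            )
            joint = logp1 - 0.5 * np.dot(r1 * r1, self.inv_mass)
            if not np.isfinite(joint):
                joint = -np.inf
            n_good = int(self.log_u <= joint)
            keep_going = self.log_u < joint + _DELTA_MAX
            if not keep_going:
                self.divergent = True
            self.alpha += min(1.0, np.exp(min(0.0, joint - self.joint0)))
            self.n_alpha += 1
            return (theta1, r1, grad1, theta1, r1, grad1, theta1, grad1, logp1, n_good, keep_going)
        # build left and right subtrees
        (tm, rm, gm, tp, rp, gp, prop, gprop, lprop, n1, going) = self.build(
            theta, r, grad, direction, depth - 1
        )
        if going:
            if direction == -1:
                (tm, rm, gm, _, _, _, prop2, gprop2, lprop2, n2, going2) = self.build(
                    tm, rm, gm, direction, depth - 1
                )
            else:
                (_, _, _, tp, rp, gp, prop2, gprop2, lprop2, n2, going2) = self.build(
                    tp, rp, gp, direction, depth - 1
                )
            if n1 + n2 > 0 and self.rng.random() < n2 / (n1 + n2):
                prop, gprop, lprop = prop2, gprop2, lprop2
            dtheta = tp - tm
            going = (
                going2
                and np.dot(dtheta, self.inv_mass * rm) >= 0.0
                and np.dot(dtheta, self.inv_mass * rp) >= 0.0
            )
            n1 += n2
        return (tm, rm, gm, tp, rp, gp, prop, gprop, lprop, n1, going)


def _adaptation_windows(n_warmup: int) -> tuple[int, int]:
    """(initial step-size-only phase, terminal step-size-only phase)."""
    init = max(1, int(0.15 * n_warmup))
    term = max(1, int(0.10 * n_warmup))
    return init, term


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    dim: int,
    config: McmcConfig,
    initial: np.ndarray | None = None,
) -> SampleResult:
    """Run NUTS chains on an unconstrained log density.

    ``initial`` may be a single point (jittered per chain) or one point per
    chain, shape (chains, dim).
    """
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.chains)
    n_warmup, n_kept = config.n_warmup, config.n_kept
    draws = np.empty((config.chains, n_kept, dim))
    step_sizes = np.empty(config.chains)
    divergences = 0
    accept_sum, accept_n = 0.0, 0

    # divergent trajectories can overflow the kinetic term; they are caught
    # by the finite-joint check, so silence the intermediate warnings
    errstate = np.errstate(over="ignore", invalid="ignore")
    errstate.__enter__()
    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        if initial is None:
            theta = 0.1 * rng.standard_normal(dim)
        elif np.ndim(initial) == 2:
            theta = np.array(initial[c], dtype=float)
        else:
            theta = np.asarray(initial, dtype=float) + 0.01 * rng.standard_normal(dim)
        logp, grad = logp_grad(theta)
        if not np.isfinite(logp):
            raise ValueError("initial point has non-finite log density")

        inv_mass = np.ones(dim)
        eps = _find_reasonable_epsilon(logp_grad, theta, logp, grad, inv_mass, rng)
        mu = np.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        da_count = 0

        init_phase, term_phase = _adaptation_windows(n_warmup)
        window_end = min(init_phase + max(25, init_phase), n_warmup - term_phase)
        welford_n = 0
        welford_mean = np.zeros(dim)
        welford_m2 = np.zeros(dim)

        for it in range(config.iterations):
            r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
            joint0 = logp - 0.5 * np.dot(r0 * r0, inv_mass)
            log_u = joint0 + np.log(rng.random())
            tree = _Tree(logp_grad, eps, inv_mass, rng, log_u, joint0)
            tm = tp = theta
            rm = rp = r0
            gm = gp = grad
            proposal, gprop, lprop = theta, grad, logp
            n_states, going, depth = 1, True, 0
            while going and depth < config.max_treedepth:
                direction = -1 if rng.random() < 0.5 else 1
                if direction == -1:
                    (tm, rm, gm, _, _, _, prop2, gprop2, lprop2, n2, going2) = tree.build(
                        tm, rm, gm, direction, depth
                    )
                else:
                    (_, _, _, tp, rp, gp, prop2, gprop2, lprop2, n2, going2) = tree.build(
                        tp, rp, gp, direction, depth
                    )
                if going2 and n2 > 0 and rng.random() < min(1.0, n2 / n_states):
                    proposal, gprop, lprop = prop2, gprop2, lprop2
                n_states += n2
                dtheta = tp - tm
                going = (
                    going2
                    and np.dot(dtheta, inv_mass * rm) >= 0.0
                    and np.dot(dtheta, inv_mass * rp) >= 0.0
                )
                depth += 1
            theta, grad, logp = proposal, gprop, lprop
            accept_stat = tree.alpha / max(tree.n_alpha, 1)

            if it < n_warmup:
                # dual averaging
                da_count += 1
                frac = 1.0 / (da_count + t0)
                h_bar = (1.0 - frac) * h_bar + frac * (config.target_accept - accept_stat)
                log_eps = mu - np.sqrt(da_count) / gamma * h_bar
                weight = da_count**-kappa
                log_eps_bar = weight * log_eps + (1.0 - weight) * log_eps_bar
                eps = np.exp(log_eps)
                # mass-matrix accumulation inside the adaptation windows
                if init_phase <= it < n_warmup - term_phase:
                    welford_n += 1
                    delta = theta - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (theta - welford_mean)
                    if it + 1 == window_end:
                        if welford_n > 1:
                            var = welford_m2 / (welford_n - 1)
                            inv_mass = (
                                welford_n / (welford_n + 5.0) * var
                                + 1e-3 * 5.0 / (welford_n + 5.0)
                            )
                        welford_n = 0
                        welford_mean[:] = 0.0
                        welford_m2[:] = 0.0
                        eps = _find_reasonable_epsilon(logp_grad, theta, logp, grad, inv_mass, rng)
                        mu = np.log(10.0 * eps)
                        log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
                        remaining = (n_warmup - term_phase) - (it + 1)
                        width = window_end - init_phase
                        next_width = 2 * width
                        if remaining < 2 * next_width:
                            next_width = remaining
                        window_end = it + 1 + next_width
                if it + 1 == n_warmup:
                    eps = np.exp(log_eps_bar)
            else:
                draws[c, it - n_warmup] = theta
                accept_sum += accept_stat
                accept_n += 1
                if tree.divergent:
                    divergences += 1
        step_sizes[c] = eps
    errstate.__exit__(None, None, None)

    return SampleResult(
        draws=draws,
        step_size=step_sizes,
        divergences=divergences,
        mean_accept=accept_sum / max(accept_n, 1),
    )
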