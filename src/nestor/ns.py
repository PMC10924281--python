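"""The nested-sampling loop: live points, shrinkage, evidence, convergence.

Nested sampling turns the evidence integral Z = ∫ L(θ) π(θ) dθ into a
one-dimensional integral over prior mass X(L) — the proportion of the
prior with likelihood above L.  N "live points" drawn from the prior are
iteratively tightened: the worst is recorded as a "dead point", the
prior mass shrinks by the deterministic factor exp(−1/N), and the dead
point's likelihood times the shrinkage width is accumulated into Z.
A run stops when constrained sampling keeps failing, when the likelihood
plateaus (growth slower than shrinkage), or at an iteration cap; the
mass still held by the live points is added as a remainder term.

The loop is agnostic to the model: a :class:`StructuralProblem` plugs in
bead models scored by the repartitioned restraints, while a
:class:`ToyProblem` wraps any ``(sample_prior, log_likelihood)`` pair so
closed-form problems can exercise the identical code path.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .representation import BeadModel, count_free_parameters, initialize_coordinates
from .restraints import RepartitionedScore
from .sampler import (
    ConstrainedSamplingFailure,
    MoveSet,
    mcmc_from_modified_prior,
    sample_constrained,
)

__all__ = [
    "prior_mass",
    "check_plateau",
    "shrinkage_log_weights",
    "NSRunResult",
    "ToyProblem",
    "StructuralProblem",
    "run_nested_sampling",
    "gaussian_toy_problem",
    "NSInitializationError",
]


class NSInitializationError(RuntimeError):
    """No finite-likelihood starting point found — the run should be relaunched."""


def prior_mass(i: int, n_live: int) -> float:
    """Expected prior mass after ``i`` shrinkages: X_i = exp(−i/N)."""
    if n_live < 1:
        raise ValueError("need at least one live point")
    if i < 0:
        raise ValueError("iteration must be non-negative")
    return math.exp(-i / n_live)


def check_plateau(
    logL_next: float, logL_curr: float, i: int, n_live: int
) -> bool:
    """Likelihood-plateau test between consecutive dead points.

    True iff L_{i+1}/L_i < X_i/X_{i+1}, i.e. the likelihood grows slower
    than the prior mass shrinks:
    logL_next − logL_curr < log X_i − log X_{i+1} = 1/N (strict).
    """
    shrink = math.log(prior_mass(i, n_live)) - math.log(prior_mass(i + 1, n_live))
    return (logL_next - logL_curr) < shrink


def shrinkage_log_weights(
    n_dead: int, n_live: int, rule: str = "trapezoid"
) -> tuple[np.ndarray, float]:
    """Log quadrature weights log ΔX_i for the dead points, plus log X_final.

    ``rectangle``: ΔX_i = X_{i−1} − X_i, X_final = X_k.
    ``trapezoid``: interior ΔX_i = ½(X_{i−1} − X_{i+1}); the first weight
    runs from X=1 to the first midpoint and the remainder mass is the
    last midpoint, so the weights plus X_final sum to exactly one for
    any iteration count.

    Everything is evaluated in log space so deep runs do not underflow.
    """
    if rule not in ("rectangle", "trapezoid"):
        raise ValueError(f"unknown integration rule {rule!r}")
    n, k = n_live, n_dead
    if k == 0:
        return np.zeros(0), 0.0
    i = np.arange(1, k + 1, dtype=float)
    if rule == "rectangle":
        # log(X_{i-1} - X_i) = -(i-1)/N + log(1 - e^{-1/N})
        log_w = -(i - 1.0) / n + math.log1p(-math.exp(-1.0 / n))
        log_x_final = -k / n
    else:
        # interior: log(0.5 * e^{-(i-1)/N} * (1 - e^{-2/N}))
        log_w = -(i - 1.0) / n + math.log1p(-math.exp(-2.0 / n)) - math.log(2.0)
        # first weight spans [midpoint(X_1, X_2), 1]
        log_w[0] = math.log1p(
            -0.5 * (math.exp(-1.0 / n) + math.exp(-2.0 / n))
        )
        log_x_final = float(
            np.logaddexp(-k / n, -(k + 1.0) / n) - math.log(2.0)
        )
    return log_w, log_x_final


@dataclass
class NSRunResult:
    """Outcome of one nested-sampling run."""

    log_Z: float
    termination: str  # failure_limit | plateau_limit | max_iterations
    iterations: int
    per_step_time: float | None  # seconds per MCMC step; None for toy problems
    nestor_process_time: float  # wall seconds for the whole run
    dead_log_likelihoods: np.ndarray
    dead_log_X: np.ndarray
    live_log_likelihoods: np.ndarray
    n_live: int
    integration: str = "trapezoid"
    live_states: list | None = None  # final live-point states (the surviving ensemble)

    @property
    def log_Z_trace(self) -> np.ndarray:
        """Running log-evidence after each dead point (remainder excluded)."""
        log_w, _ = shrinkage_log_weights(
            len(self.dead_log_likelihoods), self.n_live, self.integration
        )
        if len(log_w) == 0:
            return np.zeros(0)
        return np.logaddexp.accumulate(self.dead_log_likelihoods + log_w)


class ToyProblem:
    """Adapter exposing any prior/likelihood pair to the NS loop.

    ``sample_prior(rng)`` must return an exact prior draw; constrained
    sampling is done by batched rejection, mirroring the batch/failure
    semantics of the structural sampler.
    """

    def __init__(
        self,
        sample_prior: Callable[[np.random.Generator], object],
        log_likelihood: Callable[[object], float],
        batch_size: int = 50,
    ) -> None:
        self.sample_prior = sample_prior
        self.log_likelihood = log_likelihood
        self.batch_size = batch_size
        self.per_step_times: list[float] = []

    def sample_initial(self, rng: np.random.Generator):
        x = self.sample_prior(rng)
        return x, float(self.log_likelihood(x))

    def sample_constrained(self, live, threshold, max_failures, rng):
        for _ in range(max_failures):
            for _ in range(self.batch_size):
                x = self.sample_prior(rng)
                ll = float(self.log_likelihood(x))
                if ll >= threshold:
                    return x, ll
        return None


class StructuralProblem:
    """Bead-model sampling target for the NS loop.

    Live points are coordinate snapshots of ``template``; the modified
    prior and likelihood come from the repartitioned scoring function,
    and replacements are drawn by replica-exchange MCMC started from a
    random live point (a fresh segment with half-batch burn-in, so
    successive replacements are approximately independent).
    """

    def __init__(
        self,
        template: BeadModel,
        score: RepartitionedScore,
        moveset: MoveSet | None = None,
        mcmc_steps: int = 50,
        swap_interval: int = 10,
        thin_interval: int = 10,
        init_attempts: int = 10,
        reference=None,
    ) -> None:
        self.template = template
        self.score = score
        self.moveset = moveset or MoveSet()
        self.mcmc_steps = mcmc_steps
        self.swap_interval = swap_interval
        self.thin_interval = thin_interval
        self.init_attempts = init_attempts
        self.reference = reference
        self.per_step_times: list[float] = []

    @property
    def n_free_parameters(self) -> int:
        return count_free_parameters(self.template)

    def sample_initial(self, rng: np.random.Generator):
        for _ in range(self.init_attempts):
            start = initialize_coordinates(
                self.template,
                rng,
                reference=self.reference,
                box_halfside=self.score.params.box_halfside,
            )
            if not np.isfinite(self.score.log_prior(start.coords)):
                continue
            batch = mcmc_from_modified_prior(
                start,
                self.score,
                self.moveset,
                self.mcmc_steps,
                rng,
                swap_interval=self.swap_interval,
                thin_interval=self.thin_interval,
            )
            self.per_step_times.append(batch.per_step_time)
            ll = batch.log_likelihoods[-1]
            if np.isfinite(ll):
                return batch.models[-1], float(ll)
        raise NSInitializationError(
            "no finite-likelihood starting model found; relaunch the run"
        )

    def sample_constrained(self, live, threshold, max_failures, rng):
        def provider(r: np.random.Generator) -> BeadModel:
            pick = live[r.integers(len(live))]
            return self.template.with_coords(np.array(pick))

        res = sample_constrained(
            provider,
            threshold,
            self.score,
            self.moveset,
            batch_size=self.mcmc_steps,
            max_failures=max_failures,
            rng=rng,
            swap_interval=self.swap_interval,
            thin_interval=self.thin_interval,
        )
        if isinstance(res, ConstrainedSamplingFailure):
            return None
        coords, ll, per_step, _ = res
        self.per_step_times.append(per_step)
        return coords, float(ll)


def run_nested_sampling(
    problem,
    n_live: int = 50,
    max_failures: int = 4,
    max_plateau: int = 20,
    max_iterations: int = 10_000,
    rng: np.random.Generator | int | None = None,
    integration: str = "trapezoid",
) -> NSRunResult:
    """One nested-sampling run: estimate log Z for ``problem``.

    Initialises ``n_live`` points from the (modified) prior, then
    repeatedly replaces the worst live point with a constrained draw,
    accumulating evidence with the deterministic shrinkage
    X_i = exp(−i/N).  Terminates on ``max_failures`` consecutive empty
    sampling batches, on ``max_plateau`` consecutive likelihood-plateau
    iterations, or at ``max_iterations``; the live-point remainder
    Σ L_live / N · X_final is then added to Z.
    """
    if n_live < 1:
        raise ValueError("need at least one live point")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_free = getattr(problem, "n_free_parameters", None)
    if n_free is not None and n_live < n_free:
        warnings.warn(
            f"n_live={n_live} is below the free-parameter bound "
            f"3n+6m={n_free}; evidence errors may be large",
            stacklevel=2,
        )

    t0 = time.monotonic()
    live_states: list = []
    live_logL: list[float] = []
    for _ in range(n_live):
        state, ll = problem.sample_initial(rng)
        live_states.append(state)
        live_logL.append(ll)
    live_logL_arr = np.array(live_logL)

    dead_logL: list[float] = []
    plateau_streak = 0
    termination = "max_iterations"
    prev_dead: float | None = None

    for it in range(1, max_iterations + 1):
        worst = int(np.argmin(live_logL_arr))
        threshold = float(live_logL_arr[worst])
        repl = problem.sample_constrained(live_states, threshold, max_failures, rng)
        if repl is None:
            termination = "failure_limit"
            break
        dead_logL.append(threshold)
        if prev_dead is not None and check_plateau(
            threshold, prev_dead, len(dead_logL) - 1, n_live
        ):
            plateau_streak += 1
        else:
            plateau_streak = 0
        prev_dead = threshold
        live_states[worst], live_logL_arr[worst] = repl
        if plateau_streak >= max_plateau:
            termination = "plateau_limit"
            break

    k = len(dead_logL)
    dead = np.array(dead_logL)
    log_w, log_x_final = shrinkage_log_weights(k, n_live, integration)
    remainder = logsumexp(live_logL_arr) - math.log(n_live) + log_x_final
    terms = np.concatenate([dead + log_w, [remainder]])
    log_Z = float(logsumexp(terms))

    times = getattr(problem, "per_step_times", None)
    per_step = float(np.mean(times)) if times else None
    return NSRunResult(
        log_Z=log_Z,
        termination=termination,
        iterations=k,
        per_step_time=per_step,
        nestor_process_time=time.monotonic() - t0,
        dead_log_likelihoods=dead,
        dead_log_X=-np.arange(1, k + 1) / n_live,
        live_log_likelihoods=np.array(live_logL_arr),
        n_live=n_live,
        integration=integration,
        live_states=live_states,
    )


def gaussian_toy_problem(
    low: float = -5.0, high: float = 5.0, batch_size: int = 50
) -> tuple[ToyProblem, float]:
    """Uniform prior on [low, high] with a standard-normal likelihood.

    Returns the problem and the exact log-evidence
    log Z = log[(Φ(high) − Φ(low)) / (high − low)].
    """
    width = high - low

    def sample_prior(rng: np.random.Generator) -> float:
        return float(rng.uniform(low, high))

    def log_like(x: float) -> float:
        return -0.5 * x * x - 0.5 * math.log(2.0 * math.pi)

    analytic = math.log((norm.cdf(high) - norm.cdf(low)) / width)
    return ToyProblem(sample_prior, log_like, batch_size=batch_size), analytic
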