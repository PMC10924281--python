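"""Replica-exchange MCMC over bead coordinates.

Models are sampled from the modified prior (stereochemistry + prior
crosslink subset) with single-bead and rigid-body movers.  Constrained
sampling — draws from the prior restricted to likelihoods above a
threshold — is what nested sampling uses to replace its worst live
point.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .representation import BeadModel
from .restraints import RepartitionedScore

__all__ = [
    "MoveSet",
    "SampleBatch",
    "propose_move",
    "mcmc_from_modified_prior",
    "sample_constrained",
    "ConstrainedSamplingFailure",
]


@dataclass(frozen=True)
class MoveSet:
    """Proposal step sizes and the replica-exchange ladder.

    The temperature ladder is geometric, starts at 1.0 (the cold,
    recorded replica) and is applied to the modified prior only.
    """

    flexible_bead_step: float = 4.0  # Å, radius of the uniform ball
    rigid_translate_step: float = 4.0  # Å
    rigid_rotate_step: float = 0.2  # radians
    n_replicas: int = 4
    max_temperature: float = 2.5

    def __post_init__(self) -> None:
        if min(self.flexible_bead_step, self.rigid_translate_step) < 0 or (
            self.rigid_rotate_step < 0
        ):
            raise ValueError("step sizes must be non-negative")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")
        if self.max_temperature < 1.0:
            raise ValueError("max temperature must be >= 1")

    @property
    def temperature_ladder(self) -> np.ndarray:
        if self.n_replicas == 1:
            return np.array([1.0])
        return np.geomspace(1.0, self.max_temperature, self.n_replicas)


@dataclass
class SampleBatch:
    """Cold-replica snapshots of one MCMC segment."""

    models: list[np.ndarray]  # coordinate snapshots
    log_priors: list[float]
    log_likelihoods: list[float]
    per_step_time: float  # wall seconds per MCMC step, across replicas

    def __post_init__(self) -> None:
        if not (len(self.models) == len(self.log_priors) == len(self.log_likelihoods)):
            raise ValueError("snapshot lists must have equal length")


def _random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    u = rng.normal(size=3)
    n = np.linalg.norm(u)
    if n == 0:
        return np.zeros(3)
    return u / n * radius * rng.random() ** (1.0 / 3.0)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def _movers(model: BeadModel) -> list[tuple[str, np.ndarray]]:
    movers: list[tuple[str, np.ndarray]] = [
        ("bead", np.array([i])) for i in model.flexible_indices
    ]
    movers.extend(("body", idx) for idx in model.rigid_bodies.values())
    return movers


def _apply_move(
    coords: np.ndarray,
    kind: str,
    idx: np.ndarray,
    moveset: MoveSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one symmetric move in place on a copy of ``coords``."""
    out = coords.copy()
    if kind == "bead":
        out[idx[0]] = out[idx[0]] + _random_in_ball(rng, moveset.flexible_bead_step)
    else:
        shift = _random_in_ball(rng, moveset.rigid_translate_step)
        axis = rng.normal(size=3)
        while np.linalg.norm(axis) == 0:  # pragma: no cover
            axis = rng.normal(size=3)
        angle = rng.uniform(-moveset.rigid_rotate_step, moveset.rigid_rotate_step)
        rot = _rotation_matrix(axis, angle)
        centroid = out[idx].mean(axis=0)
        out[idx] = (out[idx] - centroid) @ rot.T + centroid + shift
    return out


def propose_move(
    model: BeadModel, moveset: MoveSet, rng: np.random.Generator
) -> BeadModel:
    """One randomly chosen mover applied to a copy of the model.

    Either a uniform-ball translation of a single flexible bead or a
    rigid-body translation plus a small random rotation about the body
    centroid.  The proposal is symmetric; everything else is unchanged.
    """
    movers = _movers(model)
    if not movers:
        raise ValueError("model has no movable degrees of freedom")
    kind, idx = movers[rng.integers(len(movers))]
    return model.with_coords(_apply_move(model.coords, kind, idx, moveset, rng))


def mcmc_from_modified_prior(
    start: BeadModel,
    score: RepartitionedScore,
    moveset: MoveSet,
    n_steps: int,
    rng: np.random.Generator,
    swap_interval: int = 10,
    thin_interval: int = 10,
    burn_in: int = 0,
) -> SampleBatch:
    """Replica-exchange Metropolis sampling of the modified prior.

    Every replica runs Metropolis on log π / T; adjacent replicas swap
    with the standard exchange criterion every ``swap_interval`` steps.
    Cold-replica snapshots are recorded every ``thin_interval`` steps
    after ``burn_in``; likelihoods are evaluated only on snapshots.
    ``per_step_time`` is wall clock over the segment divided by the total
    steps taken across replicas.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    temps = moveset.temperature_ladder
    n_rep = len(temps)
    movers = _movers(start)
    if not movers:
        raise ValueError("model has no movable degrees of freedom")

    coords = [start.coords.copy() for _ in range(n_rep)]
    logp = np.array([score.log_prior(c) for c in coords])
    if not np.all(np.isfinite(logp)):
        raise ValueError("non-finite modified prior at the starting model")

    snapshots: list[np.ndarray] = []
    t0 = time.monotonic()
    for step in range(1, n_steps + 1):
        for r in range(n_rep):
            kind, idx = movers[rng.integers(len(movers))]
            cand = _apply_move(coords[r], kind, idx, moveset, rng)
            lp = score.log_prior(cand)
            if lp >= logp[r] or math.log(rng.random()) < (lp - logp[r]) / temps[r]:
                coords[r] = cand
                logp[r] = lp
        if n_rep > 1 and step % swap_interval == 0:
            offset = (step // swap_interval) % 2
            for a in range(offset, n_rep - 1, 2):
                b = a + 1
                d = (1.0 / temps[a] - 1.0 / temps[b]) * (logp[b] - logp[a])
                if d >= 0 or math.log(rng.random()) < d:
                    coords[a], coords[b] = coords[b], coords[a]
                    logp[a], logp[b] = logp[b], logp[a]
        if step > burn_in and step % thin_interval == 0:
            snapshots.append(coords[0].copy())
    if not snapshots:
        snapshots.append(coords[0].copy())
    wall = time.monotonic() - t0
    per_step = max(wall / (n_steps * n_rep), 1e-12)
    return SampleBatch(
        models=snapshots,
        log_priors=[score.log_prior(c) for c in snapshots],
        log_likelihoods=[score.log_likelihood(c) for c in snapshots],
        per_step_time=per_step,
    )


@dataclass
class ConstrainedSamplingFailure:
    """Raised/returned when no sample beats the threshold."""

    n_failed_batches: int


def sample_constrained(
    start_provider,
    threshold: float,
    score: RepartitionedScore,
    moveset: MoveSet,
    batch_size: int,
    max_failures: int,
    rng: np.random.Generator,
    swap_interval: int = 10,
    thin_interval: int = 10,
):
    """Draw from the modified prior constrained to log L ≥ ``threshold``.

    Each attempt starts a fresh MCMC segment from ``start_provider(rng)``
    (typically a random live point), discards the first half as burn-in
    and scans the snapshots in order; the first one at or above the
    threshold is returned as ``(coords, logL, per_step_time, n_failed)``.
    After ``max_failures`` consecutive empty batches a
    :class:`ConstrainedSamplingFailure` is returned instead.
    """
    failures = 0
    while failures < max_failures:
        start = start_provider(rng)
        batch = mcmc_from_modified_prior(
            start,
            score,
            moveset,
            batch_size,
            rng,
            swap_interval=swap_interval,
            thin_interval=thin_interval,
            burn_in=batch_size // 2,
        )
        for coords, ll in zip(batch.models, batch.log_likelihoods):
            if ll >= threshold:
                return coords, ll, batch.per_step_time, failures
        failures += 1
    return ConstrainedSamplingFailure(failures)
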