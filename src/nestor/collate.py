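"""Collation of independent runs, Bayes factors, and the selection rule.

Per representation, the mean and standard error of log Z over the
independent nested-sampling runs quantify the evidence and its
uncertainty, and the mean per-MCMC-step wall time quantifies sampling
efficiency.  A representation is *optimal* when its evidence interval
overlaps the best one's (through a chain of overlaps) and its per-step
time is within a configurable fold (default 3×) of the fastest member of
that top-evidence group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ns import NSRunResult

__all__ = [
    "EvidenceEstimate",
    "SelectionResult",
    "collate_runs",
    "bayes_factor",
    "select_optimal",
]


@dataclass(frozen=True)
class EvidenceEstimate:
    """Collated evidence and efficiency of one representation."""

    label: str
    mean_logZ: float
    sem_logZ: float
    n_runs: int
    mean_per_step_time: float | None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        if self.sem_logZ < 0:
            raise ValueError("sem must be non-negative")


def collate_runs(
    results: Sequence[NSRunResult], label: str = ""
) -> EvidenceEstimate:
    """Mean and standard error of log Z across runs, plus mean step time.

    The standard error is the sample standard deviation over runs
    divided by √n_runs; a single run yields sem 0 with a warning.
    """
    if len(results) == 0:
        raise ValueError("no successful runs to collate; relaunch the runs")
    logz = np.array([r.log_Z for r in results])
    if len(logz) == 1:
        warnings.warn(
            f"representation {label!r}: only one run, evidence uncertainty "
            "cannot be estimated (sem set to 0)",
            stacklevel=2,
        )
        sem = 0.0
    else:
        sem = float(np.std(logz, ddof=1) / math.sqrt(len(logz)))
    times = [r.per_step_time for r in results if r.per_step_time is not None]
    return EvidenceEstimate(
        label=label,
        mean_logZ=float(np.mean(logz)),
        sem_logZ=sem,
        n_runs=len(results),
        mean_per_step_time=float(np.mean(times)) if times else None,
    )


def bayes_factor(
    est1: EvidenceEstimate, est2: EvidenceEstimate
) -> tuple[float, float]:
    """log Bayes factor log K = mean_logZ1 − mean_logZ2 and its error.

    Under equal prior probability of the two representations, K is the
    ratio of their evidences; the error adds the two sems in quadrature.
    """
    return (
        est1.mean_logZ - est2.mean_logZ,
        math.hypot(est1.sem_logZ, est2.sem_logZ),
    )


@dataclass(frozen=True)
class SelectionResult:
    """Ranked selection over candidate representations."""

    optimal: tuple[str, ...]
    top_evidence: tuple[str, ...]
    table: tuple[dict, ...]  # one row per scheme, ranked


def _intervals_overlap(a: EvidenceEstimate, b: EvidenceEstimate, mult: float) -> bool:
    return (a.mean_logZ - mult * a.sem_logZ) <= (
        b.mean_logZ + mult * b.sem_logZ
    ) and (b.mean_logZ - mult * b.sem_logZ) <= (a.mean_logZ + mult * a.sem_logZ)


def select_optimal(
    estimates: Sequence[EvidenceEstimate],
    fold: float = 3.0,
    sem_multiplier: float = 1.0,
) -> SelectionResult:
    """Apply the evidence + efficiency rule to a set of estimates.

    The top-evidence group is grown from the best mean log Z by interval
    overlap (mean ± sem_multiplier·sem), taking the transitive closure:
    a scheme joins if its interval overlaps any scheme already in the
    group.  Within the group, schemes whose per-step time is at most
    ``fold`` × the group's fastest are optimal.  Schemes without a
    recorded time are kept in the group but cannot be declared optimal
    unless no member has a time.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to select from")
    order = sorted(
        estimates,
        key=lambda e: (
            -e.mean_logZ,
            e.mean_per_step_time if e.mean_per_step_time is not None else math.inf,
            e.label,
        ),
    )
    best = order[0]
    group = {best.label}
    changed = True
    while changed:
        changed = False
        for e in order:
            if e.label in group:
                continue
            if any(
                _intervals_overlap(e, m, sem_multiplier)
                for m in order
                if m.label in group
            ):
                group.add(e.label)
                changed = True
    members = [e for e in order if e.label in group]
    times = [e.mean_per_step_time for e in members if e.mean_per_step_time is not None]
    if times:
        t_min = min(times)
        optimal = [
            e.label
            for e in members
            if e.mean_per_step_time is not None
            and e.mean_per_step_time <= fold * t_min
        ]
    else:
        optimal = [e.label for e in members]
    table = tuple(
        {
            "label": e.label,
            "mean_logZ": e.mean_logZ,
            "sem_logZ": e.sem_logZ,
            "n_runs": e.n_runs,
            "mean_per_step_time": e.mean_per_step_time,
            "top_evidence": e.label in group,
            "optimal": e.label in optimal,
        }
        for e in order
    )
    return SelectionResult(
        optimal=tuple(l for l in (e.label for e in order) if l in optimal),
        top_evidence=tuple(l for l in (e.label for e in order) if l in group),
        table=table,
    )
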