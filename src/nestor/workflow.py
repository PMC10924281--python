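"""End-to-end parallel workflow: runs × representations → selection.

For every candidate representation, ``n_runs`` independent nested-
sampling runs are executed (optionally across processes), failed runs
are relaunched with fresh deterministic seeds, the evidences are
collated, and the evidence + efficiency rule picks the optimal
representations.  Per-run seeds are derived from
(master seed, scheme label, run index, attempt), so results are
identical whatever the thread count.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as nio
from .collate import EvidenceEstimate, SelectionResult, collate_runs, select_optimal
from .ns import (
    NSInitializationError,
    NSRunResult,
    StructuralProblem,
    run_nested_sampling,
)
from .representation import (
    ChainTopology,
    RepresentationScheme,
    coarse_grain,
)
from .restraints import (
    CrosslinkDataset,
    GMMDensity,
    RepartitionedScore,
    RestraintPartition,
    ScoreParams,
    partition_restraints,
)
from .sampler import MoveSet
from .synthetic import make_preset

__all__ = ["NestorConfig", "WorkflowResult", "run_workflow", "emit_workspace"]


@dataclass
class NestorConfig:
    """Every knob of one NestOR invocation; loadable from YAML."""

    # inputs
    topology_file: str = ""
    pdb_file: str | None = None
    crosslinks_file: str | None = None
    gmm_file: str | None = None
    # candidates
    schemes: tuple[str, ...] = ("1", "5", "10", "20", "30", "50")
    mixed_spec: str | None = None  # YAML file defining a "mixed" scheme
    # runs
    n_runs: int = 5
    n_live: int = 50
    mcmc_steps: int = 50
    max_threads: int = 1
    retry_budget: int = 3
    # convergence
    max_failures: int = 4
    max_plateau: int = 20
    max_iterations: int = 10_000
    integration: str = "trapezoid"
    # restraints
    sigma: float = 10.0
    psi: float = 0.05
    d0: float = 21.0
    prior_fraction: float = 0.3
    partition_seed: int = 0
    use_em: bool = True
    em_weight: float = 1.0
    box_halfside: float = 300.0
    # sampler
    flexible_bead_step: float = 4.0
    rigid_translate_step: float = 4.0
    rigid_rotate_step: float = 0.2
    n_replicas: int = 4
    max_temperature: float = 2.5
    swap_interval: int = 10
    thin_interval: int = 10
    # selection
    fold: float = 3.0
    sem_multiplier: float = 1.0
    # bookkeeping
    seed: int = 0
    output_dir: str = "nestor_output"

    def __post_init__(self) -> None:
        self.schemes = tuple(str(s) for s in self.schemes)
        if self.n_runs < 1 or self.max_threads < 1:
            raise ValueError("n_runs and max_threads must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NestorConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        base = Path(path).parent
        for attr in ("topology_file", "pdb_file", "crosslinks_file", "gmm_file",
                     "mixed_spec"):
            val = getattr(cfg, attr)
            if val and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["schemes"] = list(self.schemes)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def validate_files(self) -> None:
        for attr in ("topology_file", "pdb_file", "crosslinks_file", "gmm_file",
                     "mixed_spec"):
            val = getattr(self, attr)
            if attr == "topology_file" and not val:
                raise ValueError("topology_file is required")
            if val and not Path(val).exists():
                raise FileNotFoundError(f"{attr}: {val} does not exist")


def build_scheme(label: str, config: NestorConfig) -> RepresentationScheme:
    if label == "mixed":
        if not config.mixed_spec:
            raise ValueError("scheme 'mixed' requires mixed_spec")
        data = yaml.safe_load(Path(config.mixed_spec).read_text())
        overrides = tuple(
            (str(o["chain"]), int(o["start"]), int(o["end"]),
             int(o["residues_per_bead"]))
            for o in data.get("overrides", [])
        )
        return RepresentationScheme.mixed(
            int(data["default"]), overrides, label=str(data.get("label", "mixed"))
        )
    return RepresentationScheme.uniform(int(label))


def run_seed(master_seed: int, label: str, run_idx: int, attempt: int = 0) -> np.random.SeedSequence:
    """Deterministic per-run seed from (master, scheme, run, attempt)."""
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(label.encode()), int(run_idx), int(attempt)]
    )


@dataclass
class _RunTask:
    """Self-contained, picklable description of one NS run."""

    label: str
    run_idx: int
    attempt: int
    topologies: tuple[ChainTopology, ...]
    scheme: RepresentationScheme
    partition: RestraintPartition
    density: GMMDensity | None
    reference: dict | None
    config: NestorConfig


def _execute_run(task: _RunTask):
    """Run one nested-sampling run; return the result or the failure."""
    cfg = task.config
    model = coarse_grain(task.topologies, task.scheme)
    score = RepartitionedScore(
        model,
        task.partition,
        task.density,
        ScoreParams(em_weight=cfg.em_weight, box_halfside=cfg.box_halfside),
    )
    moveset = MoveSet(
        flexible_bead_step=cfg.flexible_bead_step,
        rigid_translate_step=cfg.rigid_translate_step,
        rigid_rotate_step=cfg.rigid_rotate_step,
        n_replicas=cfg.n_replicas,
        max_temperature=cfg.max_temperature,
    )
    problem = StructuralProblem(
        model,
        score,
        moveset,
        mcmc_steps=cfg.mcmc_steps,
        swap_interval=cfg.swap_interval,
        thin_interval=cfg.thin_interval,
        reference=task.reference,
    )
    rng = np.random.default_rng(
        run_seed(cfg.seed, task.label, task.run_idx, task.attempt)
    )
    try:
        result = run_nested_sampling(
            problem,
            n_live=cfg.n_live,
            max_failures=cfg.max_failures,
            max_plateau=cfg.max_plateau,
            max_iterations=cfg.max_iterations,
            rng=rng,
            integration=cfg.integration,
        )
    except NSInitializationError as exc:
        return task.label, task.run_idx, task.attempt, exc
    return task.label, task.run_idx, task.attempt, result


@dataclass
class WorkflowResult:
    estimates: tuple[EvidenceEstimate, ...]
    selection: SelectionResult
    runs: dict[str, list[NSRunResult]]
    output_dir: Path


class WorkflowError(RuntimeError):
    pass


def _load_inputs(config: NestorConfig):
    config.validate_files()
    topologies = tuple(nio.read_topology(config.topology_file))
    reference = None
    if config.pdb_file:
        reference = nio.read_pdb_ca(config.pdb_file)
        nio.validate_reference(topologies, reference)
    else:
        for t in topologies:
            if any(s.kind == "structured" for s in t.segments):
                raise ValueError(
                    "topology declares structured segments but no PDB was given"
                )
    if config.crosslinks_file:
        links = nio.read_crosslinks_csv(
            config.crosslinks_file,
            topologies,
            d0=config.d0,
            psi=config.psi,
            sigma=config.sigma,
        )
    else:
        links = CrosslinkDataset((), d0=config.d0, psi=config.psi, sigma=config.sigma)
    if len(links) == 0:
        warnings.warn(
            "no crosslinks: the modified prior is stereochemistry only",
            stacklevel=2,
        )
    density = None
    if config.gmm_file and config.use_em:
        density = nio.read_gmm_text(config.gmm_file)
    partition = partition_restraints(
        links, config.prior_fraction, config.partition_seed, config.use_em
    )
    return topologies, reference, partition, density


def run_workflow(config: NestorConfig, write_outputs: bool = True) -> WorkflowResult:
    """Execute the full candidate-comparison workflow.

    Schedules ``n_runs`` × ``len(schemes)`` independent runs across at
    most ``max_threads`` worker processes, relaunches failed runs (up to
    ``retry_budget`` fresh-seed attempts each), collates evidences per
    scheme and applies the selection rule.  Deterministic given the
    master seed, apart from measured wall-clock times.
    """
    topologies, reference, partition, density = _load_inputs(config)
    schemes = {lbl: build_scheme(lbl, config) for lbl in config.schemes}

    pending = [
        _RunTask(lbl, i, 0, topologies, schemes[lbl], partition, density,
                 reference, config)
        for lbl in config.schemes
        for i in range(config.n_runs)
    ]
    runs: dict[str, list[tuple[int, NSRunResult]]] = {l: [] for l in config.schemes}
    while pending:
        if config.max_threads > 1:
            with ProcessPoolExecutor(max_workers=config.max_threads) as pool:
                outcomes = list(pool.map(_execute_run, pending))
        else:
            outcomes = [_execute_run(t) for t in pending]
        retry = []
        for task, (label, run_idx, attempt, res) in zip(pending, outcomes):
            if isinstance(res, NSRunResult):
                runs[label].append((run_idx, res))
            elif attempt + 1 < config.retry_budget:
                retry.append(dataclasses.replace(task, attempt=attempt + 1))
            else:
                warnings.warn(
                    f"scheme {label} run {run_idx}: gave up after "
                    f"{config.retry_budget} attempts ({res})",
                    stacklevel=2,
                )
        pending = retry

    estimates = []
    ordered_runs: dict[str, list[NSRunResult]] = {}
    for label in config.schemes:
        got = sorted(runs[label], key=lambda t: t[0])
        if not got:
            raise WorkflowError(
                f"scheme {label}: zero successful runs after "
                f"{config.retry_budget} attempts each"
            )
        ordered_runs[label] = [r for _, r in got]
        estimates.append(collate_runs(ordered_runs[label], label=label))
    selection = select_optimal(
        estimates, fold=config.fold, sem_multiplier=config.sem_multiplier
    )

    out = Path(config.output_dir)
    if write_outputs:
        _write_outputs(out, config, estimates, selection, ordered_runs)
    return WorkflowResult(tuple(estimates), selection, ordered_runs, out)


def _write_outputs(out, config, estimates, selection, runs) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "runs").mkdir(exist_ok=True)
    for label, results in runs.items():
        for i, r in enumerate(results):
            nio.write_trace_tsv(out / "runs" / f"{label}_run{i}.trace.tsv", r)
            (out / "runs" / f"{label}_run{i}.json").write_text(
                json.dumps(
                    {
                        "label": label,
                        "run": i,
                        "log_Z": r.log_Z,
                        "termination": r.termination,
                        "iterations": r.iterations,
                        "per_step_time": r.per_step_time,
                        "nestor_process_time": r.nestor_process_time,
                    },
                    indent=2,
                )
                + "\n"
            )
    nio.write_results_json(out / "results.json", estimates, selection)
    write_selection_report(out / "selection.md", selection)
    try:
        plot_evidence(out / "evidence.png", estimates, selection)
    except Exception as exc:  # plotting must never sink a finished workflow
        warnings.warn(f"could not write evidence plot: {exc}", stacklevel=2)


def write_selection_report(path: str | Path, selection: SelectionResult) -> None:
    lines = [
        "| scheme | mean log Z | sem | runs | s / MCMC step | top evidence | optimal |",
        "|---|---|---|---|---|---|---|",
    ]
    for row in selection.table:
        t = row["mean_per_step_time"]
        lines.append(
            "| {label} | {mean_logZ:.2f} | {sem_logZ:.2f} | {n_runs} | {t} | "
            "{te} | {opt} |".format(
                label=row["label"],
                mean_logZ=row["mean_logZ"],
                sem_logZ=row["sem_logZ"],
                n_runs=row["n_runs"],
                t="-" if t is None else f"{t:.2e}",
                te="yes" if row["top_evidence"] else "",
                opt="**yes**" if row["optimal"] else "",
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def plot_evidence(path: str | Path, estimates, selection: SelectionResult) -> None:
    """Evidence ± sem and per-step time per candidate scheme."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [e.label for e in estimates]
    x = np.arange(len(labels))
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.errorbar(
        x,
        [e.mean_logZ for e in estimates],
        yerr=[e.sem_logZ for e in estimates],
        fmt="o-",
        color="tab:blue",
        capsize=3,
        label="mean log Z ± sem",
    )
    ax1.set_xlabel("residues per bead")
    ax1.set_ylabel("log model evidence", color="tab:blue")
    ax1.set_xticks(x, labels)
    times = [e.mean_per_step_time for e in estimates]
    if all(t is not None for t in times):
        ax2 = ax1.twinx()
        ax2.plot(x, times, "s--", color="tab:green", label="s / MCMC step")
        ax2.set_yscale("log")
        ax2.set_ylabel("time per MCMC step (s)", color="tab:green")
    for i, lbl in enumerate(labels):
        if lbl in selection.optimal:
            ax1.axvspan(i - 0.2, i + 0.2, color="orange", alpha=0.2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def emit_workspace(
    preset: str,
    out_dir: str | Path,
    seed: int | None = None,
    schemes: Sequence[str] = ("1", "5", "10", "20", "30", "50"),
    **config_overrides,
) -> Path:
    """Write a complete ready-to-run workspace from a synthetic preset.

    Emits topology TSV, CA-only reference PDB, crosslink CSV, GMM text
    and a config.yaml wired to them; returns the config path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assembly, links, density = make_preset(preset, seed=seed)
    nio.write_topology(out / "topology.tsv", assembly.topologies)
    nio.write_pdb_ca(out / "reference.pdb", assembly.coordinates)
    nio.write_crosslinks_csv(out / "crosslinks.csv", links)
    nio.write_gmm_text(out / "density.gmm.txt", density)
    cfg = NestorConfig(
        topology_file="topology.tsv",
        pdb_file="reference.pdb",
        crosslinks_file="crosslinks.csv",
        gmm_file="density.gmm.txt",
        schemes=tuple(schemes),
        sigma=links.sigma,
        psi=links.psi,
        d0=links.d0,
        output_dir=str(out / "output"),
        **config_overrides,
    )
    cfg.to_yaml(out / "config.yaml")
    return out / "config.yaml"
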