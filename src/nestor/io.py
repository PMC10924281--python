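"""Readers and writers for the plain-text input/output dialects.

Formats: topology TSV, CA-only PDB, crosslink CSV, IMP-style GMM text,
per-run dead-point trace TSV, and the collated results JSON.  All
readers raise line-numbered errors on malformed input; every writer
round-trips through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .collate import EvidenceEstimate, SelectionResult
from .ns import NSRunResult
from .representation import ChainTopology, Segment
from .restraints import Crosslink, CrosslinkDataset, GMMDensity

__all__ = [
    "LINKER_LENGTHS",
    "read_topology",
    "write_topology",
    "read_pdb_ca",
    "write_pdb_ca",
    "validate_reference",
    "read_crosslinks_csv",
    "write_crosslinks_csv",
    "read_gmm_text",
    "write_gmm_text",
    "write_trace_tsv",
    "write_results_json",
]

#: Default effective linker lengths (Å) by crosslinker keyword.
LINKER_LENGTHS: dict[str, float] = {"DSS": 21.0, "BS3": 21.0}


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# topology TSV: chain_id <TAB> start <TAB> end <TAB> kind <TAB> rigid_body [<TAB> pdb_chain]


def read_topology(path: str | Path) -> list[ChainTopology]:
    rows: dict[str, list[tuple[int, Segment]]] = {}
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty topology file")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["chain_id", "start", "end", "kind", "rigid_body"]
    if [h.strip() for h in header[:5]] != expected:
        raise ParseError(
            f"{path}:1: expected header {expected} (tab-separated), got {header[:5]}"
        )
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ParseError(
                f"{path}:{ln}: expected at least 5 tab-separated fields, got {len(parts)}"
            )
        chain, start_s, end_s, kind, rb = (p.strip() for p in parts[:5])
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(
                f"{path}:{ln}: start/end must be integers, got {start_s!r}/{end_s!r}"
            ) from None
        body = None if rb in ("-", "") else int(rb)
        try:
            seg = Segment(start, end, kind, body)
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from None
        rows.setdefault(chain, []).append((ln, seg))
    tops = []
    for chain, segs in rows.items():
        segs.sort(key=lambda x: x[1].start)
        length = segs[-1][1].end
        tops.append(ChainTopology(chain, length, tuple(s for _, s in segs)))
    return tops


def write_topology(path: str | Path, topologies: Sequence[ChainTopology]) -> None:
    lines = ["chain_id\tstart\tend\tkind\trigid_body"]
    for top in topologies:
        for seg in top.segments:
            rb = "-" if seg.rigid_body is None else str(seg.rigid_body)
            lines.append(f"{top.chain_id}\t{seg.start}\t{seg.end}\t{seg.kind}\t{rb}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CA-only PDB


def write_pdb_ca(
    path: str | Path, coordinates: Mapping[str, np.ndarray]
) -> None:
    """Write per-chain CA traces as a minimal PDB (GLY residues)."""
    lines = []
    serial = 1
    for chain, xyz in coordinates.items():
        for i, (x, y, z) in enumerate(np.asarray(xyz), start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY {chain[:1]}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb_ca(
    path: str | Path, chains: Sequence[str] | None = None
) -> dict[tuple[str, int], np.ndarray]:
    """CA coordinates keyed by (chain id, residue number)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(path))
    out: dict[tuple[str, int], np.ndarray] = {}
    model = next(iter(structure))
    for chain in model:
        cid = chain.id
        if chains is not None and cid not in chains:
            continue
        for residue in chain:
            if "CA" in residue:
                out[(cid, residue.id[1])] = np.asarray(
                    residue["CA"].coord, dtype=float
                )
    return out


def validate_reference(
    topologies: Sequence[ChainTopology],
    reference: Mapping[tuple[str, int], np.ndarray],
) -> None:
    """Every residue of a structured segment must have a CA coordinate."""
    missing = []
    for top in topologies:
        for seg in top.segments:
            if seg.kind != "structured":
                continue
            for r in range(seg.start, seg.end + 1):
                if (top.chain_id, r) not in reference:
                    missing.append(f"{top.chain_id}:{r}")
    if missing:
        raise ValueError(
            "structured residues missing from the reference PDB: "
            + ", ".join(missing)
        )


# ---------------------------------------------------------------------------
# crosslink CSV: chain1,residue1,chain2,residue2[,linker]


def read_crosslinks_csv(
    path: str | Path,
    topologies: Sequence[ChainTopology] | None = None,
    linker_lengths: Mapping[str, float] | None = None,
    d0: float = 21.0,
    psi: float = 0.05,
    sigma: float = 10.0,
) -> CrosslinkDataset:
    """Read crosslinks; validate residues against the topology if given.

    A ``linker`` column selects d0 from ``linker_lengths`` (default
    DSS/BS3 → 21 Å); an unknown keyword is an error.  With several
    linker types, the most permissive (largest) length is used for the
    dataset.
    """
    table = linker_lengths if linker_lengths is not None else LINKER_LENGTHS
    df = pd.read_csv(path)
    needed = ["chain1", "residue1", "chain2", "residue2"]
    if [c.strip() for c in df.columns[:4].tolist()] != needed:
        raise ParseError(
            f"{path}: expected columns {needed}[,linker], got {df.columns.tolist()}"
        )
    lengths = {t.chain_id: t.length for t in topologies} if topologies else None
    links = []
    linker_d0s = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        c1, r1, c2, r2 = str(row[0]), int(row[1]), str(row[2]), int(row[3])
        if lengths is not None:
            for c, r in ((c1, r1), (c2, r2)):
                if c not in lengths:
                    raise ParseError(
                        f"{path}:{row_idx}: chain {c!r} absent from topology"
                    )
                if not (1 <= r <= lengths[c]):
                    raise ParseError(
                        f"{path}:{row_idx}: residue {c}:{r} outside 1..{lengths[c]}"
                    )
        if len(row) > 4 and isinstance(row[4], str) and row[4].strip():
            key = row[4].strip().upper()
            if key not in table:
                raise ParseError(
                    f"{path}:{row_idx}: unknown linker {key!r}; known: {sorted(table)}"
                )
            linker_d0s.append(table[key])
        links.append(Crosslink(c1, r1, c2, r2))
    d0_eff = max(linker_d0s) if linker_d0s else d0
    return CrosslinkDataset(tuple(links), d0=d0_eff, psi=psi, sigma=sigma)


def write_crosslinks_csv(
    path: str | Path, links: CrosslinkDataset, linker: str | None = None
) -> None:
    rows = []
    for l in links.links:
        row = {
            "chain1": l.chain1,
            "residue1": l.residue1,
            "chain2": l.chain2,
            "residue2": l.residue2,
        }
        if linker:
            row["linker"] = linker
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# IMP-style GMM text: index|weight|mx my mz|c11 c12 c13 c22 c23 c33


def write_gmm_text(path: str | Path, density: GMMDensity) -> None:
    lines = ["# index|weight|mean|covariance (upper triangle)"]
    for i, (w, m, c) in enumerate(
        zip(density.weights, density.means, density.covariances)
    ):
        tri = [c[0, 0], c[0, 1], c[0, 2], c[1, 1], c[1, 2], c[2, 2]]
        lines.append(
            f"{i}|{w:.12g}|"
            + " ".join(f"{v:.12g}" for v in m)
            + "|"
            + " ".join(f"{v:.12g}" for v in tri)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmm_text(path: str | Path) -> GMMDensity:
    weights, means, covs = [], [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("|")
        if len(parts) != 4:
            raise ParseError(
                f"{path}:{ln}: expected 'index|weight|mean|covariance', got {line!r}"
            )
        try:
            w = float(parts[1])
            m = [float(v) for v in parts[2].split()]
            tri = [float(v) for v in parts[3].split()]
        except ValueError:
            raise ParseError(f"{path}:{ln}: non-numeric field") from None
        if len(m) != 3 or len(tri) != 6:
            raise ParseError(
                f"{path}:{ln}: mean needs 3 values and covariance 6, "
                f"got {len(m)} and {len(tri)}"
            )
        c11, c12, c13, c22, c23, c33 = tri
        weights.append(w)
        means.append(m)
        covs.append([[c11, c12, c13], [c12, c22, c23], [c13, c23, c33]])
    if not weights:
        raise ParseError(f"{path}: no GMM components found")
    return GMMDensity(np.array(weights), np.array(means), np.array(covs))


# ---------------------------------------------------------------------------
# run traces and collated results


def write_trace_tsv(path: str | Path, result: NSRunResult) -> None:
    """Dead-point trace (iteration, logL, logX, running logZ) for L-vs-X plots."""
    trace = result.log_Z_trace
    lines = ["iteration\tlogL\tlogX\tlogZ_so_far"]
    for i, (ll, lx, lz) in enumerate(
        zip(result.dead_log_likelihoods, result.dead_log_X, trace), start=1
    ):
        lines.append(f"{i}\t{ll:.10g}\t{lx:.10g}\t{lz:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_results_json(
    path: str | Path,
    estimates: Sequence[EvidenceEstimate],
    selection: SelectionResult,
) -> None:
    payload = {
        "schemes": {
            e.label: {
                "mean_logZ": e.mean_logZ,
                "sem_logZ": e.sem_logZ,
                "n_runs": e.n_runs,
                "mean_per_step_time": e.mean_per_step_time,
                "optimal": e.label in selection.optimal,
                "top_evidence": e.label in selection.top_evidence,
            }
            for e in estimates
        },
        "optimal": list(selection.optimal),
        "top_evidence": list(selection.top_evidence),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
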