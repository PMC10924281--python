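"""Synthetic assemblies, crosslinks and densities with known ground truth.

Stands in for real benchmark systems: chains are self-avoiding CA-level
random walks whose *compactness* parameter interpolates between an
extended coil (0) and a collapsed globule (1); crosslinks are sampled
from reference CA–CA distances at a true-positive cutoff with a
controlled false-positive rate; the density is a Gaussian-mixture blur
of the reference coordinates.  Three fixed-seed presets ("extended",
"globular", "mixed") make the whole workflow reproducible without any
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .representation import ChainTopology, Segment
from .restraints import Crosslink, CrosslinkDataset, GMMDensity

__all__ = [
    "SyntheticAssembly",
    "generate_assembly",
    "simulate_crosslinks",
    "simulate_density",
    "make_preset",
    "PRESETS",
]

BOND_LENGTH = 3.8  # Å, consecutive CA distance
MIN_SEPARATION = 2.0  # Å, hard-sphere limit between any two residues


@dataclass(frozen=True)
class SyntheticAssembly:
    """Reference structure plus topology for a toy assembly."""

    topologies: tuple[ChainTopology, ...]
    coordinates: dict[str, np.ndarray]  # chain_id -> (length, 3) CA positions, Å
    compactness: dict[str, float]

    def reference_map(self) -> dict[tuple[str, int], np.ndarray]:
        """(chain, 1-based residue) -> CA coordinate."""
        out: dict[tuple[str, int], np.ndarray] = {}
        for top in self.topologies:
            xyz = self.coordinates[top.chain_id]
            for r in range(1, top.length + 1):
                out[(top.chain_id, r)] = xyz[r - 1]
        return out

    def all_coordinates(self) -> np.ndarray:
        return np.concatenate(
            [self.coordinates[t.chain_id] for t in self.topologies]
        )


def _grow_chain(
    length: int,
    compactness: float,
    start: np.ndarray,
    occupied: list[np.ndarray],
    rng: np.random.Generator,
    max_tries: int = 80,
    max_backtracks: int = 400,
) -> np.ndarray:
    """Self-avoiding walk with fixed bond length and centroid attraction."""
    chain = [start.copy()]
    backtracks = 0
    occ = occupied  # previously placed chains
    while len(chain) < length:
        cur = chain[-1]
        centroid = np.mean(chain, axis=0)
        placed = False
        for attempt in range(max_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # after many failures, fall back to an unbiased direction
            if compactness > 0 and len(chain) > 1 and attempt < max_tries // 2:
                t = centroid - cur
                tn = np.linalg.norm(t)
                if tn > 1e-9:
                    u = (1.0 - compactness) * u + compactness * (t / tn)
                    u /= np.linalg.norm(u)
            cand = cur + BOND_LENGTH * u
            ok = True
            if len(chain) > 1:
                d2 = np.sum((np.asarray(chain[:-1]) - cand) ** 2, axis=1)
                ok = bool(np.all(d2 >= MIN_SEPARATION**2))
            if ok:
                for other in occ:
                    if np.any(
                        np.sum((other - cand) ** 2, axis=1) < MIN_SEPARATION**2
                    ):
                        ok = False
                        break
            if ok:
                chain.append(cand)
                placed = True
                break
        if not placed:
            backtracks += 1
            if backtracks > max_backtracks:
                raise RuntimeError(
                    f"chain packing infeasible after {max_backtracks} backtracks "
                    f"(length {length}, compactness {compactness})"
                )
            del chain[-min(5, len(chain) - 1) :]
            if not chain:  # pragma: no cover
                chain = [start.copy()]
    return np.asarray(chain)


def generate_assembly(
    lengths: Sequence[int],
    compactness: Sequence[float],
    seed: int,
    chain_ids: Sequence[str] | None = None,
    segments: Mapping[str, Sequence[Segment]] | None = None,
    chain_spacing: float = 25.0,
) -> SyntheticAssembly:
    """Build a toy assembly of self-avoiding random-walk chains.

    ``compactness`` in [0, 1] biases each step toward the running chain
    centroid: 0 gives an extended coil, 1 a collapsed globule.  Chains
    are started ``chain_spacing`` Å apart so inter-chain contacts (hence
    inter-chain crosslinks) occur without heavy clashes.  ``segments``
    optionally overrides the default single-unstructured-segment
    topology per chain.  Deterministic per seed.
    """
    if len(lengths) != len(compactness):
        raise ValueError("lengths and compactness must align")
    for L in lengths:
        if L < 10:
            raise ValueError("chains must have at least 10 residues")
    for c in compactness:
        if not (0.0 <= c <= 1.0):
            raise ValueError("compactness must lie in [0, 1]")
    ids = list(chain_ids) if chain_ids else [chr(ord("A") + i) for i in range(len(lengths))]
    rng = np.random.default_rng(seed)

    coords: dict[str, np.ndarray] = {}
    occupied: list[np.ndarray] = []
    for k, (cid, L, c) in enumerate(zip(ids, lengths, compactness)):
        start = np.array([k * chain_spacing, 0.0, 0.0])
        xyz = _grow_chain(L, c, start, occupied, rng)
        coords[cid] = xyz
        occupied.append(xyz)

    tops = []
    for cid, L in zip(ids, lengths):
        if segments and cid in segments:
            tops.append(ChainTopology(cid, L, tuple(segments[cid])))
        else:
            tops.append(ChainTopology.unstructured(cid, L))
    return SyntheticAssembly(
        topologies=tuple(tops),
        coordinates=coords,
        compactness=dict(zip(ids, compactness)),
    )


def simulate_crosslinks(
    assembly: SyntheticAssembly,
    n_links: int,
    d_max: float = 21.0,
    fp_rate: float = 0.1,
    seed: int = 0,
    min_seq_sep: int = 5,
    d0: float = 21.0,
    psi: float = 0.05,
    sigma: float = 10.0,
) -> CrosslinkDataset:
    """Sample crosslinks from the reference structure.

    True positives are residue pairs whose reference CA–CA distance is
    at most ``d_max``; decoys (a ``fp_rate`` fraction) come from pairs
    beyond it.  Intra-chain pairs closer than ``min_seq_sep`` residues
    in sequence are excluded (they are trivially satisfied and carry no
    information).  Ground truth uses reference CA distances, not bead
    distances, so it is representation-independent.
    """
    residues: list[tuple[str, int]] = []
    points: list[np.ndarray] = []
    for top in assembly.topologies:
        xyz = assembly.coordinates[top.chain_id]
        for r in range(1, top.length + 1):
            residues.append((top.chain_id, r))
            points.append(xyz[r - 1])
    pts = np.asarray(points)
    n = len(residues)
    iu, ju = np.triu_indices(n, k=1)
    dist = np.linalg.norm(pts[iu] - pts[ju], axis=1)
    same_chain = np.array(
        [residues[a][0] == residues[b][0] for a, b in zip(iu, ju)]
    )
    seq_sep = np.array(
        [abs(residues[a][1] - residues[b][1]) for a, b in zip(iu, ju)]
    )
    eligible = ~(same_chain & (seq_sep < min_seq_sep))
    true_pool = np.flatnonzero(eligible & (dist <= d_max))
    decoy_pool = np.flatnonzero(eligible & (dist > d_max))

    n_fp = int(math.floor(fp_rate * n_links + 0.5))
    n_tp = n_links - n_fp
    if len(true_pool) < n_tp or len(decoy_pool) < n_fp:
        raise ValueError(
            f"insufficient candidate pairs: need {n_tp} true (have "
            f"{len(true_pool)}) and {n_fp} decoy (have {len(decoy_pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = np.concatenate(
        [
            rng.choice(true_pool, size=n_tp, replace=False),
            rng.choice(decoy_pool, size=n_fp, replace=False),
        ]
    ).astype(int)
    links = [
        Crosslink(*residues[iu[c]], *residues[ju[c]]) for c in chosen
    ]
    return CrosslinkDataset(tuple(links), d0=d0, psi=psi, sigma=sigma)


def simulate_density(
    assembly: SyntheticAssembly,
    n_components: int,
    blur_sigma: float = 4.25,
    seed: int = 0,
) -> GMMDensity:
    """Gaussian-mixture density blurred from the reference coordinates.

    Reference CA positions are split into ``n_components`` k-means
    groups; each becomes one Gaussian (mean = centroid, covariance =
    group scatter + blur_sigma²·I, weight ∝ group size).  The default
    blur corresponds to roughly a 10 Å-resolution map
    (σ ≈ resolution / 2.355).
    """
    pts = assembly.all_coordinates()
    if n_components < 1:
        raise ValueError("need at least one component")
    if n_components > len(pts):
        raise ValueError(
            f"n_components={n_components} exceeds {len(pts)} residues"
        )
    if n_components == 1:
        labels = np.zeros(len(pts), dtype=int)
    else:
        km = KMeans(
            n_clusters=n_components, random_state=seed % (2**31), n_init=4
        ).fit(pts)
        labels = km.labels_
    weights, means, covs = [], [], []
    for c in range(n_components):
        grp = pts[labels == c]
        if len(grp) == 0:  # pragma: no cover - k-means rarely empties a cluster
            continue
        weights.append(len(grp))
        means.append(grp.mean(axis=0))
        covs.append(np.cov(grp.T, bias=True) if len(grp) > 1 else np.zeros((3, 3)))
        covs[-1] = covs[-1] + blur_sigma**2 * np.eye(3)
    return GMMDensity(np.array(weights, float), np.array(means), np.array(covs))


@dataclass(frozen=True)
class _Preset:
    lengths: tuple[int, ...]
    compactness: tuple[float, ...]
    n_links: int
    n_components: int
    fp_rate: float
    seed: int
    structured: tuple[tuple[str, int, int, int], ...] = ()  # chain, start, end, body


#: Named study conditions. "extended" is a single disordered coil (the
#: hard case for coarse beads); "globular" is a compact two-chain core,
#: half of each chain rigid; "mixed" pairs one compact and one extended
#: chain, the default end-to-end fixture.
PRESETS: dict[str, _Preset] = {
    "extended": _Preset(
        lengths=(100,),
        compactness=(0.0,),
        n_links=30,
        n_components=10,
        fp_rate=0.1,
        seed=101,
    ),
    "globular": _Preset(
        lengths=(60, 60),
        compactness=(0.85, 0.85),
        n_links=40,
        n_components=8,
        fp_rate=0.1,
        seed=202,
        structured=(("A", 1, 30, 1), ("B", 1, 30, 2)),
    ),
    "mixed": _Preset(
        lengths=(80, 80),
        compactness=(0.9, 0.1),
        n_links=60,
        n_components=10,
        fp_rate=0.1,
        seed=303,
        structured=(("A", 1, 40, 1),),
    ),
}


def make_preset(
    name: str, seed: int | None = None
) -> tuple[SyntheticAssembly, CrosslinkDataset, GMMDensity]:
    """Build one of the named fixture suites (fixed seed unless overridden)."""
    try:
        p = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    seed = p.seed if seed is None else seed
    segments: dict[str, list[Segment]] = {}
    for chain, start, end, body in p.structured:
        idx = [chr(ord("A") + i) for i in range(len(p.lengths))].index(chain)
        length = p.lengths[idx]
        segs = [Segment(start, end, "structured", body)]
        if end < length:
            segs.append(Segment(end + 1, length, "unstructured"))
        if start > 1:  # pragma: no cover - presets start structured at 1
            segs.insert(0, Segment(1, start - 1, "unstructured"))
        segments[chain] = segs
    assembly = generate_assembly(
        p.lengths, p.compactness, seed=seed, segments=segments or None
    )
    links = simulate_crosslinks(
        assembly, p.n_links, fp_rate=p.fp_rate, seed=seed + 1
    )
    density = simulate_density(assembly, p.n_components, seed=seed + 2)
    return assembly, links, density
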