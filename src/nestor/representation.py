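"""Coarse-grained bead representations of multi-chain assemblies.

A *representation* maps contiguous stretches of residues to spherical
beads.  Chains are described by a :class:`ChainTopology` (structured /
unstructured segments, rigid-body assignments); a candidate
:class:`RepresentationScheme` assigns a residues-per-bead granularity to
every segment; :func:`coarse_grain` turns the two into a
:class:`BeadModel`, whose bead coordinates are the parameter space that
nested sampling explores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Segment",
    "ChainTopology",
    "RepresentationScheme",
    "Bead",
    "BeadModel",
    "bead_radius",
    "coarse_grain",
    "count_free_parameters",
    "initialize_coordinates",
    "InvalidTopologyError",
    "InvalidSchemeError",
]

#: Mean volume of one residue in Å^3, used to assign bead radii.
DEFAULT_RESIDUE_VOLUME = 130.0


class InvalidTopologyError(ValueError):
    """Raised when a chain topology violates its invariants."""


class InvalidSchemeError(ValueError):
    """Raised when a representation scheme violates its invariants."""


@dataclass(frozen=True)
class Segment:
    """A contiguous residue range of one chain.

    ``start``/``end`` are 1-based and inclusive on both ends.  A
    structured segment may belong to a rigid body (``rigid_body`` is an
    integer id shared by all segments of that body); unstructured
    segments are always flexible.
    """

    start: int
    end: int
    kind: str  # "structured" | "unstructured"
    rigid_body: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("structured", "unstructured"):
            raise InvalidTopologyError(f"unknown segment kind {self.kind!r}")
        if self.start > self.end:
            raise InvalidTopologyError(
                f"segment start {self.start} > end {self.end}"
            )
        if self.kind == "unstructured" and self.rigid_body is not None:
            raise InvalidTopologyError("unstructured segments cannot be rigid")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ChainTopology:
    """One chain: total length plus an ordered tiling of segments."""

    chain_id: str
    length: int
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidTopologyError(f"chain {self.chain_id}: empty chain")
        if not self.segments:
            raise InvalidTopologyError(f"chain {self.chain_id}: no segments")
        object.__setattr__(self, "segments", tuple(self.segments))
        expect = 1
        for seg in self.segments:
            if seg.start != expect:
                raise InvalidTopologyError(
                    f"chain {self.chain_id}: segments must tile 1..{self.length} "
                    f"without gaps/overlaps (got start {seg.start}, expected {expect})"
                )
            expect = seg.end + 1
        if expect != self.length + 1:
            raise InvalidTopologyError(
                f"chain {self.chain_id}: segments end at {expect - 1}, "
                f"chain length is {self.length}"
            )

    @classmethod
    def unstructured(cls, chain_id: str, length: int) -> "ChainTopology":
        """A fully flexible chain: a single unstructured segment."""
        return cls(chain_id, length, (Segment(1, length, "unstructured"),))


@dataclass(frozen=True)
class RepresentationScheme:
    """Residues-per-bead granularity for every segment.

    ``default`` applies everywhere unless an override rule
    ``(chain_id, start, end) -> residues_per_bead`` covers the whole
    segment.  ``label`` identifies the scheme in outputs (``"1"``,
    ``"50"``, ``"mixed"`` ...).
    """

    label: str
    default: int
    overrides: tuple[tuple[str, int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.default < 1:
            raise InvalidSchemeError("residues_per_bead must be >= 1")
        for chain, start, end, rpb in self.overrides:
            if rpb < 1:
                raise InvalidSchemeError(
                    f"override for {chain}:{start}-{end}: residues_per_bead "
                    f"{rpb} must be >= 1"
                )
            if start > end:
                raise InvalidSchemeError(
                    f"override for {chain}: start {start} > end {end}"
                )

    @classmethod
    def uniform(cls, residues_per_bead: int) -> "RepresentationScheme":
        return cls(label=str(residues_per_bead), default=int(residues_per_bead))

    @classmethod
    def mixed(
        cls,
        default: int,
        overrides: Sequence[tuple[str, int, int, int]],
        label: str = "mixed",
    ) -> "RepresentationScheme":
        return cls(label=label, default=int(default), overrides=tuple(overrides))

    def residues_per_bead(self, chain_id: str, segment: Segment) -> int:
        """Granularity for a segment: the first override that contains it."""
        for chain, start, end, rpb in self.overrides:
            if chain == chain_id and start <= segment.start and segment.end <= end:
                return rpb
        return self.default


@dataclass(frozen=True)
class Bead:
    """One spherical bead: a residue range of a chain plus a radius."""

    chain_id: str
    first_residue: int
    last_residue: int
    radius: float
    rigid_body: int | None = None

    @property
    def n_residues(self) -> int:
        return self.last_residue - self.first_residue + 1


def bead_radius(n_residues: int, residue_volume: float = DEFAULT_RESIDUE_VOLUME) -> float:
    """Radius (Å) of a bead holding ``n_residues`` residues.

    Volume-conserving sphere: r = (3 n V_res / 4π)^(1/3) with V_res the
    mean per-residue volume (default 130 Å^3).  Strictly increasing in
    ``n_residues``.
    """
    if n_residues < 1:
        raise ValueError(f"a bead must hold at least one residue (got {n_residues})")
    return float((3.0 * n_residues * residue_volume / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass
class BeadModel:
    """A structural model M_R: beads plus their 3-D centers.

    ``coords`` holds one row per bead (Å).  Beads in the same rigid body
    move as a unit (6 DoF per body); the remaining beads are flexible
    (3 DoF each).  The free coordinates of the model are the parameter
    space θ of the evidence integral.
    """

    beads: tuple[Bead, ...]
    coords: np.ndarray  # (n_beads, 3), Å

    def __post_init__(self) -> None:
        self.beads = tuple(self.beads)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.beads), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.beads)} beads"
            )

    # -- structure ----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads])

    @property
    def rigid_bodies(self) -> dict[int, np.ndarray]:
        """Map rigid-body id -> bead indices belonging to it."""
        bodies: dict[int, list[int]] = {}
        for i, b in enumerate(self.beads):
            if b.rigid_body is not None:
                bodies.setdefault(b.rigid_body, []).append(i)
        return {k: np.array(v) for k, v in bodies.items()}

    @property
    def flexible_indices(self) -> np.ndarray:
        return np.array(
            [i for i, b in enumerate(self.beads) if b.rigid_body is None], dtype=int
        )

    @property
    def n_flexible(self) -> int:
        return int(sum(1 for b in self.beads if b.rigid_body is None))

    @property
    def m_rigid(self) -> int:
        return len({b.rigid_body for b in self.beads if b.rigid_body is not None})

    def chain_bead_indices(self) -> dict[str, np.ndarray]:
        """Bead indices per chain, in residue order."""
        chains: dict[str, list[int]] = {}
        for i, b in enumerate(self.beads):
            chains.setdefault(b.chain_id, []).append(i)
        return {k: np.array(v) for k, v in chains.items()}

    def residue_to_bead(self) -> dict[tuple[str, int], int]:
        """Map (chain_id, residue) -> bead index.  Unique by construction."""
        out: dict[tuple[str, int], int] = {}
        for i, b in enumerate(self.beads):
            for r in range(b.first_residue, b.last_residue + 1):
                out[(b.chain_id, r)] = i
        return out

    def with_coords(self, coords: np.ndarray) -> "BeadModel":
        """A snapshot sharing bead metadata but with new centers."""
        return BeadModel(self.beads, np.array(coords, dtype=float))

    def copy(self) -> "BeadModel":
        return self.with_coords(self.coords.copy())


def coarse_grain(
    topology: ChainTopology | Sequence[ChainTopology],
    scheme: RepresentationScheme,
    residue_volume: float = DEFAULT_RESIDUE_VOLUME,
) -> BeadModel:
    """Partition every segment into beads of ``residues_per_bead`` residues.

    Each segment is cut into consecutive beads of exactly the scheme's
    residues-per-bead; leftover residues at the segment end form a
    smaller final bead (so no bead ever exceeds the nominal size).
    Structured segments keep their rigid-body id; unstructured beads are
    flexible.  Coordinates are initialised to zero — call
    :func:`initialize_coordinates` before scoring.
    """
    topologies = [topology] if isinstance(topology, ChainTopology) else list(topology)
    if not topologies:
        raise InvalidTopologyError("no chains given")
    seen: set[str] = set()
    for t in topologies:
        if t.chain_id in seen:
            raise InvalidTopologyError(f"duplicate chain id {t.chain_id!r}")
        seen.add(t.chain_id)

    beads: list[Bead] = []
    for top in topologies:
        for seg in top.segments:
            rpb = scheme.residues_per_bead(top.chain_id, seg)
            if rpb < 1:
                raise InvalidSchemeError("residues_per_bead must be >= 1")
            first = seg.start
            while first <= seg.end:
                last = min(first + rpb - 1, seg.end)
                beads.append(
                    Bead(
                        chain_id=top.chain_id,
                        first_residue=first,
                        last_residue=last,
                        radius=bead_radius(last - first + 1, residue_volume),
                        rigid_body=seg.rigid_body,
                    )
                )
                first = last + 1
    return BeadModel(tuple(beads), np.zeros((len(beads), 3)))


def count_free_parameters(model: BeadModel) -> int:
    """Upper bound on free parameters: 3 per flexible bead + 6 per rigid body."""
    return 3 * model.n_flexible + 6 * model.m_rigid


def initialize_coordinates(
    model: BeadModel,
    rng: np.random.Generator,
    reference: Mapping[tuple[str, int], np.ndarray] | None = None,
    box_halfside: float = 300.0,
) -> BeadModel:
    """Assign starting bead centers.

    Structured beads with reference coordinates sit at the centroid of
    their residues' CA positions; everything else is built as a random
    chain walk — the first bead of each chain uniform inside the
    bounding sphere of radius ``box_halfside``/4, each later bead placed
    at touching distance from its predecessor in a random direction.
    Rigid bodies keep whatever internal geometry this produces; only
    their 6 rigid DoF move afterwards.
    """
    coords = np.zeros((model.n_beads, 3))
    for chain, idx in model.chain_bead_indices().items():
        prev = None
        for i in idx:
            b = model.beads[i]
            ref_xyz = None
            if reference is not None and b.rigid_body is not None:
                pts = [
                    reference[(chain, r)]
                    for r in range(b.first_residue, b.last_residue + 1)
                    if (chain, r) in reference
                ]
                if pts:
                    ref_xyz = np.mean(np.asarray(pts, dtype=float), axis=0)
            if ref_xyz is not None:
                coords[i] = ref_xyz
            elif prev is None:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                coords[i] = u * (box_halfside / 4.0) * rng.random() ** (1.0 / 3.0)
            else:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                coords[i] = coords[prev] + u * (
                    model.beads[prev].radius + b.radius
                )
            prev = i
    return model.with_coords(coords)
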