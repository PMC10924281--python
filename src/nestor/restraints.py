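"""Bayesian scoring of bead models and posterior repartitioning.

Three restraint families score a :class:`~nestor.representation.BeadModel`:

* stereochemistry — chain connectivity (consecutive beads should touch)
  and excluded volume (non-bonded beads should not overlap), quadratic
  soft-wall penalties;
* crosslinks — a per-link sigmoidal likelihood on bead-surface distance,
  with a false-positive floor ψ and structural uncertainty σ;
* EM density — normalised Gaussian overlap (cross-correlation) between a
  per-bead model GMM and a data GMM.

Posterior repartitioning moves a random subset of the crosslinks into
the sampling prior (together with stereochemistry) while the remaining
restraints form the likelihood; the product of the two is invariant to
the split, which is what makes the trick legitimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import erf, logsumexp

from .representation import BeadModel

__all__ = [
    "Crosslink",
    "CrosslinkDataset",
    "GMMDensity",
    "RestraintPartition",
    "StereochemistryRestraint",
    "CrosslinkRestraint",
    "EMDensityRestraint",
    "RepartitionedScore",
    "score_stereochemistry",
    "score_crosslinks",
    "score_em",
    "partition_restraints",
    "modified_log_prior",
    "log_likelihood",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Crosslink:
    """One chemical crosslink between two residues (unordered pair)."""

    chain1: str
    residue1: int
    chain2: str
    residue2: int

    def canonical(self) -> "Crosslink":
        a = (self.chain1, self.residue1)
        b = (self.chain2, self.residue2)
        if b < a:
            a, b = b, a
        return Crosslink(a[0], a[1], b[0], b[1])


@dataclass(frozen=True)
class CrosslinkDataset:
    """A set of crosslinks with the linker/forward-model parameters.

    ``d0`` is the effective linker length (Å), ``psi`` the false-positive
    weight in [0, 0.5), ``sigma`` the structural uncertainty (Å) that
    also absorbs the coarse-graining error of the representation.
    """

    links: tuple[Crosslink, ...]
    d0: float = 21.0
    psi: float = 0.05
    sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("linker length d0 must be positive")
        if not (0.0 <= self.psi < 0.5):
            raise ValueError("psi must lie in [0, 0.5)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(
            self, "links", tuple(l.canonical() for l in self.links)
        )

    def __len__(self) -> int:
        return len(self.links)

    def subset(self, indices: Sequence[int]) -> "CrosslinkDataset":
        return replace(self, links=tuple(self.links[i] for i in indices))


@dataclass(frozen=True)
class GMMDensity:
    """A density map approximated as a 3-D Gaussian mixture."""

    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, 3), Å
    covariances: np.ndarray  # (k, 3, 3), Å^2

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float).reshape(-1, 3)
        c = np.asarray(self.covariances, dtype=float).reshape(-1, 3, 3)
        if not (len(w) == len(m) == len(c)):
            raise ValueError("weights, means, covariances must have equal length")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and sum > 0")
        for cov in c:
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError("covariances must be symmetric")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError("covariances must be positive-definite")
        object.__setattr__(self, "weights", w / w.sum())
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class RestraintPartition:
    """The prior/likelihood split of the crosslink data.

    ``prior_links`` joins the stereochemistry restraints to form the
    modified sampling prior π; ``likelihood_links`` (plus the EM term,
    when enabled) form the likelihood L.  The two sets are disjoint and
    exhaustive.
    """

    prior_links: CrosslinkDataset
    likelihood_links: CrosslinkDataset
    use_em_in_likelihood: bool = True
    partition_seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.prior_links.links) & set(self.likelihood_links.links)
        if overlap:
            raise ValueError(f"prior and likelihood links overlap: {overlap}")


def partition_restraints(
    links: CrosslinkDataset, fraction: float, seed: int, use_em_in_likelihood: bool = True
) -> RestraintPartition:
    """Randomly assign ``round(fraction * n)`` links to the prior set.

    Deterministic given ``seed``; the remaining links (and the EM term,
    if enabled) inform the likelihood.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    n = len(links)
    n_prior = int(math.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=n_prior, replace=False).tolist()) if n_prior else set()
    prior_idx = [i for i in range(n) if i in chosen]
    lik_idx = [i for i in range(n) if i not in chosen]
    return RestraintPartition(
        prior_links=links.subset(prior_idx),
        likelihood_links=links.subset(lik_idx),
        use_em_in_likelihood=use_em_in_likelihood,
        partition_seed=seed,
    )


# ---------------------------------------------------------------------------
# stereochemistry


class StereochemistryRestraint:
    """Connectivity + excluded-volume prior on a bead model.

    log-probability (up to a constant) is
    ``-(Σ_bonded k_c·max(0, gap)² + Σ_nonbonded k_ev·max(0, overlap)²)``
    with ``gap = d − (r_i + r_j + slack)`` for consecutive beads of a
    chain and ``overlap = (r_i + r_j) − d`` for all other pairs.  Pairs
    inside one rigid body are fixed by construction and skipped.
    Pair index arrays are precomputed once per model topology so that
    evaluation is pure vectorised numpy on the coordinate array.
    """

    def __init__(
        self,
        model: BeadModel,
        k_connect: float = 1.0,
        k_excluded: float = 1.0,
        slack: float = 2.0,
    ) -> None:
        self.k_connect = k_connect
        self.k_excluded = k_excluded
        self.slack = slack
        radii = model.radii
        body = np.array(
            [-1 if b.rigid_body is None else b.rigid_body for b in model.beads]
        )

        bonded = []
        for idx in model.chain_bead_indices().values():
            for a, b in zip(idx[:-1], idx[1:]):
                bonded.append((a, b))
        bonded_set = set(bonded)

        n = model.n_beads
        iu, ju = np.triu_indices(n, k=1)
        same_body = (body[iu] == body[ju]) & (body[iu] >= 0)
        is_bonded = np.array([(a, b) in bonded_set for a, b in zip(iu, ju)])

        keep_b = is_bonded & ~same_body
        keep_nb = ~is_bonded & ~same_body
        self._bi, self._bj = iu[keep_b], ju[keep_b]
        self._ni, self._nj = iu[keep_nb], ju[keep_nb]
        self._bsum = radii[self._bi] + radii[self._bj]
        self._nsum = radii[self._ni] + radii[self._nj]

    def log_prob(self, coords: np.ndarray) -> float:
        total = 0.0
        if len(self._bi):
            d = np.linalg.norm(coords[self._bi] - coords[self._bj], axis=1)
            gap = np.maximum(0.0, d - (self._bsum + self.slack))
            total += self.k_connect * float(gap @ gap)
        if len(self._ni):
            d = np.linalg.norm(coords[self._ni] - coords[self._nj], axis=1)
            ov = np.maximum(0.0, self._nsum - d)
            total += self.k_excluded * float(ov @ ov)
        return -total


def score_stereochemistry(
    model: BeadModel,
    k_connect: float = 1.0,
    k_excluded: float = 1.0,
    slack: float = 2.0,
) -> float:
    """Stereochemistry log-probability of one model (convenience wrapper)."""
    return StereochemistryRestraint(model, k_connect, k_excluded, slack).log_prob(
        model.coords
    )


# ---------------------------------------------------------------------------
# crosslinks


class CrosslinkRestraint:
    """Sigmoidal Bayesian crosslink likelihood on bead-surface distances.

    Per link: ``log[ψ + (1 − 2ψ)·S(d)]`` with
    ``S(d) = ½(1 − erf((d − d0)/(σ√2)))`` and
    ``d = max(0, |x_i − x_j| − r_i − r_j)`` the distance between bead
    surfaces.  Surface (rather than center) distance keeps coarse beads
    from being spuriously penalised: it is the channel through which the
    representation changes the fit.
    """

    def __init__(self, model: BeadModel, links: CrosslinkDataset) -> None:
        self.links = links
        r2b = model.residue_to_bead()
        radii = model.radii
        li, lj = [], []
        for link in links.links:
            try:
                a = r2b[(link.chain1, link.residue1)]
                b = r2b[(link.chain2, link.residue2)]
            except KeyError:
                raise KeyError(
                    f"crosslink {link.chain1}:{link.residue1}-"
                    f"{link.chain2}:{link.residue2} references a residue "
                    f"absent from the model"
                ) from None
            li.append(a)
            lj.append(b)
        self._i = np.array(li, dtype=int)
        self._j = np.array(lj, dtype=int)
        self._rsum = radii[self._i] + radii[self._j] if len(links) else np.zeros(0)

    def log_prob(self, coords: np.ndarray) -> float:
        if len(self._i) == 0:
            return 0.0
        d = np.linalg.norm(coords[self._i] - coords[self._j], axis=1)
        surf = np.maximum(0.0, d - self._rsum)
        ds = self.links
        s = 0.5 * (1.0 - erf((surf - ds.d0) / (ds.sigma * math.sqrt(2.0))))
        return float(np.sum(np.log(ds.psi + (1.0 - 2.0 * ds.psi) * s)))


def score_crosslinks(model: BeadModel, links: CrosslinkDataset) -> float:
    """Crosslink log-likelihood of one model (convenience wrapper)."""
    return CrosslinkRestraint(model, links).log_prob(model.coords)


# ---------------------------------------------------------------------------
# EM density


def _pairwise_overlap_iso_full(
    means_a: np.ndarray,
    var_a: np.ndarray,
    means_b: np.ndarray,
    cov_b: np.ndarray,
) -> np.ndarray:
    """Gaussian product integrals ∫ N(x; m_a, v_a·I) N(x; m_b, C_b) dx.

    Returns an (n_a, n_b) matrix, evaluated in the eigenbasis of each
    data covariance so adding the isotropic model variance is diagonal.
    """
    out = np.empty((len(means_a), len(means_b)))
    for j in range(len(means_b)):
        lam, q = np.linalg.eigh(cov_b[j])
        delta = (means_a - means_b[j]) @ q  # rotate into eigenbasis
        s = var_a[:, None] + lam[None, :]  # (n_a, 3)
        logdet = np.sum(np.log(s), axis=1)
        quad = np.sum(delta * delta / s, axis=1)
        out[:, j] = np.exp(-0.5 * (3 * LOG_2PI + logdet + quad))
    return out


def _pairwise_overlap_full_full(means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Gaussian product integrals between all pairs of full-covariance components."""
    k = len(means)
    out = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            s = covs[i] + covs[j]
            sign, logdet = np.linalg.slogdet(s)
            delta = means[i] - means[j]
            quad = float(delta @ np.linalg.solve(s, delta))
            out[i, j] = math.exp(-0.5 * (3 * LOG_2PI + logdet + quad))
    return out


def _pairwise_overlap_iso_iso(
    means: np.ndarray, var: np.ndarray, means2: np.ndarray, var2: np.ndarray
) -> np.ndarray:
    s = var[:, None] + var2[None, :]
    d2 = np.sum((means[:, None, :] - means2[None, :, :]) ** 2, axis=2)
    return np.exp(-0.5 * (3 * LOG_2PI + 3 * np.log(s) + d2 / s))


class EMDensityRestraint:
    """Normalised Gaussian-overlap score of a model GMM against a data GMM.

    The model GMM has one isotropic component per bead (mean = center,
    variance = radius², weight ∝ residue count).  The score is
    ``w_em · log(cc)`` where ``cc = ⟨f,g⟩ / (‖f‖·‖g‖)`` is evaluated with
    closed-form Gaussian product integrals and clamped to [ε, 1].
    """

    def __init__(
        self,
        model: BeadModel,
        density: GMMDensity,
        weight: float = 1.0,
        eps: float = 1e-12,
    ) -> None:
        if model.n_beads == 0:
            raise ValueError("empty model")
        self.weight = weight
        self.eps = eps
        self.density = density
        self._var = model.radii**2
        self._w = np.array([b.n_residues for b in model.beads], dtype=float)
        self._w /= self._w.sum()
        # data-data norm is a constant of the run
        gg = _pairwise_overlap_full_full(density.means, density.covariances)
        self._norm_g = math.sqrt(
            float(density.weights @ gg @ density.weights)
        )

    def cross_correlation(self, coords: np.ndarray) -> float:
        fg = _pairwise_overlap_iso_full(
            coords, self._var, self.density.means, self.density.covariances
        )
        ff = _pairwise_overlap_iso_iso(coords, self._var, coords, self._var)
        num = float(self._w @ fg @ self.density.weights)
        norm_f = math.sqrt(float(self._w @ ff @ self._w))
        cc = num / (norm_f * self._norm_g)
        return float(np.clip(cc, self.eps, 1.0))

    def log_prob(self, coords: np.ndarray) -> float:
        return self.weight * math.log(self.cross_correlation(coords))


def score_em(
    model: BeadModel, density: GMMDensity, weight: float = 1.0, eps: float = 1e-12
) -> float:
    """EM-density log-likelihood of one model (convenience wrapper)."""
    return EMDensityRestraint(model, density, weight, eps).log_prob(model.coords)


# ---------------------------------------------------------------------------
# repartitioned scoring function


@dataclass
class ScoreParams:
    """Tunables of the combined scoring function."""

    k_connect: float = 1.0
    k_excluded: float = 1.0
    slack: float = 2.0
    em_weight: float = 1.0
    em_eps: float = 1e-12
    box_halfside: float = 300.0  # uniform support of the prior, Å


class RepartitionedScore:
    """Modified prior π and likelihood L for one model topology.

    π = stereochemistry + prior-subset crosslinks, truncated to a
    uniform bounding box (so the prior mass is proper);
    L = remaining crosslinks (+ EM overlap when enabled).
    π·L is invariant to the crosslink split — repartitioning only moves
    probability mass between the two factors.
    """

    def __init__(
        self,
        model: BeadModel,
        partition: RestraintPartition,
        density: GMMDensity | None = None,
        params: ScoreParams | None = None,
    ) -> None:
        self.params = params or ScoreParams()
        self.partition = partition
        self.stereo = StereochemistryRestraint(
            model, self.params.k_connect, self.params.k_excluded, self.params.slack
        )
        self.prior_xl = CrosslinkRestraint(model, partition.prior_links)
        self.lik_xl = CrosslinkRestraint(model, partition.likelihood_links)
        self.em: EMDensityRestraint | None = None
        if density is not None and partition.use_em_in_likelihood:
            self.em = EMDensityRestraint(
                model, density, self.params.em_weight, self.params.em_eps
            )

    def log_prior(self, coords: np.ndarray) -> float:
        if np.any(np.abs(coords) > self.params.box_halfside):
            return -np.inf
        return self.stereo.log_prob(coords) + self.prior_xl.log_prob(coords)

    def log_likelihood(self, coords: np.ndarray) -> float:
        val = self.lik_xl.log_prob(coords)
        if self.em is not None:
            val += self.em.log_prob(coords)
        return val


def modified_log_prior(
    model: BeadModel,
    partition: RestraintPartition,
    params: ScoreParams | None = None,
) -> float:
    """log π(θ): stereochemistry plus the prior crosslink subset."""
    return RepartitionedScore(model, partition, None, params).log_prior(model.coords)


def log_likelihood(
    model: BeadModel,
    partition: RestraintPartition,
    density: GMMDensity | None = None,
    params: ScoreParams | None = None,
) -> float:
    """log L(θ): the likelihood crosslink subset plus the EM term."""
    return RepartitionedScore(model, partition, density, params).log_likelihood(
        model.coords
    )
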