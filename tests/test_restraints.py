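import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestor.representation import (
    Bead,
    BeadModel,
    ChainTopology,
    RepresentationScheme,
    coarse_grain,
    initialize_coordinates,
)
from nestor.restraints import (
    Crosslink,
    CrosslinkDataset,
    CrosslinkRestraint,
    EMDensityRestraint,
    GMMDensity,
    RepartitionedScore,
    RestraintPartition,
    log_likelihood,
    modified_log_prior,
    partition_restraints,
    score_crosslinks,
    score_em,
    score_stereochemistry,
)


def two_bead_model(distance, radius=2.0, same_chain=False):
    """Two beads ``distance`` apart; same chain -> bonded, else non-bonded."""
    beads = (
        Bead("A", 1, 1, radius),
        Bead("A" if same_chain else "B", 2 if same_chain else 1, 2 if same_chain else 1, radius),
    )
    coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    return BeadModel(beads, coords)


class TestStereochemistry:
    def test_bonded_pair_touching_scores_zero(self):
        m = two_bead_model(4.0, radius=2.0, same_chain=True)  # d = r1 + r2
        assert score_stereochemistry(m) == 0.0

    def test_coincident_nonbonded_pair_penalised_quadratically(self):
        # overlap = (2 + 2) - 0 = 4 -> -k_ev * 16
        m = two_bead_model(0.0, radius=2.0)
        assert score_stereochemistry(m, k_excluded=1.0) == pytest.approx(-16.0)

    def test_bonded_gap_penalised(self):
        # gap = 10 - (2 + 2 + slack 2) = 4 -> -16
        m = two_bead_model(10.0, radius=2.0, same_chain=True)
        assert score_stereochemistry(m) == pytest.approx(-16.0)

    def test_rigid_transform_invariance(self, rng):
        top = ChainTopology.unstructured("A", 40)
        model = initialize_coordinates(
            coarse_grain(top, RepresentationScheme.uniform(5)), rng
        )
        base = score_stereochemistry(model)
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.linalg.det(q))
        moved = model.with_coords(model.coords @ q.T + np.array([11.0, -3.0, 7.0]))
        assert score_stereochemistry(moved) == pytest.approx(base, abs=1e-9)


class TestCrosslinks:
    def make(self, surface_distance, **params):
        radius = 2.0
        m = two_bead_model(surface_distance + 2 * radius, radius=radius)
        links = CrosslinkDataset(
            (Crosslink("A", 1, "B", 1),), **{"d0": 21.0, "psi": 0.05, "sigma": 10.0, **params}
        )
        return m, links

    def test_at_linker_length_term_is_log_half(self):
        m, links = self.make(21.0)
        assert score_crosslinks(m, links) == pytest.approx(math.log(0.5))

    def test_far_limit_is_log_psi(self):
        m, links = self.make(500.0)
        assert score_crosslinks(m, links) == pytest.approx(math.log(0.05), abs=1e-9)

    def test_satisfied_limit_approaches_log_one_minus_psi(self):
        m, links = self.make(0.0, sigma=2.0)  # d0 >> sigma
        assert score_crosslinks(m, links) == pytest.approx(math.log(0.95), abs=1e-3)

    def test_term_bounded_between_log_psi_and_log_one_minus_psi(self, rng):
        m, links = self.make(0.0)
        for d in rng.uniform(0, 200, size=50):
            mm = two_bead_model(d + 4.0)
            s = score_crosslinks(mm, links)
            assert math.log(0.05) - 1e-12 <= s <= math.log(0.95) + 1e-12

    def test_monotone_in_surface_distance(self):
        _, links = self.make(0.0)
        ds = np.linspace(0, 120, 60)
        scores = [score_crosslinks(two_bead_model(d + 4.0), links) for d in ds]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_unknown_residue_names_the_link(self):
        m, _ = self.make(10.0)
        bad = CrosslinkDataset((Crosslink("A", 1, "C", 99),))
        with pytest.raises(KeyError, match="C:99"):
            CrosslinkRestraint(m, bad)


class TestEMDensity:
    def test_identical_gmms_give_unit_correlation(self):
        m = two_bead_model(10.0, radius=2.0)
        density = GMMDensity(
            weights=np.array([0.5, 0.5]),
            means=m.coords.copy(),
            covariances=np.array([np.eye(3) * 4.0] * 2),
        )
        assert score_em(m, density) == pytest.approx(0.0, abs=1e-12)

    def test_far_displacement_hits_epsilon_floor(self):
        beads = (Bead("A", 1, 1, 1.0),)
        m = BeadModel(beads, np.array([[1000.0, 0.0, 0.0]]))
        density = GMMDensity(np.array([1.0]), np.zeros((1, 3)), np.array([np.eye(3)]))
        assert score_em(m, density, eps=1e-12) == pytest.approx(math.log(1e-12))

    def test_unit_variance_pair_closed_form(self):
        # single unit-variance bead vs unit-variance component at distance 2:
        # cc = exp(-d^2 / 4) = e^-1
        beads = (Bead("A", 1, 1, 1.0),)
        m = BeadModel(beads, np.array([[2.0, 0.0, 0.0]]))
        density = GMMDensity(np.array([1.0]), np.zeros((1, 3)), np.array([np.eye(3)]))
        r = EMDensityRestraint(m, density)
        assert r.cross_correlation(m.coords) == pytest.approx(math.exp(-1.0), rel=1e-9)

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_matches_grid_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_beads, n_comp = rng.integers(1, 4), rng.integers(1, 4)
        beads = tuple(Bead("A", i + 1, i + 1, float(rng.uniform(1, 3))) for i in range(n_beads))
        coords = rng.uniform(-5, 5, size=(n_beads, 3))
        model = BeadModel(beads, coords)
        means = rng.uniform(-5, 5, size=(n_comp, 3))
        covs = []
        for _ in range(n_comp):
            a = rng.normal(size=(3, 3))
            covs.append(a @ a.T + 3.0 * np.eye(3))
        density = GMMDensity(rng.uniform(0.5, 2, size=n_comp), means, np.array(covs))
        r = EMDensityRestraint(model, density)

        # brute-force cross-correlation on a regular grid
        ax = np.arange(-25.0, 25.0, 0.8)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

        def gmm_eval(w, mu, cov):
            out = np.zeros(len(pts))
            for wi, mi, ci in zip(w, mu, cov):
                d = pts - mi
                inv = np.linalg.inv(ci)
                quad = np.einsum("ij,jk,ik->i", d, inv, d)
                out += (
                    wi
                    * np.exp(-0.5 * quad)
                    / np.sqrt((2 * np.pi) ** 3 * np.linalg.det(ci))
                )
            return out

        w_model = np.array([b.n_residues for b in beads], float)
        w_model /= w_model.sum()
        f = gmm_eval(w_model, coords, [np.eye(3) * b.radius**2 for b in beads])
        g = gmm_eval(density.weights, density.means, density.covariances)
        cc_grid = float(f @ g / np.sqrt((f @ f) * (g @ g)))
        assert r.cross_correlation(coords) == pytest.approx(cc_grid, abs=1e-3)

    def test_rejects_non_positive_definite_covariance(self):
        with pytest.raises(ValueError):
            GMMDensity(
                np.array([1.0]),
                np.zeros((1, 3)),
                np.array([np.diag([1.0, -1.0, 1.0])]),
            )


class TestPartition:
    def links(self, n=10):
        return CrosslinkDataset(
            tuple(Crosslink("A", i + 1, "B", i + 1) for i in range(n))
        )

    def test_fraction_rounding(self):
        p = partition_restraints(self.links(10), 0.3, seed=1)
        assert len(p.prior_links) == 3 and len(p.likelihood_links) == 7

    def test_zero_fraction_empty_prior(self):
        p = partition_restraints(self.links(10), 0.0, seed=1)
        assert len(p.prior_links) == 0 and len(p.likelihood_links) == 10

    def test_deterministic_and_disjoint(self):
        a = partition_restraints(self.links(20), 0.3, seed=42)
        b = partition_restraints(self.links(20), 0.3, seed=42)
        assert a.prior_links.links == b.prior_links.links
        assert not set(a.prior_links.links) & set(a.likelihood_links.links)
        assert set(a.prior_links.links) | set(a.likelihood_links.links) == set(
            self.links(20).links
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            partition_restraints(self.links(), 1.0, seed=0)
        with pytest.raises(ValueError):
            partition_restraints(self.links(), -0.1, seed=0)


class TestRepartitioning:
    def test_zero_fraction_prior_is_stereochemistry_alone(self, mixed_preset, rng):
        assembly, links, _ = mixed_preset
        model = initialize_coordinates(
            coarse_grain(assembly.topologies, RepresentationScheme.uniform(10)), rng
        )
        p0 = partition_restraints(links, 0.0, seed=1)
        assert modified_log_prior(model, p0) == pytest.approx(
            score_stereochemistry(model), abs=1e-9
        )

    def test_no_links_no_density_likelihood_is_zero(self, rng):
        top = ChainTopology.unstructured("A", 30)
        model = initialize_coordinates(
            coarse_grain(top, RepresentationScheme.uniform(10)), rng
        )
        p = partition_restraints(CrosslinkDataset(()), 0.0, seed=0)
        assert log_likelihood(model, p) == 0.0

    def test_posterior_invariant_across_partitions(self, mixed_preset, rng):
        # pi * L unchanged by re-splitting the same links (EM fixed)
        assembly, links, density = mixed_preset
        template = coarse_grain(assembly.topologies, RepresentationScheme.uniform(10))
        for _ in range(10):
            model = initialize_coordinates(template, rng)
            totals = []
            for seed in (1, 2, 3):
                p = partition_restraints(links, 0.3, seed=seed)
                totals.append(
                    modified_log_prior(model, p)
                    + log_likelihood(model, p, density)
                )
            assert max(totals) - min(totals) < 1e-9
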