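import numpy as np
import pytest

from nestor.representation import RepresentationScheme, coarse_grain
from nestor.restraints import partition_restraints, score_em
from nestor.synthetic import (
    BOND_LENGTH,
    MIN_SEPARATION,
    generate_assembly,
    make_preset,
    simulate_crosslinks,
    simulate_density,
)


def reference_bead_model(assembly, rpb):
    """Beads placed at the centroids of their residues' reference CAs."""
    model = coarse_grain(assembly.topologies, RepresentationScheme.uniform(rpb))
    ref = assembly.reference_map()
    coords = np.array(
        [
            np.mean(
                [ref[(b.chain_id, r)] for r in range(b.first_residue, b.last_residue + 1)],
                axis=0,
            )
            for b in model.beads
        ]
    )
    return model.with_coords(coords)


class TestAssemblyGeneration:
    def test_bond_lengths_exact_and_no_clashes(self):
        asm = generate_assembly([80, 60], [0.2, 0.8], seed=5)
        pts = asm.all_coordinates()
        for cid in ("A", "B"):
            xyz = asm.coordinates[cid]
            d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            np.testing.assert_allclose(d, BOND_LENGTH, atol=1e-6)
        pair = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(pair, np.inf)
        assert pair.min() >= MIN_SEPARATION - 1e-9

    def test_same_seed_reproduces_coordinates(self):
        a = generate_assembly([50], [0.5], seed=9)
        b = generate_assembly([50], [0.5], seed=9)
        np.testing.assert_array_equal(a.coordinates["A"], b.coordinates["A"])

    def test_compactness_controls_radius_of_gyration(self):
        # extended coils are statistically larger than collapsed globules
        def rg(xyz):
            c = xyz.mean(axis=0)
            return np.sqrt(np.mean(np.sum((xyz - c) ** 2, axis=1)))

        wins = 0
        for seed in range(10):
            ext = generate_assembly([200], [0.0], seed=seed)
            cmp_ = generate_assembly([200], [1.0], seed=seed)
            if rg(ext.coordinates["A"]) > rg(cmp_.coordinates["A"]):
                wins += 1
        assert wins == 10

    def test_short_chains_rejected(self):
        with pytest.raises(ValueError):
            generate_assembly([5], [0.0], seed=0)


class TestCrosslinkSimulation:
    def test_zero_fp_rate_links_respect_cutoff(self):
        asm = generate_assembly([120], [0.7], seed=3)
        links = simulate_crosslinks(asm, 30, d_max=21.0, fp_rate=0.0, seed=1)
        ref = asm.reference_map()
        assert len(links) == 30
        for l in links.links:
            d = np.linalg.norm(ref[(l.chain1, l.residue1)] - ref[(l.chain2, l.residue2)])
            assert d <= 21.0

    def test_full_fp_rate_links_violate_cutoff(self):
        # an extended coil has plenty of far pairs to draw decoys from
        asm = generate_assembly([150], [0.0], seed=3)
        links = simulate_crosslinks(asm, 15, d_max=21.0, fp_rate=1.0, seed=1)
        ref = asm.reference_map()
        for l in links.links:
            d = np.linalg.norm(ref[(l.chain1, l.residue1)] - ref[(l.chain2, l.residue2)])
            assert d > 21.0

    def test_no_duplicate_pairs_and_count_conserved(self):
        asm = generate_assembly([150], [0.8], seed=4)
        links = simulate_crosslinks(asm, 40, fp_rate=0.1, seed=2)
        assert len(links) == 40
        assert len(set(links.links)) == 40

    def test_insufficient_candidates_reports_counts(self):
        asm = generate_assembly([12], [0.0], seed=0)
        with pytest.raises(ValueError, match="insufficient"):
            simulate_crosslinks(asm, 500, fp_rate=0.0, seed=0)


class TestDensitySimulation:
    def test_single_component_sits_at_global_centroid(self):
        asm = generate_assembly([60], [0.5], seed=6)
        dens = simulate_density(asm, 1, seed=0)
        np.testing.assert_allclose(
            dens.means[0], asm.all_coordinates().mean(axis=0), atol=1e-9
        )
        assert dens.weights.sum() == pytest.approx(1.0)

    def test_weights_normalised_for_many_components(self):
        asm = generate_assembly([100], [0.6], seed=7)
        dens = simulate_density(asm, 8, seed=1)
        assert len(dens) == 8
        assert dens.weights.sum() == pytest.approx(1.0)

    def test_too_many_components_rejected(self):
        asm = generate_assembly([20], [0.5], seed=0)
        with pytest.raises(ValueError):
            simulate_density(asm, 21, seed=0)

    def test_true_structure_outscores_shuffled_coordinates(self):
        # self-consistency: the density must prefer the model it was
        # simulated from over an impostor whose residues were scrambled
        # before coarse-graining (bead centroids of random residue sets
        # collapse toward the global centre of mass)
        asm = generate_assembly([90], [0.4], seed=8)
        dens = simulate_density(asm, 8, seed=2)
        model = reference_bead_model(asm, 5)
        true_score = score_em(model, dens)
        xyz = asm.coordinates["A"]
        rng = np.random.default_rng(0)
        for _ in range(10):
            scrambled = xyz[rng.permutation(len(xyz))]
            centroids = np.array(
                [
                    scrambled[b.first_residue - 1 : b.last_residue].mean(axis=0)
                    for b in model.beads
                ]
            )
            assert true_score >= score_em(model.with_coords(centroids), dens)


class TestPresets:
    @pytest.mark.parametrize("name", ["extended", "globular", "mixed"])
    def test_presets_are_reproducible(self, name):
        a1, l1, d1 = make_preset(name)
        a2, l2, d2 = make_preset(name)
        for cid in a1.coordinates:
            np.testing.assert_array_equal(a1.coordinates[cid], a2.coordinates[cid])
        assert l1.links == l2.links
        np.testing.assert_array_equal(d1.means, d2.means)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            make_preset("nope")

    def test_mixed_preset_matches_stated_conditions(self, mixed_preset):
        assembly, links, density = mixed_preset
        assert len(assembly.topologies) == 2
        assert len(links) == 60
        assert len(density) == 10


def test_evidence_rank_tracks_posthoc_crosslink_fit(mixed_preset):
    """Across schemes, evidence and post-run crosslink fit move together.

    The fit metric is the average per-link crosslink score of the final
    live models (the good-scoring ensemble of each run), mirroring how
    fit-to-data is assessed after production sampling.
    """
    import warnings

    from scipy.stats import spearmanr

    from nestor.ns import run_nested_sampling
    from nestor.representation import RepresentationScheme, coarse_grain
    from nestor.restraints import CrosslinkRestraint, RepartitionedScore
    from nestor.sampler import MoveSet
    from nestor.ns import StructuralProblem

    assembly, links, density = mixed_preset
    part = partition_restraints(links, 0.3, seed=11)
    evidences, fits = [], []
    for rpb in (1, 5, 10, 20, 50):
        model = coarse_grain(assembly.topologies, RepresentationScheme.uniform(rpb))
        score = RepartitionedScore(model, part, density)
        problem = StructuralProblem(
            model, score, MoveSet(n_replicas=2), mcmc_steps=25,
            reference=assembly.reference_map(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = run_nested_sampling(problem, n_live=15, max_iterations=250, rng=77)
        all_links = CrosslinkRestraint(model, links)
        # final live set = the good-scoring ensemble of the run
        fit = np.mean(
            [all_links.log_prob(np.asarray(c)) / len(links) for c in r.live_states]
        )
        evidences.append(r.log_Z)
        fits.append(fit)
    rho = spearmanr(evidences, fits).statistic
    assert rho > 0
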