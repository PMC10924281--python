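import numpy as np
import pytest

from nestor import (
    MoveSet,
    RepartitionedScore,
    RepresentationScheme,
    StructuralProblem,
    coarse_grain,
    make_preset,
    partition_restraints,
)

# Reduced sampler settings shared by the heavier tests: small replica
# count and short segments keep runs in seconds while exercising every
# code path.
FAST = dict(mcmc_steps=25, moveset=MoveSet(n_replicas=2))


@pytest.fixture(scope="session")
def mixed_preset():
    return make_preset("mixed")


@pytest.fixture(scope="session")
def globular_preset():
    return make_preset("globular")


@pytest.fixture(scope="session")
def extended_preset():
    return make_preset("extended")


def build_problem(preset, rpb, partition_seed=7, fraction=0.3, **kwargs):
    """Structural NS problem on a preset at reduced settings."""
    assembly, links, density = preset
    part = partition_restraints(links, fraction, seed=partition_seed)
    model = coarse_grain(assembly.topologies, RepresentationScheme.uniform(rpb))
    score = RepartitionedScore(model, part, density)
    opts = {**FAST, **kwargs}
    return StructuralProblem(
        model, score, opts["moveset"], mcmc_steps=opts["mcmc_steps"],
        reference=assembly.reference_map(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)
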