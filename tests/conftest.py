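"""Shared fixtures: synthetic pocket sets and seeded rigid motions.

The heavyweight three-class set (3 classes × 8 seeds, full default
parameters) is session-scoped because the class-recovery and
mutant-projection checks both consume it.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from biogps.compare import all_against_all, describe_site
from biogps.fixtures import CLASS_FRACTIONS, PocketRecipe, make_class_set, make_toy_pocket
from biogps.structure_io import RigidTransform
from biogps.upca import fit_upca


def random_rigid(seed: int, max_shift: float = 10.0) -> RigidTransform:
    """A seeded uniformly random proper rigid motion."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.uniform(-max_shift, max_shift, 3))


@pytest.fixture(scope="session")
def toy_site():
    """One default-parameter site description of a donor-rich cup."""
    return describe_site(make_toy_pocket(PocketRecipe(seed=11), "toy"))


@pytest.fixture(scope="session")
def small_site_pair():
    """A donor-rich and a hydrophobic site, reduced budgets (fast)."""
    d = make_toy_pocket(PocketRecipe(seed=21, fractions=CLASS_FRACTIONS["donor"]), "donor21")
    h = make_toy_pocket(PocketRecipe(seed=22, fractions=CLASS_FRACTIONS["dry"]), "dry22")
    kw = dict(k_max=10, max_pooled=20)
    return describe_site(d, **kw), describe_site(h, **kw)


@pytest.fixture(scope="session")
def class_structs():
    """3 classes × 8 seeds of synthetic pockets (the study-condition set)."""
    return make_class_set(per_class=8, seed=7)


@pytest.fixture(scope="session")
def class_sites(class_structs):
    return [describe_site(s) for s in class_structs]


@pytest.fixture(scope="session")
def class_sims(class_sites):
    return all_against_all(class_sites)


@pytest.fixture(scope="session")
def class_model(class_sims):
    model, emb = fit_upca(class_sims, which="global", n_components=2)
    return model, emb
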