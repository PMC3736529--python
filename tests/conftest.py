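"""Shared fixtures: small synthetic embryos and a hand-built toy path atlas."""

import numpy as np
import pytest

from stripefit import atlas as atlas_mod
from stripefit import labeling as lab
from stripefit import synthetic as syn


@pytest.fixture(scope="session")
def truth_model():
    return syn.stripe2_like_truth()


@pytest.fixture(scope="session")
def small_spec():
    return syn.default_spec(n_nuclei=1500, seed=11)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    """1500-nucleus stripe-2-like embryo with a noise-free target."""
    return syn.generate_atlas(small_spec)


@pytest.fixture(scope="session")
def small_labels(small_atlas):
    return lab.label_target(small_atlas, "eve")


@pytest.fixture(scope="session")
def noisy_atlas():
    """Bernoulli-sampled target; fits stay away from separation blow-up."""
    spec = syn.SyntheticSpec(n_nuclei=3000, seed=21, patterns=syn.stripe2_like_patterns(),
                             truth_model=syn.recovery_truth(), noise="bernoulli")
    return syn.generate_atlas(spec)


@pytest.fixture(scope="session")
def noisy_training_set(noisy_atlas):
    truth = syn.recovery_truth()
    regs = list(truth.spec.regulators)
    X = np.column_stack([noisy_atlas.values(g, kind=k) for g, k in regs])
    return lab.TrainingSet(noisy_atlas.nucleus_ids.copy(), X,
                           noisy_atlas.values("eve").copy(), regs, frozenset())


def make_path_atlas(n=10, on_ids=(5, 6)):
    """Nuclei on a line with a path neighbor graph and a binary target."""
    ids = np.arange(1, n + 1)
    neighbors = []
    for i in ids:
        nb = [j for j in (i - 1, i + 1) if 1 <= j <= n]
        neighbors.append(np.array(nb))
    target = np.isin(ids, on_ids).astype(float)
    reg = np.linspace(0.0, 1.0, n)
    channels = [
        atlas_mod.GeneChannel("eve", atlas_mod.MRNA, 1, target),
        atlas_mod.GeneChannel("regA", atlas_mod.MRNA, 1, reg),
    ]
    a = atlas_mod.ExpressionAtlas(
        nucleus_ids=ids, x=10.0 * ids.astype(float),
        y=np.zeros(n), z=np.zeros(n),
        neighbors=neighbors, channels=channels)
    a.validate()
    return a


@pytest.fixture()
def path_atlas():
    return make_path_atlas()
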