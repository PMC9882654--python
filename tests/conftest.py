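import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True)
settings.load_profile("suite")

from rasevol.io import ProteinRecord
from rasevol.simulate import archetype, balanced_tree, build_archetypes, evolve_family


@pytest.fixture(scope="session")
def archetypes():
    return build_archetypes()


@pytest.fixture(scope="session")
def template_records(archetypes):
    """One noiseless record per archetype template."""
    return [
        ProteinRecord(id=t.label.replace("-", "_"), residues=t.sequence,
                      species=f"synthetic {t.label}", clade_label=t.clade)
        for t in archetypes
    ]


@pytest.fixture(scope="session")
def kras4b_family():
    """12-leaf masked KRAS4B-like family at moderate divergence."""
    template = archetype("KRAS4B-like")
    records, truth = evolve_family(template, balanced_tree(12, 0.1),
                                   subs_per_site_per_branch=0.1,
                                   mask_respect=True, seed=7)
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
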