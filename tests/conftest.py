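import numpy as np
import pytest

from evofoodweb.trophic_network import Resource, SpeciesTraits
from evofoodweb.biomass_equilibrium import LocalWeb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_web(rng, n_species=None, resource=None, delta=0.25, cutoff=1.0):
    """A random small community assembled with the model's own trait rules.

    Body masses follow the speciation ladder (each within a factor q of a
    previous one), feeding centers sit 1-3 units below body mass, widths in
    [0.5, 1] — so the webs are structurally like evolved ones.
    """
    if n_species is None:
        n_species = int(rng.integers(1, 11))
    if resource is None:
        resource = Resource(0.0, 25.0)
    masses = [float(rng.uniform(1.0, 3.0))]
    while len(masses) < n_species:
        parent = masses[int(rng.integers(0, len(masses)))]
        masses.append(parent + float(rng.uniform(-np.log(5), np.log(5))))
    traits = [
        SpeciesTraits(
            m,
            m - float(rng.uniform(1.0, 3.0)),
            float(rng.uniform(0.5, 1.0)),
        )
        for m in masses
    ]
    ids = list(range(1, n_species + 1))
    return LocalWeb.assemble(ids, traits, resource, delta, cutoff)


@pytest.fixture
def random_web_factory(rng):
    def make(n_species=None, **kw):
        return random_web(rng, n_species, **kw)

    return make
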