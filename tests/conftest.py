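import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from zcmeta.monomers import load_monomers
from zcmeta.pipeline import DatasetManifest
from zcmeta.simulate import GradientSpec, gen_gradient


@pytest.fixture(scope="session")
def monomers():
    return load_monomers()


@pytest.fixture(scope="session")
def gradient_dataset(tmp_path_factory):
    """A coherent synthetic 5-sample gradient (GC and protein composition
    both rising toward the oxidizing end), shared across pipeline tests."""
    out = tmp_path_factory.mktemp("gradient")
    spec = GradientSpec(seed=11)
    manifest_path, truth = gen_gradient(spec, out)
    return DatasetManifest.from_tsv(manifest_path), truth, out
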