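import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")

from gliakit import GeneSpec, build_gamma_gene, load_epitope_db  # noqa: E402
from gliakit.synthetic import sample_gene_spec as random_gene_spec  # noqa: E402,F401


@pytest.fixture(scope="session")
def default_gene():
    """One canonical synthetic γ-gliadin gene with planted epitopes."""
    return build_gamma_gene(
        GeneSpec(seed=1, embedded_epitopes=(("QQPQQPFPQ", 3),)))


@pytest.fixture(scope="session")
def epitope_db():
    return load_epitope_db()
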