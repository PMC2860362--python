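import numpy as np
import pytest

from gopreclust import PreclustConfig, generate, precluster_catalog
from gopreclust.io_annotation import build_membership
from gopreclust.synthgen import benchmark_spec


@pytest.fixture(scope="session")
def benchmark():
    """The planted benchmark, preclustered once and shared across tests.

    20 classes × 24 genes on a 24-point time course; classes 0–4 consist of
    three subgroups at phases 0, π/2, π (noise sd 0.2), the rest are
    homogeneous sinusoids.
    """
    spec = benchmark_spec()
    expression, annotation, truth = generate(spec)
    membership, expression = build_membership(annotation, expression)
    catalog = precluster_catalog(expression, membership, PreclustConfig(seed=42))
    return {
        "spec": spec,
        "expression": expression,
        "membership": membership,
        "truth": truth,
        "catalog": catalog,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def write_tsv(path, text):
    path.write_text(text)
    return path
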