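import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fsqtl.types import GenotypeMatrix, LinkageMap, Marker, SegType

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140620)


@pytest.fixture
def one_of_each_map() -> LinkageMap:
    """Four markers, one per cross type, on one linkage group."""
    return LinkageMap(
        [
            Marker("m_ab", SegType.ABXCD, 1, 0.0),
            Marker("m_hk", SegType.HKXHK, 1, 5.0),
            Marker("m_lm", SegType.LMXLL, 1, 10.0),
            Marker("m_nn", SegType.NNXNP, 1, 15.0),
        ]
    )


def make_genotypes(lmap: LinkageMap, calls: dict[str, list]) -> GenotypeMatrix:
    inds = [f"i{k}" for k in range(len(next(iter(calls.values()))))]
    df = pd.DataFrame.from_dict(calls, orient="index", columns=inds)
    return GenotypeMatrix(df, lmap)


@pytest.fixture
def make_genotypes_fixture():
    return make_genotypes
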