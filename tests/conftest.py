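import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genes():
    """Ten genes on one chromosome plus three on a second."""
    from tandemscape.tandem_finder import GeneModel, assign_ranks

    genes = [
        GeneModel(f"g{i}", "chr01", 1000 * i + 1, 1000 * i + 600) for i in range(10)
    ] + [
        GeneModel(f"h{i}", "chr02", 1000 * i + 1, 1000 * i + 600) for i in range(3)
    ]
    return assign_ranks(genes)


def make_hits(pairs, evalue=1e-50, bitscore=500.0):
    """Build a minimal outfmt-6 frame from (query, subject) tuples."""
    import pandas as pd

    from tandemscape.tandem_finder import HOMOLOGY_COLUMNS

    rows = [
        (q, s, 90.0, 200, 10, 0, 1, 600, 1, 600, evalue, bitscore)
        for q, s in pairs
    ]
    return pd.DataFrame(rows, columns=HOMOLOGY_COLUMNS)
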