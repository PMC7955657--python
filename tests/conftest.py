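import numpy as np
import pytest

from densfam.alignments import Alignment, Region
from densfam.metaclusters import MetaclusteringParams
from densfam.pipeline import run_cluster
from densfam.synthetic import SyntheticConfig, simulate


def make_alignment(
    query_id="Q",
    search_id="S",
    q=(1, 100),
    s=(1, 100),
    evalue=1e-10,
):
    return Alignment(
        query_id=query_id,
        search_id=search_id,
        query_region=Region(query_id, *q),
        search_region=Region(search_id, *s),
        evalue=evalue,
    )


def random_alignments(rng, n, query_id="Q", n_search=None, seq_len=500):
    """Random alignments of one query, for oracle-equivalence checks."""
    n_search = n_search or max(2, n // 3)
    out = []
    for i in range(n):
        qs = int(rng.integers(1, seq_len - 30))
        qe = qs + int(rng.integers(20, 120))
        sid = f"S{int(rng.integers(n_search))}"
        ss = int(rng.integers(1, seq_len - 30))
        se = ss + int(rng.integers(20, 120))
        out.append(
            make_alignment(query_id, sid, (qs, min(qe, seq_len)),
                           (ss, min(se, seq_len)),
                           evalue=float(10.0 ** rng.uniform(-30, -1)))
        )
    return out


@pytest.fixture(scope="session")
def benchmark_config():
    """The planted three-family benchmark: two architectures -A- and -A-B-,
    a third independent family, 300 proteins, 90% detection, endpoint
    jitter SD 3, spurious-alignment rate 0.1 per protein."""
    return SyntheticConfig(rng_seed=20240101)


@pytest.fixture(scope="session")
def benchmark_data(benchmark_config):
    return simulate(benchmark_config)


@pytest.fixture(scope="session")
def benchmark_result(benchmark_data):
    _, _, alignments = benchmark_data
    return run_cluster(alignments, meta=MetaclusteringParams(min_size=20))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
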