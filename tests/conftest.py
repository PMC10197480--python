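import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import traitnet as tn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_matrix() -> tn.TraitMatrix:
    """Deterministic 20-record, 5-trait positive matrix (raw scale)."""
    rng = np.random.default_rng(42)
    vals = np.exp(rng.standard_normal((20, 5)) * 0.5)
    return tn.TraitMatrix(
        values=vals,
        record_ids=[f"r{i}" for i in range(20)],
        trait_names=["t1", "t2", "t3", "t4", "t5"],
    )


@pytest.fixture
def planted_matrix() -> tn.TraitMatrix:
    """Log-transformed matrix with strong planted 6/6/4 block structure."""
    cfg = tn.SyntheticConfig(
        n_records=300,
        blocks=tn.default_blocks(rho_in=0.9),
        rho_out=0.0,
        seed=7,
    )
    return tn.log_transform(tn.generate(cfg))


def make_network(adj: np.ndarray) -> tn.TraitNetwork:
    """Wrap a 0/1 adjacency matrix in a TraitNetwork for metric tests."""
    p = adj.shape[0]
    return tn.TraitNetwork(
        adjacency=np.asarray(adj, dtype=int),
        trait_names=[f"n{i:02d}" for i in range(p)],
        alpha=0.05,
    )
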