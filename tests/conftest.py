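import numpy as np
import pytest

from stoverann.ann_model import init_network, load_reference_weights
from stoverann.dataset_io import Dataset, DesignSpace, ExperimentRecord


def dataset_from_arrays(X, Y=None, provenance="synthetic"):
    """Build a Dataset from an N x 6 condition array (canonical input order)
    and an optional N x 2 output array."""
    recs = []
    for i, x in enumerate(np.atleast_2d(X)):
        y = (None, None) if Y is None else Y[i]
        recs.append(
            ExperimentRecord(
                run_id=f"r{i:03d}",
                k_IA=int(x[4]),
                C_IA=float(x[0]),
                T=float(x[1]),
                t=float(x[2]),
                R_SL=float(x[3]),
                E=float(x[5]),
                C_Glc=None if y[0] is None else float(y[0]),
                C_Phe=None if y[1] is None else float(y[1]),
            )
        )
    return Dataset(recs, provenance=provenance)


def random_conditions(n, seed):
    """n condition rows uniform over the standard design space."""
    rng = np.random.default_rng(seed)
    sp = DesignSpace()
    return np.column_stack(
        [
            rng.uniform(*sp.C_IA, n),
            rng.uniform(*sp.T, n),
            rng.uniform(*sp.t, n),
            rng.uniform(*sp.R_SL, n),
            rng.integers(1, 4, n).astype(float),
            rng.uniform(*sp.E, n),
        ]
    )


@pytest.fixture(scope="session")
def reference_params():
    """The published 6-12-2 weight set."""
    return load_reference_weights()


@pytest.fixture
def random_params():
    """Factory for seeded random networks of a given hidden size."""

    def make(n=5, seed=0):
        return init_network(n, seed)

    return make
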