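import numpy as np
import pytest

from ribocycle import AssayConfig, RecyclingParams


@pytest.fixture
def assay_config():
    """Default-condition assay at a moderate recycle number, noise-free."""
    return AssayConfig(
        params=RecyclingParams(P=0.2, k=1.0),
        timepoints=(1, 2, 5, 10, 20, 40),
        n_ribosomes=50_000,
        noise_cv=0.0,
        seed=11,
    )


def exact_condition_moments(P: float, cycles: int) -> tuple[float, float]:
    """Exact mean and variance of peptides per ribosome with competitor.

    Peptides = 1 + min(G, m) where G is the number of consecutive survived
    release decisions (P release each); enumerated directly.
    """
    j = np.arange(cycles)
    pmf_j = (1 - P) ** j * P          # min = j, released at step j+1 <= m
    tail = (1 - P) ** cycles          # survived all m decisions
    vals = np.append(j, cycles)
    pmf = np.append(pmf_j, tail)
    mean = float(np.dot(vals, pmf))
    var = float(np.dot(vals**2, pmf) - mean**2)
    return 1.0 + mean, var
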