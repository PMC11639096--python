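import numpy as np
import pytest

from topohic.matrix_ops import BalancedMatrix, balance, expected_by_distance
from topohic.synthetic_cohort import (
    CohortSpec,
    LoopSpec,
    default_spec,
    expected_intensity,
    simulate_contact_map,
)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """150-bin toy cohort: 6 TADs, 2 loops, cheap enough for unit tests."""
    return default_spec(
        seed=1,
        chrom_length=7_500_000,
        tad_intervals=((0, 25), (25, 50), (50, 75), (75, 100), (100, 125), (125, 150)),
        boundary_strengths={g: (0.7,) * 5 for g in ("SHH", "G3", "G4", "WNT")},
        loop_anchors=(LoopSpec(20, 40, 2.0), LoopSpec(60, 90, 2.0)),
        de_genes=(),
        library_size=1_000_000.0,
        n_genes=50,
    )


@pytest.fixture(scope="session")
def small_sample(small_spec):
    """One simulated (matrix, truth) pair from the toy spec."""
    return simulate_contact_map(small_spec, "G3", sample_seed=0)


@pytest.fixture(scope="session")
def small_balanced(small_sample):
    matrix, _truth = small_sample
    return balance(matrix)


@pytest.fixture(scope="session")
def small_expected(small_balanced):
    return expected_by_distance(small_balanced)


def noise_free_balanced(spec, group="G3", sv_specs=()):
    """The exact expected-intensity matrix wrapped as a BalancedMatrix (a
    zero-noise stand-in used by analytic oracles)."""
    mu = expected_intensity(spec, group, sv_specs)
    n = mu.shape[0]
    return BalancedMatrix(mu, np.ones(n), np.zeros(n, dtype=bool),
                          spec.chrom, spec.bin_size)
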