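from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import fourfold as ff

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def sgc():
    return ff.get_code(1)


@pytest.fixture(scope="session")
def grantham_acceptance():
    return ff.build_acceptance_matrix(stop_floor=0.0)


@pytest.fixture(scope="session")
def neutral_acceptance():
    """Acceptance matrix that switches selection off entirely."""
    return ff.build_acceptance_matrix(
        stop_floor=1.0, conversion=lambda d: np.ones((20, 20)), strict=False
    )


@pytest.fixture(scope="session")
def stop_only_acceptance():
    """Selection against stop codons only: amino-acid pairs fully accepted."""
    return ff.build_acceptance_matrix(
        stop_floor=0.0, conversion=lambda d: np.ones((20, 20))
    )


@pytest.fixture(scope="session")
def reference_summary():
    return pd.read_csv(DATA / "reference_fpi_summary.tsv", sep="\t")


@pytest.fixture(scope="session")
def reference_extremal():
    return pd.read_csv(DATA / "reference_extremal_pressures.tsv", sep="\t")


def random_grid_pressure(rng: np.random.Generator) -> ff.StationaryDistribution:
    """A uniform draw from the default 0.01-step stationary lattice."""
    while True:
        counts = rng.integers(5, 86, size=4)
        if counts.sum() == 100:
            return ff.StationaryDistribution(counts / 100.0)


def combined_chain(code, pi, acceptance, seed):
    """Random pressure -> combined mutation-selection chain, for tests."""
    q = ff.sample_rate_matrix(pi, seed)
    p = ff.uniformize(q)
    m = ff.codon_mutation_matrix(p)
    return q, ff.combined_codon_matrix(m, acceptance, code)
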