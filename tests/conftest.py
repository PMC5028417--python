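import numpy as np
import pytest

from catchseq import CoverageTrack, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic experiment at package defaults, shared across tests."""
    return generate_dataset(SyntheticConfig(rng_seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A fast, small experiment for tests that regenerate data repeatedly."""
    return SyntheticConfig(
        chrom_length=400_000,
        n_genes=50,
        n_interactors=12,
        bait_position=200_000,
        n_coexpr_datasets=5,
        rng_seed=11,
    )


def make_track(values, bin_size=10, chrom="chrT"):
    values = np.asarray(values, dtype=float)
    return CoverageTrack(
        chrom=chrom,
        chrom_length=len(values) * bin_size,
        bin_size=bin_size,
        values=values,
    )
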