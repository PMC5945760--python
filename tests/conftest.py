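import numpy as np
import pytest

from karyodepth.genome import ChromosomeSpec, GenomeSpec, default_genome
from karyodepth.simulate import SimConfig
from karyodepth.thresholds import derive_thresholds


def make_genome(scale: int = 100_000, window_size: int = 10_000) -> GenomeSpec:
    """A small 12-chromosome genome with uneven sizes and centromeres.

    ``scale`` is the length unit; the default gives chromosomes of
    0.5–1.5 Mb (50–150 windows each), cheap enough for per-test
    simulation while keeping distinct relative sizes and asymmetric arms.
    """
    lengths = [15, 12, 13, 11, 9, 10, 9, 8, 5, 6, 9, 8]
    cen_frac = [0.40, 0.38, 0.55, 0.27, 0.42, 0.49, 0.41, 0.45, 0.13, 0.35, 0.41, 0.43]
    chroms = []
    for i, (units, frac) in enumerate(zip(lengths, cen_frac), start=1):
        length = units * scale
        chroms.append(
            ChromosomeSpec(
                id=i,
                length=length,
                centromere=int(round(frac * length)),
                relative_size=length / (lengths[0] * scale),
            )
        )
    return GenomeSpec(chromosomes=tuple(chroms), window_size=window_size)


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return make_genome()


@pytest.fixture(scope="session")
def rice_genome() -> GenomeSpec:
    return default_genome()


@pytest.fixture(scope="session")
def rice_thresholds(rice_genome):
    """Monte-Carlo thresholds at 1× depth on the bundled genome."""
    cfg = SimConfig(genome=rice_genome, mean_depth=1.0, seed=2)
    return derive_thresholds(rice_genome, cfg, n_reps=3)


@pytest.fixture(scope="session")
def rice_exact_thresholds(rice_genome):
    """Noise-free (expected-count) thresholds on the bundled genome."""
    cfg = SimConfig(genome=rice_genome, noise="none", seed=1)
    return derive_thresholds(rice_genome, cfg, n_reps=1)
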