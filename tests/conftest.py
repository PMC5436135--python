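import numpy as np
import pandas as pd
import pytest

from renalmatch.genome import GenomeModel, make_genome
from renalmatch.harmonize import LOG2, SegmentProfile
from renalmatch.synthetic import default_archetypes, simulate_cna_cohort


@pytest.fixture(scope="session")
def genome():
    return make_genome(n_chromosomes=22, genes_per_arm=25, seed=0)


@pytest.fixture(scope="session")
def tiny_genome():
    """Four short chromosomes, two genes per arm — fast oracle checks."""
    return make_genome(n_chromosomes=4, genes_per_arm=2, scale=4e-5, seed=3)


@pytest.fixture(scope="session")
def small_cohort(genome):
    profiles, truth = simulate_cna_cohort(
        genome, default_archetypes(), n_per_group=12,
        n_cell_lines_per_group=3, segment_noise_sd=0.1, seed=7)
    return profiles, truth


def random_profile(rng: np.random.Generator, genome: GenomeModel,
                   sample_id: str = "S", max_segments: int = 6) -> SegmentProfile:
    """A random log2 profile whose segments partition each chromosome."""
    rows = []
    for name, length in genome.chromosomes:
        k = int(rng.integers(1, max_segments + 1))
        if k >= length:
            k = 1
        cuts = np.sort(rng.choice(np.arange(2, length + 1), size=k - 1, replace=False)) \
            if k > 1 else np.array([], dtype=int)
        starts = np.concatenate(([1], cuts))
        ends = np.concatenate((cuts - 1, [length]))
        for s, e in zip(starts, ends):
            rows.append((name, int(s), int(e), float(rng.normal(0, 0.5))))
    seg = pd.DataFrame(rows, columns=["chromosome", "start", "end", "value"])
    return SegmentProfile(sample_id, seg, LOG2)
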