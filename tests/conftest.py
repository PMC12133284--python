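import pytest

import indelnet as dn


@pytest.fixture(scope="session")
def small_spec():
    return dn.SyntheticSpec(L=40, mode="random", n_mutants=3000, noise_sd=0.1, seed=11)


@pytest.fixture(scope="session")
def small_benchmark(small_spec):
    """(annotation, ground truth, raw 20-column dataset) for a 40-residue
    pseudo-protein with 3000 mutants."""
    return dn.generate_benchmark(small_spec)


@pytest.fixture(scope="session")
def normalized_small(small_benchmark):
    """Preprocessed (18-column, z-scored) dataset plus its stats."""
    _, _, raw = small_benchmark
    dataset = dn.drop_constant_scores_dataset(raw)
    stats = dn.fit_normalization(dataset)
    return dn.apply_normalization(dataset, stats), stats


@pytest.fixture(scope="session")
def small_splits(normalized_small):
    dataset, _ = normalized_small
    return dn.make_splits(dataset, dn.SplitSpec(seed=11))
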