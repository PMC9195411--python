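import numpy as np
import pytest

import methylnet as mn


@pytest.fixture(scope="session")
def tiny_spec() -> mn.SyntheticSpec:
    """A small corpus: 4 classes x 30 samples over 60 islands."""
    return mn.SyntheticSpec(n_classes=4, samples_per_class=30, n_islands=60, seed=11)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec):
    manifest = mn.generate_manifest(tiny_spec)
    beta, meta = mn.generate_cohort(tiny_spec)
    return manifest, beta, meta


@pytest.fixture(scope="session")
def tiny_features(tiny_corpus):
    manifest, beta, _meta = tiny_corpus
    return mn.build_features(manifest, beta)


def random_probes(rng: np.random.Generator, n: int, n_chroms: int = 3) -> list[mn.ProbeRecord]:
    """Random manifest for oracle-based clustering tests."""
    chroms = rng.integers(1, n_chroms + 1, size=n)
    positions = rng.integers(0, 5000, size=n)
    return [
        mn.ProbeRecord(f"cg{i:05d}", f"chr{c}", int(p), True)
        for i, (c, p) in enumerate(zip(chroms, positions))
    ]
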