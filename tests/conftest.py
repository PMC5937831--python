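"""Session-scoped synthetic experiment shared across the test modules.

A 20,000-read-per-library simulation is built once; most tests assert
exact-accounting properties against its ground-truth manifest (which do
not depend on depth).  Depth-sensitive recovery checks live in
tests/test_acceptance.py at the full 100,000-read scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from spidmir import annotate, preprocess
from spidmir.simulate import SimulationConfig, build_reference, simulate_libraries

SMALL_SEED = 101


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(seed=SMALL_SEED, n_reads_per_library=20_000)


@pytest.fixture(scope="session")
def reference(small_cfg):
    return build_reference(small_cfg)


@pytest.fixture(scope="session")
def libraries(small_cfg, reference):
    return simulate_libraries(small_cfg, reference)


@pytest.fixture(scope="session")
def manifest(libraries):
    return libraries[1]


@pytest.fixture(scope="session")
def filtered(small_cfg, libraries):
    reads, _ = libraries
    inserts, reports = {}, {}
    for lib in small_cfg.libraries:
        raw = (preprocess.RawRead(i, s, q) for i, s, q in reads[lib])
        ins, rep = preprocess.filter_reads(
            raw, small_cfg.adapter3, small_cfg.adapter5
        )
        inserts[lib] = ins
        reports[lib] = rep
    return inserts, reports


@pytest.fixture(scope="session")
def tags(filtered):
    return preprocess.collapse_tags(filtered[0])


@pytest.fixture(scope="session")
def annotated(tags, reference):
    hits = annotate.map_to_genome(tags.index, reference.genome)
    assignments, summary = annotate.classify(
        tags, hits, reference.features, reference.known, reference.genome
    )
    return hits, assignments, summary


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
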