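import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import methreprog as mr

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def tiny_table():
    """Hand-built 6-record table spanning contexts, strands and coverages."""
    return mr.MethylomeTable.from_records(
        [
            ("chr1", 9, "+", "CG", 3, 10),
            ("chr1", 10, "-", "CG", 2, 10),
            ("chr1", 99, "+", "CG", 0, 0),
            ("chr1", 149, "+", "CG", 4, 4),
            ("chr2", 5, "+", "CHH", 1, 30),
            ("chr2", 19, "+", "CG", 0, 30),
        ],
        sample_id="tiny",
    )


def _dataset(preset, **overrides):
    spec = mr.make_spec(preset, seed=1, **overrides)
    truth = mr.assign_truth(spec)
    tables = {stage: mr.simulate_counts(truth, spec, stage) for stage in spec.stages}
    return spec, truth, tables


@pytest.fixture(scope="session")
def anemone():
    return _dataset("anemone_mosaic")


@pytest.fixture(scope="session")
def deutero():
    return _dataset("deutero_mosaic")


@pytest.fixture(scope="session")
def fish():
    return _dataset("fish_global")


@pytest.fixture(scope="session")
def mammal():
    return _dataset("mammal_global")


@pytest.fixture(scope="session")
def dmp_dataset():
    """Gamete-asymmetry preset with 200 designed DMPs among ~1000 promoters."""
    spec = mr.make_spec("deutero_mosaic", seed=1, n_genes=1000, n_dmps=200)
    truth = mr.assign_truth(spec)
    sperm = mr.simulate_counts(truth, spec, "sperm")
    oocyte = mr.simulate_counts(truth, spec, "oocyte")
    return spec, truth, sperm, oocyte
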