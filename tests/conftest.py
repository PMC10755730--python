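import numpy as np
import pytest

import deamseq as d


@pytest.fixture(scope="session")
def ideal_model():
    """Deterministic readout: C and 5mC always convert, 5hmC never does."""
    return d.DeaminationModel.uniform("ideal", 1.0, 1.0, 0.0)


@pytest.fixture(scope="session")
def small_ref():
    """50 kb genome with default spike-ins, seeded."""
    return d.build_reference(11, [("chr1", 50_000)], spike_ins=d.default_spike_ins())


@pytest.fixture(scope="session")
def small_run(small_ref):
    """One analyzed sequencing run over the 50 kb genome (default enzyme)."""
    mods = d.plant_modifications(small_ref, seed=12)
    return d.simulate_genome_run(seed=13, ref=small_ref, mods=mods), mods


@pytest.fixture(scope="session")
def substrate():
    """A 400 bp amplicon-like substrate with ~100 cytosines."""
    rng = np.random.default_rng(3)
    return "".join(rng.choice(list("ACGT"), p=[0.27, 0.25, 0.21, 0.27], size=400))
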