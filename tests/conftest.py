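import numpy as np
import pytest

import wqscan as w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wqs_protocol():
    return w.wqs_preset()


@pytest.fixture(scope="session")
def wqs_null_ensemble(wqs_protocol):
    """Shared drift-null ensemble for the WQS preset: 2,000 unlinked loci
    with starting frequencies uniform on [0.05, 0.95], 1,000 replicates.

    Session-scoped because several calibration checks consume the same
    ensemble (as the analysis itself would)."""
    rng = np.random.default_rng(20150202)
    p0 = rng.uniform(0.05, 0.95, size=2000)
    null = w.drift_null_thresholds(p0, wqs_protocol, rng, n_reps=1000)
    return p0, null


@pytest.fixture(scope="session")
def small_wqs_geno():
    """One linked-genome WQS run: 800 SNPs, 4 cycles x 20 families."""
    rng = np.random.default_rng(7)
    gmap = w.GeneticMap.uniform(800)
    return w.simulate_wqs_genomes(w.wqs_preset(), gmap, rng)
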