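"""Shared fixtures.

The two expensive end-to-end studies (grammar inference and the spike-word
benchmark) are computed once per session and shared by every test that
asserts on them.
"""

from __future__ import annotations

import numpy as np
import pytest

from kaarma.benchmarks import (run_compaction_check, run_spike_word_benchmark,
                               run_tomita_experiment)

N_SEEDS = 5
SNR_LIST = (25.0, 15.0, 5.0, -5.0)


@pytest.fixture(scope="session")
def tomita_results():
    """Single-pass grammar-inference runs on Tomita #4 over five seeds."""
    return [run_tomita_experiment(seed=seed) for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def benchmark_results():
    """Five-seed spike-word benchmark incl. the white-noise SNR sweep."""
    return [run_spike_word_benchmark(seed=seed, snr_list=SNR_LIST)
            for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def compaction_results():
    """Dictionary growth of one chain network at the reference and zero
    quantization thresholds."""
    return {
        0.25: run_compaction_check(seed=0, epsilon=0.25),
        0.0: run_compaction_check(seed=0, epsilon=0.0),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
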