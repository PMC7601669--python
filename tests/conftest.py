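"""Shared fixtures: the synthetic three-class benchmark, analysed once.

The benchmark emulates the published recording condition (100 kHz, ~0.18 nA
open-pore baseline, three DNA samples with overlapping blockade/dwell
marginals and class-informative pulse asymmetry).  Generating and analysing
it is the expensive part of the suite, so it is session-scoped.
"""

import pytest

import porepulse as pp
from porepulse.pipeline import analyze_dataset, match_events

BENCHMARK_SEED = 7
N_PER_CLASS = 150


@pytest.fixture(scope="session")
def benchmark_dataset():
    return pp.make_benchmark_dataset(n_per_class=N_PER_CLASS, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_table(benchmark_dataset):
    return analyze_dataset(benchmark_dataset)


@pytest.fixture(scope="session")
def benchmark_matched(benchmark_dataset, benchmark_table):
    pairs, recall = match_events(benchmark_dataset.truth, benchmark_table)
    return pairs, recall


@pytest.fixture(scope="session")
def benchmark_reports(benchmark_table):
    return pp.compare_feature_sets(benchmark_table, pp.SvmConfig(seed=0))
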