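"""Shared fixtures.

The benchmark fixtures are session-scoped because the full leave-2-out run
over 40 reactions × 3 scales is the expensive part of the suite; everything
downstream (summaries, leakage audit, ordering checks) reuses one fit.
"""

import numpy as np
import pytest

import proteorate as pr

BENCHMARK_SEED = 0  # generator + CV seed for all frozen-fixture assertions


@pytest.fixture(scope="session")
def benchmark_dataset():
    """5 media × 5 dilution rates, 200 proteins, 40 reactions, noise 0.25."""
    return pr.generate_dataset(pr.GeneratorConfig(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def benchmark_model(benchmark_dataset):
    d = benchmark_dataset
    return pr.RatePredictionModel(d.expression, d.rates, d.design, d.annotations)


@pytest.fixture(scope="session")
def benchmark_fit(benchmark_model):
    """Leave-2-out, 100 iterations, all three scales, ridge."""
    scheme = pr.CVScheme(kind="leave_n_out", n_out=2, iterations=100)
    return benchmark_model.fit(scheme=scheme, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def media_out_proteome_fit(benchmark_model):
    scheme = pr.CVScheme(kind="leave_media_out")
    return benchmark_model.fit(scheme=scheme, scales=("proteome",), seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def noiseless_dataset():
    return pr.generate_dataset(pr.GeneratorConfig(noise_sd_log2=0.0, seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def noiseless_proteome_fit(noiseless_dataset):
    d = noiseless_dataset
    m = pr.RatePredictionModel(d.expression, d.rates, d.design, d.annotations)
    scheme = pr.CVScheme(kind="leave_n_out", n_out=2, iterations=100)
    return m.fit(scheme=scheme, scales=("proteome",), seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap 3×3 design for unit-level pipeline tests."""
    cfg = pr.GeneratorConfig(
        n_media=3,
        n_growth_rates=3,
        n_bystander_proteins=30,
        n_simple_constant=2,
        n_simple_hidden=3,
        n_branched=2,
        seed=7,
    )
    return pr.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
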