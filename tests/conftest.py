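"""Shared fixtures.

The heavy session fixtures (benchmark cross-validation, a fully trained
model, its Shapley report) define the default study conditions used by
the learning-sanity and explainability tests: the 200+200 synthetic
benchmark at seed 7 and the basic/mix model with 32 Bi-LSTM units, a
50-unit dense layer and 15 epochs.
"""

import numpy as np
import pytest

import acpkit as a

BENCH_CONFIG = dict(
    scheme="mix",
    architecture="basic",
    n_units=32,
    dense_units=50,
    epochs=15,
    batch_size=32,
    seed=7,
)


@pytest.fixture(scope="session")
def benchmark():
    return a.make_benchmark(a.GeneratorSpec())


@pytest.fixture(scope="session")
def bench_config():
    return a.ModelConfig(**BENCH_CONFIG)


@pytest.fixture(scope="session")
def cv_result(benchmark, bench_config):
    return a.cross_validate(bench_config, benchmark, K=5, seed=7)


@pytest.fixture(scope="session")
def trained_model(benchmark, bench_config):
    return a.train(bench_config, benchmark)


@pytest.fixture(scope="session")
def benchmark_encoded(benchmark, trained_model):
    return a.encode_dataset(benchmark, "mix", trained_model.standardization)


@pytest.fixture(scope="session")
def shap_report(trained_model, benchmark, benchmark_encoded):
    y = benchmark.labels
    explain_idx = np.concatenate(
        [np.flatnonzero(y == 1)[:6], np.flatnonzero(y == 0)[:6]]
    )
    background = benchmark_encoded[:100]
    return a.shapley_attributions(
        trained_model,
        benchmark_encoded[explain_idx],
        background,
        n_perm=2,
        seed=11,
        sample_ids=[benchmark.ids[i] for i in explain_idx],
    )


@pytest.fixture()
def separable_dataset():
    """Trivially separable: all-lysine positives vs all-aspartate negatives."""
    peps = [a.Peptide(f"pos{i}", "K" * (8 + i), label=1) for i in range(10)]
    peps += [a.Peptide(f"neg{i}", "D" * (8 + i), label=0) for i in range(10)]
    return a.PeptideDataset(peps, name="separable")
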