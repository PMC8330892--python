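import pytest

from depsignal import CategoryLexicon, compile_patterns, default_config, generate_corpus
from depsignal.pipeline import run_benchmark, run_trend_benchmark

N_SEEDS = 5


@pytest.fixture(scope="session")
def lexicon():
    return CategoryLexicon.default()


@pytest.fixture(scope="session")
def matcher():
    return compile_patterns()


@pytest.fixture(scope="session")
def small_corpus():
    """A small default-effect cohort for cheap structural tests."""
    return generate_corpus(default_config(n_users=60, tweets_per_user=(12.0, 0.2), seed=11))


@pytest.fixture(scope="session")
def benchmark_runs():
    """The default synthetic benchmark at five seeds (shared across tests)."""
    return [run_benchmark(seed=s) for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def trend_runs(benchmark_runs):
    """Trend-recovery benchmark at five seeds, reusing the fitted scorers."""
    return [run_trend_benchmark(seed=s, scorer=benchmark_runs[s]["scorer"])
            for s in range(N_SEEDS)]
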