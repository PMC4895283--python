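import math

import numpy as np
import pytest
from hypothesis import settings

from rriscan.energy import EnergyModel, default_model

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from rriscan.pipeline import PipelineConfig, run_pipeline
from rriscan.synthetic import BenchmarkSpec, generate_benchmark


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def reference_model():
    """Pair-additive folding model (no stacking, no helix initiation).

    Closed-form Boltzmann sums are easy to write down under this model, so
    it backs the hand-derived partition-function and structure-energy
    checks; the production default adds cooperativity on top of the same
    grammar.
    """
    return EnergyModel(
        pair_energies={
            "CG": -2.0, "GC": -2.0, "AU": -1.0, "UA": -1.0, "GU": -0.5, "UG": -0.5,
        },
        intra_stack_energies={},
        helix_init=0.0,
        max_pair_span=None,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_rna(rng, length, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale benchmark reused by the pipeline-level tests."""
    return generate_benchmark(
        BenchmarkSpec(n_queries=6, n_targets=30, q_len=120, t_len=180, rng_seed=7)
    )


@pytest.fixture(scope="session")
def small_benchmark_run(small_benchmark):
    """One unfiltered pipeline run on the small benchmark (shared)."""
    config = PipelineConfig(t=math.inf)
    result = run_pipeline(small_benchmark.queries, small_benchmark.targets, config)
    return small_benchmark, config, result


@pytest.fixture(scope="session")
def default_benchmark_run():
    """The full planted-interaction benchmark at its default geometry.

    Session-scoped because the run is the most expensive fixture in the
    suite; several pipeline-level tests share it read-only.
    """
    bench = generate_benchmark(BenchmarkSpec())
    result = run_pipeline(bench.queries, bench.targets, PipelineConfig(t=math.inf))
    return bench, result
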