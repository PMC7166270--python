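import numpy as np
import pytest

from ciamb import EvalProtocol, run_ci_amb
from ciamb.synthetic import ScenarioSpec, generate

N_STUDY_SEEDS = 20


def fast_protocol(seed: int) -> EvalProtocol:
    """Light scan objective for tests: ridge RMSE over 5 repeated 6:4 splits.

    The evaluator is pluggable by design; the default boosting pair is
    exercised separately where its behaviour (not its speed) is the point.
    """
    return EvalProtocol(repeats=5, regressors=("ridge",), seed=seed)


@pytest.fixture(scope="session")
def default_study():
    """The reference scenario run end-to-end over 20 seeds.

    Shared by the redundancy/recovery, blanket-freeness and reduction checks
    so the (deterministic) pipeline runs only once per seed.
    """
    runs = []
    for seed in range(N_STUDY_SEEDS):
        table, truth = generate(ScenarioSpec(seed=seed))
        result = run_ci_amb(table, evaluator=fast_protocol(seed), seed=seed)
        runs.append({"seed": seed, "table": table, "truth": truth, "result": result})
    return runs


@pytest.fixture()
def small_table():
    """A 40-sample, 12-feature table with one planted signal pair."""
    rng = np.random.default_rng(123)
    from ciamb import FeatureTable

    n = 40
    X = rng.standard_normal((n, 12))
    y = X[:, 0] + 0.5 * X[:, 1] + 0.2 * rng.standard_normal(n)
    return FeatureTable(X, [f"g{i}" for i in range(12)], y)
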