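"""RMSE metric and the repeated split-train-evaluate harness.

The selection scans judge a feature subset by the mean test RMSE of one or
more regressors over repeated random train/test splits (default 6:4, ten
repeats). The default regressor pair — a gradient-boosted decision tree
ensemble and XGBoost — mirrors common practice for small metabolomics tables;
both run with fixed, documented hyperparameters so a given (table, subset,
protocol) triple always reproduces the identical report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import root_mean_squared_error

from .containers import FeatureTable

__all__ = [
    "EvalProtocol",
    "EvalReport",
    "rmse",
    "evaluate_subset",
    "split_indices",
    "make_regressor",
]

# Fixed hyperparameters for the named regressors. The boosting pair uses the
# libraries' long-standing defaults (100 trees, depth 3, learning rate 0.1).
_REGRESSOR_DEFAULTS = {
    "gbdt": dict(n_estimators=100, learning_rate=0.1, max_depth=3),
    "xgboost": dict(
        n_estimators=100,
        learning_rate=0.1,
        max_depth=3,
        tree_method="hist",
        n_jobs=1,
        verbosity=0,
    ),
}


def rmse(actual, predicted) -> float:
    """Root mean squared error; >= 0, exactly 0 iff the vectors are identical."""
    actual = np.asarray(actual, dtype=np.float64).ravel()
    predicted = np.asarray(predicted, dtype=np.float64).ravel()
    if actual.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    if actual.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {actual.shape[0]} vs {predicted.shape[0]}"
        )
    return float(root_mean_squared_error(actual, predicted))


def make_regressor(spec, seed: int):
    """Instantiate a regressor from a spec name or ``(name, factory)`` pair."""
    if isinstance(spec, tuple):
        _, factory = spec
        return factory(seed)
    if spec == "gbdt":
        from sklearn.ensemble import GradientBoostingRegressor

        return GradientBoostingRegressor(random_state=seed, **_REGRESSOR_DEFAULTS["gbdt"])
    if spec == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(random_state=seed, **_REGRESSOR_DEFAULTS["xgboost"])
    if spec == "ridge":
        from sklearn.linear_model import Ridge

        return Ridge(alpha=1.0)
    if spec == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression()
    raise ValueError(f"unknown regressor spec: {spec!r}")


def _spec_name(spec) -> str:
    return spec[0] if isinstance(spec, tuple) else str(spec)


@dataclass(frozen=True)
class EvalProtocol:
    """How a feature subset is scored.

    ``train_fraction`` of the samples (floored) trains each regressor; the
    rest are scored by RMSE; the procedure repeats ``repeats`` times with
    splits derived deterministically from ``(seed, repeat)``.
    """

    train_fraction: float = 0.6
    repeats: int = 10
    seed: int = 0
    regressors: tuple = ("gbdt", "xgboost")

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if len(self.regressors) < 1:
            raise ValueError("at least one regressor is required")


@dataclass
class EvalReport:
    """Per-model mean RMSEs and their (order-invariant) combined mean."""

    per_model_rmse: list[tuple[str, float]]
    combined: float
    n_features_used: int


def _repeat_seed(seed: int, r: int) -> int:
    """Stable per-repeat seed below 2^31, derived from (seed, repeat)."""
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] & 0x7FFFFFFF)


def split_indices(n: int, protocol: EvalProtocol, r: int):
    """Deterministic train/test index split for repeat ``r``.

    Training size is ``floor(train_fraction * n)``; train and test are
    disjoint and together cover all samples.
    """
    n_train = math.floor(protocol.train_fraction * n)
    if n_train < 1 or n_train >= n:
        raise ValueError(f"split leaves an empty half for n={n}")
    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, r]))
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train:]


def evaluate_subset(
    table: FeatureTable,
    indices: Sequence[int],
    protocol: EvalProtocol,
) -> EvalReport:
    """Score a feature subset by repeated split-fit-test RMSE.

    For each repeat the samples are split by :func:`split_indices`, every
    regressor in the protocol is fitted on the training portion restricted to
    ``indices``, and the test RMSE is recorded. The report carries each
    model's mean over repeats and the across-model mean.
    """
    indices = np.asarray(indices, dtype=np.intp)
    if indices.size == 0:
        raise ValueError("cannot evaluate an empty feature subset")
    X = table.values[:, indices]
    y = table.target
    n = table.n_samples
    sums = {_spec_name(s): 0.0 for s in protocol.regressors}
    if len(sums) != len(protocol.regressors):
        raise ValueError("regressor names must be unique")
    for r in range(protocol.repeats):
        train, test = split_indices(n, protocol, r)
        seed_r = _repeat_seed(protocol.seed, r)
        for spec in protocol.regressors:
            name = _spec_name(spec)
            model = make_regressor(spec, seed_r)
            try:
                model.fit(X[train], y[train])
                pred = model.predict(X[test])
            except Exception as exc:  # pragma: no cover - regressor failure path
                raise RuntimeError(
                    f"regressor {name!r} failed on repeat {r}: {exc}"
                ) from exc
            sums[name] += rmse(y[test], pred)
    per_model = [(name, s / protocol.repeats) for name, s in sums.items()]
    combined = math.fsum(v for _, v in per_model) / len(per_model)
    return EvalReport(
        per_model_rmse=per_model,
        combined=combined,
        n_features_used=int(indices.size),
    )


def make_subset_evaluator(
    table: FeatureTable, protocol: EvalProtocol
) -> Callable[[Sequence[int]], float]:
    """Bind a table and protocol into the scalar objective the scans minimise."""

    def _evaluate(indices) -> float:
        return evaluate_subset(table, indices, protocol).combined

    return _evaluate
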