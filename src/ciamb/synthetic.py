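"""Seeded synthetic feature tables with planted ground truth.

The generator emulates the data regime the selector targets — many more
features than samples, with four planted roles mirroring the classic feature
taxonomy: strongly predictive features, weakly predictive features, redundant
features (noisy copies of a predictive parent), and target-independent noise
features. Feature marginals are standard Gaussian and the target is a linear
combination of the predictive features plus Gaussian noise, so relevance is
graded by coefficient size and redundancy by copy noise.

Every run is fully determined by the spec's seed, columns are shuffled (with
role bookkeeping recorded post-shuffle), and tables round-trip through the
CSV reader in :mod:`ciamb.io`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import FeatureTable

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "generate",
    "write_fixture",
    "read_ground_truth",
    "relevant_recall",
    "max_duplicate_survivors",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    The defaults describe the reference scenario used throughout the test
    suite: 60 samples, 5 strong + 5 weak predictive features, one exact
    (zero-noise) duplicate of each, and 80 independent noise features — a
    100-feature table in the n << m regime.
    """

    n_samples: int = 60
    n_strong: int = 5
    n_weak: int = 5
    n_redundant_per_relevant: int = 1
    n_noise: int = 80
    redundancy_noise_sd: float = 0.0
    target_noise_sd: float = 0.4
    strong_coef: float = 1.0
    weak_coef: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        for name in ("n_strong", "n_weak", "n_redundant_per_relevant", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.redundancy_noise_sd < 0 or self.target_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_features < 1:
            raise ValueError("scenario must contain at least one feature")

    @property
    def n_relevant(self) -> int:
        return self.n_strong + self.n_weak

    @property
    def n_features(self) -> int:
        return self.n_relevant * (1 + self.n_redundant_per_relevant) + self.n_noise


@dataclass
class GroundTruth:
    """Post-shuffle role bookkeeping for a generated table.

    ``redundant_groups`` maps each predictive parent's column index to the
    column indices of its noisy copies; the four roles partition all columns.
    """

    strong_indices: list[int]
    weak_indices: list[int]
    redundant_groups: dict[int, list[int]] = field(default_factory=dict)
    noise_indices: list[int] = field(default_factory=list)

    @property
    def relevant_indices(self) -> list[int]:
        return list(self.strong_indices) + list(self.weak_indices)

    def all_indices(self) -> list[int]:
        out = list(self.relevant_indices) + list(self.noise_indices)
        for copies in self.redundant_groups.values():
            out.extend(copies)
        return out


def generate(spec: ScenarioSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate a seeded table and its ground truth.

    Predictive features are iid standard normal; the target is
    ``sum(strong_coef * strong) + sum(weak_coef * weak) + N(0, target_noise_sd)``.
    Each redundant copy equals its parent plus ``N(0, redundancy_noise_sd)``
    (exact duplicates at the default sd of 0). Columns are shuffled with the
    same seed stream and the truth is recorded post-shuffle.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    parents = rng.standard_normal((n, spec.n_relevant))
    coefs = np.concatenate(
        [
            np.full(spec.n_strong, spec.strong_coef),
            np.full(spec.n_weak, spec.weak_coef),
        ]
    )
    target = parents @ coefs + rng.normal(0.0, spec.target_noise_sd, n)

    columns: list[np.ndarray] = [parents[:, i] for i in range(spec.n_relevant)]
    roles: list[tuple[str, int]] = [
        ("strong" if i < spec.n_strong else "weak", i) for i in range(spec.n_relevant)
    ]
    for i in range(spec.n_relevant):
        for _ in range(spec.n_redundant_per_relevant):
            copy = parents[:, i] + rng.normal(0.0, spec.redundancy_noise_sd, n)
            columns.append(copy)
            roles.append(("redundant", i))
    for _ in range(spec.n_noise):
        columns.append(rng.standard_normal(n))
        roles.append(("noise", -1))

    m = len(columns)
    perm = rng.permutation(m)
    values = np.column_stack([columns[j] for j in perm])
    names = [f"f{j:04d}" for j in range(m)]

    parent_pos: dict[int, int] = {}
    strong: list[int] = []
    weak: list[int] = []
    noise: list[int] = []
    copies_by_parent: dict[int, list[int]] = {}
    for new_col, old_col in enumerate(perm):
        role, parent = roles[old_col]
        if role == "strong":
            strong.append(new_col)
            parent_pos[parent] = new_col
        elif role == "weak":
            weak.append(new_col)
            parent_pos[parent] = new_col
        elif role == "noise":
            noise.append(new_col)
        else:
            copies_by_parent.setdefault(parent, []).append(new_col)
    groups = {parent_pos[p]: sorted(c) for p, c in copies_by_parent.items()}

    table = FeatureTable(values, names, target, target_name="target")
    truth = GroundTruth(
        strong_indices=sorted(strong),
        weak_indices=sorted(weak),
        redundant_groups=groups,
        noise_indices=sorted(noise),
    )
    return table, truth


def write_fixture(table: FeatureTable, truth: GroundTruth, path) -> tuple[Path, Path]:
    """Write the table as CSV (target last) plus a JSON ground-truth sidecar.

    ``path`` is a base path; ``<path>.csv`` and ``<path>.truth.json`` are
    written (parent directories created). The CSV round-trips losslessly
    through :func:`ciamb.io.read_feature_table`.
    """
    import pandas as pd

    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    truth_path = base.with_suffix(".truth.json")
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df[table.target_name] = table.target
    df.to_csv(csv_path, index=False, float_format="%.17g")
    payload = {
        "strong_indices": list(map(int, truth.strong_indices)),
        "weak_indices": list(map(int, truth.weak_indices)),
        "redundant_groups": {
            str(k): list(map(int, v)) for k, v in truth.redundant_groups.items()
        },
        "noise_indices": list(map(int, truth.noise_indices)),
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return csv_path, truth_path


def read_ground_truth(path) -> GroundTruth:
    """Load a ground-truth sidecar written by :func:`write_fixture`."""
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        strong_indices=payload["strong_indices"],
        weak_indices=payload["weak_indices"],
        redundant_groups={int(k): v for k, v in payload["redundant_groups"].items()},
        noise_indices=payload["noise_indices"],
    )


def relevant_recall(truth: GroundTruth, selected) -> float:
    """Fraction of predictive signals represented in a selected subset.

    A signal counts as recovered when its parent column *or* any of its
    redundant copies is selected (the copies carry the same information, so
    selecting either recovers the signal).
    """
    selected = set(int(i) for i in np.asarray(selected).ravel())
    parents = truth.relevant_indices
    if not parents:
        return float("nan")
    hits = 0
    for p in parents:
        group = {p, *truth.redundant_groups.get(p, [])}
        if group & selected:
            hits += 1
    return hits / len(parents)


def max_duplicate_survivors(truth: GroundTruth, selected) -> int:
    """Largest number of co-selected members of any one redundant group."""
    selected = set(int(i) for i in np.asarray(selected).ravel())
    worst = 0
    for p, copies in truth.redundant_groups.items():
        group = {p, *copies}
        worst = max(worst, len(group & selected))
    return worst
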