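"""Neural-network perturbation feature selection.

A small feed-forward regressor is trained once on all features and its
held-out R² recorded as a benchmark.  For each feature, the network is then
retrained twice on modified copies of the data: once with that feature's
column forced to 1 everywhere (fully methylated) and once forced to 0
(fully unmethylated) — both extremes are used because a site's natural
level may already sit near either end.  The feature's score is the absolute
difference between the benchmark and the mean of the two perturbed scores:
a feature whose forced presence/absence swings the prediction quality is
deemed important.  The top ``top_n`` features by this delta are selected.

The feature space must already be small (the procedure trains ``1 + 2p``
networks); compose with %-RFE to reach ``prefilter_target`` features first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import r2_score
from sklearn.neural_network import MLPRegressor

from .data_io import FeatureSet, MethylationMatrix

__all__ = ["NnConfig", "PerturbationScore", "nn_perturbation_select", "NnSelector"]


@dataclass(frozen=True)
class NnConfig:
    """Perturbation-selection parameters.

    ``strict`` enforces the conventional ``top_n`` window of [50, 75]
    intended for full-scale runs; small test problems can disable it.
    ``epochs`` caps the optimiser's iterations (lbfgs by default: fast and
    deterministic on small data; ``solver="adam"`` uses ``learning_rate``).
    """

    prefilter_target: int = 100
    top_n: int = 65
    hidden_layers: tuple[int, ...] = (32,)
    epochs: int = 300
    learning_rate: float = 1e-3
    solver: str = "lbfgs"
    test_fraction: float = 0.2
    seed: int = 0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.top_n > self.prefilter_target:
            raise ValueError("top_n must not exceed prefilter_target")
        if self.strict and not 50 <= self.top_n <= 75:
            raise ValueError("top_n must lie in [50, 75] (strict mode)")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class PerturbationScore:
    cpg_id: str
    benchmark_score: float
    score_all_ones: float
    score_all_zeros: float

    @property
    def delta(self) -> float:
        return abs(
            self.benchmark_score
            - 0.5 * (self.score_all_ones + self.score_all_zeros)
        )


def _make_net(cfg: NnConfig) -> MLPRegressor:
    kwargs = dict(
        hidden_layer_sizes=tuple(cfg.hidden_layers),
        activation="tanh",
        solver=cfg.solver,
        max_iter=cfg.epochs,
        random_state=cfg.seed,  # same init for every per-feature retraining
    )
    if cfg.solver == "adam":
        kwargs["learning_rate_init"] = cfg.learning_rate
    return MLPRegressor(**kwargs)


def _train_and_score(
    X_train: np.ndarray, y_train: np.ndarray,
    X_test: np.ndarray, y_test: np.ndarray,
    cfg: NnConfig, label: str,
) -> float:
    net = _make_net(cfg)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at fixed epoch budgets
        net.fit(X_train, y_train)
    pred = net.predict(X_test)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError(f"non-finite network output while scoring {label}")
    return float(r2_score(y_test, pred))


def nn_perturbation_select(
    m: MethylationMatrix, cfg: NnConfig = NnConfig()
) -> tuple[FeatureSet, list[PerturbationScore]]:
    """Rank features by the score swing under forced (un)methylation.

    Returns the selected :class:`FeatureSet` (``top_n`` features by delta
    descending, scores = delta) and the full list of per-feature
    :class:`PerturbationScore` records.  Trains ``1 + 2p`` networks, all
    from the same seeded initialisation so deltas reflect the perturbation
    rather than initialisation randomness.
    """
    if m.has_missing:
        raise ValueError("matrix contains missing betas")
    p = m.n_cpgs
    if p > cfg.prefilter_target:
        raise ValueError(
            f"{p} features exceed prefilter_target={cfg.prefilter_target}; "
            "pre-reduce (e.g. with %-RFE) first"
        )
    if cfg.top_n > p:
        raise ValueError(f"top_n={cfg.top_n} exceeds available features ({p})")

    X = m.X
    y = m.y
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    n_test = max(1, round(cfg.test_fraction * n))
    perm = rng.permutation(n)
    test, train = perm[:n_test], perm[n_test:]

    benchmark = _train_and_score(X[train], y[train], X[test], y[test], cfg, "benchmark")

    records: list[PerturbationScore] = []
    cpgs = m.cpg_ids
    for j, cpg in enumerate(cpgs):
        scores = {}
        for value in (1.0, 0.0):
            X_mod = X.copy()
            X_mod[:, j] = value
            scores[value] = _train_and_score(
                X_mod[train], y[train], X_mod[test], y[test], cfg, f"{cpg}@{value}"
            )
        records.append(PerturbationScore(cpg, benchmark, scores[1.0], scores[0.0]))

    order = sorted(range(p), key=lambda i: (-records[i].delta, cpgs[i]))[: cfg.top_n]
    fs = FeatureSet(
        tuple(cpgs[i] for i in order),
        scores=tuple(records[i].delta for i in order),
        provenance=(
            f"nn_perturbation(top_n={cfg.top_n}, hidden={cfg.hidden_layers}, "
            f"trainings={1 + 2 * p})"
        ),
    )
    return fs, records


@dataclass
class NnSelector:
    cfg: NnConfig = NnConfig()
    name: str = "nn-perturbation"

    def select(self, m: MethylationMatrix) -> FeatureSet:
        fs, _ = nn_perturbation_select(m, self.cfg)
        return fs
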