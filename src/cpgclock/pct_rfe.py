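"""Percentage-based recursive feature elimination (%-RFE).

Classic RFE removes a fixed number of features per iteration, which is
hopeless on array-scale methylation data (~5e5 CpGs): removing one feature
at a time means half a million model fits.  %-RFE instead removes a fixed
*percentage* of the current feature space each round — aggressive early
(4730 features go in the first pass over 473,035 at 1%) and meticulous late
(a single feature per pass once the space is down to ~100), because the
removal count rescales to the shrinking feature space on every iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .base_selectors import (
    EstimatorKind,
    estimator_importances,
    make_penalized_linear,
    make_tree_ensemble,
)
from .data_io import FeatureSet, MethylationMatrix

__all__ = ["PctRfeConfig", "removal_count", "pct_rfe_select", "PctRfeSelector"]


@dataclass(frozen=True)
class PctRfeConfig:
    """%-RFE parameters.

    ``target_n`` is the surviving feature count (typical presets 100, 1500
    or 10,000, matched to how many features the next, slower selector can
    digest); ``pct`` is the per-iteration removal fraction of the *current*
    feature space (default 1%).
    """

    target_n: int = 100
    pct: float = 0.01
    estimator: EstimatorKind = "penalized-linear"
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pct < 1:
            raise ValueError("pct must lie in (0, 1)")
        if self.target_n < 1:
            raise ValueError("target_n must be >= 1")


def removal_count(current_p: int, pct: float) -> int:
    """Features to drop this iteration: ``max(1, floor(pct * current_p))``.

    At a 1% rate this is 4730 features when 473,035 remain and 1 feature
    when 100 remain.  The caller clips the count so the surviving total
    never undershoots the target.
    """
    if current_p < 1:
        raise ValueError("current_p must be >= 1")
    return max(1, math.floor(pct * current_p))


def _fit_importances(
    X: np.ndarray, y: np.ndarray, cfg: PctRfeConfig
) -> np.ndarray:
    if cfg.estimator == "penalized-linear":
        est = make_penalized_linear()
    else:
        est = make_tree_ensemble(n_trees=cfg.n_trees, seed=cfg.seed)
    est.fit(X, y)
    return estimator_importances(est, cfg.estimator)


def pct_rfe_select(m: MethylationMatrix, cfg: PctRfeConfig) -> FeatureSet:
    """Iteratively eliminate the lowest-importance percentage of CpGs.

    Each iteration refits the estimator on the survivors, ranks them by
    importance (absolute coefficient or impurity importance) and removes
    ``removal_count(current_p, pct)`` of the weakest — clipped so the loop
    terminates at exactly ``cfg.target_n`` survivors.  Ties at the
    elimination boundary are resolved lexicographically by CpG id.
    Survivors carry their final-iteration importances as scores.
    """
    if m.has_missing:
        raise ValueError("matrix contains missing betas")
    if cfg.target_n > m.n_cpgs:
        raise ValueError(
            f"target_n={cfg.target_n} exceeds available CpGs ({m.n_cpgs})"
        )
    surviving = list(m.cpg_ids)
    if cfg.target_n == len(surviving):
        return FeatureSet(
            tuple(surviving), provenance=f"pct_rfe(target={cfg.target_n}, identity)"
        )

    y = m.y
    frame = m.betas
    scores: dict[str, float] = {}
    iteration = 0
    while len(surviving) > cfg.target_n:
        iteration += 1
        X = frame.loc[:, surviving].to_numpy(dtype=float)
        try:
            imp = _fit_importances(X, y, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"%-RFE estimator failed at iteration {iteration} "
                f"with {len(surviving)} surviving features: {exc}"
            ) from exc
        n_drop = min(
            removal_count(len(surviving), cfg.pct), len(surviving) - cfg.target_n
        )
        # weakest first: ascending importance, ties by CpG id
        order = sorted(range(len(surviving)), key=lambda i: (imp[i], surviving[i]))
        drop = {surviving[i] for i in order[:n_drop]}
        scores = {c: float(imp[i]) for i, c in enumerate(surviving)}
        surviving = [c for c in surviving if c not in drop]

    return FeatureSet(
        tuple(surviving),
        scores=tuple(scores[c] for c in surviving),
        provenance=(
            f"pct_rfe(target={cfg.target_n}, pct={cfg.pct}, "
            f"estimator={cfg.estimator}, iterations={iteration})"
        ),
    )


@dataclass
class PctRfeSelector:
    cfg: PctRfeConfig
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"pct-rfe-{self.cfg.target_n}"

    def select(self, m: MethylationMatrix) -> FeatureSet:
        return pct_rfe_select(m, self.cfg)
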