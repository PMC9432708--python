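"""Fast single-pass selectors: KBest, variance threshold and SelectFromModel.

All selectors in the package share one contract: a ``select(matrix)`` method
returning a :class:`~cpgclock.data_io.FeatureSet`, so that any of them can be
composed by :func:`cpgclock.workflow.chain`.  Ties are always broken by
larger score first, then lexicographic CpG id, so results are reproducible
and invariant to column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Protocol, runtime_checkable

import numpy as np
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import ElasticNet

from .data_io import FeatureSet, MethylationMatrix

__all__ = [
    "Selector",
    "ImportanceVector",
    "select_k_best",
    "variance_threshold",
    "select_from_model",
    "KBestSelector",
    "VarianceThresholdSelector",
    "SfmSelector",
    "abs_pearson_with_age",
    "make_penalized_linear",
    "make_tree_ensemble",
]

EstimatorKind = Literal["penalized-linear", "tree-ensemble"]


@runtime_checkable
class Selector(Protocol):
    """Uniform selector contract used by the chaining/CV workflow."""

    name: str

    def select(self, m: MethylationMatrix) -> FeatureSet: ...


@dataclass(frozen=True)
class ImportanceVector:
    """Per-CpG non-negative importances with their provenance."""

    cpg_ids: tuple[str, ...]
    values: tuple[float, ...]
    source: str  # absolute-coefficient | mean-impurity-importance | absolute-correlation | variance

    def __post_init__(self) -> None:
        if len(self.cpg_ids) != len(self.values):
            raise ValueError("importance length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite importance value")


def _require_complete(m: MethylationMatrix) -> None:
    if m.has_missing:
        raise ValueError(
            "matrix contains missing betas; apply drop_incomplete_cpgs first"
        )


def rank_order(scores: np.ndarray, cpg_ids: list[str]) -> np.ndarray:
    """Indices sorted by descending score, ties by ascending CpG id."""
    order = sorted(range(len(cpg_ids)), key=lambda i: (-scores[i], cpg_ids[i]))
    return np.asarray(order, dtype=int)


def make_penalized_linear(alpha: float = 0.01, l1_ratio: float = 0.5) -> ElasticNet:
    """Elastic-net estimator used for coefficient-based importances."""
    return ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000, tol=1e-4)


def make_tree_ensemble(
    n_trees: int = 100, seed: int = 0, max_features: float | str = 1.0
) -> ExtraTreesRegressor:
    """Extremely-randomized-trees estimator for impurity importances.

    Extra-trees draws split thresholds at random rather than optimising
    them, which keeps ensembles tractable on wide methylation matrices.
    """
    return ExtraTreesRegressor(
        n_estimators=n_trees, random_state=seed, max_features=max_features, n_jobs=1
    )


def estimator_importances(estimator, kind: EstimatorKind) -> np.ndarray:
    if kind == "penalized-linear":
        return np.abs(np.asarray(estimator.coef_, dtype=float))
    if kind == "tree-ensemble":
        return np.asarray(estimator.feature_importances_, dtype=float)
    raise ValueError(f"unknown estimator kind {kind!r}")


def abs_pearson_with_age(m: MethylationMatrix) -> np.ndarray:
    """Absolute Pearson correlation of each CpG column with age.

    Zero-variance columns (or zero-variance age) get correlation 0 rather
    than NaN, so constant probes rank last instead of poisoning the sort.
    """
    X = m.X
    y = m.y
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xnorm = np.sqrt((xc**2).sum(axis=0))
    ynorm = np.sqrt((yc**2).sum())
    denom = xnorm * ynorm
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc.T @ yc) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(np.clip(r, -1.0, 1.0))


def select_k_best(m: MethylationMatrix, k: int) -> FeatureSet:
    """The k CpGs most correlated (|Pearson r|) with age, ranked descending.

    This is the classic correlation-with-age screen used to prune array-scale
    feature spaces before slower selectors run.
    """
    _require_complete(m)
    if not 1 <= k <= m.n_cpgs:
        raise ValueError(f"k={k} outside [1, {m.n_cpgs}]")
    scores = abs_pearson_with_age(m)
    cpgs = m.cpg_ids
    order = rank_order(scores, cpgs)[:k]
    return FeatureSet(
        tuple(cpgs[i] for i in order),
        scores=tuple(scores[i] for i in order),
        provenance=f"select_k_best(k={k})",
    )


def variance_threshold(m: MethylationMatrix, t: float) -> FeatureSet:
    """Retain CpGs whose population variance strictly exceeds ``t``."""
    _require_complete(m)
    if t < 0:
        raise ValueError("threshold must be non-negative")
    var = m.X.var(axis=0)  # population variance (ddof=0)
    cpgs = m.cpg_ids
    kept = [i for i in range(len(cpgs)) if var[i] > t]
    kept.sort(key=lambda i: (-var[i], cpgs[i]))
    return FeatureSet(
        tuple(cpgs[i] for i in kept),
        scores=tuple(var[i] for i in kept),
        provenance=f"variance_threshold(t={t})",
    )


def select_from_model(
    m: MethylationMatrix,
    estimator: EstimatorKind = "penalized-linear",
    threshold: float = 0.01,
    n_trees: int = 100,
    seed: int = 0,
) -> FeatureSet:
    """Single model fit; keep CpGs whose importance is >= ``threshold``.

    Importance is the absolute coefficient for the penalized-linear
    estimator and the mean impurity importance for the tree ensemble.
    Coefficients are used raw (unstandardized): beta values share the [0, 1]
    scale, so no per-feature rescaling is applied.  A threshold above the
    maximum importance yields an empty set, not an error.
    """
    _require_complete(m)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if estimator == "penalized-linear":
        est = make_penalized_linear()
    elif estimator == "tree-ensemble":
        est = make_tree_ensemble(n_trees=n_trees, seed=seed)
    else:
        raise ValueError(f"unknown estimator kind {estimator!r}")
    try:
        est.fit(m.X, m.y)
    except Exception as exc:
        raise RuntimeError(f"select_from_model estimator fit failed: {exc}") from exc
    imp = estimator_importances(est, estimator)
    cpgs = m.cpg_ids
    kept = [i for i in range(len(cpgs)) if imp[i] >= threshold and imp[i] > 0]
    kept.sort(key=lambda i: (-imp[i], cpgs[i]))
    return FeatureSet(
        tuple(cpgs[i] for i in kept),
        scores=tuple(imp[i] for i in kept),
        provenance=f"select_from_model({estimator}, threshold={threshold})",
    )


# ---------------------------------------------------------------------------
# selector objects (uniform contract for the workflow module)
# ---------------------------------------------------------------------------


@dataclass
class KBestSelector:
    k: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"kbest-{self.k}"

    def select(self, m: MethylationMatrix) -> FeatureSet:
        return select_k_best(m, self.k)


@dataclass
class VarianceThresholdSelector:
    t: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"variance-{self.t}"

    def select(self, m: MethylationMatrix) -> FeatureSet:
        return variance_threshold(m, self.t)


@dataclass
class SfmSelector:
    estimator: EstimatorKind = "penalized-linear"
    threshold: float = 0.01
    n_trees: int = 100
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"sfm-{self.estimator}-{self.threshold}"

    def select(self, m: MethylationMatrix) -> FeatureSet:
        return select_from_model(
            m, self.estimator, self.threshold, n_trees=self.n_trees, seed=self.seed
        )
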