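"""The cross-validated selection workflow.

Feature selection is unstable on wide data: run the same selector on a
slightly different subsample and you get a different CpG list.  The
workflow here treats that instability as signal.  Selectors (possibly
chained) are run on the training portion of each of 10 CV folds; the
per-fold selections are then post-processed in several ways —

* per-method union of unique features across folds (the aggregated table),
* per-fold intersection across methods, unioned and refined with a
  shadow-feature pass,
* frequency ranking of CpGs across all (method, fold) results,
* intersection of all methods' aggregated sets —

and every resulting feature set is scored by repeatedly refitting an
elastic-net clock on seeded train/test splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold

from .base_selectors import Selector
from .boruta import BorutaConfig, boruta_select
from .clock import EvaluationReport, evaluate_feature_set  # noqa: F401  (module surface)
from .data_io import FeatureSet, MethylationMatrix

__all__ = [
    "SelectionRecord",
    "AggregatedSelectionTable",
    "EvaluationReport",
    "ChainSelector",
    "chain",
    "run_cv_selection",
    "aggregate_unique",
    "intersect_per_fold_then_refine",
    "top_frequent",
    "post_selection_intersection",
    "evaluate_feature_set",
    "EmptyIntersectionError",
]

log = logging.getLogger(__name__)


class EmptyIntersectionError(ValueError):
    """Per-fold intersections were empty everywhere."""


@dataclass(frozen=True)
class SelectionRecord:
    """One selector's output on one CV fold (or its failure)."""

    method_name: str
    fold_index: int
    selected: Optional[FeatureSet]
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.selected is not None


@dataclass(frozen=True)
class AggregatedSelectionTable:
    """method name -> deduplicated union of its per-fold selections."""

    methods: Mapping[str, FeatureSet]

    def __getitem__(self, name: str) -> FeatureSet:
        return self.methods[name]

    def names(self) -> list[str]:
        return list(self.methods)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


@dataclass
class ChainSelector:
    """Run selectors in sequence, each on the previous stage's survivors."""

    stages: Sequence[Selector]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("chain needs at least one stage")
        if not self.name:
            self.name = " then ".join(s.name for s in self.stages)

    def select(self, m: MethylationMatrix) -> FeatureSet:
        current = m
        out: FeatureSet | None = None
        for stage in self.stages:
            out = stage.select(current)
            if len(out) == 0:
                raise ValueError(
                    f"chain stage {stage.name!r} returned an empty feature set"
                )
            current = current.restrict(list(out.cpg_ids))
        assert out is not None
        return FeatureSet(out.cpg_ids, out.scores, provenance=self.name)


def chain(stages: Sequence[Selector], name: str = "") -> ChainSelector:
    """Compose selectors; stage i+1 sees only stage i's selected CpGs."""
    return ChainSelector(list(stages), name=name)


# ---------------------------------------------------------------------------
# cross-validated selection
# ---------------------------------------------------------------------------


def run_cv_selection(
    m: MethylationMatrix,
    methods: Mapping[str, Selector] | Sequence[Selector],
    folds: int = 10,
    seed: int = 0,
) -> list[SelectionRecord]:
    """Run every selector on the training portion of each CV fold.

    Selection never sees the held-out fold.  A selector failing on a fold
    is recorded (``record.error``) and the run continues; failures are
    summarised in a warning at the end.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if m.n_samples < folds:
        raise ValueError(f"{m.n_samples} samples cannot form {folds} folds")
    if not isinstance(methods, Mapping):
        methods = {s.name: s for s in methods}

    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    records: list[SelectionRecord] = []
    failures = []
    for fold_index, (train_idx, _test_idx) in enumerate(splitter.split(m.X)):
        train = m.take_samples(train_idx)
        for name, selector in methods.items():
            try:
                fs = selector.select(train)
                records.append(SelectionRecord(name, fold_index, fs))
            except Exception as exc:
                records.append(SelectionRecord(name, fold_index, None, str(exc)))
                failures.append((name, fold_index, exc))
    if failures:
        summary = "; ".join(f"{n} on fold {i}: {e}" for n, i, e in failures)
        warnings.warn(f"{len(failures)} selection run(s) failed: {summary}")
    return records


def aggregate_unique(records: Sequence[SelectionRecord]) -> AggregatedSelectionTable:
    """Per method, the deduplicated union of selected CpGs over folds."""
    by_method: dict[str, set[str]] = {}
    for rec in records:
        if not rec.ok:
            continue
        by_method.setdefault(rec.method_name, set()).update(rec.selected.cpg_ids)
    return AggregatedSelectionTable(
        {
            name: FeatureSet(tuple(sorted(cpgs)), provenance=f"{name} (union over folds)")
            for name, cpgs in by_method.items()
        }
    )


def intersect_per_fold_then_refine(
    records: Sequence[SelectionRecord],
    m: MethylationMatrix,
    boruta_cfg: BorutaConfig = BorutaConfig(),
) -> FeatureSet:
    """Intersect methods within each fold, union over folds, refine by shadows.

    The per-fold intersection keeps only CpGs every method agreed on for
    that fold; the union of those consensus sets is then put through a
    shadow-feature pass as a final all-relevant filter.
    """
    folds = sorted({r.fold_index for r in records})
    union: set[str] = set()
    for fold in folds:
        fold_sets = [
            set(r.selected.cpg_ids)
            for r in records
            if r.fold_index == fold and r.ok
        ]
        if not fold_sets:
            continue
        inter = set.intersection(*fold_sets)
        union |= inter
    if not union:
        raise EmptyIntersectionError(
            "per-fold intersections are empty in every fold"
        )
    restricted = m.restrict(sorted(union))
    fs = boruta_select(restricted, boruta_cfg)
    return FeatureSet(fs.cpg_ids, fs.scores,
                      provenance="per-fold intersection then shadow refinement")


def top_frequent(records: Sequence[SelectionRecord], n: int) -> FeatureSet:
    """The n CpGs appearing in the most (method, fold) selection results.

    Each record contributes at most one count per CpG; ties are broken by
    lexicographic CpG id.  Scores are the counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.ok:
            continue
        for cpg in set(rec.selected.cpg_ids):
            counts[cpg] = counts.get(cpg, 0) + 1
    if len(counts) < n:
        raise ValueError(
            f"only {len(counts)} distinct CpGs ever selected; cannot rank top {n}"
        )
    ranked = sorted(counts, key=lambda c: (-counts[c], c))[:n]
    return FeatureSet(
        tuple(ranked),
        scores=tuple(float(counts[c]) for c in ranked),
        provenance=f"top-{n} most frequent across records",
    )


def post_selection_intersection(table: AggregatedSelectionTable) -> FeatureSet:
    """CpGs present in every method's aggregated unique set (may be empty)."""
    names = table.names()
    if len(names) < 2:
        raise ValueError("need at least two methods to intersect")
    common = set(table[names[0]].cpg_ids)
    for name in names[1:]:
        common &= set(table[name].cpg_ids)
    return FeatureSet(
        tuple(sorted(common)), provenance="post-selection intersection of all methods"
    )
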