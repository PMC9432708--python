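"""Methylation matrices, feature sets and annotation tables.

The central container is :class:`MethylationMatrix`: an ``n_samples x n_cpgs``
grid of beta values (fraction of methylated signal at a CpG site, in [0, 1])
together with per-sample chronological ages in years.  Matrices are read from
and written to delimited text tables in either orientation — samples in rows
(one CpG per column, plus an age column) or CpGs in rows (GEO
series-matrix style, one sample per column, plus an age row).  The
orientation is always stated explicitly by the caller; it is never guessed,
because a silently transposed methylation table is a classic source of
nonsense clocks.

Missing beta values are represented as NaN; empty cells and the tokens
``NA``/``NaN``/``nan`` are accepted as missing on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "FeatureSet",
    "AnnotationTable",
    "FormatError",
    "ValidationError",
    "EmptyFeatureSpaceError",
    "load_methylation_table",
    "load_prediction_table",
    "save_methylation_table",
    "drop_incomplete_cpgs",
    "load_annotation",
    "annotate_features",
]

MISSING_TOKENS = ("", "NA", "NaN", "nan")

SAMPLES_IN_ROWS = "samples-in-rows"
CPGS_IN_ROWS = "cpgs-in-rows"
_LAYOUTS = (SAMPLES_IN_ROWS, CPGS_IN_ROWS)


class FormatError(ValueError):
    """A table could not be parsed into a methylation matrix."""


class ValidationError(ValueError):
    """Parsed values violate a matrix invariant (range, uniqueness, ...)."""


class EmptyFeatureSpaceError(ValueError):
    """A filtering step left no CpG sites."""


@dataclass
class MethylationMatrix:
    """Beta-value matrix with per-sample chronological ages.

    Parameters
    ----------
    betas
        ``n_samples x n_cpgs`` DataFrame of methylation fractions.  The index
        holds sample identifiers, the columns CpG identifiers (e.g.
        ``cg16867657``).  NaN marks a missing measurement; every non-missing
        value must lie in [0, 1].
    ages
        Chronological age in years per sample (non-negative reals), aligned
        with ``betas.index``.  ``None`` only for prediction-only matrices
        loaded without a label.
    """

    betas: pd.DataFrame
    ages: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.betas.index.is_unique:
            dup = self.betas.index[self.betas.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not self.betas.columns.is_unique:
            dup = self.betas.columns[self.betas.columns.duplicated()][0]
            raise ValidationError(f"duplicate CpG id: {dup!r}")
        values = self.betas.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {values[i, j]!r} outside [0, 1] at sample "
                f"{self.betas.index[i]!r}, CpG {self.betas.columns[j]!r}"
            )
        if self.ages is not None:
            self.ages = pd.Series(
                np.asarray(self.ages, dtype=float), index=self.betas.index, name="age"
            ) if not isinstance(self.ages, pd.Series) else self.ages.astype(float)
            if len(self.ages) != len(self.betas):
                raise ValidationError(
                    f"{len(self.ages)} ages for {len(self.betas)} samples"
                )
            if not self.ages.index.equals(self.betas.index):
                raise ValidationError("ages index does not match sample ids")
            arr = self.ages.to_numpy()
            if np.isnan(arr).any():
                raise ValidationError("missing age value")
            if (arr < 0).any():
                raise ValidationError("negative age value")

    # -- basic views ------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.betas.columns)

    @property
    def n_samples(self) -> int:
        return self.betas.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.betas.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.betas.isna().to_numpy().any())

    @property
    def X(self) -> np.ndarray:
        """Beta values as a float array (samples x CpGs)."""
        return self.betas.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Ages as a float vector; raises if the matrix is unlabeled."""
        if self.ages is None:
            raise ValidationError("matrix has no ages (prediction-only)")
        return self.ages.to_numpy(dtype=float)

    # -- subsetting -------------------------------------------------------

    def restrict(self, cpg_ids: Sequence[str]) -> "MethylationMatrix":
        """Restrict to the given CpGs, in the given order."""
        missing = [c for c in cpg_ids if c not in self.betas.columns]
        if missing:
            raise KeyError(f"CpGs absent from matrix: {missing}")
        return MethylationMatrix(self.betas.loc[:, list(cpg_ids)], self.ages)

    def take_samples(self, positions: Sequence[int]) -> "MethylationMatrix":
        """Subset samples by integer position (e.g. a CV fold)."""
        betas = self.betas.iloc[list(positions)]
        ages = None if self.ages is None else self.ages.iloc[list(positions)]
        return MethylationMatrix(betas, ages)


@dataclass(frozen=True)
class FeatureSet:
    """An ordered set of CpG identifiers produced by a selector.

    ``scores`` optionally carries a per-feature importance aligned 1:1 with
    ``cpg_ids``; ``provenance`` is a free-text descriptor of the method that
    produced the set.
    """

    cpg_ids: tuple[str, ...]
    scores: tuple[float, ...] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError("duplicate CpG ids in feature set")
        if self.scores is not None:
            object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
            if len(self.scores) != len(self.cpg_ids):
                raise ValidationError("scores length does not match cpg_ids")

    def __len__(self) -> int:
        return len(self.cpg_ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.cpg_ids)

    def __contains__(self, cpg: object) -> bool:
        return cpg in set(self.cpg_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cpg_id": list(self.cpg_ids)})
        if self.scores is not None:
            df["score"] = list(self.scores)
        return df


@dataclass(frozen=True)
class AnnotationTable:
    """CpG identifier -> gene symbol mapping (one symbol per CpG)."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def gene(self, cpg_id: str) -> str:
        return self.mapping.get(cpg_id, "")


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    # pandas silently renames duplicate header labels (cg1 -> cg1.1), so
    # uniqueness must be checked on the raw header line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for label in header:
        if label in seen:
            raise ValidationError(f"duplicate label in header: {label!r}")
        seen.add(label)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
        )
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return df


def _coerce_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    newly_bad = out.isna() & df.notna()
    if newly_bad.to_numpy().any():
        i, j = np.argwhere(newly_bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    return out


def load_methylation_table(
    path: str | Path,
    layout: str = SAMPLES_IN_ROWS,
    age_field: str = "age",
    sep: str | None = None,
) -> MethylationMatrix:
    """Read a labeled methylation table from delimited text.

    Parameters
    ----------
    path
        Delimited text file.  The separator defaults to tab, or comma for
        ``.csv`` files; pass ``sep`` to override.
    layout
        ``"samples-in-rows"``: first column holds sample ids, one column per
        CpG, plus one age column named ``age_field``.
        ``"cpgs-in-rows"``: first column holds CpG ids, one column per
        sample, plus one age *row* labeled ``age_field`` (GEO
        series-matrix style).
    age_field
        Label of the age column (or row).

    Raises
    ------
    FormatError
        If the file cannot be parsed or a cell is non-numeric.
    ValidationError
        If a beta value is outside [0, 1], an id is duplicated, or an age
        is missing or negative.
    """
    path = Path(path)
    if layout not in _LAYOUTS:
        raise ValueError(f"layout must be one of {_LAYOUTS}, got {layout!r}")
    df = _read_table(path, _sep_for(path, sep))
    if layout == CPGS_IN_ROWS:
        if age_field not in df.index:
            raise FormatError(f"{path}: age row {age_field!r} not found")
        df = df.T
    if age_field not in df.columns:
        raise FormatError(f"{path}: age column {age_field!r} not found")
    df = _coerce_numeric(df, path)
    ages = df[age_field]
    betas = df.drop(columns=[age_field])
    betas.index = betas.index.astype(str).rename(None)
    betas.columns = betas.columns.astype(str).rename(None)
    ages.index = betas.index
    ages.name = "age"
    return MethylationMatrix(betas, ages)


def load_prediction_table(
    path: str | Path,
    layout: str = SAMPLES_IN_ROWS,
    sep: str | None = None,
) -> MethylationMatrix:
    """Read an unlabeled (prediction-only) methylation table.

    Selectors and clock fitting require ages; this loader exists solely to
    feed :func:`cpgclock.clock.predict_age` with new samples.
    """
    path = Path(path)
    if layout not in _LAYOUTS:
        raise ValueError(f"layout must be one of {_LAYOUTS}, got {layout!r}")
    df = _read_table(path, _sep_for(path, sep))
    if layout == CPGS_IN_ROWS:
        df = df.T
    df = _coerce_numeric(df, path)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    return MethylationMatrix(df, None)


def save_methylation_table(
    m: MethylationMatrix,
    path: str | Path,
    layout: str = SAMPLES_IN_ROWS,
    age_field: str = "age",
    sep: str | None = None,
) -> None:
    """Write a matrix back to delimited text; round-trips cell-for-cell."""
    path = Path(path)
    if layout not in _LAYOUTS:
        raise ValueError(f"layout must be one of {_LAYOUTS}, got {layout!r}")
    df = m.betas.copy()
    if m.ages is not None:
        df[age_field] = m.ages
    if layout == CPGS_IN_ROWS:
        df = df.T
        df.index.name = "cpg_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path, sep), na_rep="NA")


# ---------------------------------------------------------------------------
# filtering and annotation
# ---------------------------------------------------------------------------


def drop_incomplete_cpgs(
    *matrices: MethylationMatrix,
) -> tuple[MethylationMatrix, ...]:
    """Restrict matrices to the CpGs complete (no missing value) in all of them.

    Mirrors the standard pre-comparison filter applied when several array
    datasets must share a feature space: a CpG is retained only if it is
    present, with no missing beta, in every input matrix.  Sample sets are
    unchanged; the retained CpG order follows the first matrix.
    """
    if not matrices:
        raise ValueError("at least one matrix required")
    complete: set[str] | None = None
    for m in matrices:
        ok = set(m.betas.columns[m.betas.notna().all(axis=0)])
        complete = ok if complete is None else complete & ok
    assert complete is not None
    kept = [c for c in matrices[0].cpg_ids if c in complete]
    if not kept:
        raise EmptyFeatureSpaceError(
            "no CpG site is complete across all input matrices"
        )
    return tuple(m.restrict(kept) for m in matrices)


def load_annotation(path: str | Path, sep: str | None = None) -> AnnotationTable:
    """Read a two-column (cpg_id, gene_symbol) annotation table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cpg_id, gene_symbol)")
    cpgs = df.iloc[:, 0]
    if cpgs.duplicated().any():
        raise ValidationError(f"duplicate CpG in annotation: {cpgs[cpgs.duplicated()].iloc[0]!r}")
    return AnnotationTable(dict(zip(cpgs, df.iloc[:, 1])))


def annotate_features(
    fs: FeatureSet, ann: AnnotationTable
) -> list[tuple[str, str]]:
    """Pair each CpG in ``fs`` with its gene symbol (blank when unannotated)."""
    return [(cpg, ann.gene(cpg)) for cpg in fs]
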