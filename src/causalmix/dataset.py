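"""Mixed continuous/categorical tabular data.

A :class:`MixedDataset` is the in-memory container used throughout the
package: an ``n x p`` table whose columns are either continuous (stored as
floats) or categorical (stored as non-negative level codes, with the level
labels kept on the per-column :class:`VariableSpec`).  Categorical levels are
ordered by first appearance in the source data; the first level is the
reference level for dummy coding everywhere in the package.

Missing values are rejected at load time: every downstream procedure
(pseudo-likelihood fitting, regression-based independence tests) assumes a
complete table, and silent imputation would change their results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: tokens treated as missing cells (always an error at load)
_NA_TOKENS = {"", "NA", "N/A", "NaN", "nan", "NAN", "null", "NULL", "."}


@dataclass(frozen=True)
class VariableSpec:
    """Type description of a single column.

    Parameters
    ----------
    name : str
        Column name (unique within a dataset).
    vtype : {"continuous", "categorical"}
    levels : tuple of str
        Category labels in first-appearance order; empty for continuous
        columns.  Categorical columns must have at least two levels.
    """

    name: str
    vtype: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.vtype not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.vtype == CATEGORICAL:
            if len(self.levels) < 2:
                raise ValueError(
                    f"categorical variable {self.name!r} needs >=2 levels, "
                    f"got {len(self.levels)}"
                )
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels for {self.name!r}")
        elif self.levels:
            raise ValueError(f"continuous variable {self.name!r} cannot have levels")

    @property
    def is_continuous(self) -> bool:
        return self.vtype == CONTINUOUS

    @property
    def is_categorical(self) -> bool:
        return self.vtype == CATEGORICAL

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class MixedDataset:
    """Complete mixed-type data table.

    ``frame`` holds floats for continuous columns and integer level codes for
    categorical columns, in the same column order as ``specs``.
    """

    specs: list[VariableSpec]
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if list(self.frame.columns) != names:
            raise ValueError("frame columns do not match specs")
        if self.frame.shape[0] < 1 or self.frame.shape[1] < 1:
            raise ValueError("dataset must have n >= 1 and p >= 1")
        if self.frame.isna().any().any():
            raise ValueError("dataset contains missing cells")
        for s in self.specs:
            col = self.frame[s.name].to_numpy()
            if s.is_categorical:
                codes = col.astype(int)
                if codes.min() < 0 or codes.max() >= s.n_levels:
                    raise ValueError(f"level code out of range in {s.name!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.frame.shape[0]

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def continuous_names(self) -> list[str]:
        return [s.name for s in self.specs if s.is_continuous]

    @property
    def categorical_names(self) -> list[str]:
        return [s.name for s in self.specs if s.is_categorical]

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def constant_columns(self) -> list[str]:
        """Names of columns with a single distinct value (degenerate)."""
        out = []
        for s in self.specs:
            if len(np.unique(self.column(s.name))) <= 1:
                out.append(s.name)
        return out

    def subset(self, names: Sequence[str]) -> "MixedDataset":
        specs = [self.spec(n) for n in names]
        return MixedDataset(specs=specs, frame=self.frame[list(names)].copy())

    def copy(self) -> "MixedDataset":
        return MixedDataset(specs=list(self.specs), frame=self.frame.copy())

    def to_labeled_frame(self) -> pd.DataFrame:
        """Frame with categorical codes mapped back to their labels."""
        out = {}
        for s in self.specs:
            col = self.frame[s.name]
            if s.is_categorical:
                out[s.name] = col.map(lambda c, lv=s.levels: lv[int(c)])
            else:
                out[s.name] = col
        return pd.DataFrame(out, columns=self.names)


# ---------------------------------------------------------------------------
# type inference and table reading
# ---------------------------------------------------------------------------

def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def infer_variable_types(
    values: Sequence, name: str = "x", max_levels: int = 5
) -> VariableSpec:
    """Infer a :class:`VariableSpec` from raw column tokens.

    Rules: any non-numeric token makes the column categorical; all-numeric
    columns with at most ``max_levels`` distinct values, all integral, are
    categorical (integer-coded factors); everything else is continuous.
    Constant columns are kept but flagged with a warning — they carry no
    information for any downstream method.
    """
    tokens = [str(v) for v in values]
    if len(tokens) == 0:
        raise ValueError(f"column {name!r} is empty")
    distinct = list(dict.fromkeys(tokens))  # first-appearance order
    if len(distinct) <= 1:
        warnings.warn(f"column {name!r} is constant", UserWarning, stacklevel=2)

    numeric = all(_is_number(t) for t in tokens)
    if not numeric:
        if len(distinct) < 2:
            # constant non-numeric column: treat as 2-level degenerate factor
            return VariableSpec(name, CATEGORICAL, tuple(distinct) + ("__other__",))
        return VariableSpec(name, CATEGORICAL, tuple(distinct))
    vals = [float(t) for t in distinct]
    if len(distinct) <= max_levels and all(float(v).is_integer() for v in vals):
        if len(distinct) < 2:
            return VariableSpec(name, CONTINUOUS)
        return VariableSpec(name, CATEGORICAL, tuple(distinct))
    return VariableSpec(name, CONTINUOUS)


def read_mixed_table(
    path: str | Path,
    delimiter: str = "\t",
    max_levels: int = 5,
    type_hints: Mapping[str, str] | None = None,
) -> MixedDataset:
    """Read a delimited text table (header row required) into a MixedDataset.

    ``type_hints`` maps column names to ``"continuous"``/``"categorical"``,
    overriding inference.  Missing cells, duplicate header names, empty files
    and non-numeric tokens in a continuous column are all load errors.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in header_line.rstrip("\n").split(delimiter)]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate header names {dups}")

    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, header=0, keep_default_na=False,
        skipinitialspace=True,
    )
    raw.columns = header
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: no data rows (header only)")

    # missing-cell scan with row/column coordinates (1-based data rows)
    for col in raw.columns:
        vals = raw[col].to_numpy()
        for i, v in enumerate(vals):
            if str(v).strip() in _NA_TOKENS:
                raise ValueError(
                    f"{path}: missing value at row {i + 1}, column {col!r}"
                )

    type_hints = dict(type_hints or {})
    specs: list[VariableSpec] = []
    columns: dict[str, np.ndarray] = {}
    for col in raw.columns:
        tokens = [str(v).strip() for v in raw[col]]
        hint = type_hints.get(col)
        if hint == CONTINUOUS:
            spec = VariableSpec(col, CONTINUOUS)
        elif hint == CATEGORICAL:
            distinct = list(dict.fromkeys(tokens))
            if len(distinct) < 2:
                warnings.warn(f"column {col!r} is constant", UserWarning,
                              stacklevel=2)
                distinct.append("__other__")
            spec = VariableSpec(col, CATEGORICAL, tuple(distinct))
        else:
            spec = infer_variable_types(tokens, name=col, max_levels=max_levels)
        if spec.is_continuous:
            bad = [t for t in tokens if not _is_number(t)]
            if bad:
                raise ValueError(
                    f"{path}: non-numeric token {bad[0]!r} in continuous "
                    f"column {col!r}"
                )
            columns[col] = np.array([float(t) for t in tokens])
        else:
            index = {lab: i for i, lab in enumerate(spec.levels)}
            columns[col] = np.array([index[t] for t in tokens], dtype=int)
        specs.append(spec)

    frame = pd.DataFrame(columns, columns=header)
    return MixedDataset(specs=specs, frame=frame)


def write_mixed_table(
    dataset: MixedDataset, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a dataset back to delimited text with level labels restored."""
    dataset.to_labeled_frame().to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# nonparanormal (Gaussian copula) transform
# ---------------------------------------------------------------------------

def nonparanormal_transform(dataset: MixedDataset) -> MixedDataset:
    """Rank-based Gaussianization of every continuous column.

    Each continuous column is replaced by standard-normal quantiles of its
    Winsorized empirical CDF: ranks (average over ties) are scaled to (0, 1),
    truncated at ``delta = 1 / (4 n^{1/4} sqrt(pi log n))``, mapped through
    the standard normal quantile function, and rescaled so the transformed
    column keeps the original sample standard deviation.  Ranks — and hence
    every downstream rank statistic — are preserved; applying the transform
    twice is a no-op up to floating point.  Categorical columns are untouched.
    """
    n = dataset.n
    if n < 3:
        raise ValueError("nonparanormal transform needs n >= 3")
    delta = 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))
    frame = dataset.frame.copy()
    for s in dataset.specs:
        if not s.is_continuous:
            continue
        x = frame[s.name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            warnings.warn(
                f"column {s.name!r} is constant; left untransformed",
                UserWarning, stacklevel=2,
            )
            continue
        u = rankdata(x, method="average") / n
        u = np.clip(u, delta, 1.0 - delta)
        z = ndtri(u)
        frame[s.name] = z / z.std() * sd
    return MixedDataset(specs=list(dataset.specs), frame=frame)


def from_dataframe(
    df: pd.DataFrame,
    max_levels: int = 5,
    type_hints: Mapping[str, str] | None = None,
) -> MixedDataset:
    """Build a MixedDataset from a pandas DataFrame.

    pandas ``category``/object/bool columns become categorical (levels in
    first-appearance order); numeric columns go through the same inference
    rule as :func:`read_mixed_table`.
    """
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError("empty DataFrame")
    if df.isna().any().any():
        raise ValueError("DataFrame contains missing values")
    if len(set(df.columns)) != len(df.columns):
        raise ValueError("duplicate column names")
    type_hints = dict(type_hints or {})
    specs: list[VariableSpec] = []
    columns: dict[str, np.ndarray] = {}
    for col in df.columns:
        series = df[col]
        hint = type_hints.get(col)
        if hint is None and (
            isinstance(series.dtype, pd.CategoricalDtype)
            or series.dtype == object
            or series.dtype == bool
        ):
            hint = CATEGORICAL
        tokens = [str(v) for v in series]
        if hint == CONTINUOUS:
            spec = VariableSpec(col, CONTINUOUS)
        elif hint == CATEGORICAL:
            distinct = list(dict.fromkeys(tokens))
            if len(distinct) < 2:
                warnings.warn(f"column {col!r} is constant", UserWarning,
                              stacklevel=2)
                distinct.append("__other__")
            spec = VariableSpec(col, CATEGORICAL, tuple(distinct))
        else:
            spec = infer_variable_types(tokens, name=col, max_levels=max_levels)
        if spec.is_continuous:
            columns[col] = series.to_numpy(dtype=float)
        else:
            index = {lab: i for i, lab in enumerate(spec.levels)}
            columns[col] = np.array([index[t] for t in tokens], dtype=int)
        specs.append(spec)
    return MixedDataset(specs=specs, frame=pd.DataFrame(columns, columns=list(df.columns)))


def as_mixed_dataset(X, max_levels: int = 5) -> MixedDataset:
    """Coerce an input (MixedDataset, DataFrame, or 2-D array) to MixedDataset."""
    if isinstance(X, MixedDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return from_dataframe(X, max_levels=max_levels)
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D table")
    df = pd.DataFrame(arr, columns=[f"V{j}" for j in range(arr.shape[1])])
    return from_dataframe(df, max_levels=max_levels)
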