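"""Wide-form data handling for two-instance repeated-measures designs.

Each participant is observed twice on the same outcome (two conditions, or
two time points) and once on each between-participant moderator.  Analyses
operate on the *difference score* ``Y_D = y_first - y_second``, taken in the
order the outcome columns are supplied, so a positive difference means the
first-listed outcome was larger.

This module owns ingestion (CSV with listwise deletion), mean-centering of
continuous moderators, difference-score construction, and contrast coding of
multicategorical moderators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CenteringError,
    FileFormatError,
    MissingColumnError,
    RepmodError,
    SampleSizeError,
    SingularDesignError,
)

__all__ = [
    "WideDataset",
    "ModelSpec",
    "read_wide_csv",
    "make_difference",
    "center_moderators",
    "encode_multicategorical",
    "expand_categoricals",
]

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"


@dataclass(frozen=True)
class WideDataset:
    """One row per participant: two outcome instances plus moderators.

    Parameters
    ----------
    y1, y2 : ndarray
        Outcome in the first- and second-listed instance (same units).
    moderators : DataFrame
        One column per between-participant moderator, aligned with ``y1``.
    y_names : tuple of str
        Names of the two outcome columns, in subtraction order.
    categorical : frozenset of str
        Moderator columns to treat as categorical (never centered; contrast
        coded before entering a design).
    n_dropped : int
        Rows removed by listwise deletion at read time.
    centered_means : dict
        Original sample means of columns that have been mean-centered, so
        probe values can be translated between the raw and analysis scales.
    """

    y1: np.ndarray
    y2: np.ndarray
    moderators: pd.DataFrame
    y_names: tuple[str, str] = ("y1", "y2")
    categorical: frozenset = frozenset()
    n_dropped: int = 0
    centered_means: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "y1", np.asarray(self.y1, dtype=float))
        object.__setattr__(self, "y2", np.asarray(self.y2, dtype=float))
        if len(self.y1) != len(self.y2) or len(self.y1) != len(self.moderators):
            raise RepmodError("y1, y2 and moderators must have equal length")

    @property
    def n(self) -> int:
        return len(self.y1)

    @property
    def w_names(self) -> list[str]:
        return list(self.moderators.columns)

    def validate(self, q: int | None = None) -> None:
        """Check minimum sample size and that no moderator is constant."""
        q = len(self.w_names) if q is None else q
        if self.n < q + 2:
            raise SampleSizeError(
                f"need at least q + 2 = {q + 2} complete rows, got {self.n}"
            )
        for name in self.w_names:
            if self.moderators[name].nunique(dropna=True) < 2:
                raise SingularDesignError(
                    f"moderator {name!r} has fewer than 2 distinct values"
                )


@dataclass(frozen=True)
class ModelSpec:
    """Analysis options for a two-instance moderation model.

    ``model_type`` selects additive moderation (moderators do not interact
    with each other) or multiplicative moderation (all cross-products enter,
    so with two moderators the W1*W2 coefficient tests a three-way
    interaction with condition).  With a single moderator the two are the
    same model.

    ``center`` is ``True`` (default: mean-center continuous moderators;
    numeric 0/1 columns and categoricals are left alone), ``False``
    (center nothing) or a per-column ``{name: bool}`` mapping.
    """

    model_type: str = MULTIPLICATIVE
    center: bool | Mapping[str, bool] = True
    alpha: float = 0.05
    probe_mode: str = "meansd"  # 'meansd' | 'percentile' | 'custom'
    probe_values: Mapping[str, Sequence[float]] | None = None
    jn: bool = False

    def __post_init__(self):
        if self.model_type not in (ADDITIVE, MULTIPLICATIVE):
            raise RepmodError(f"unknown model_type {self.model_type!r}")
        if not (0.0 < self.alpha < 1.0):
            raise RepmodError("alpha must be in (0, 1)")
        if self.probe_mode not in ("meansd", "percentile", "custom"):
            raise RepmodError(f"unknown probe_mode {self.probe_mode!r}")
        if self.probe_values is not None:
            for name, vals in self.probe_values.items():
                if not all(math.isfinite(float(v)) for v in vals):
                    raise RepmodError(f"non-finite probe value for {name!r}")


def read_wide_csv(
    path,
    y_names: Sequence[str],
    w_names: Sequence[str],
    categorical: Sequence[str] = (),
) -> WideDataset:
    """Read a wide-form CSV: two outcome columns plus moderator columns.

    Rows with a missing value in any named column are dropped listwise and
    the count recorded (difference scores require complete pairs).  Columns
    with non-numeric values are treated as categorical automatically.
    """
    if len(y_names) != 2:
        raise RepmodError("y_names must name exactly two outcome columns")
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FileFormatError(f"cannot parse {path} as CSV: {exc}") from exc
    wanted = list(y_names) + list(w_names)
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"column(s) {missing} not found in {path} "
            f"(available: {list(df.columns)})"
        )
    sub = df[wanted].dropna()
    n_dropped = len(df) - len(sub)

    for yc in y_names:
        if not pd.api.types.is_numeric_dtype(sub[yc]):
            raise RepmodError(f"outcome column {yc!r} is not numeric")

    cats = set(categorical)
    for wc in w_names:
        if not pd.api.types.is_numeric_dtype(sub[wc]):
            cats.add(wc)

    d = WideDataset(
        y1=sub[y_names[0]].to_numpy(dtype=float),
        y2=sub[y_names[1]].to_numpy(dtype=float),
        moderators=sub[list(w_names)].reset_index(drop=True),
        y_names=(y_names[0], y_names[1]),
        categorical=frozenset(cats),
        n_dropped=n_dropped,
    )
    if d.n < len(w_names) + 2:
        raise SampleSizeError(
            f"only {d.n} complete rows after listwise deletion; "
            f"need at least {len(w_names) + 2}"
        )
    return d


def make_difference(d: WideDataset) -> np.ndarray:
    """Difference score ``Y_D = y_first - y_second`` (input order)."""
    return d.y1 - d.y2


def _is_dichotomous01(col: pd.Series) -> bool:
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1, 0.0, 1.0}


def resolve_centering(d: WideDataset, spec: ModelSpec) -> dict[str, bool]:
    """Decide per moderator column whether it will be mean-centered.

    Default policy: center continuous numeric moderators; leave numeric 0/1
    (dichotomous) columns and categorical columns on their original coding.
    A per-column mapping in ``spec.center`` overrides the default; asking to
    center a categorical column is an error.
    """
    out: dict[str, bool] = {}
    for name in d.w_names:
        if isinstance(spec.center, Mapping):
            want = spec.center.get(name, None)
        else:
            want = None if spec.center else False
        if name in d.categorical:
            if want:
                raise CenteringError(f"cannot mean-center categorical column {name!r}")
            out[name] = False
        elif want is not None:
            out[name] = bool(want)
        else:
            out[name] = not _is_dichotomous01(d.moderators[name])
    return out


def center_moderators(d: WideDataset, spec: ModelSpec) -> WideDataset:
    """Mean-center the flagged moderator columns, recording original means."""
    flags = resolve_centering(d, spec)
    mods = d.moderators.copy()
    means = dict(d.centered_means)
    for name, do in flags.items():
        if not do:
            continue
        mu = float(mods[name].mean()) + means.get(name, 0.0)
        mods[name] = mods[name] - mods[name].mean()
        means[name] = mu
    return replace(d, moderators=mods, centered_means=means)


def encode_multicategorical(w: pd.Series, scheme: str = "indicator") -> pd.DataFrame:
    """Code a k-category column into k-1 numeric contrast columns.

    ``indicator``: the first category (by sorted label) is the reference and
    maps to an all-zero row; each other category gets its own 0/1 column.
    ``helmert``: column j contrasts category j+1 against all earlier
    categories (-1 for earlier categories, j for category j+1, 0 after), so
    every column sums to zero over the category set.
    """
    name = w.name if w.name is not None else "w"
    cats = sorted(pd.unique(w.dropna()), key=str)
    k = len(cats)
    if k < 2:
        raise SingularDesignError(
            f"column {name!r} has {k} category; no contrast possible"
        )
    idx = w.map({c: i for i, c in enumerate(cats)}).to_numpy()
    cols = {}
    if scheme == "indicator":
        for j, cat in enumerate(cats[1:], start=1):
            cols[f"{name}[{cat}]"] = (idx == j).astype(float)
    elif scheme == "helmert":
        for j in range(1, k):
            col = np.zeros(len(w))
            col[idx < j] = -1.0
            col[idx == j] = float(j)
            cols[f"{name}.H{j}"] = col
    else:
        raise RepmodError(f"unknown coding scheme {scheme!r}")
    return pd.DataFrame(cols, index=w.index)


def expand_categoricals(d: WideDataset, scheme: str = "indicator") -> WideDataset:
    """Replace categorical moderator columns with their contrast codes."""
    if not d.categorical:
        return d
    pieces = []
    for name in d.w_names:
        if name in d.categorical:
            pieces.append(encode_multicategorical(d.moderators[name], scheme))
        else:
            pieces.append(d.moderators[[name]])
    mods = pd.concat(pieces, axis=1)
    return replace(d, moderators=mods, categorical=frozenset())
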