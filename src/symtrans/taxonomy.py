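"""Variable taxonomy and metafile handling.

Clinical tables mix measurement types — serum levels, event counts,
questionnaire scores, ranks — and each type has its own natural family of
symmetry-targeting re-expressions.  A ten-kind taxonomy captures the
distinctions that matter for choosing a transformation: whether the variable
is bounded, whether it is a count, whether it is built from two other
columns.  The dataset is accompanied by a *metafile*, one row per variable,
declaring its kind, context bounds, component columns and an optional
direction-reversal flag; everything downstream (skew scanning, candidate
search, the transform registry) is driven by this declaration.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariableKind",
    "VariableMeta",
    "Metafile",
    "MetafileError",
    "Violation",
    "read_metafile",
    "validate_against_data",
]

#: columns the metafile reader understands, in canonical order
METAFILE_COLUMNS = (
    "variable",
    "type",
    "lower",
    "upper",
    "denominator",
    "components",
    "reverse",
    "order",
)

_TRUE_TOKENS = {"true", "1", "yes", "t", "y"}
_FALSE_TOKENS = {"false", "0", "no", "f", "n", ""}

#: tolerance for deciding a stored float is an integer
INTEGER_TOL = 1e-9


class VariableKind(str, enum.Enum):
    """The ten admissible measurement kinds.

    ``amount``           nonnegative continuous measurement (serum protein);
    ``count``            nonnegative integer count of units (adverse events);
    ``ratio``            one amount divided by another (protein/creatinine);
    ``fraction``         a ratio bounded in [0, 1];
    ``counted_fraction`` n successes out of m trials;
    ``bounded_amount``   continuous, inherently bounded a <= y <= b;
    ``bounded_count``    integer, inherently bounded l <= n <= m (test score);
    ``difference``       difference of two amounts/counts, may be negative;
    ``rank``             rank out of N items, treated as a bounded count;
    ``ordinal``          ordered named categories.
    """

    AMOUNT = "amount"
    COUNT = "count"
    RATIO = "ratio"
    FRACTION = "fraction"
    COUNTED_FRACTION = "counted_fraction"
    BOUNDED_AMOUNT = "bounded_amount"
    BOUNDED_COUNT = "bounded_count"
    DIFFERENCE = "difference"
    RANK = "rank"
    ORDINAL = "ordinal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class MetafileError(ValueError):
    """Fatal metafile problem (missing required column, duplicate names)."""


@dataclass
class VariableMeta:
    """One metafile row: everything needed to transform one variable.

    Parameters
    ----------
    name : str
        Column name in the data table.
    kind : VariableKind
        Taxonomy kind; drives the transform dispatch.
    lower, upper : float, optional
        Context bounds.  Required (both) for ``bounded_amount`` /
        ``bounded_count``; ``upper`` is the total ranked N for ``rank``
        (inferred from the data, with a flag, when absent).
    denominator : str or float, optional
        For ratio/fraction/counted_fraction variables built from two
        columns: the denominator column name, or a constant total.
    components : (str, str), optional
        The two component columns of a ``difference`` variable.
    reverse : bool
        Negate the transformed values so that "healthy" points the same
        way across variables.
    category_order : list of str, optional
        Ordered category labels, required for ``ordinal``.
    """

    name: str
    kind: VariableKind
    lower: Optional[float] = None
    upper: Optional[float] = None
    denominator: Optional[Union[str, float]] = None
    components: Optional[tuple] = None
    reverse: bool = False
    category_order: Optional[list] = None
    rank_total_inferred: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.kind = VariableKind(self.kind)
        k = self.kind
        if k in (VariableKind.BOUNDED_AMOUNT, VariableKind.BOUNDED_COUNT):
            if self.lower is None or self.upper is None:
                raise ValueError(
                    f"{self.name}: kind {k} requires both lower and upper bounds"
                )
            if not self.lower < self.upper:
                raise ValueError(
                    f"{self.name}: lower bound {self.lower} must be < upper {self.upper}"
                )
        if k is VariableKind.COUNTED_FRACTION:
            if self.denominator is None:
                raise ValueError(
                    f"{self.name}: counted_fraction requires a denominator "
                    "(column name or positive integer total)"
                )
            if isinstance(self.denominator, (int, float)) and self.denominator <= 0:
                raise ValueError(
                    f"{self.name}: constant denominator must be a positive integer"
                )
        if k is VariableKind.ORDINAL:
            if self.category_order is None or len(set(self.category_order)) < 2:
                raise ValueError(
                    f"{self.name}: ordinal requires category_order with >=2 distinct labels"
                )
        if k is VariableKind.RANK and self.upper is None:
            # allowed, but the total ranked N will be inferred from the data
            self.rank_total_inferred = True
        if self.components is not None:
            self.components = tuple(self.components)
            if len(self.components) != 2:
                raise ValueError(f"{self.name}: components must name exactly two columns")

    # -- serialization -----------------------------------------------------

    def to_row(self) -> dict:
        """Render as a metafile row (dict keyed by METAFILE_COLUMNS)."""
        return {
            "variable": self.name,
            "type": self.kind.value,
            "lower": "" if self.lower is None else repr(self.lower),
            "upper": "" if self.upper is None else repr(self.upper),
            "denominator": "" if self.denominator is None else str(self.denominator),
            "components": "|".join(self.components) if self.components else "",
            "reverse": "true" if self.reverse else "false",
            "order": "|".join(map(str, self.category_order))
            if self.category_order
            else "",
        }


@dataclass
class Metafile:
    """Parsed metafile: valid rows plus the row-level errors encountered."""

    variables: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)  # (row_number, message)
    warnings: list = field(default_factory=list)

    def __iter__(self) -> Iterator[VariableMeta]:
        return iter(self.variables.values())

    def __len__(self) -> int:
        return len(self.variables)

    def __getitem__(self, name: str) -> VariableMeta:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def raise_on_errors(self) -> "Metafile":
        if self.errors:
            lines = "; ".join(f"row {r}: {m}" for r, m in self.errors)
            raise MetafileError(f"metafile row errors: {lines}")
        return self

    def to_csv(self, path) -> None:
        rows = [m.to_row() for m in self]
        pd.DataFrame(rows, columns=list(METAFILE_COLUMNS)).to_csv(path, index=False)


def _parse_optional_float(cell: str, what: str):
    if cell is None or cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ValueError(f"{what}: not a number: {cell!r}") from exc


def _parse_denominator(cell: str):
    if cell is None or cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        return cell  # a column name


def _parse_bool(cell: str) -> bool:
    token = (cell or "").strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"reverse flag not understood: {cell!r}")


def read_metafile(path) -> Metafile:
    """Read and validate a metafile.

    The metafile is a comma-delimited text file with a header row naming at
    least ``variable`` and ``type``; the optional columns are ``lower``,
    ``upper``, ``denominator``, ``components``, ``reverse`` and ``order``
    (``components`` and ``order`` hold pipe-separated lists).  Unknown
    columns are ignored with a warning.  Row-level problems (e.g. an unknown
    kind token) are collected with their row numbers on the returned
    :class:`Metafile` rather than aborting the read; missing required
    columns and duplicate variable names are fatal.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    missing = {"variable", "type"} - set(raw.columns)
    if missing:
        raise MetafileError(f"metafile missing required column(s): {sorted(missing)}")

    meta = Metafile()
    unknown = [c for c in raw.columns if c not in METAFILE_COLUMNS]
    for col in unknown:
        msg = f"ignoring unknown metafile column {col!r}"
        meta.warnings.append(msg)
        logger.warning(msg)

    names = raw["variable"].str.strip()
    dupes = names[names.duplicated()].unique()
    if len(dupes):
        raise MetafileError(f"duplicate variable names in metafile: {sorted(dupes)}")

    def cell(row, col):
        return str(row[col]).strip() if col in raw.columns else ""

    for idx, row in raw.iterrows():
        rownum = int(idx) + 2  # 1-based, after the header
        name = cell(row, "variable")
        try:
            kind_token = cell(row, "type")
            if kind_token not in VariableKind._value2member_map_:
                raise ValueError(f"unknown kind {kind_token!r}")
            comp = cell(row, "components")
            order = cell(row, "order")
            vm = VariableMeta(
                name=name,
                kind=VariableKind(kind_token),
                lower=_parse_optional_float(cell(row, "lower"), f"{name}.lower"),
                upper=_parse_optional_float(cell(row, "upper"), f"{name}.upper"),
                denominator=_parse_denominator(cell(row, "denominator")),
                components=tuple(comp.split("|")) if comp else None,
                reverse=_parse_bool(cell(row, "reverse")),
                category_order=order.split("|") if order else None,
            )
        except ValueError as exc:
            meta.errors.append((rownum, str(exc)))
            continue
        meta.variables[name] = vm
    return meta


@dataclass(frozen=True)
class Violation:
    """One data/metafile inconsistency found by :func:`validate_against_data`."""

    variable: str
    message: str
    count: int = 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.variable}: {self.message} ({self.count} value(s))"


_INTEGER_KINDS = (
    VariableKind.COUNT,
    VariableKind.BOUNDED_COUNT,
    VariableKind.RANK,
    VariableKind.COUNTED_FRACTION,
)


def validate_against_data(
    metas: Iterable[VariableMeta], table: pd.DataFrame
) -> list:
    """Check a data table against its metafile declarations.

    Returns a list of :class:`Violation`; an empty list means the table is
    consistent with the metadata.  A declared variable that is absent from
    the table is itself a violation (the variable is skipped downstream,
    not fatal).  Missing values are ignored by every check.
    """
    violations: list = []

    def add(var: str, message: str, count: int = 1) -> None:
        violations.append(Violation(var, message, count))

    for m in metas:
        if m.name not in table.columns:
            add(m.name, "declared in metafile but absent from data table")
            continue
        col = table[m.name]
        if m.kind is VariableKind.ORDINAL:
            labels = col.dropna().astype(str)
            bad = ~labels.isin([str(c) for c in m.category_order])
            if bad.any():
                add(m.name, "ordinal labels not in category_order", int(bad.sum()))
            continue
        vals = pd.to_numeric(col, errors="coerce")
        newly_bad = vals.isna() & col.notna()
        if newly_bad.any():
            add(m.name, "non-numeric values", int(newly_bad.sum()))
        x = vals.dropna().to_numpy(dtype=float)
        if m.kind in (VariableKind.AMOUNT, VariableKind.COUNT):
            neg = x < (m.lower if m.kind is VariableKind.AMOUNT and m.lower is not None else 0)
            if neg.any():
                what = "below lower bound" if m.lower else f"negative {m.kind.value}"
                add(m.name, what, int(neg.sum()))
        if m.kind in _INTEGER_KINDS:
            frac = np.abs(x - np.round(x)) > INTEGER_TOL
            if frac.any():
                add(m.name, f"non-integer values for kind {m.kind.value}", int(frac.sum()))
        if m.lower is not None and m.kind not in (VariableKind.AMOUNT, VariableKind.COUNT):
            below = x < m.lower
            if below.any():
                add(m.name, "below lower bound", int(below.sum()))
        if m.upper is not None:
            above = x > m.upper
            if above.any():
                add(m.name, "above upper bound", int(above.sum()))
        if m.kind is VariableKind.FRACTION and m.denominator is None:
            out = (x < 0) | (x > 1)
            if out.any():
                add(m.name, "fraction values outside [0, 1]", int(out.sum()))
        if isinstance(m.denominator, str) and m.denominator not in table.columns:
            add(m.name, f"denominator column {m.denominator!r} missing from table")
        if m.components is not None:
            for c in m.components:
                if c not in table.columns:
                    add(m.name, f"component column {c!r} missing from table")
    return violations
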