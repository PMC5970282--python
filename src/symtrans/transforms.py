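"""Symmetry-targeting re-expressions: the power ladder and the kind dispatch.

The workhorse family is the ladder of powers x -> x**p over the discrete
grid p = m/n with n in {1, 2, 3} and m in {-2, ..., 2} (11 distinct rungs),
where p = 0 stands for the logarithm.  A discrete, interpretable grid is
deliberate: square root of a count is a rate-like score, an inverse of a
time is a speed.  Negative rungs are monotone *decreasing*.

Each taxonomy kind composes the ladder with its own re-expression:

=================  ====================================================
amount             (y - C + start) ** p, C the context lower bound
count              (n + start) ** p, default p = 1/2 (Poisson-stabilizing)
ratio              x**p - y**p; log x - log y at p = 0
fraction           folded power r**p - (1-r)**p; logit at p = 0
counted_fraction   logit-style with a 1/3 start: log((n+1/3)/(m-n+1/3))
bounded_amount     rewrite as fraction r = (y-a)/(b-a), then as fraction
bounded_count      log((n-l+1/3)/(m-n+1/3))
rank               bounded count with l = 1, m = N
ordinal            mid-proportion logit scores against a logistic reference
difference         transform the two components separately and subtract
=================  ====================================================

The 1/3 start keeps the counted logits finite at the boundaries n = 0 and
n = m.  ``power == 1`` always denotes the identity (no transformation):
for every family the literal p = 1 member is affine in the raw values, so
nothing is lost and "untransformed" stays exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .taxonomy import VariableKind, VariableMeta

__all__ = [
    "LADDER",
    "DomainError",
    "TransformSpec",
    "ladder_powers",
    "power_transform",
    "amount_transform",
    "count_transform",
    "ratio_transform",
    "fraction_transform",
    "counted_fraction_logit",
    "bounded_amount_transform",
    "bounded_count_transform",
    "rank_transform",
    "ordinal_scores",
    "difference_transform",
    "default_start",
    "identity_spec",
    "apply",
]

#: the 11 distinct rungs of the ladder, ascending
LADDER = tuple(
    sorted({Fraction(m, n) for n in (1, 2, 3) for m in (-2, -1, 0, 1, 2)})
)

START_THIRD = 1.0 / 3.0


class DomainError(ValueError):
    """An input fell outside the transformation's domain."""


def ladder_powers() -> list:
    """The ladder rungs {m/n : n=1,2,3; m=-2..2} as ascending Fractions."""
    return list(LADDER)


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def _first_offender(arr: np.ndarray, bad: np.ndarray) -> float:
    return float(np.asarray(arr).reshape(-1)[np.flatnonzero(np.asarray(bad).reshape(-1))[0]])


def power_transform(x, p, log_base: float = math.e):
    """x**p for a ladder rung p; the log for p = 0.

    Monotone increasing for p >= 0, monotone decreasing for p < 0.
    Requires x > 0 (x >= 0 is tolerated for p > 0, where the limit is 0);
    callers are expected to shift/start their values first.
    """
    p = Fraction(p)
    arr, scalar = _as_array(x)
    with np.errstate(invalid="ignore"):
        if p <= 0:
            bad = ~(arr > 0) & ~np.isnan(arr)
        else:
            bad = ~(arr >= 0) & ~np.isnan(arr)
    if bad.any():
        raise DomainError(
            f"value {_first_offender(arr, bad)} outside domain of power p={p}"
        )
    if p == 0:
        out = np.log(arr) / math.log(log_base)
    else:
        out = np.power(arr, float(p))
    return _ret(out, scalar)


def amount_transform(y, C: float = 0.0, p=1, start: float = 0.0):
    """Transform an amount bounded below by C: power of (y - C + start).

    ``start`` > 0 keeps zero shifted amounts inside the log/negative-power
    domain (see :func:`default_start`).
    """
    arr, scalar = _as_array(y)
    bad = (arr < C) & ~np.isnan(arr)
    if bad.any():
        raise DomainError(f"amount value {_first_offender(arr, bad)} below lower bound {C}")
    if start < 0:
        raise DomainError("start must be nonnegative")
    return _ret(np.asarray(power_transform(arr - C + start, p)), scalar)


def count_transform(n, p=Fraction(1, 2), start: float = 0.0):
    """Transform a nonnegative count; default rung p = 1/2.

    The square root stabilizes Poisson variance (to ~1/4) and usually
    symmetrizes.  ``start`` is only needed when zeros are present and
    p <= 0.
    """
    arr, scalar = _as_array(n)
    bad = (arr < 0) & ~np.isnan(arr)
    if bad.any():
        raise DomainError(f"negative count {_first_offender(arr, bad)}")
    return _ret(np.asarray(power_transform(arr + start, p)), scalar)


def ratio_transform(x, y, p, log_base: float = math.e):
    """Transform a ratio of two amounts: x**p - y**p (log x - log y at p=0)."""
    p = Fraction(p)
    xa, sx = _as_array(x)
    ya, sy = _as_array(y)
    tx = np.asarray(power_transform(xa, p, log_base))
    ty = np.asarray(power_transform(ya, p, log_base))
    return _ret(tx - ty, sx and sy)


def fraction_transform(r, p, log_base: float = math.e):
    """Transform a fraction r in [0, 1]: the logit at p = 0, else the
    folded power r**p - (1-r)**p.

    The folded power preserves the complement antisymmetry
    T(1 - r) = -T(r) that makes a fraction and its complement carry the
    same information.  The boundaries r = 0, 1 are outside the domain for
    p <= 0 (use the counted-fraction 1/3 start, or a positive folded
    power, for data that attains them).
    """
    p = Fraction(p)
    arr, scalar = _as_array(r)
    out01 = ((arr < 0) | (arr > 1)) & ~np.isnan(arr)
    if out01.any():
        raise DomainError(f"fraction value {_first_offender(arr, out01)} outside [0, 1]")
    if p <= 0:
        boundary = ((arr == 0) | (arr == 1)) & ~np.isnan(arr)
        if boundary.any():
            raise DomainError(
                f"fraction value {_first_offender(arr, boundary)} on the boundary: "
                "use the counted-fraction 1/3 start or a positive folded power"
            )
    if p == 0:
        out = (np.log(arr) - np.log1p(-arr)) / math.log(log_base)
    else:
        out = np.power(arr, float(p)) - np.power(1.0 - arr, float(p))
    return _ret(out, scalar)


def counted_fraction_logit(n, m, start: float = START_THIRD, log_base: float = math.e):
    """Started logit of n successes out of m: log((n + 1/3)/(m - n + 1/3)).

    The 1/3 start keeps the value finite at n = 0 and n = m.
    """
    na, sn = _as_array(n)
    ma, sm = _as_array(m)
    bad = ((na < 0) | (na > ma)) & ~(np.isnan(na) | np.isnan(ma))
    if bad.any():
        raise DomainError(
            f"counted fraction numerator {_first_offender(na, bad)} outside [0, m]"
        )
    out = (np.log(na + start) - np.log(ma - na + start)) / math.log(log_base)
    return _ret(out, sn and sm)


def _started_fraction(n, l, m, start: float = START_THIRD):
    """(n - l + start) / (m - l + 2*start): the started fraction whose logit
    is exactly log((n - l + start)/(m - n + start))."""
    na, scalar = _as_array(n)
    return _ret((na - l + start) / (m - l + 2 * start), scalar)


def bounded_amount_transform(y, a: float, b: float, p, log_base: float = math.e):
    """Transform an inherently bounded amount a <= y <= b as the fraction
    r = (y - a)/(b - a)."""
    if not a < b:
        raise DomainError(f"bounds must satisfy a < b, got a={a}, b={b}")
    arr, scalar = _as_array(y)
    bad = ((arr < a) | (arr > b)) & ~np.isnan(arr)
    if bad.any():
        raise DomainError(
            f"bounded amount {_first_offender(arr, bad)} outside [{a}, {b}]"
        )
    return _ret(
        np.asarray(fraction_transform((arr - a) / (b - a), p, log_base)), scalar
    )


def bounded_count_transform(n, l: float, m: float, start: float = START_THIRD,
                            log_base: float = math.e):
    """Transform an inherently bounded count l <= n <= m as a counted
    fraction with the 1/3 start: log((n - l + 1/3)/(m - n + 1/3))."""
    if not l < m:
        raise DomainError(f"bounds must satisfy l < m, got l={l}, m={m}")
    arr, scalar = _as_array(n)
    bad = ((arr < l) | (arr > m)) & ~np.isnan(arr)
    if bad.any():
        raise DomainError(
            f"bounded count {_first_offender(arr, bad)} outside [{l}, {m}]"
        )
    out = (np.log(arr - l + start) - np.log(m - arr + start)) / math.log(log_base)
    return _ret(out, scalar)


def rank_transform(rank, N: int, start: float = START_THIRD, log_base: float = math.e):
    """Transform a rank out of N as the bounded count on [1, N].

    Ties resolved upstream to mid-ranks map to equal transformed values.
    """
    return bounded_count_transform(rank, 1, N, start=start, log_base=log_base)


def ordinal_scores(category_counts: Sequence[int]) -> np.ndarray:
    """Numeric scores for ordered categories against a logistic reference.

    Category k (proportion f_k, cumulative proportion F_{k-1} strictly
    below it) scores logit(F_{k-1} + f_k / 2) — the logit of the midpoint
    of its cumulative interval, akin to mid-ranks with ties.  Scores are
    strictly increasing over nonempty categories and antisymmetric for
    count vectors symmetric under reversal.  An empty category receives
    the logit of its zero-width midpoint (infinite when that midpoint sits
    on a boundary).
    """
    counts = np.asarray(category_counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise DomainError("need counts for at least two ordered categories")
    if (counts < 0).any():
        raise DomainError("category counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise DomainError("all category counts are zero")
    f = counts / total
    F_below = np.concatenate(([0.0], np.cumsum(f)[:-1]))
    mid = F_below + f / 2.0
    with np.errstate(divide="ignore"):
        return np.log(mid) - np.log1p(-mid)


def difference_transform(x, y, spec_x: "TransformSpec", spec_y: "TransformSpec"):
    """Transform a difference by re-expressing its two components
    separately and subtracting: T1(x) - T2(y)."""
    if VariableKind.DIFFERENCE in (spec_x.kind, spec_y.kind):
        raise DomainError("difference components cannot themselves be differences")
    return _apply_spec_to_values(np.asarray(x, dtype=float), spec_x) - \
        _apply_spec_to_values(np.asarray(y, dtype=float), spec_y)


def default_start(values, p) -> float:
    """Start policy for amounts/counts containing zeros.

    Half the smallest positive observed value, applied only when zeros are
    present *and* the rung needs it (p <= 0); otherwise 0.
    """
    if Fraction(p) > 0:
        return 0.0
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0 or (arr > 0).all():
        return 0.0
    pos = arr[arr > 0]
    if pos.size == 0:
        raise DomainError("no positive values: cannot choose a start")
    return float(pos.min()) / 2.0


# ---------------------------------------------------------------------------
# TransformSpec: a concrete, serializable transformation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransformSpec:
    """A concrete transformation: taxonomy family + ladder rung + constants.

    ``power == 1`` denotes the identity (pass-through) for every kind.
    Serializes to the flat record ``kind|p_num/p_den|lower|upper|const|
    reverse|base`` and re-parses bit-identically.
    """

    kind: VariableKind
    power: Fraction = Fraction(1)
    lower: Optional[float] = None
    upper: Optional[float] = None
    additive_constant: float = 0.0
    reverse: bool = False
    log_base: float = math.e

    def __post_init__(self):
        object.__setattr__(self, "kind", VariableKind(self.kind))
        object.__setattr__(self, "power", Fraction(self.power))
        if self.power not in LADDER:
            raise ValueError(f"power {self.power} is not on the ladder {LADDER}")
        if self.additive_constant < 0:
            raise ValueError("additive_constant must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return self.power == 1

    def describe(self) -> str:
        """Human-readable label for reports."""
        if self.is_identity:
            base = "identity"
        elif self.power == 0:
            base = {
                VariableKind.FRACTION: "logit",
                VariableKind.COUNTED_FRACTION: "started logit",
                VariableKind.BOUNDED_AMOUNT: "logit",
                VariableKind.BOUNDED_COUNT: "started logit",
                VariableKind.RANK: "started logit",
            }.get(self.kind, "log")
        elif self.power == Fraction(-1):
            base = "inverse"
        elif self.power == Fraction(1, 2):
            base = "square root"
        else:
            base = f"power {self.power}"
        return base + (" (reversed)" if self.reverse else "")

    # -- registry serialization -------------------------------------------

    def serialize(self) -> str:
        def num(v):
            return "" if v is None else repr(float(v))

        return "|".join(
            [
                self.kind.value,
                f"{self.power.numerator}/{self.power.denominator}",
                num(self.lower),
                num(self.upper),
                repr(float(self.additive_constant)),
                "true" if self.reverse else "false",
                repr(float(self.log_base)),
            ]
        )

    @classmethod
    def deserialize(cls, text: str) -> "TransformSpec":
        parts = text.strip().split("|")
        if len(parts) != 7:
            raise ValueError(f"malformed TransformSpec record: {text!r}")
        kind, p, lower, upper, const, reverse, base = parts
        n, d = p.split("/")
        return cls(
            kind=VariableKind(kind),
            power=Fraction(int(n), int(d)),
            lower=float(lower) if lower else None,
            upper=float(upper) if upper else None,
            additive_constant=float(const),
            reverse=reverse == "true",
            log_base=float(base),
        )


def identity_spec(kind: VariableKind, reverse: bool = False) -> TransformSpec:
    """The no-transformation spec for a kind (power 1, no constants)."""
    return TransformSpec(kind=VariableKind(kind), power=Fraction(1), reverse=reverse)


# ---------------------------------------------------------------------------
# applying a spec to a data column
# ---------------------------------------------------------------------------


def _apply_spec_to_values(x: np.ndarray, spec: TransformSpec,
                          aux: Optional[np.ndarray] = None) -> np.ndarray:
    """Elementwise dispatch on non-missing numeric values (no reversal)."""
    if spec.is_identity:
        return x.astype(float)
    k, p, base = spec.kind, spec.power, spec.log_base
    if k is VariableKind.AMOUNT:
        C = spec.lower if spec.lower is not None else 0.0
        return np.asarray(amount_transform(x, C, p, spec.additive_constant))
    if k is VariableKind.COUNT:
        return np.asarray(count_transform(x, p, spec.additive_constant))
    if k is VariableKind.RATIO:
        if aux is not None:
            return np.asarray(ratio_transform(x, aux, p, base))
        # precomputed positive ratio column: transform as an amount
        return np.asarray(amount_transform(x, 0.0, p, spec.additive_constant))
    if k is VariableKind.FRACTION:
        r = x / aux if aux is not None else x
        return np.asarray(fraction_transform(r, p, base))
    if k in (VariableKind.COUNTED_FRACTION, VariableKind.BOUNDED_COUNT,
             VariableKind.RANK):
        if k is VariableKind.COUNTED_FRACTION:
            if aux is None:
                raise DomainError("counted_fraction needs its denominator m")
            low, high = 0.0, aux
        elif k is VariableKind.RANK:
            low, high = 1.0, spec.upper
        else:
            low, high = spec.lower, spec.upper
        bad = ((x < low) | (x > high)) & ~np.isnan(x)
        if bad.any():
            raise DomainError(
                f"value {_first_offender(x, bad)} outside [{low}, {np.max(high)}]"
            )
        start = spec.additive_constant or START_THIRD
        r = _started_fraction(x, low, high, start)
        return np.asarray(fraction_transform(r, p, base))
    if k is VariableKind.BOUNDED_AMOUNT:
        return np.asarray(bounded_amount_transform(x, spec.lower, spec.upper, p, base))
    raise DomainError(f"no elementwise dispatch for kind {k}")


def apply(values: pd.Series, meta: VariableMeta, spec: TransformSpec,
          table: Optional[pd.DataFrame] = None) -> pd.Series:
    """Apply a transformation spec to one data column.

    Missing values stay missing.  ``table`` supplies denominator /
    component columns for ratio-like and difference variables.  If
    ``meta.reverse`` (or ``spec.reverse``), the result is negated *after*
    transformation, keeping direction handling orthogonal to shape.  The
    returned Series carries the serialized spec in ``attrs['transform']``.
    A domain error anywhere aborts with the offending row index and value.
    """
    if spec.kind != meta.kind:
        raise ValueError(
            f"{meta.name}: spec kind {spec.kind} does not match metafile kind {meta.kind}"
        )
    name = meta.name

    if meta.kind is VariableKind.ORDINAL:
        out = _apply_ordinal(values, meta, spec)
    elif meta.kind is VariableKind.DIFFERENCE:
        out = _apply_difference(values, meta, spec, table)
    else:
        numeric = pd.to_numeric(values, errors="coerce")
        mask = numeric.notna()
        x = numeric[mask].to_numpy(dtype=float)
        aux = _resolve_aux(meta, table, mask)
        try:
            tx = _apply_spec_to_values(x, spec, aux)
        except DomainError as exc:
            raise DomainError(f"{name}: {exc}") from exc
        out = pd.Series(np.nan, index=values.index, dtype=float, name=name)
        out[mask] = tx
    if meta.reverse or spec.reverse:
        out = -out
    out.name = name
    out.attrs["transform"] = spec.serialize()
    return out


def _resolve_aux(meta: VariableMeta, table, mask):
    if meta.denominator is None:
        return None
    if isinstance(meta.denominator, str):
        if table is None or meta.denominator not in table.columns:
            raise DomainError(
                f"{meta.name}: denominator column {meta.denominator!r} unavailable"
            )
        return pd.to_numeric(table[meta.denominator], errors="coerce")[mask].to_numpy(float)
    return np.asarray(float(meta.denominator))


def _apply_ordinal(values: pd.Series, meta: VariableMeta, spec: TransformSpec) -> pd.Series:
    order = [str(c) for c in meta.category_order]
    labels = values.astype("string")
    counts = labels.value_counts()
    scores = ordinal_scores([int(counts.get(c, 0)) for c in order])
    if spec.is_identity:
        mapping = {c: float(i) for i, c in enumerate(order)}  # plain codes
    else:
        mapping = dict(zip(order, scores))
    out = labels.map(mapping).astype(float)
    out.index = values.index
    return out


def _apply_difference(values: pd.Series, meta: VariableMeta, spec: TransformSpec,
                      table) -> pd.Series:
    if spec.is_identity:
        return pd.to_numeric(values, errors="coerce").astype(float)
    have_components = (
        meta.components is not None
        and table is not None
        and all(c in table.columns for c in meta.components)
    )
    if not have_components:
        numeric = pd.to_numeric(values, errors="coerce")
        x = numeric.dropna()
        if (x > 0).all() and len(x):
            # strictly positive difference: usable as an amount
            comp_spec = replace(spec, kind=VariableKind.AMOUNT, lower=None)
            mask = numeric.notna()
            out = pd.Series(np.nan, index=values.index, dtype=float)
            out[mask] = _apply_spec_to_values(numeric[mask].to_numpy(float), comp_spec)
            return out
        import logging

        logging.getLogger(__name__).warning(
            "%s: difference components unavailable and values change sign; "
            "leaving untransformed", meta.name,
        )
        return numeric.astype(float)
    cx = pd.to_numeric(table[meta.components[0]], errors="coerce")
    cy = pd.to_numeric(table[meta.components[1]], errors="coerce")
    comp_spec = replace(spec, kind=VariableKind.AMOUNT, lower=None)
    mask = cx.notna() & cy.notna()
    out = pd.Series(np.nan, index=values.index, dtype=float)
    out[mask] = difference_transform(
        cx[mask].to_numpy(float), cy[mask].to_numpy(float), comp_spec, comp_spec
    )
    return out
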