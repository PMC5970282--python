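"""Semi-automated choice of symmetry transforms, and the reproducible registry.

For every variable flagged by the skew scan, the ladder of kind-appropriate
re-expressions is searched for the rung minimizing |post-transform Yule
skewness|.  The search is automated; the *choice* is not meant to be: the
ranked candidates (best rung plus its ladder neighbors, and the raw data
as reference) are returned with their skewness so a human can inspect the
histograms and override — e.g. when a double-humped variable fools the
index.  Whatever is chosen, the decision lands in a :class:`Registry`
that can be re-applied to the same table byte-identically, with an audit
trail of overrides.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import skewness as _skew
from . import transforms as _tr
from .taxonomy import Metafile, VariableKind, VariableMeta
from .transforms import DomainError, TransformSpec, identity_spec

logger = logging.getLogger(__name__)

__all__ = [
    "Candidate",
    "Registry",
    "RegistryEntry",
    "SelectionReport",
    "candidate_transforms",
    "auto_select",
    "override",
    "apply_registry",
]

#: candidates within this |post_sk| band of the best are considered tied
TIE_BAND = 0.01
#: classically interpretable rungs, in preference order for tie-breaking
_PREFERRED_RUNGS = (Fraction(0), Fraction(1, 2), Fraction(-1))


@dataclass
class Candidate:
    """One concrete transformation option with its achieved symmetry."""

    spec: TransformSpec
    post_sk: float
    rank: int = 0

    @property
    def power(self) -> Fraction:
        return self.spec.power


def _metas_as_dict(metas) -> Dict[str, VariableMeta]:
    if isinstance(metas, Metafile):
        return dict(metas.variables)
    return {m.name: m for m in metas}


def _robust_sk(numeric: pd.Series, meta: VariableMeta) -> float:
    """|sk| machinery shared with the scan: quartile Yule, eighths fallback
    for collapsed quartiles or few-level bounded kinds; NaN if hopeless."""
    clean = pd.Series(numeric).dropna()
    clean = clean[np.isfinite(clean)]
    if len(clean) < 4:
        return np.nan
    few_levels = (
        meta.kind in _skew._FALLBACK_KINDS
        and clean.nunique() <= _skew._FALLBACK_MAX_DISTINCT
    )
    try:
        if few_levels:
            return _skew.resistant_fallback_skewness(clean)
        return _skew.yule_skewness(clean)
    except ValueError:
        try:
            return _skew.resistant_fallback_skewness(clean)
        except ValueError:
            return np.nan


def _spec_for(meta: VariableMeta, values: pd.Series, p: Fraction) -> TransformSpec:
    """Build the kind-appropriate spec at ladder rung p, with the start
    policy for zero-containing amounts/counts baked in."""
    numeric = pd.to_numeric(values, errors="coerce")
    k = meta.kind
    if k in (VariableKind.AMOUNT, VariableKind.COUNT) or (
        k is VariableKind.RATIO and meta.denominator is None
    ):
        C = meta.lower if (k is VariableKind.AMOUNT and meta.lower is not None) else 0.0
        shifted = numeric.dropna() - C
        start = _tr.default_start(shifted, p) if p != 1 else 0.0
        return TransformSpec(kind=k, power=p, lower=meta.lower,
                             additive_constant=start, reverse=meta.reverse)
    if k in (VariableKind.COUNTED_FRACTION, VariableKind.BOUNDED_COUNT):
        return TransformSpec(kind=k, power=p, lower=meta.lower, upper=meta.upper,
                             additive_constant=_tr.START_THIRD, reverse=meta.reverse)
    if k is VariableKind.RANK:
        upper = meta.upper
        if upper is None:
            upper = float(numeric.max())  # inferred total ranked, flagged in meta
        return TransformSpec(kind=k, power=p, lower=1.0, upper=upper,
                             additive_constant=_tr.START_THIRD, reverse=meta.reverse)
    return TransformSpec(kind=k, power=p, lower=meta.lower, upper=meta.upper,
                         reverse=meta.reverse)


def _evaluate(values: pd.Series, meta: VariableMeta, spec: TransformSpec,
              table) -> float:
    try:
        t = _tr.apply(values, meta, spec, table)
    except (DomainError, ValueError):
        return np.nan
    arr = t.to_numpy(dtype=float)
    if not np.isfinite(arr[~np.isnan(arr)]).all():
        return np.nan
    return _robust_sk(t, meta)


def _tie_break_key(c: Candidate):
    pref = (
        _PREFERRED_RUNGS.index(c.power)
        if c.power in _PREFERRED_RUNGS
        else len(_PREFERRED_RUNGS)
    )
    return (abs(c.power - 1), pref, c.power)


def candidate_transforms(values: pd.Series, meta: VariableMeta,
                         table: Optional[pd.DataFrame] = None) -> List[Candidate]:
    """Search the ladder for the symmetry-optimal transform of one variable.

    Every rung admissible for the variable's kind is evaluated on the data
    and scored by |post-transform skewness|.  Returns the best rung plus up
    to two ladder neighbors on each side, sorted by ascending |post_sk|
    (ties broken toward rungs closer to the identity, then toward the
    classically interpretable log / square root / inverse), with the
    untransformed reference always included.  If nothing beats the raw
    data, the identity alone is returned with a warning.

    Ordinal variables have a single non-identity candidate — the logistic
    reference scores — rather than a ladder.
    """
    identity = identity_spec(meta.kind, reverse=meta.reverse)
    raw_sk = _evaluate(values, meta, identity, table)

    if meta.kind is VariableKind.ORDINAL:
        powers = [Fraction(0)]
    elif meta.kind is VariableKind.DIFFERENCE:
        powers = [p for p in _tr.LADDER if p != 1]
    else:
        powers = [p for p in _tr.LADDER if p != 1]

    evaluated: List[Candidate] = []
    for p in powers:
        try:
            spec = _spec_for(meta, values, p)
        except (DomainError, ValueError):
            continue
        sk = _evaluate(values, meta, spec, table)
        if np.isnan(sk):
            continue
        evaluated.append(Candidate(spec=spec, post_sk=float(sk)))
    id_cand = Candidate(spec=identity, post_sk=float(raw_sk))
    pool = evaluated + ([id_cand] if np.isfinite(raw_sk) else [])
    if not pool:
        logger.warning("%s: no admissible transform; returning identity only", meta.name)
        return [Candidate(spec=identity, post_sk=float(raw_sk), rank=1)]

    best_abs = min(abs(c.post_sk) for c in pool)
    # Candidates whose residual |sk| is already below the decision threshold
    # are statistically indistinguishable from symmetric at this sample size
    # (the index's sampling SD is ~1.45/sqrt(n), about half the threshold);
    # among those, prefer the canonical interpretable rung, the logarithm.
    n_obs = int(pd.to_numeric(values, errors="coerce").notna().sum())
    c_thresh = _skew.skew_threshold(max(n_obs, 1))
    good_enough = min(c_thresh, abs(raw_sk)) if np.isfinite(raw_sk) else c_thresh
    log_cands = [c for c in evaluated
                 if c.power == 0 and abs(c.post_sk) < good_enough]
    if log_cands:
        best = log_cands[0]
    else:
        tied = [c for c in pool if abs(c.post_sk) <= best_abs + TIE_BAND]
        best = min(tied, key=_tie_break_key)

    if best.spec.is_identity:
        logger.warning(
            "%s: no admissible transform improves |sk|=%.3f; identity retained",
            meta.name, abs(raw_sk),
        )
        id_cand.rank = 1
        return [id_cand]

    # the best rung plus two ladder neighbors on each side (<=5 shown)
    evaluated.sort(key=lambda c: c.power)
    i = next(j for j, c in enumerate(evaluated) if c.spec is best.spec)
    window = evaluated[max(0, i - 2): i + 3]
    if not any(c.spec.is_identity for c in window):
        window = window + [id_cand]
    window.sort(key=lambda c: (abs(c.post_sk) if np.isfinite(c.post_sk) else np.inf,
                               _tie_break_key(c)))
    # the tie-break winner leads even if a tied rival has nominally smaller |sk|
    window.remove(best)
    window.insert(0, best)
    for r, c in enumerate(window, start=1):
        c.rank = r
    return window


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fingerprint:
    rows: int
    cols: int
    digest: str

    @classmethod
    def of(cls, table: pd.DataFrame) -> "Fingerprint":
        digest = hashlib.sha256(table.to_csv(index=False).encode()).hexdigest()[:16]
        return cls(rows=len(table), cols=table.shape[1], digest=digest)


@dataclass
class RegistryEntry:
    spec: TransformSpec
    chooser: str = "auto"  # auto | manual
    timestamp: str = field(default="", compare=False)
    audit: list = field(default_factory=list, compare=False)


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


@dataclass
class Registry:
    """The persisted record of the chosen transformation per variable.

    Equality ignores timestamps and audit trails, so a fixed table and
    metafile in auto mode yield an identical registry across runs.
    """

    entries: Dict[str, RegistryEntry] = field(default_factory=dict)
    provenance: Optional[Fingerprint] = None

    def register(self, variable: str, spec: TransformSpec, chooser: str = "auto") -> None:
        self.entries[variable] = RegistryEntry(spec=spec, chooser=chooser,
                                               timestamp=_now())

    def __contains__(self, variable: str) -> bool:
        return variable in self.entries

    def __getitem__(self, variable: str) -> RegistryEntry:
        return self.entries[variable]

    def __len__(self) -> int:
        return len(self.entries)

    # -- persistence -------------------------------------------------------

    def to_text(self) -> str:
        lines = ["# symtrans registry v1"]
        if self.provenance:
            fp = self.provenance
            lines.append(f"# fingerprint rows={fp.rows} cols={fp.cols} digest={fp.digest}")
        for name, e in self.entries.items():
            lines.append("\t".join(["entry", name, e.spec.serialize(), e.chooser,
                                    e.timestamp]))
            for prior in e.audit:
                lines.append("\t".join(["audit", name, *prior]))
        return "\n".join(lines) + "\n"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "Registry":
        reg = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# fingerprint"):
                kv = dict(tok.split("=") for tok in line.split()[2:])
                reg.provenance = Fingerprint(int(kv["rows"]), int(kv["cols"]),
                                             kv["digest"])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "entry":
                _, name, spec, chooser, ts = parts
                reg.entries[name] = RegistryEntry(
                    spec=TransformSpec.deserialize(spec), chooser=chooser, timestamp=ts
                )
            elif parts[0] == "audit":
                reg.entries[parts[1]].audit.append(tuple(parts[2:]))
        return reg

    @classmethod
    def from_file(cls, path) -> "Registry":
        with open(path) as fh:
            return cls.from_text(fh.read())


def override(registry: Registry, variable: str, spec: TransformSpec) -> Registry:
    """Replace a registry entry with a human choice, keeping an audit trail.

    The prior choice is retained as an audit record; the new entry is
    marked ``chooser='manual'``.  The spec's kind must match the entry's.
    """
    if variable not in registry:
        raise KeyError(f"variable {variable!r} not in registry")
    entry = registry[variable]
    if spec.kind != entry.spec.kind:
        raise ValueError(
            f"{variable}: override kind {spec.kind} does not match registered "
            f"kind {entry.spec.kind}"
        )
    entry.audit.append((entry.spec.serialize(), entry.chooser, entry.timestamp))
    entry.spec = spec
    entry.chooser = "manual"
    entry.timestamp = _now()
    return registry


@dataclass
class SelectionReport:
    """Everything a reviewer needs to audit (and override) the auto choices."""

    skew_reports: list
    candidates: Dict[str, List[Candidate]]

    def to_frame(self) -> pd.DataFrame:
        frame = _skew.reports_to_frame(self.skew_reports)
        chosen, post = [], []
        for var in frame["variable"]:
            cands = self.candidates.get(var)
            if cands:
                chosen.append(cands[0].spec.describe())
                post.append(cands[0].post_sk)
            else:
                chosen.append("identity")
                post.append(frame.loc[frame["variable"] == var, "sk"].iloc[0])
        frame["chosen"] = chosen
        frame["post_sk"] = post
        return frame

    def save(self, directory, table: Optional[pd.DataFrame] = None,
             metas=None) -> None:
        """Write the index table and, if the data is given, one histogram
        panel per flagged variable (raw + each candidate, annotated with
        its skewness) for visual review."""
        import os

        os.makedirs(directory, exist_ok=True)
        self.to_frame().to_csv(os.path.join(directory, "index.csv"), index=False)
        if table is None or metas is None:
            return
        metas = _metas_as_dict(metas)
        for var, cands in self.candidates.items():
            if var in table.columns and var in metas:
                fig = plot_candidates(table[var], metas[var], cands, table)
                fig.savefig(os.path.join(directory, f"{var}.png"), dpi=100)
                import matplotlib.pyplot as plt

                plt.close(fig)


def _fd_bins(arr: np.ndarray, min_bins: int = 10) -> int:
    """Freedman-Diaconis bin count with a floor of 10 bins."""
    arr = arr[np.isfinite(arr)]
    if arr.size < 2 or arr.max() == arr.min():
        return min_bins
    iqr = np.subtract(*np.percentile(arr, [75, 25]))
    if iqr <= 0:
        return min_bins
    width = 2 * iqr / arr.size ** (1 / 3)
    return max(min_bins, int(np.ceil((arr.max() - arr.min()) / width)))


def plot_candidates(values: pd.Series, meta: VariableMeta,
                    candidates: List[Candidate],
                    table: Optional[pd.DataFrame] = None):
    """Histogram panel: the raw variable and each candidate re-expression,
    each annotated with its quartile skewness."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(candidates)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 2.8), squeeze=False)
    for ax, cand in zip(axes[0], candidates):
        try:
            t = _tr.apply(values, meta, cand.spec, table).dropna().to_numpy(float)
        except (DomainError, ValueError):
            continue
        t = t[np.isfinite(t)]
        ax.hist(t, bins=_fd_bins(t), color="#4878d0", edgecolor="white")
        ax.set_title(f"{cand.spec.describe()}\nsk={cand.post_sk:+.3f}", fontsize=9)
        ax.tick_params(labelsize=7)
    fig.suptitle(meta.name)
    fig.tight_layout()
    return fig


def auto_select(table: pd.DataFrame, metas,
                threshold: Optional[float] = None) -> Tuple[Registry, SelectionReport]:
    """Run the automated arm of the workflow on a whole table.

    Variables under the skew threshold are registered as identity (no
    transformation needed); flagged variables get their rank-1 candidate.
    The returned report carries the scan and the full candidate lists so a
    reviewer can :func:`override` any entry.  Deterministic: no randomness
    anywhere in the search.
    """
    metas = _metas_as_dict(metas)
    reports = _skew.scan(table, metas.values())
    if threshold is not None:
        for r in reports:
            r.threshold = threshold
            r.needs_transform = (
                not r.degenerate and np.isfinite(r.sk) and abs(r.sk) >= threshold
            )
    registry = Registry(provenance=Fingerprint.of(table))
    candidates: Dict[str, List[Candidate]] = {}
    for rep in reports:
        meta = metas[rep.variable]
        if meta.name not in table.columns:
            continue
        if not rep.needs_transform:
            registry.register(meta.name, identity_spec(meta.kind, meta.reverse))
            continue
        try:
            cands = candidate_transforms(table[meta.name], meta, table)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("%s: candidate search failed: %s", meta.name, exc)
            registry.register(meta.name, identity_spec(meta.kind, meta.reverse))
            continue
        candidates[meta.name] = cands
        registry.register(meta.name, cands[0].spec)
    return registry, SelectionReport(skew_reports=reports, candidates=candidates)


def apply_registry(table: pd.DataFrame, metas, registry: Registry) -> pd.DataFrame:
    """Apply every registered transformation to a copy of the table.

    Registered variables are replaced by their transformed versions
    (reversal included); unregistered columns pass through untouched.
    Re-applying the same registry to the same table is byte-stable.
    """
    metas = _metas_as_dict(metas)
    out = table.copy()
    for name, entry in registry.entries.items():
        if name not in table.columns:
            raise KeyError(f"registered variable {name!r} absent from table")
        meta = metas.get(name)
        if meta is None:
            raise KeyError(f"registered variable {name!r} absent from metafile")
        out[name] = _tr.apply(table[name], meta, entry.spec, table)
    return out
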