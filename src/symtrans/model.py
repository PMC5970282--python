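"""Model/Results facade over the scan -> suggest -> apply workflow.

:class:`SymmetryModel` is constructed from a data table plus its metafile
and plays the role of a statistical model whose "fit" is the automated
search for symmetry-targeting transformations.  :meth:`SymmetryModel.fit`
returns a :class:`SymmetryResults` carrying the per-variable skew
diagnoses, the chosen transforms (the registry), and the ranked candidate
alternatives; ``summary()`` renders the familiar one-table overview,
``transform()`` produces the re-expressed dataset, and plotting hangs off
the results object.
"""

from __future__ import annotations

from typing import Optional, Union

import pandas as pd

from . import selection as _sel
from . import skewness as _skew
from .selection import Registry, SelectionReport, apply_registry, override
from .taxonomy import Metafile, VariableMeta, read_metafile, validate_against_data
from .transforms import TransformSpec

__all__ = ["SymmetryModel", "SymmetryResults"]


class SymmetryModel:
    """Semi-automated symmetry-transformation model for one data table.

    Parameters
    ----------
    data : DataFrame
        Subjects as rows, one named column per clinical variable.
    metadata : Metafile or iterable of VariableMeta
        The taxonomy declaration for each variable.
    threshold : float, optional
        Override the sample-size-dependent skewness threshold with a
        fixed c for every variable.

    Examples
    --------
    >>> model = SymmetryModel.from_csv("data.csv", "meta.csv")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> transformed = res.transform()
    """

    def __init__(self, data: pd.DataFrame, metadata, threshold: Optional[float] = None):
        self.data = data
        if isinstance(metadata, Metafile):
            self.metadata = metadata
        else:
            mf = Metafile()
            for m in metadata:
                mf.variables[m.name] = m
            self.metadata = mf
        self.threshold = threshold
        self.violations = validate_against_data(self.metadata, data)

    @classmethod
    def from_csv(cls, data_path, metafile_path,
                 threshold: Optional[float] = None) -> "SymmetryModel":
        """Build a model from a data CSV and its metafile CSV."""
        meta = read_metafile(metafile_path).raise_on_errors()
        data = pd.read_csv(data_path)
        return cls(data, meta, threshold=threshold)

    def scan(self) -> pd.DataFrame:
        """Skew-scan only (no candidate search): the diagnosis table."""
        return _skew.reports_to_frame(_skew.scan(self.data, self.metadata))

    def fit(self) -> "SymmetryResults":
        """Run the automated transform search and return the results."""
        registry, report = _sel.auto_select(self.data, self.metadata,
                                            threshold=self.threshold)
        return SymmetryResults(self, registry, report)


class SymmetryResults:
    """Fitted transform choices with their diagnostics.

    Attributes
    ----------
    registry : Registry
        The chosen transformation per variable (auditable, serializable).
    report : SelectionReport
        Skew scan plus the ranked candidate lists per flagged variable.
    """

    def __init__(self, model: SymmetryModel, registry: Registry,
                 report: SelectionReport):
        self.model = model
        self.registry = registry
        self.report = report

    @property
    def skew_reports(self) -> pd.DataFrame:
        return _skew.reports_to_frame(self.report.skew_reports)

    @property
    def candidates(self):
        return self.report.candidates

    def transform(self, data: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        """Apply the fitted registry (to new data if given)."""
        table = self.model.data if data is None else data
        return apply_registry(table, self.model.metadata, self.registry)

    def override(self, variable: str, spec: TransformSpec) -> "SymmetryResults":
        """Replace one auto choice with a human one (audited)."""
        override(self.registry, variable, spec)
        return self

    def summary(self) -> str:
        """One-row-per-variable overview: n, quartiles, sk, chosen transform."""
        from statsmodels.iolib.table import SimpleTable

        frame = self.report.to_frame()
        headers = ["variable", "n", "sk", "thresh", "flag", "chosen", "post sk"]
        rows = []
        for _, r in frame.iterrows():
            rows.append(
                [
                    str(r["variable"]),
                    f"{int(r['n'])}",
                    "---" if pd.isna(r["sk"]) else f"{r['sk']:+.3f}",
                    "---" if pd.isna(r["threshold"]) else f"{r['threshold']:.2f}",
                    "*" if r["needs_transform"] else "",
                    str(r["chosen"]),
                    "---" if pd.isna(r["post_sk"]) else f"{r['post_sk']:+.3f}",
                ]
            )
        n_flagged = int(frame["needs_transform"].sum())
        title = (
            f"Symmetry transformation summary "
            f"({len(frame)} variables, {n_flagged} flagged)"
        )
        return str(SimpleTable(rows, headers=headers, title=title))

    def plot_variable(self, variable: str):
        """Histogram panel of raw + candidate re-expressions for one variable."""
        cands = self.candidates.get(variable)
        if cands is None:
            raise KeyError(f"{variable!r} was not flagged; no candidates to plot")
        meta = self.model.metadata[variable]
        return _sel.plot_candidates(self.model.data[variable], meta, cands,
                                    self.model.data)

    def save_report(self, directory) -> None:
        """Write index.csv plus per-variable histogram panels."""
        self.report.save(directory, self.model.data, self.model.metadata)
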