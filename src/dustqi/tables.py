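"""Core tabular types and CSV/JSON input/output.

Concentrations are mg/kg dry weight throughout; no unit conversion is
performed (detection limits quoted in µg/kg must be converted by the
caller).  Element symbols are case-sensitive strings matched exactly
between tables — no alias resolution, so a symbol mismatch surfaces as a
hard error instead of a silently wrong background.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationTable",
    "BackgroundTable",
    "BlankSeries",
    "AnalysisConfig",
    "TableValidationError",
    "read_concentration_table",
    "read_background_table",
    "write_assessment_report",
]


class TableValidationError(ValueError):
    """A table violates a structural invariant; the message names the cell."""


@dataclasses.dataclass(frozen=True)
class ConcentrationTable:
    """Site × element matrix of concentrations (mg/kg dry weight).

    Rows are sites, columns are element symbols, values are strictly
    positive and finite.  Row and column order is preserved from the
    source (file or constructor).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise TableValidationError("concentration table needs at least 1 site and 1 element")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise TableValidationError(f"duplicate site id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise TableValidationError(f"duplicate element symbol {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_bad_cell(df, lambda v: not _is_number(v))
            raise TableValidationError(f"non-numeric concentration at site {bad[0]!r}, element {bad[1]!r}")
        if not np.all(np.isfinite(values)):
            bad = _first_bad_cell(df, lambda v: not np.isfinite(v))
            raise TableValidationError(f"non-finite concentration at site {bad[0]!r}, element {bad[1]!r}")
        if np.any(values <= 0):
            bad = _first_bad_cell(df, lambda v: v <= 0)
            raise TableValidationError(
                f"non-positive concentration {df.loc[bad]!r} at site {bad[0]!r}, element {bad[1]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def elements(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    def drop_elements(self, elements: Iterable[str]) -> "ConcentrationTable":
        """Return a copy without the named element columns (all must exist)."""
        drop = list(elements)
        missing = [e for e in drop if e not in self.data.columns]
        if missing:
            raise KeyError(f"elements not in table: {missing}")
        return ConcentrationTable(self.data.drop(columns=drop))

    def transpose(self) -> "ConcentrationTable":
        """Element × site view, for clustering by elements."""
        return ConcentrationTable(self.data.T)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="site_id", float_format="%.17g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclasses.dataclass(frozen=True)
class BackgroundTable:
    """Element symbol → background concentration CB (mg/kg)."""

    values: pd.Series

    def __post_init__(self) -> None:
        s = self.values
        if s.index.duplicated().any():
            dup = s.index[s.index.duplicated()][0]
            raise TableValidationError(f"duplicate element symbol {dup!r} in background table")
        arr = s.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            for el, v in s.items():
                if not _is_number(v) or not np.isfinite(v) or v <= 0:
                    raise TableValidationError(f"invalid background value {v!r} for element {el!r}")
        s = s.astype(float)
        s.index = s.index.astype(str).rename("element")
        object.__setattr__(self, "values", s)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "BackgroundTable":
        return cls(pd.Series(mapping, dtype=float))

    def lookup(self, element: str) -> float:
        if element not in self.values.index:
            raise KeyError(f"element {element!r} missing from background table")
        return float(self.values[element])

    def for_elements(self, elements: Sequence[str]) -> pd.Series:
        """Background values aligned to *elements*; missing symbols error."""
        missing = [e for e in elements if e not in self.values.index]
        if missing:
            raise KeyError(f"elements missing from background table: {missing}")
        return self.values.reindex(elements)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"element": self.values.index, "background_mg_per_kg": self.values.to_numpy()})
        df.to_csv(path, index=False, float_format="%.17g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BackgroundTable):
            return NotImplemented
        return self.values.equals(other.values)


@dataclasses.dataclass(frozen=True)
class BlankSeries:
    """Replicate laboratory-blank measurements for one element.

    Blank readings may legitimately be negative (instrument noise around
    zero), so only finiteness and n ≥ 2 are enforced.
    """

    element: str
    measurements: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.measurements, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise TableValidationError(f"blank series for {self.element!r} needs n >= 2 replicates")
        if not np.all(np.isfinite(arr)):
            raise TableValidationError(f"non-finite blank measurement for {self.element!r}")
        object.__setattr__(self, "measurements", arr)

    @property
    def n(self) -> int:
        return int(self.measurements.size)


@dataclasses.dataclass
class AnalysisConfig:
    """Collected analysis choices shared by the CLI and library pipelines.

    reference_element : str
        Conservative reference element for the enrichment factor (Al by
        default; Ca and Fe are the usual alternatives).
    pli_threshold : float
        PIs below this are excluded from the trimmed pollution load index
        PLI_d (near-zero ratios otherwise drag the geometric mean down).
    drop_elements : list of lists
        Each inner list is one removal-sensitivity variant; every
        aggregate index is recomputed with those elements excluded.
    """

    reference_element: str = "Al"
    pli_threshold: float = 0.03
    drop_elements: list[list[str]] = dataclasses.field(default_factory=lambda: [["Ca"]])
    normalization: str = "zscore"
    k_min: int = 2
    k_max: int = 6
    linkages: list[str] = dataclasses.field(
        default_factory=lambda: ["average", "complete", "ward", "median"]
    )
    bootstrap_replicates: int = 100
    kmeans_restarts: int = 25
    seed: int = 0
    report_digits: int | None = None

    def __post_init__(self) -> None:
        if self.pli_threshold < 0:
            raise ValueError("pli_threshold must be >= 0")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _is_number(v) -> bool:
    return isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool)


def _first_bad_cell(df: pd.DataFrame, pred) -> tuple:
    for site in df.index:
        for el in df.columns:
            try:
                if pred(df.at[site, el]):
                    return (site, el)
            except TypeError:
                return (site, el)
    raise AssertionError("no offending cell found")


def read_concentration_table(path: str | Path) -> ConcentrationTable:
    """Read a ``site_id,El1,El2,...`` CSV into a ConcentrationTable.

    Row/column order is preserved; any non-numeric or non-positive cell
    raises :class:`TableValidationError` naming the offending cell.
    """
    # round_trip parsing: 17-significant-digit text must reproduce doubles exactly
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for site in df.index:
        for el in df.columns:
            v = df.at[site, el]
            if not _is_number(v) or not np.isfinite(v):
                raise TableValidationError(
                    f"{path}: non-numeric concentration at site {site!r}, element {el!r}"
                )
    return ConcentrationTable(df)


def read_background_table(path: str | Path) -> BackgroundTable:
    """Read a two-column ``element,value`` CSV into a BackgroundTable."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] != 2:
        raise TableValidationError(f"{path}: background CSV must have exactly two columns")
    elements = df.iloc[:, 0].astype(str)
    series = pd.Series(df.iloc[:, 1].to_numpy(), index=elements)
    return BackgroundTable(series)


def write_assessment_report(assessment, path: str | Path, format: str = "csv") -> None:
    """Write a SiteAssessment to *path* as CSV (one row per site, aggregate
    values and class labels) or JSON (nested per-site records including the
    per-element index layers, full double precision)."""
    if format == "csv":
        assessment.to_frame().to_csv(path, index_label="site_id", float_format="%.17g")
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(assessment.to_dict(), fh, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'csv' or 'json')")
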