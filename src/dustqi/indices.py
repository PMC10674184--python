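"""Pollution indices for element concentration surveys.

Per-element layers
------------------
PI   = C / CB                     pollution index (contamination factor)
Igeo = log2(C / (1.5 CB))         geoaccumulation index; the 1.5 buffers
                                  natural background fluctuation
EF   = (C / C_ref) / (CB / CB_ref) enrichment factor against a
                                  conservative reference element
                                  (Al by default; Ca or Fe selectable)

Per-site aggregates over the element panel
------------------------------------------
PLI    = geometric mean of the PIs (computed in log space)
PLI_d  = PLI after dropping PIs below a small threshold — near-zero
         ratios otherwise drag the geometric mean far below what the
         contaminated elements warrant
PINem  = sqrt((mean(PI)^2 + max(PI)^2) / 2)   Nemerow index, weighting
         the single worst element
CPI    = arithmetic mean of the PIs (combined pollution index, graded on
         the Nemerow scale)
AQI    = sum(w Q) / sum(w) with Q = 100 PI and weights w proportional to
         1/CB, so scarce-background elements count more

Classification schemes follow the published grade tables; boundary
values are assigned to the upper class except where the source grade
table states a strict inequality the other way (see each scheme).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import AnalysisConfig, BackgroundTable, ConcentrationTable

__all__ = [
    "ElementIndices",
    "PLIResult",
    "AQIResult",
    "ClassificationScheme",
    "SiteAssessment",
    "PI_SCHEME",
    "EF_SCHEME",
    "NEMEROW_SCHEME",
    "CPI_SCHEME",
    "AQI_SCHEME",
    "IGEO_SCHEME",
    "compute_pi",
    "compute_igeo",
    "compute_ef",
    "element_indices",
    "pli",
    "nemerow",
    "cpi",
    "aqi",
    "classify",
    "assess_sites",
]

IGEO_BUFFER = 1.5


# ---------------------------------------------------------------------------
# per-element layers

def compute_pi(table: ConcentrationTable, background: BackgroundTable) -> pd.DataFrame:
    """Pollution index PI = C/CB, site × element."""
    cb = background.for_elements(table.elements)
    return table.data.div(cb, axis=1)


def compute_igeo(table: ConcentrationTable, background: BackgroundTable) -> pd.DataFrame:
    """Geoaccumulation index Igeo = log2(C / (1.5 CB)), site × element."""
    return np.log2(compute_pi(table, background) / IGEO_BUFFER)


def compute_ef(
    table: ConcentrationTable,
    background: BackgroundTable,
    reference: str = "Al",
) -> pd.DataFrame:
    """Enrichment factor EF_j = (C_j / C_ref) / (CB_j / CB_ref), site × element.

    Identically PI_j / PI_ref, so the reference column is exactly 1.
    """
    if reference not in table.elements:
        raise KeyError(f"reference element {reference!r} not in concentration table")
    pi = compute_pi(table, background)
    return pi.div(pi[reference], axis=0)


@dataclasses.dataclass(frozen=True)
class ElementIndices:
    """Bundled per-element index layers for one survey."""

    pi: pd.DataFrame
    igeo: pd.DataFrame
    ef: pd.DataFrame
    reference_element: str


def element_indices(
    table: ConcentrationTable,
    background: BackgroundTable,
    reference: str = "Al",
) -> ElementIndices:
    return ElementIndices(
        pi=compute_pi(table, background),
        igeo=compute_igeo(table, background),
        ef=compute_ef(table, background, reference),
        reference_element=reference,
    )


# ---------------------------------------------------------------------------
# per-site aggregates

@dataclasses.dataclass(frozen=True)
class PLIResult:
    value: float
    dropped: tuple


def pli(pi_values: Sequence[float] | pd.Series, exclude_below: float | None = None) -> PLIResult:
    """Geometric mean of a site's PIs, optionally trimming PIs below a
    threshold; the trimmed entries are reported back.

    The geometric mean is computed as exp(mean(log PI)) — PIs can span
    several orders of magnitude and a direct product would under/overflow.
    """
    s = pd.Series(pi_values, dtype=float)
    if s.empty:
        raise ValueError("pli needs at least one PI")
    if (s <= 0).any() or not np.all(np.isfinite(s)):
        raise ValueError("all PIs must be positive and finite")
    if exclude_below is not None:
        keep = s >= exclude_below
        dropped = tuple(s.index[~keep])
        s = s[keep]
        if s.empty:
            raise ValueError(f"threshold {exclude_below} excluded every PI")
    else:
        dropped = ()
    return PLIResult(value=float(np.exp(np.mean(np.log(s)))), dropped=dropped)


def nemerow(pi_values: Sequence[float] | pd.Series) -> float:
    """Nemerow index sqrt((mean^2 + max^2)/2) of a site's PIs."""
    arr = np.asarray(pd.Series(pi_values, dtype=float))
    if arr.size == 0:
        raise ValueError("nemerow needs at least one PI")
    return float(np.sqrt((arr.mean() ** 2 + arr.max() ** 2) / 2.0))


def cpi(pi_values: Sequence[float] | pd.Series) -> float:
    """Combined pollution index: arithmetic mean of a site's PIs."""
    arr = np.asarray(pd.Series(pi_values, dtype=float))
    if arr.size == 0:
        raise ValueError("cpi needs at least one PI")
    return float(arr.mean())


@dataclasses.dataclass(frozen=True)
class AQIResult:
    value: float
    weights: pd.Series
    subindices: pd.Series


def aqi(conc_row: pd.Series, background: BackgroundTable) -> AQIResult:
    """Background-weighted quality index for one site.

    Q_j = 100 C_j/CB_j; w_j ∝ 1/CB_j normalised to sum 1.  The weights
    sum to 1 by construction but the normalising denominator is still
    carried explicitly.
    """
    conc = pd.Series(conc_row, dtype=float)
    cb = background.for_elements(list(conc.index))
    q = 100.0 * conc / cb
    raw_w = 1.0 / cb
    w = raw_w / raw_w.sum()
    value = float((w * q).sum() / w.sum())
    return AQIResult(value=value, weights=w, subindices=q)


# ---------------------------------------------------------------------------
# classification

@dataclasses.dataclass(frozen=True)
class ClassificationScheme:
    """Ordered grade boundaries with per-boundary inclusion.

    ``upper_inclusive[j]`` True means a value equal to ``boundaries[j]``
    belongs to the class above the boundary (the default reading of a
    grade table whose lowest class is "less than b0"); False means it
    stays below (used where the table says "greater than b" strictly).
    ``classify`` is total and monotone non-decreasing.
    """

    name: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    upper_inclusive: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError(f"{self.name}: need one more label than boundaries")
        if len(self.upper_inclusive) != len(self.boundaries):
            raise ValueError(f"{self.name}: need one inclusion flag per boundary")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError(f"{self.name}: boundaries must be strictly increasing")

    def classify(self, value: float) -> str:
        if not np.isfinite(value):
            raise ValueError(f"cannot classify non-finite value {value!r}")
        k = 0
        for b, inc in zip(self.boundaries, self.upper_inclusive):
            if value > b or (inc and value == b):
                k += 1
        return self.labels[k]


PI_SCHEME = ClassificationScheme(
    name="PI",
    boundaries=(1.0, 2.0, 3.0, 5.0),
    labels=("no pollution", "low", "moderate", "strong", "very strong"),
    # grade table: <1, 1-2, 2-3, 3-5, >5 (the top bound is strict)
    upper_inclusive=(True, True, True, False),
)

EF_SCHEME = ClassificationScheme(
    name="EF",
    boundaries=(2.0, 5.0, 20.0, 40.0),
    labels=("deficient to minimal", "moderate", "significant", "very high", "extremely high"),
    # <2, 2-5, 5-20, 20-40, >40
    upper_inclusive=(True, True, True, False),
)

NEMEROW_SCHEME = ClassificationScheme(
    name="PINem",
    boundaries=(0.7, 1.0, 2.0, 3.0),
    labels=("no pollution", "warning level", "slight contamination", "moderate pollution", "heavy contamination"),
    # <0.7, 0.7-1, 1-2, 2-3, >3
    upper_inclusive=(True, True, True, False),
)

# The combined pollution index is graded on the Nemerow scale.
CPI_SCHEME = dataclasses.replace(NEMEROW_SCHEME, name="CPI")
PLI_SCHEME = ClassificationScheme(
    name="PLI",
    boundaries=(1.0,),
    labels=("baseline or better", "progressive deterioration"),
    upper_inclusive=(False,),
)

AQI_SCHEME = ClassificationScheme(
    name="AQI",
    boundaries=(25.0, 50.0, 75.0, 100.0),
    labels=("unpolluted", "warning level", "slight pollution", "moderate pollution", "heavy pollution"),
    # 0-25, 26-50, 51-75, 76-100, >100: each upper bound belongs below,
    # and the gaps (25,26) etc. fall to the class above the bound
    upper_inclusive=(False, False, False, False),
)

IGEO_SCHEME = ClassificationScheme(
    name="Igeo",
    boundaries=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    labels=(
        "uncontaminated",
        "uncontaminated to moderately contaminated",
        "moderately contaminated",
        "moderately to strongly contaminated",
        "strongly contaminated",
        "strongly to extremely contaminated",
        "extremely contaminated",
    ),
    # Igeo <= 0 is class 0; every later boundary belongs upward
    upper_inclusive=(False, True, True, True, True, True),
)

SCHEMES: dict[str, ClassificationScheme] = {
    "PI": PI_SCHEME,
    "EF": EF_SCHEME,
    "PINem": NEMEROW_SCHEME,
    "CPI": CPI_SCHEME,
    "PLI": PLI_SCHEME,
    "AQI": AQI_SCHEME,
    "Igeo": IGEO_SCHEME,
}


def classify(scheme: ClassificationScheme, value: float) -> str:
    """Grade label for *value* under *scheme*; out-of-range values map to
    the extreme labels."""
    return scheme.classify(value)


# ---------------------------------------------------------------------------
# full per-site assessment

AGGREGATE_COLUMNS = ["PLI", "PLI_d", "PINem", "CPI", "AQI", "PI_mean", "PI_max"]
CLASSED = {"PLI": PLI_SCHEME, "PLI_d": PLI_SCHEME, "PINem": NEMEROW_SCHEME, "CPI": CPI_SCHEME, "AQI": AQI_SCHEME}


@dataclasses.dataclass(frozen=True)
class VariantAssessment:
    """Aggregates recomputed with a configured element list removed."""

    dropped_elements: tuple[str, ...]
    aggregates: pd.DataFrame
    classes: pd.DataFrame


@dataclasses.dataclass(frozen=True)
class SiteAssessment:
    """Complete index bundle for one survey.

    ``aggregates`` has one row per site with PLI, PLI_d, PINem, CPI, AQI
    plus the intermediates PI_mean and PI_max; ``classes`` holds the
    matching grade labels.  ``variants`` carries the removal-sensitivity
    reruns, keyed by the dropped-element tuple.
    """

    indices: ElementIndices
    aggregates: pd.DataFrame
    classes: pd.DataFrame
    pli_dropped: dict
    aqi_weights: pd.Series
    aqi_subindices: pd.DataFrame
    variants: dict[tuple[str, ...], VariantAssessment]
    config: AnalysisConfig

    def to_frame(self) -> pd.DataFrame:
        """Flat per-site frame: aggregates, their classes, and variant columns."""
        out = self.aggregates.copy()
        for col, scheme in CLASSED.items():
            out[f"{col}_class"] = self.classes[col]
        for key, var in self.variants.items():
            tag = "-" + "".join(key)
            for col in AGGREGATE_COLUMNS:
                out[f"{col}{tag}"] = var.aggregates[col]
            for col in CLASSED:
                out[f"{col}{tag}_class"] = var.classes[col]
        return out

    def to_dict(self) -> dict:
        """Nested per-site records (JSON-ready, full double precision)."""
        sites = {}
        for site in self.aggregates.index:
            rec = {
                "aggregates": {c: self.aggregates.at[site, c] for c in AGGREGATE_COLUMNS},
                "classes": {c: self.classes.at[site, c] for c in CLASSED},
                "pi": self.indices.pi.loc[site].to_dict(),
                "igeo": self.indices.igeo.loc[site].to_dict(),
                "ef": self.indices.ef.loc[site].to_dict(),
                "aqi_subindices": self.aqi_subindices.loc[site].to_dict(),
                "pli_dropped": list(self.pli_dropped[site]),
                "variants": {
                    "-".join(k): {
                        "aggregates": {c: v.aggregates.at[site, c] for c in AGGREGATE_COLUMNS},
                        "classes": {c: v.classes.at[site, c] for c in CLASSED},
                    }
                    for k, v in self.variants.items()
                },
            }
            sites[str(site)] = rec
        return {
            "reference_element": self.indices.reference_element,
            "pli_threshold": self.config.pli_threshold,
            "aqi_weights": self.aqi_weights.to_dict(),
            "sites": sites,
        }


def _aggregate_rows(
    table: ConcentrationTable,
    background: BackgroundTable,
    threshold: float,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    pi = compute_pi(table, background)
    agg = pd.DataFrame(index=pi.index, columns=AGGREGATE_COLUMNS, dtype=float)
    dropped = {}
    for site in pi.index:
        row = pi.loc[site]
        plain = pli(row)
        trimmed = pli(row, exclude_below=threshold)
        dropped[site] = trimmed.dropped
        agg.at[site, "PLI"] = plain.value
        agg.at[site, "PLI_d"] = trimmed.value
        agg.at[site, "PINem"] = nemerow(row)
        agg.at[site, "CPI"] = cpi(row)
        agg.at[site, "AQI"] = aqi(table.data.loc[site], background).value
        agg.at[site, "PI_mean"] = float(row.mean())
        agg.at[site, "PI_max"] = float(row.max())
    classes = pd.DataFrame(index=pi.index, columns=list(CLASSED), dtype=object)
    for col, scheme in CLASSED.items():
        classes[col] = [scheme.classify(v) for v in agg[col]]
    return agg, classes, dropped


def assess_sites(
    table: ConcentrationTable,
    background: BackgroundTable,
    config: AnalysisConfig | None = None,
) -> SiteAssessment:
    """Full per-site assessment: PI/Igeo/EF layers, every aggregate with
    its grade, and one removal-sensitivity variant per configured
    dropped-element list (default: without Ca).

    In each variant the configured elements are removed first and the
    PLI_d threshold is applied afterwards to the reduced PI set.
    """
    config = config or AnalysisConfig()
    idx = element_indices(table, background, config.reference_element)
    agg, classes, dropped = _aggregate_rows(table, background, config.pli_threshold)
    first_site = table.site_ids[0]
    aqi_full = aqi(table.data.loc[first_site], background)

    variants: dict[tuple[str, ...], VariantAssessment] = {}
    for drop in config.drop_elements:
        key = tuple(drop)
        present = [e for e in drop if e in table.data.columns]
        if len(present) == len(table.elements):
            raise ValueError(f"variant {key} would drop every element")
        sub = table.drop_elements(present) if present else table
        v_agg, v_classes, _ = _aggregate_rows(sub, background, config.pli_threshold)
        variants[key] = VariantAssessment(dropped_elements=key, aggregates=v_agg, classes=v_classes)

    return SiteAssessment(
        indices=idx,
        aggregates=agg,
        classes=classes,
        pli_dropped=dropped,
        aqi_weights=aqi_full.weights,
        aqi_subindices=100.0 * idx.pi,
        variants=variants,
        config=config,
    )
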