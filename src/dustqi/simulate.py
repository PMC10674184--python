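"""Synthetic concentration and blank generation.

Indoor-dust element concentrations are strictly positive and typically
right-skewed, so the generator draws independent lognormal marginals per
element, moment-matched to target (mean, CV) pairs:

    sigma^2 = ln(1 + CV^2),   mu = ln(mean) - sigma^2 / 2,

which makes the analytic mean and CV of the lognormal equal the targets
exactly.  Optional multiplicative group effects emulate a survey whose
sites split into contamination regimes (e.g. downtown vs. seafront); an
optional common per-site lognormal factor induces positive inter-element
correlation for correlation-pipeline tests (off by default).

The default element panel (:data:`URBAN_DUST_SUMMARY`) carries the 17
elements and per-element mean/CV levels of a 20-site urban indoor-dust
survey in an arid region, with Ca/K/Mg/Al/Fe dominating the mass and
trace metals (Co, As, Pb, Cd) at the mg/kg level.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import BlankSeries, ConcentrationTable

__all__ = [
    "SyntheticSpec",
    "URBAN_DUST_SUMMARY",
    "spec_from_summary",
    "default_spec",
    "generate_concentrations",
    "generate_blanks",
]

# Per-element (mean mg/kg, CV) of the default 17-element survey panel.
URBAN_DUST_SUMMARY: dict[str, tuple[float, float]] = {
    "Cu": (94.30, 1.04),
    "Ni": (52.14, 0.36),
    "Pb": (4.62, 1.46),
    "Zn": (247.08, 0.37),
    "Co": (1.85, 0.52),
    "Cr": (56.96, 1.12),
    "Ba": (85.17, 0.65),
    "Fe": (997.28, 0.26),
    "Mn": (126.58, 0.34),
    "Mg": (1876.22, 0.49),
    "Sr": (47.50, 0.49),
    "Na": (561.39, 0.53),
    "Al": (1033.78, 0.38),
    "Ca": (14170.02, 0.22),
    "K": (9159.12, 0.31),
    "As": (3.89, 0.36),
    "Cd": (6.73, 0.05),
}

DEFAULT_N_SITES = 20


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Distribution parameters driving the concentration simulator.

    means / cvs
        Per-element target mean (mg/kg) and coefficient of variation.
    group_shifts
        Mapping group label → per-element multiplicative shift (> 0).
        Empty mapping means a single homogeneous population.
    group_proportions
        Mapping group label → site share; must sum to 1 over the same
        labels as ``group_shifts``.
    site_factor_cv
        CV of an optional common lognormal site factor (mean 1) applied to
        every element of a site, inducing positive correlation; 0 = off.
    """

    means: pd.Series
    cvs: pd.Series
    group_shifts: dict[str, pd.Series] = dataclasses.field(default_factory=dict)
    group_proportions: dict[str, float] = dataclasses.field(default_factory=dict)
    n_sites: int = DEFAULT_N_SITES
    seed: int = 0
    site_factor_cv: float = 0.0

    def __post_init__(self) -> None:
        means = pd.Series(self.means, dtype=float)
        cvs = pd.Series(self.cvs, dtype=float).reindex(means.index)
        if means.empty:
            raise ValueError("spec needs at least one element")
        if not np.all(np.isfinite(means)) or (means <= 0).any():
            raise ValueError("all target means must be positive and finite")
        if not np.all(np.isfinite(cvs)) or (cvs <= 0).any():
            raise ValueError("all target CVs must be positive and finite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "cvs", cvs)
        if self.group_shifts:
            if set(self.group_shifts) != set(self.group_proportions):
                raise ValueError("group_shifts and group_proportions must share labels")
            if not math.isclose(sum(self.group_proportions.values()), 1.0, rel_tol=1e-9):
                raise ValueError("group proportions must sum to 1")
            shifts = {}
            for label, shift in self.group_shifts.items():
                s = pd.Series(shift, dtype=float).reindex(means.index).fillna(1.0)
                if (s <= 0).any():
                    raise ValueError(f"group {label!r} has a non-positive shift")
                shifts[label] = s
            object.__setattr__(self, "group_shifts", shifts)
        if self.site_factor_cv < 0:
            raise ValueError("site_factor_cv must be >= 0")

    @property
    def elements(self) -> list[str]:
        return list(self.means.index)

    @property
    def sigma(self) -> pd.Series:
        """Lognormal shape parameter per element: sqrt(ln(1 + CV^2))."""
        return np.sqrt(np.log1p(self.cvs**2))

    @property
    def mu(self) -> pd.Series:
        """Lognormal log-scale per element: ln(mean) - sigma^2/2."""
        return np.log(self.means) - self.sigma**2 / 2


def spec_from_summary(
    summary: Mapping[str, tuple[float, float]] | pd.DataFrame,
    **kwargs,
) -> SyntheticSpec:
    """Build a SyntheticSpec from per-element (mean, CV) targets.

    ``summary`` is either a mapping element → (mean, CV) or a DataFrame
    with ``mean`` and ``cv`` columns indexed by element.  Moment matching
    is exact: the analytic lognormal mean and CV equal the targets.
    """
    if isinstance(summary, pd.DataFrame):
        means = summary["mean"].astype(float)
        cvs = summary["cv"].astype(float)
    else:
        elements = list(summary)
        means = pd.Series({e: summary[e][0] for e in elements}, dtype=float)
        cvs = pd.Series({e: summary[e][1] for e in elements}, dtype=float)
    return SyntheticSpec(means=means, cvs=cvs, **kwargs)


def default_spec(**kwargs) -> SyntheticSpec:
    """Spec for the default 17-element urban indoor-dust panel."""
    return spec_from_summary(URBAN_DUST_SUMMARY, **kwargs)


def two_group_spec(
    shift: float = 4.0,
    shifted_elements: Sequence[str] | None = None,
    proportions: tuple[float, float] = (0.5, 0.5),
    **kwargs,
) -> SyntheticSpec:
    """Default panel with two site groups, group "B" shifted up by *shift*.

    By default every element is shifted, giving two clearly separated
    contamination regimes for structure-recovery tests.
    """
    base = default_spec()
    elements = base.elements if shifted_elements is None else list(shifted_elements)
    up = pd.Series(1.0, index=base.means.index)
    up[elements] = shift
    return spec_from_summary(
        {e: (base.means[e], base.cvs[e]) for e in base.elements},
        group_shifts={"A": pd.Series(1.0, index=base.means.index), "B": up},
        group_proportions={"A": proportions[0], "B": proportions[1]},
        **kwargs,
    )


def _group_counts(proportions: dict[str, float], n_sites: int) -> dict[str, int]:
    # largest-remainder allocation so counts sum exactly to n_sites
    labels = list(proportions)
    raw = {g: proportions[g] * n_sites for g in labels}
    counts = {g: int(math.floor(raw[g])) for g in labels}
    short = n_sites - sum(counts.values())
    for g in sorted(labels, key=lambda g: raw[g] - counts[g], reverse=True)[:short]:
        counts[g] += 1
    return counts


def generate_concentrations(
    spec: SyntheticSpec,
    n_sites: int | None = None,
    seed: int | None = None,
) -> tuple[ConcentrationTable, pd.Series]:
    """Draw a site × element concentration table from *spec*.

    Returns the table and the true group labels (all ``"A"`` when the
    spec has no groups).  Deterministic for a fixed seed.
    """
    n = spec.n_sites if n_sites is None else int(n_sites)
    if n < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    elements = spec.elements
    sigma = spec.sigma.to_numpy()
    mu = spec.mu.to_numpy()

    if spec.group_shifts:
        counts = _group_counts(spec.group_proportions, n)
        labels = np.concatenate([np.repeat(g, c) for g, c in counts.items()])
        shift_rows = np.vstack([spec.group_shifts[g].to_numpy() for g in labels])
    else:
        labels = np.repeat("A", n)
        shift_rows = np.ones((n, len(elements)))

    log_draws = rng.normal(loc=mu, scale=sigma, size=(n, len(elements)))
    values = np.exp(log_draws) * shift_rows
    if spec.site_factor_cv > 0:
        s2 = math.log1p(spec.site_factor_cv**2)
        factor = np.exp(rng.normal(-s2 / 2, math.sqrt(s2), size=n))
        values = values * factor[:, None]

    site_ids = [f"S{i + 1:02d}" for i in range(n)]
    table = ConcentrationTable(pd.DataFrame(values, index=site_ids, columns=elements))
    return table, pd.Series(labels, index=site_ids, name="group")


def generate_blanks(
    element: str,
    mean: float,
    sd: float,
    n: int,
    seed: int,
) -> BlankSeries:
    """Draw *n* replicate blank readings as independent normals.

    Blanks fluctuate around a (possibly zero) mean and may go negative,
    as real instrument blanks do.
    """
    if n < 2:
        raise ValueError("need n >= 2 blank replicates")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    return BlankSeries(element=element, measurements=rng.normal(mean, sd, size=n))
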