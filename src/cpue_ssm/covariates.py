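"""Period schemes, period indicators, and per-period temperature anomalies.

The growth model partitions the study years into stressor eras ("periods").
Every taxon shares the default three-period partition; taxa subject to
restoration measures carry a fourth period that truncates their period 3.
Covariates are evaluated with a one-year lag: the growth increment from
year ``t-1`` to ``t`` uses the indicators and anomaly of year ``t-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeriodScheme",
    "IndicatorMatrix",
    "AnomalySeries",
    "assign_periods",
    "build_indicators",
    "compute_anomaly",
    "build_anomalies",
    "design_matrix",
    "default_scheme",
    "restoration_scheme",
    "DEFAULT_YEAR_START",
    "DEFAULT_YEAR_END",
]

DEFAULT_YEAR_START = 1966
DEFAULT_YEAR_END = 2022

#: default era boundaries: baseline, shoreline development, water-level regulation
DEFAULT_BOUNDARIES = ((1, 1966, 1975), (2, 1976, 1991), (3, 1992, 2022))

#: number of drift-design columns: intercept, P2, P3, anomaly, P4
N_DESIGN_COLS = 5


class SchemeError(ValueError):
    """Raised for invalid period schemes or out-of-coverage queries."""


@dataclass(frozen=True)
class PeriodScheme:
    """Partition of a contiguous year range into labelled periods.

    Parameters
    ----------
    taxon_id
        Identifier of the taxon this scheme applies to.
    boundaries
        Ordered tuples ``(period_label, first_year, last_year)``; must be
        contiguous, non-overlapping, and have strictly increasing labels.
    """

    taxon_id: str
    boundaries: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        bs = tuple(tuple(int(v) for v in b) for b in self.boundaries)
        object.__setattr__(self, "boundaries", bs)
        if not bs:
            raise SchemeError(f"{self.taxon_id}: empty period scheme")
        labels = [b[0] for b in bs]
        if labels != sorted(set(labels)):
            raise SchemeError(f"{self.taxon_id}: period labels must strictly increase")
        if any(lab not in (1, 2, 3, 4) for lab in labels):
            raise SchemeError(f"{self.taxon_id}: period labels must be in 1..4")
        for (_, f, l) in bs:
            if l < f:
                raise SchemeError(f"{self.taxon_id}: period with last_year < first_year")
        for (_, _, l_prev), (_, f_next, _) in zip(bs, bs[1:]):
            if f_next != l_prev + 1:
                raise SchemeError(
                    f"{self.taxon_id}: periods must be contiguous "
                    f"({l_prev} is followed by {f_next})"
                )

    @property
    def year_start(self) -> int:
        return self.boundaries[0][1]

    @property
    def year_end(self) -> int:
        return self.boundaries[-1][2]

    @property
    def has_period4(self) -> bool:
        return any(lab == 4 for lab, _, _ in self.boundaries)

    def period_of(self, year: int) -> int:
        """Period label containing ``year``; raises outside coverage."""
        year = int(year)
        for lab, first, last in self.boundaries:
            if first <= year <= last:
                return lab
        raise SchemeError(
            f"{self.taxon_id}: year {year} outside scheme coverage "
            f"[{self.year_start}, {self.year_end}]"
        )

    def period_years(self, label: int) -> range:
        for lab, first, last in self.boundaries:
            if lab == label:
                return range(first, last + 1)
        raise SchemeError(f"{self.taxon_id}: no period {label} in scheme")

    def labels(self) -> tuple[int, ...]:
        return tuple(lab for lab, _, _ in self.boundaries)


def default_scheme(
    taxon_id: str,
    year_start: int = DEFAULT_YEAR_START,
    year_end: int = DEFAULT_YEAR_END,
) -> PeriodScheme:
    """Three-period scheme; boundary years clip to the requested range."""
    return PeriodScheme(taxon_id, _clip_boundaries(DEFAULT_BOUNDARIES, year_start, year_end))


def restoration_scheme(
    taxon_id: str,
    period4_start: int,
    year_start: int = DEFAULT_YEAR_START,
    year_end: int = DEFAULT_YEAR_END,
) -> PeriodScheme:
    """Four-period scheme: period 3 is truncated at ``period4_start - 1``.

    ``period4_start=2012`` and ``period4_start=2009`` give the two
    restoration configurations used in the study design.
    """
    if not (1993 <= period4_start <= year_end):
        raise SchemeError(f"{taxon_id}: period 4 must start after period 3 begins")
    bounds = ((1, 1966, 1975), (2, 1976, 1991),
              (3, 1992, period4_start - 1), (4, period4_start, 2022))
    return PeriodScheme(taxon_id, _clip_boundaries(bounds, year_start, year_end))


def _clip_boundaries(
    bounds: Iterable[tuple[int, int, int]], year_start: int, year_end: int
) -> tuple[tuple[int, int, int], ...]:
    out = []
    for lab, first, last in bounds:
        f, l = max(first, year_start), min(last, year_end)
        if f <= l:
            out.append((lab, f, l))
    return tuple(out)


def assign_periods(year: int, scheme: PeriodScheme) -> int:
    """Period label of ``year`` under ``scheme`` (error outside coverage)."""
    return scheme.period_of(year)


@dataclass
class IndicatorMatrix:
    """One-hot period indicators per taxon and year (baseline is all-zeros).

    ``values[i, t, k]`` holds (P2, P3, P4) for taxon ``i`` in year
    ``years[t]``.  For restoration taxa the P3 column is the truncated
    taxon-specific indicator.
    """

    taxa: tuple[str, ...]
    years: np.ndarray
    values: np.ndarray  # (n_taxa, n_years, 3) of 0/1

    COLUMNS = ("P2", "P3", "P4")

    def row(self, taxon: str, year: int) -> tuple[int, int, int]:
        i = self.taxa.index(taxon)
        t = int(np.searchsorted(self.years, year))
        if t >= len(self.years) or self.years[t] != year:
            raise SchemeError(f"year {year} not in indicator matrix")
        return tuple(int(v) for v in self.values[i, t])

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, taxon in enumerate(self.taxa):
            for t, year in enumerate(self.years):
                recs.append((taxon, int(year), *self.values[i, t]))
        return pd.DataFrame(recs, columns=["taxon", "year", *self.COLUMNS])


def build_indicators(
    schemes: Sequence[PeriodScheme], years: Sequence[int] | None = None
) -> IndicatorMatrix:
    """One-hot encode non-baseline period membership for every taxon-year."""
    if years is None:
        years = range(schemes[0].year_start, schemes[0].year_end + 1)
    years = np.asarray(sorted(int(y) for y in years))
    vals = np.zeros((len(schemes), len(years), 3), dtype=np.int64)
    for i, scheme in enumerate(schemes):
        for t, year in enumerate(years):
            lab = scheme.period_of(int(year))
            if lab > 1:
                vals[i, t, lab - 2] = 1
    return IndicatorMatrix(tuple(s.taxon_id for s in schemes), years, vals)


@dataclass
class AnomalySeries:
    """Per-taxon temperature anomalies (deviation from the period mean)."""

    taxa: tuple[str, ...]
    years: np.ndarray
    values: np.ndarray  # (n_taxa, n_years)

    def series(self, taxon: str) -> pd.Series:
        i = self.taxa.index(taxon)
        return pd.Series(self.values[i], index=self.years, name=taxon)


def compute_anomaly(temperature: pd.Series, scheme: PeriodScheme) -> pd.Series:
    """Centre the temperature series within each period of ``scheme``.

    The anomaly of a year is the temperature minus the mean temperature of
    the period (under this taxon's scheme) containing that year, so
    anomalies sum to zero within every period block.
    """
    temp = pd.Series(temperature).astype(float).sort_index()
    years = [int(y) for y in temp.index]
    if temp.isna().any():
        bad = temp.index[temp.isna()].tolist()
        raise ValueError(f"temperature series has missing values at years {bad}")
    covered = set(range(scheme.year_start, scheme.year_end + 1))
    missing = sorted(covered - set(years))
    if missing:
        raise ValueError(f"temperature series missing years {missing}")
    labels = np.array([scheme.period_of(y) for y in years])
    out = temp.copy()
    for lab in np.unique(labels):
        mask = labels == lab
        out[mask] = temp[mask] - temp[mask].mean()
    out.name = scheme.taxon_id
    return out


def build_anomalies(schemes: Sequence[PeriodScheme], temperature: pd.Series) -> AnomalySeries:
    series = [compute_anomaly(temperature, s) for s in schemes]
    years = np.asarray(sorted(int(y) for y in pd.Series(temperature).index))
    vals = np.vstack([s.loc[years].to_numpy() for s in series])
    return AnomalySeries(tuple(s.taxon_id for s in schemes), years, vals)


def design_matrix(
    schemes: Sequence[PeriodScheme],
    temperature: pd.Series,
    years: Sequence[int] | None = None,
) -> np.ndarray:
    """Lagged drift design ``U`` with columns (1, P2, P3, T, P4).

    ``U[i, t]`` multiplies the coefficient vector
    ``(beta1, beta2, beta3, gamma, beta4)`` of taxon ``i`` to give the drift
    of the transition from year ``t-1`` to year ``t``; covariates are those
    of year ``t-1``.  Row ``t=0`` is zero (no transition into the first
    year).
    """
    if years is None:
        years = range(schemes[0].year_start, schemes[0].year_end + 1)
    years = np.asarray(sorted(int(y) for y in years))
    ind = build_indicators(schemes, years)
    anom = build_anomalies(schemes, pd.Series(temperature).loc[years])
    n_i, n_t = len(schemes), len(years)
    U = np.zeros((n_i, n_t, N_DESIGN_COLS))
    U[:, 1:, 0] = 1.0
    U[:, 1:, 1] = ind.values[:, :-1, 0]  # P2 at t-1
    U[:, 1:, 2] = ind.values[:, :-1, 1]  # P3 at t-1
    U[:, 1:, 3] = anom.values[:, :-1]    # anomaly at t-1
    U[:, 1:, 4] = ind.values[:, :-1, 2]  # P4 at t-1
    return U


def schemes_from_frame(df: pd.DataFrame) -> dict[str, PeriodScheme]:
    """Build schemes from a long table (taxon_id, period, first_year, last_year)."""
    required = {"taxon_id", "period", "first_year", "last_year"}
    if not required.issubset(df.columns):
        raise ValueError(f"scheme table must have columns {sorted(required)}")
    out: dict[str, PeriodScheme] = {}
    for taxon, grp in df.groupby("taxon_id", sort=False):
        grp = grp.sort_values("period")
        bounds = tuple(
            (int(r.period), int(r.first_year), int(r.last_year))
            for r in grp.itertuples()
        )
        out[str(taxon)] = PeriodScheme(str(taxon), bounds)
    return out
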