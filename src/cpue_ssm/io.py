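"""Panel readers/writers and validation.

File layout (long-format, UTF-8 CSV):

* ``catch.csv``        — columns ``taxon, year, catch_g``
* ``effort.csv``       — columns ``year, n_fishers`` (blank cell = missing)
* ``temperature.csv``  — columns ``year, temp_c``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FisheryPanel", "PanelError", "read_panel", "write_panel"]


class PanelError(ValueError):
    """Raised when panel files violate the schema."""


@dataclass
class FisheryPanel:
    """Observed data rectangle: catch, shared effort, temperature.

    Attributes
    ----------
    catch
        Wide frame, index = year (contiguous ints), columns = taxa, values
        in grams (``>= 0``).
    effort
        Float series indexed by year; NaN marks missing years. Observed
        values are positive integers (number of fishers).
    temperature
        Complete float series indexed by year (degrees C).
    """

    catch: pd.DataFrame
    effort: pd.Series
    temperature: pd.Series

    def __post_init__(self) -> None:
        self.catch = self.catch.sort_index()
        self.effort = self.effort.sort_index().astype(float)
        self.temperature = self.temperature.sort_index().astype(float)
        self.validate()

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.catch.columns)

    @property
    def years(self) -> np.ndarray:
        return self.catch.index.to_numpy()

    @property
    def missing_effort_years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.effort.index[self.effort.isna()])

    def validate(self) -> None:
        years = self.catch.index.to_numpy()
        if len(years) == 0:
            raise PanelError("empty panel")
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise PanelError("catch years are not a contiguous range")
        for name, idx in (("effort", self.effort.index), ("temperature", self.temperature.index)):
            if not np.array_equal(idx.to_numpy(), years):
                raise PanelError(f"{name} years do not match catch years")
        if (self.catch.to_numpy() < 0).any():
            raise PanelError("negative catch values present")
        if self.temperature.isna().any():
            raise PanelError("temperature series has missing values")
        obs = self.effort.dropna()
        if (obs < 1).any():
            raise PanelError("observed effort must be >= 1")
        if not np.allclose(obs, np.round(obs)):
            raise PanelError("observed effort must be integer counts")


def _read_csv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise PanelError(f"missing file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PanelError(f"{path.name}: missing columns {missing}")
    return df


def read_panel(directory: str | Path) -> FisheryPanel:
    """Read and validate the CSV trio from ``directory``.

    Schema errors name the offending file and 1-based data row.
    """
    directory = Path(directory)
    cdf = _read_csv(directory / "catch.csv", ["taxon", "year", "catch_g"])
    edf = _read_csv(directory / "effort.csv", ["year", "n_fishers"])
    tdf = _read_csv(directory / "temperature.csv", ["year", "temp_c"])

    for row, rec in enumerate(cdf.itertuples(), start=1):
        if pd.isna(rec.catch_g) or rec.catch_g < 0:
            raise PanelError(f"catch.csv row {row}: invalid catch {rec.catch_g!r}")
    for row, rec in enumerate(edf.itertuples(), start=1):
        v = rec.n_fishers
        if pd.isna(v):
            continue
        if v < 1 or float(v) != int(v):
            raise PanelError(f"effort.csv row {row}: invalid effort {v!r}")

    catch = cdf.pivot_table(index="year", columns="taxon", values="catch_g", sort=False)
    if catch.isna().any().any():
        gaps = catch.isna().stack()
        taxon, year = gaps[gaps].index[0][1], gaps[gaps].index[0][0]
        raise PanelError(f"catch.csv: no record for taxon {taxon!r} in year {year}")
    catch = catch[sorted(catch.columns)]
    effort = edf.set_index("year")["n_fishers"]
    temp = tdf.set_index("year")["temp_c"]
    return FisheryPanel(catch=catch, effort=effort, temperature=temp)


def write_panel(panel: FisheryPanel, directory: str | Path) -> dict[str, Path]:
    """Write the CSV trio; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    long = panel.catch.stack().rename("catch_g").reset_index()
    long.columns = ["year", "taxon", "catch_g"]
    long = long[["taxon", "year", "catch_g"]].sort_values(["taxon", "year"])
    paths = {
        "catch": directory / "catch.csv",
        "effort": directory / "effort.csv",
        "temperature": directory / "temperature.csv",
    }
    long.to_csv(paths["catch"], index=False)
    eff = panel.effort.rename("n_fishers").reset_index().rename(columns={"index": "year"})
    eff.columns = ["year", "n_fishers"]
    # keep observed efforts as integer literals, missing as blank cells
    eff["n_fishers"] = eff["n_fishers"].map(
        lambda v: "" if pd.isna(v) else str(int(round(v)))
    )
    eff.to_csv(paths["effort"], index=False)
    tmp = panel.temperature.rename("temp_c").reset_index()
    tmp.columns = ["year", "temp_c"]
    tmp.to_csv(paths["temperature"], index=False)
    return paths
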