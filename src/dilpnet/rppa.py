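"""Protein × timepoint fold-change tables and their ternary discretization.

The measurement of interest is the fold-change ratio rho of each protein
between two culture conditions at each timepoint of the sampling grid
(e.g. 5 h / 24 h / 48 h).  Ratios are discretized to ternary states with
inclusive thresholds: rho >= 1.2 -> up-regulated (+1), rho <= 0.8 ->
down-regulated (-1), otherwise no change (0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementTable",
    "TableFormatError",
    "load_table",
    "discretize",
    "ratio_of_conditions",
    "UP_THRESHOLD",
    "DOWN_THRESHOLD",
]

UP_THRESHOLD = 1.2
DOWN_THRESHOLD = 0.8


class TableFormatError(ValueError):
    """Malformed or inconsistent measurement table."""


@dataclass(frozen=True)
class MeasurementTable:
    """Fold-change ratios and (optionally) their discretized ternary states.

    ``ratios`` is a proteins × timepoints DataFrame of positive ratios;
    ``states`` is None until :func:`discretize` is applied, after which it is
    an int DataFrame over {-1, 0, 1} with the same index/columns.
    """

    ratios: pd.DataFrame
    states: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ratios.index.has_duplicates:
            dup = self.ratios.index[self.ratios.index.duplicated()][0]
            raise TableFormatError(f"duplicate protein row {dup!r}")
        if self.ratios.columns.has_duplicates:
            raise TableFormatError("duplicate timepoint labels")
        if self.ratios.size and not (self.ratios.to_numpy() > 0).all():
            bad = self.ratios.stack()
            bad = bad[bad <= 0].index[0]
            raise TableFormatError(
                f"fold-change ratio must be > 0 (protein {bad[0]!r}, "
                f"timepoint {bad[1]!r})"
            )
        if self.states is not None:
            if not self.states.index.equals(self.ratios.index) or not (
                self.states.columns.equals(self.ratios.columns)
            ):
                raise TableFormatError("states must align with ratios")
            vals = self.states.to_numpy()
            if vals.size and not np.isin(vals, (-1, 0, 1)).all():
                raise TableFormatError("states must be in {-1, 0, 1}")

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self.ratios.index)

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.ratios.columns)

    @property
    def n_timepoints(self) -> int:
        return self.ratios.shape[1]

    def state(self, protein: str, timepoint_index: int) -> int:
        if self.states is None:
            raise TableFormatError("table has not been discretized")
        return int(self.states.loc[protein].iloc[timepoint_index])

    @classmethod
    def from_states(
        cls, states: pd.DataFrame, ratios: pd.DataFrame | None = None
    ) -> "MeasurementTable":
        """Build a table directly from ternary states (ratios synthesized as
        representative band midpoints when not given)."""
        states = states.astype(int)
        if ratios is None:
            ratios = states.replace({1: 1.5, 0: 1.0, -1: 0.5}).astype(float)
        return cls(ratios=ratios, states=states)


def load_table(path: str | Path) -> MeasurementTable:
    """Load a CSV/TSV fold-change table.

    First column: protein identifier; header row: timepoint labels; cells:
    positive ratios.  Delimiter is taken from the extension (.csv comma,
    .tsv/.txt tab).  Non-numeric cells and non-positive ratios are errors.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    if numeric.size:
        bad = numeric.isna() & raw.notna()
        missing = raw.isna()
        problem = bad | missing
        if problem.to_numpy().any():
            stacked = problem.stack()
            protein, tp = stacked[stacked].index[0]
            raise TableFormatError(
                f"{path.name}: non-numeric cell at protein {protein!r}, "
                f"timepoint {tp!r}"
            )
    return MeasurementTable(ratios=numeric.astype(float))


def discretize(
    table: MeasurementTable,
    up: float = UP_THRESHOLD,
    down: float = DOWN_THRESHOLD,
) -> MeasurementTable:
    """Discretize fold-change ratios to ternary states.

    rho >= up -> +1, rho <= down -> -1, otherwise 0 (both thresholds
    inclusive on the significant side).  Idempotent on the states and
    monotone in rho.
    """
    if not up > down > 0:
        raise ValueError(f"thresholds must satisfy up > down > 0, got {up}, {down}")
    rho = table.ratios.to_numpy()
    m = np.where(rho >= up, 1, np.where(rho <= down, -1, 0))
    states = pd.DataFrame(
        m, index=table.ratios.index, columns=table.ratios.columns, dtype=int
    )
    return MeasurementTable(ratios=table.ratios, states=states)


def ratio_of_conditions(
    treated: MeasurementTable, reference: MeasurementTable
) -> MeasurementTable:
    """Element-wise treated / reference ratio table (states cleared).

    Both tables must cover the same proteins and timepoints in the same
    order; this is how a contrast such as "co-cultured vs alone" or
    "hypoxia vs normoxia" is formed from two per-condition tables.
    """
    if list(treated.ratios.index) != list(reference.ratios.index):
        raise TableFormatError("protein sets/order differ between conditions")
    if list(treated.ratios.columns) != list(reference.ratios.columns):
        raise TableFormatError("timepoints differ between conditions")
    return MeasurementTable(ratios=treated.ratios / reference.ratios)
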