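"""Panel data container and CSV I/O.

A panel holds one nonnegative observation per (DMU, period, variable) plus a
group label per DMU.  DMUs are the benchmarked units (hospitals in the
intended application); variables are absolute quantities — counts, hours,
monetary costs, days.  Ratios and percentages are rejected at ingestion by
default because slack-based DEA scores are only meaningful on volume data.

The on-disk format is a long/wide hybrid CSV: one row per (dmu, period),
header ``dmu,period,group,<var1>,...,<varJ>``, UTF-8, decimal point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("dmu", "period", "group")


class PanelError(ValueError):
    """Base class for panel ingestion/validation problems."""


class SchemaError(PanelError):
    """A required column is missing or a reserved name is misused."""


class ValidationError(PanelError):
    """Panel contents violate an invariant (negativity, duplicates, NaN)."""


@dataclass(frozen=True)
class PanelDataset:
    """Immutable (n DMUs) x (T periods) x (J variables) observation array.

    ``values[i, t, j]`` is the observation of variable ``variable_ids[j]``
    for DMU ``dmu_ids[i]`` in period ``periods[t]``.  All entries are finite
    and nonnegative; every DMU carries exactly one group label.
    """

    dmu_ids: tuple[str, ...]
    periods: tuple[str, ...]
    variable_ids: tuple[str, ...]
    values: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dmu_ids", tuple(str(d) for d in self.dmu_ids))
        object.__setattr__(self, "periods", tuple(str(p) for p in self.periods))
        object.__setattr__(
            self, "variable_ids", tuple(str(v) for v in self.variable_ids)
        )
        vals = np.asarray(self.values, dtype=float)
        expected = (len(self.dmu_ids), len(self.periods), len(self.variable_ids))
        if vals.shape != expected:
            raise ValidationError(
                f"values shape {vals.shape} != (n, T, J) = {expected}"
            )
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        if len(set(self.dmu_ids)) != len(self.dmu_ids):
            raise ValidationError("duplicate dmu ids")
        if len(set(self.periods)) != len(self.periods):
            raise ValidationError("duplicate period labels")
        if len(set(self.variable_ids)) != len(self.variable_ids):
            raise ValidationError("duplicate variable ids")
        for v in self.variable_ids:
            if v in RESERVED_COLUMNS:
                raise SchemaError(f"variable id {v!r} is a reserved column name")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("panel contains NaN or infinite entries")
        if np.any(vals < 0):
            i, t, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value for variable {self.variable_ids[j]!r}, "
                f"dmu {self.dmu_ids[i]!r}, period {self.periods[t]!r}"
            )
        groups = {str(k): str(v) for k, v in self.groups.items()}
        missing = [d for d in self.dmu_ids if d not in groups]
        if missing:
            raise ValidationError(f"dmus without group label: {missing}")
        object.__setattr__(
            self, "groups", {d: groups[d] for d in self.dmu_ids}
        )

    # -- basic accessors -------------------------------------------------
    @property
    def n_dmus(self) -> int:
        return len(self.dmu_ids)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    def var_index(self, variable_id: str) -> int:
        try:
            return self.variable_ids.index(variable_id)
        except ValueError:
            raise KeyError(f"unknown variable {variable_id!r}") from None

    def period_index(self, period: str) -> int:
        try:
            return self.periods.index(str(period))
        except ValueError:
            raise KeyError(f"unknown period {period!r}") from None

    def column(self, variable_id: str) -> np.ndarray:
        """(n, T) array of observations of one variable."""
        return np.array(self.values[:, :, self.var_index(variable_id)])

    # -- functional updates ----------------------------------------------
    def with_column(self, variable_id: str, column: np.ndarray) -> "PanelDataset":
        """Return a new panel with one column replaced (or appended)."""
        column = np.broadcast_to(
            np.asarray(column, dtype=float), (self.n_dmus, self.n_periods)
        )
        vals = np.array(self.values)
        if variable_id in self.variable_ids:
            vals[:, :, self.var_index(variable_id)] = column
            var_ids = self.variable_ids
        else:
            vals = np.concatenate([vals, column[:, :, None]], axis=2)
            var_ids = self.variable_ids + (variable_id,)
        return replace(self, variable_ids=var_ids, values=vals)

    def drop_columns(self, variable_ids) -> "PanelDataset":
        drop = set(variable_ids)
        keep = [j for j, v in enumerate(self.variable_ids) if v not in drop]
        return replace(
            self,
            variable_ids=tuple(self.variable_ids[j] for j in keep),
            values=self.values[:, :, keep],
        )

    # -- frame conversion -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per (dmu, period): ``dmu,period,group,<variables...>``."""
        rows = []
        for i, d in enumerate(self.dmu_ids):
            for t, p in enumerate(self.periods):
                rows.append(
                    {"dmu": d, "period": p, "group": self.groups[d]}
                    | dict(zip(self.variable_ids, self.values[i, t]))
                )
        return pd.DataFrame(rows, columns=list(RESERVED_COLUMNS) + list(self.variable_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, schema=None) -> "PanelDataset":
        for col in RESERVED_COLUMNS:
            if col not in frame.columns:
                raise SchemaError(f"missing required column {col!r}")
        variable_ids = [c for c in frame.columns if c not in RESERVED_COLUMNS]
        if schema is not None:
            missing = [v for v in schema if v not in variable_ids]
            if missing:
                raise SchemaError(f"missing variable column(s): {missing}")
            variable_ids = list(schema)
        if frame.duplicated(subset=["dmu", "period"]).any():
            dup = frame[frame.duplicated(subset=["dmu", "period"])].iloc[0]
            raise ValidationError(
                f"duplicated (dmu, period) key: ({dup['dmu']!r}, {dup['period']!r})"
            )
        dmu_ids = list(dict.fromkeys(frame["dmu"].astype(str)))
        periods = list(dict.fromkeys(frame["period"].astype(str)))
        groups: dict[str, str] = {}
        for d, g in zip(frame["dmu"].astype(str), frame["group"].astype(str)):
            if d in groups and groups[d] != g:
                raise ValidationError(f"dmu {d!r} has conflicting group labels")
            groups[d] = g
        n, T, J = len(dmu_ids), len(periods), len(variable_ids)
        values = np.full((n, T, J), np.nan)
        di = {d: i for i, d in enumerate(dmu_ids)}
        ti = {p: t for t, p in enumerate(periods)}
        for row_idx, row in frame.iterrows():
            vals = pd.to_numeric(row[variable_ids], errors="coerce")
            if vals.isna().any():
                bad = vals.index[vals.isna()][0]
                raise ValidationError(
                    f"non-numeric or missing value in column {bad!r} at row {row_idx}"
                )
            if (vals < 0).any():
                bad = vals.index[vals < 0][0]
                raise ValidationError(
                    f"negative value in column {bad!r} at row {row_idx}"
                )
            values[di[str(row["dmu"])], ti[str(row["period"])]] = vals.to_numpy(float)
        if np.isnan(values).any():
            raise ValidationError("panel is not a complete (dmu x period) grid")
        return cls(tuple(dmu_ids), tuple(periods), tuple(variable_ids), values, groups)


def read_panel(
    path,
    schema=None,
    *,
    counts_only: bool = True,
    ratio_columns=(),
) -> PanelDataset:
    """Read and validate a panel CSV.

    Parameters
    ----------
    path : str or pathlib.Path
        CSV with header ``dmu,period,group,<var1>,...,<varJ>``.
    schema : sequence of str, optional
        Expected variable columns; a missing one raises :class:`SchemaError`
        naming it, and the returned panel keeps exactly these columns in
        this order.
    counts_only : bool
        When true (default), any column declared in ``ratio_columns`` is
        rejected: the scores are only defined on absolute quantities.
    ratio_columns : sequence of str
        Columns the caller declares to be ratios/percentages.
    """
    frame = pd.read_csv(
        path,
        dtype={"dmu": str, "period": str, "group": str},
        float_precision="round_trip",
    )
    if counts_only:
        present = [c for c in ratio_columns if c in frame.columns]
        if present:
            raise ValidationError(
                f"ratio/percentage column(s) not accepted (counts_only): {present}"
            )
    return PanelDataset.from_frame(frame, schema=schema)


def write_panel(panel: PanelDataset, path) -> None:
    """Write a panel as CSV; ``read_panel`` round-trips it bit-exactly."""
    # repr-roundtrip float formatting keeps read(write(p)) == p exactly
    panel.to_frame().to_csv(path, index=False, float_format=lambda x: repr(float(x)))
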