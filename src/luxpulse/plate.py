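"""Reading, validating, and pre-processing plate-reader time courses.

The canonical on-disk format is a long CSV with header
``time_h,well,channel,value``; an import-only wide dialect (one column per
``well/channel`` pair) is also accepted.  Times may be recorded in minutes
or hours and are always stored in hours.

Pre-processing covers blank correction (per-channel, per-timepoint median
of the blank wells subtracted from sample wells, with an OD floor so the
logarithm stays defined) and replicate alignment (time-wise mean, SD and CV
per well group), mirroring how duplicate wells are handled on a real
96-well run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError
from .simulate import PlateRun

__all__ = [
    "PlateTable",
    "read_plate_csv",
    "write_plate_csv",
    "from_run",
    "blank_correct",
    "align_replicates",
    "fill_missing",
]

_COLUMNS = ["time_h", "well", "channel", "value"]


@dataclass
class PlateTable:
    """Validated long-format plate data plus provenance."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _validate(self.data)

    @property
    def wells(self) -> list[str]:
        return sorted(self.data["well"].unique())

    @property
    def channels(self) -> list[str]:
        return sorted(self.data["channel"].unique())

    @property
    def time(self) -> np.ndarray:
        return np.sort(self.data["time_h"].unique())

    def series(self, well: str, channel: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data[(self.data["well"] == well) & (self.data["channel"] == channel)]
        sub = sub.sort_values("time_h")
        return sub["time_h"].to_numpy(), sub["value"].to_numpy()


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns {missing}")
    df = df[_COLUMNS].copy()
    df["time_h"] = pd.to_numeric(df["time_h"], errors="raise")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    dup = df.duplicated(subset=["time_h", "well", "channel"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ParseError(
            f"duplicate record for (t={first['time_h']}, well={first['well']}, "
            f"channel={first['channel']})")
    for (well, channel), grp in df.groupby(["well", "channel"], sort=False):
        t = grp["time_h"].to_numpy()
        if np.any(np.diff(np.sort(t)) <= 0):
            raise ParseError(f"non-monotone time grid for well {well}, channel {channel}")
    return df.sort_values(["well", "channel", "time_h"]).reset_index(drop=True)


def read_plate_csv(path: str | Path, dialect: str = "long",
                   time_unit: str = "hours") -> PlateTable:
    """Read a plate CSV in the long (canonical) or wide (import-only) dialect.

    Wide files have a leading time column and one column per
    ``well/channel`` pair, e.g. ``A1/OD600``.  ``time_unit`` may be
    ``"hours"`` or ``"minutes"``; values are stored in hours.
    """
    path = Path(path)
    if dialect not in ("long", "wide"):
        raise ParseError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    if time_unit not in ("hours", "minutes"):
        raise ParseError(f"unknown time_unit {time_unit!r}")
    try:
        raw = pd.read_csv(path)
    except pd.errors.ParserError as err:
        line = getattr(err, "lineno", None)
        raise ParseError(f"{path}: {err}", line=line) from err
    if raw.isna().any().any():
        bad = int(raw.index[raw.isna().any(axis=1)][0]) + 2  # header + 1-based
        raise ParseError(f"{path}: ragged or missing values", line=bad)

    if dialect == "wide":
        time_col = raw.columns[0]
        records = []
        for col in raw.columns[1:]:
            if "/" not in col:
                raise ParseError(
                    f"{path}: wide column {col!r} is not of the form well/channel")
            well, channel = col.split("/", 1)
            records.append(pd.DataFrame({
                "time_h": raw[time_col], "well": well,
                "channel": channel, "value": raw[col]}))
        df = pd.concat(records, ignore_index=True)
    else:
        df = raw

    if time_unit == "minutes":
        df = df.copy()
        df["time_h"] = df["time_h"] / 60.0
    table = PlateTable(df, provenance={"source": str(path), "dialect": dialect})
    return table


def from_run(run: PlateRun) -> PlateTable:
    """Wrap a simulated :class:`PlateRun` as a validated table."""
    return PlateTable(run.data.copy(), provenance=dict(run.metadata))


def write_plate_csv(table: PlateTable | PlateRun, path: str | Path) -> None:
    """Write long-format CSV; a PlateRun also gets a metadata JSON sidecar."""
    import json

    path = Path(path)
    if isinstance(table, PlateRun):
        table.data[_COLUMNS].to_csv(path, index=False)
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(table.metadata, indent=2))
    else:
        table.data[_COLUMNS].to_csv(path, index=False)


def blank_correct(table: PlateTable, blank_wells: Iterable[str],
                  od_floor: float = 1e-4, od_channel: str = "OD600",
                  correct_rlu: bool = False) -> PlateTable:
    """Subtract the per-channel, per-timepoint median of the blank wells.

    OD values are corrected and clipped at ``od_floor`` (a warning reports
    how many readings were floored); luminescence blanks are only
    subtracted when ``correct_rlu`` is set, since published traces are not
    necessarily RLU-blanked.  The blank wells are dropped from the output.
    """
    blank_wells = list(blank_wells)
    if not blank_wells:
        raise DomainError("blank_correct: blank_wells must be non-empty")
    present = set(table.data["well"])
    missing = [w for w in blank_wells if w not in present]
    if missing:
        raise DomainError(f"blank wells not present in table: {missing}")
    sample = table.data[~table.data["well"].isin(blank_wells)].copy()
    if sample.empty:
        raise DomainError("blank_correct: table contains only blank wells")
    blanks = table.data[table.data["well"].isin(blank_wells)]
    med = (blanks.groupby(["channel", "time_h"])["value"].median()
           .rename("blank_median").reset_index())

    channels = [od_channel] + ([c for c in table.channels if c != od_channel]
                               if correct_rlu else [])
    sample = sample.merge(med, on=["channel", "time_h"], how="left")
    do = sample["channel"].isin(channels) & sample["blank_median"].notna()
    sample.loc[do, "value"] = sample.loc[do, "value"] - sample.loc[do, "blank_median"]
    is_od = sample["channel"] == od_channel
    n_floored = int((is_od & (sample["value"] < od_floor)).sum())
    if n_floored:
        warnings.warn(f"blank_correct: floored {n_floored} OD readings at {od_floor}")
    sample.loc[is_od, "value"] = sample.loc[is_od, "value"].clip(lower=od_floor)
    out = sample[_COLUMNS]
    prov = dict(table.provenance)
    prov.update({"blank_corrected": True, "blank_wells": blank_wells,
                 "od_floor": od_floor, "n_floored": n_floored})
    return PlateTable(out, provenance=prov)


def align_replicates(table: PlateTable,
                     group_map: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Time-wise mean, SD and CV per well group and channel.

    ``group_map`` maps a group label to its wells.  Singleton groups get a
    warning and missing (NaN) SD/CV.  Returns a tidy frame with columns
    ``group, channel, time_h, mean, sd, cv``.
    """
    frames = []
    for group, wells in group_map.items():
        wells = list(wells)
        sub = table.data[table.data["well"].isin(wells)]
        missing = set(wells) - set(sub["well"])
        if missing:
            raise DomainError(f"group {group!r}: wells not in table: {sorted(missing)}")
        if len(wells) < 2:
            warnings.warn(f"group {group!r} has a single well; CV undefined")
        agg = (sub.groupby(["channel", "time_h"])["value"]
               .agg(mean="mean", sd="std").reset_index())
        if len(wells) < 2:
            agg["sd"] = np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            agg["cv"] = np.where(agg["mean"] != 0, agg["sd"] / agg["mean"], np.nan)
        agg.insert(0, "group", group)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def fill_missing(table: PlateTable, max_gap: int = 2) -> PlateTable:
    """Linearly interpolate short dropouts onto the union time grid.

    Each (well, channel) series is reindexed onto the union of observed
    times; runs of at most ``max_gap`` consecutive missing samples are
    filled by linear interpolation, longer gaps are left missing (the
    series is effectively split there).
    """
    grid = table.time
    frames = []
    for (well, channel), grp in table.data.groupby(["well", "channel"], sort=False):
        s = grp.set_index("time_h")["value"].reindex(grid)
        filled = s.interpolate(method="index", limit=max_gap, limit_area="inside")
        out = filled.dropna().rename("value").reset_index()
        out.insert(1, "well", well)
        out.insert(2, "channel", channel)
        frames.append(out)
    df = pd.concat(frames, ignore_index=True)
    return PlateTable(df, provenance=dict(table.provenance))
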