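"""Reading, validating and writing per-second tracking tables.

A tracking table is a long-format table with one row per detected bee per
second: ``bee_id,t,x,y,nx,ny`` where ``t`` is integer seconds since trial
start, ``x``/``y`` are pixel coordinates inside the arena and ``(nx, ny)``
is the unit head-direction vector.  Missing seconds are absences (the
substrate for trip detection), never interpolated.

Coordinates are 0-based pixels; no assumption is made about whether y
increases upward or downward — every downstream criterion uses only
distances and sign-consistent angle tests, so the convention merely has to
be consistent within a trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialMetadata",
    "TrackingTable",
    "TrackingFormatError",
    "TrackingIntegrityError",
    "read_tracking",
    "write_tracking",
    "read_metadata",
    "write_metadata",
    "presence_intervals",
]

#: Default arena extent in pixels (width, height).
DEFAULT_ARENA = (6576.0, 4384.0)

COLUMNS = ["bee_id", "t", "x", "y", "nx", "ny"]


class TrackingFormatError(ValueError):
    """Raised when a tracking file does not follow the CSV dialect."""


class TrackingIntegrityError(ValueError):
    """Raised when a tracking file violates table invariants (duplicates)."""


@dataclass(frozen=True)
class TrialMetadata:
    """Trial-level metadata: clock anchor, entrance opening, disturbances.

    Parameters
    ----------
    trial_id
        Free-form trial label.
    start_datetime
        Wall-clock timestamp of ``t = 0``; used for calendar-day and
        before-noon rules in forager filtering.
    entrance_open_t
        Second at which the hive entrance was opened; absences before this
        are tracking loss, not trips.
    cleaning_times
        Seconds at which the observation glass was cleaned (artificial
        disturbances).
    arena_width, arena_height
        Arena bounds in pixels.
    T_total
        Total trial duration in seconds.
    """

    trial_id: str
    start_datetime: datetime
    entrance_open_t: int
    T_total: int
    cleaning_times: tuple[int, ...] = ()
    arena_width: float = DEFAULT_ARENA[0]
    arena_height: float = DEFAULT_ARENA[1]

    def __post_init__(self) -> None:
        if not (0 < self.entrance_open_t < self.T_total):
            raise ValueError(
                f"entrance_open_t must lie in (0, T_total); got "
                f"{self.entrance_open_t} vs T_total={self.T_total}"
            )
        object.__setattr__(self, "cleaning_times", tuple(int(c) for c in self.cleaning_times))

    def clock_at(self, t: int | float) -> datetime:
        """Wall-clock time corresponding to trial second ``t``."""
        return self.start_datetime + pd.Timedelta(seconds=float(t))


@dataclass
class TrackingTable:
    """Validated per-second tracking detections.

    ``df`` holds columns ``bee_id,t,x,y,nx,ny`` sorted by (bee_id, t) with
    at most one row per (bee_id, t).  ``n_rejected`` counts input rows
    dropped during validation (out-of-arena positions, non-unit headings).
    """

    df: pd.DataFrame
    meta: TrialMetadata
    sampling_period: int = 1
    n_rejected: int = 0
    _by_bee: dict | None = field(default=None, repr=False, compare=False)

    @property
    def roster(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["bee_id"].unique()))

    def times_of(self, bee_id: str) -> np.ndarray:
        """Sorted detection times of one bee."""
        if self._by_bee is None:
            self._by_bee = {
                b: g for b, g in self.df.groupby("bee_id", sort=False)
            }
        if bee_id not in self._by_bee:
            raise KeyError(f"unknown bee_id: {bee_id!r}")
        return self._by_bee[bee_id]["t"].to_numpy()

    def bee(self, bee_id: str) -> pd.DataFrame:
        if self._by_bee is None:
            self.times_of(self.df["bee_id"].iloc[0])
        if bee_id not in self._by_bee:
            raise KeyError(f"unknown bee_id: {bee_id!r}")
        return self._by_bee[bee_id]

    def __len__(self) -> int:
        return len(self.df)


def _validate(df: pd.DataFrame, meta: TrialMetadata) -> tuple[pd.DataFrame, int]:
    dup = df.duplicated(subset=["bee_id", "t"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise TrackingIntegrityError(
            f"duplicate (bee_id, t) record: ({first['bee_id']!r}, {int(first['t'])})"
        )
    norm = np.hypot(df["nx"].to_numpy(), df["ny"].to_numpy())
    in_arena = (
        (df["x"] >= 0)
        & (df["x"] <= meta.arena_width)
        & (df["y"] >= 0)
        & (df["y"] <= meta.arena_height)
        & (df["t"] >= 0)
    ).to_numpy()
    renormable = (norm >= 0.99) & (norm <= 1.01)
    keep = in_arena & renormable
    n_rejected = int((~keep).sum())
    df = df.loc[keep].copy()
    norm = norm[keep]
    df["nx"] = df["nx"].to_numpy() / norm
    df["ny"] = df["ny"].to_numpy() / norm
    df = df.sort_values(["bee_id", "t"], kind="mergesort").reset_index(drop=True)
    return df, n_rejected


def from_dataframe(df: pd.DataFrame, meta: TrialMetadata) -> TrackingTable:
    """Build a validated table from an in-memory dataframe."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrackingFormatError(f"missing columns: {missing}")
    df = df[COLUMNS].copy()
    df["t"] = df["t"].astype(np.int64)
    for c in ("x", "y", "nx", "ny"):
        df[c] = df[c].astype(float)
    df, n_rejected = _validate(df, meta)
    return TrackingTable(df=df, meta=meta, n_rejected=n_rejected)


def read_tracking(path: str | Path, meta: TrialMetadata) -> TrackingTable:
    """Read and validate a tracking CSV (header ``bee_id,t,x,y,nx,ny``).

    Rows outside the arena bounds or with heading norm outside
    [0.99, 1.01] are rejected (count kept in ``n_rejected``); headings with
    norm inside that band are renormalized to unit length.  Duplicate
    (bee_id, t) rows raise :class:`TrackingIntegrityError` naming the
    first offender.
    """
    try:
        df = pd.read_csv(path, dtype={"bee_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrackingFormatError(str(exc)) from exc
    return from_dataframe(df, meta)


def write_tracking(table: TrackingTable, path: str | Path) -> None:
    """Write a tracking table in the canonical CSV dialect."""
    df = table.df.copy()
    df.to_csv(path, index=False, float_format="%.17g")


def read_metadata(path: str | Path) -> TrialMetadata:
    """Read trial metadata from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    start = raw["start_datetime"]
    if isinstance(start, str):
        start = datetime.fromisoformat(start)
    return TrialMetadata(
        trial_id=str(raw["trial_id"]),
        start_datetime=start,
        entrance_open_t=int(raw["entrance_open_t"]),
        T_total=int(raw["T_total"]),
        cleaning_times=tuple(raw.get("cleaning_times", ())),
        arena_width=float(raw.get("arena_width", DEFAULT_ARENA[0])),
        arena_height=float(raw.get("arena_height", DEFAULT_ARENA[1])),
    )


def write_metadata(meta: TrialMetadata, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "trial_id": meta.trial_id,
                "start_datetime": meta.start_datetime.isoformat(),
                "entrance_open_t": int(meta.entrance_open_t),
                "T_total": int(meta.T_total),
                "cleaning_times": list(meta.cleaning_times),
                "arena_width": float(meta.arena_width),
                "arena_height": float(meta.arena_height),
            },
            fh,
        )


def presence_intervals(table: TrackingTable, bee_id: str) -> list[tuple[int, int]]:
    """Maximal runs of consecutive detection seconds for one bee.

    Returns sorted, disjoint closed integer intervals whose union is the
    bee's detection-time set.  Unknown bees raise ``KeyError``.
    """
    times = table.times_of(bee_id)
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > table.sampling_period)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [times.size - 1]))
    return [(int(times[s]), int(times[e])) for s, e in zip(starts, ends)]
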