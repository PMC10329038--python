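"""Behavioral event detectors: waggle dances, dance followers, trips and
per-burst role labels.

Waggle dances are detected from the head-direction vector alone: over 5
consecutive tracked seconds the bee must reverse its orientation by more
than 90° at every step (all four consecutive dot products negative) while
strictly alternating left and right turns (the scalar cross products
alternate in sign).  Overlapping or adjacent dance windows of a bee merge
into one event.

A dance follower is a bee within 600 px of an active dancer whose head
direction stays within 90° of the direction toward the dancer, for at
least ``min_follow`` tracked seconds inside the dance.

Trips are detection gaps of at least ``min_gap`` seconds starting after
the entrance opened; earlier gaps are tracking loss.  Orientation flights
(early exploratory flights) are separated from foraging by the
first-foraging-day rule: the first calendar day with ≥ 6 trips of which
> 25 % leave before noon; all trips before that day are orientation
flights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .burst_detection import Burst
from .tracking_io import TrackingTable, TrialMetadata

__all__ = [
    "detect_dances",
    "detect_followers",
    "detect_trips",
    "first_foraging_day",
    "flag_orientation_trips",
    "label_burst_roles",
]

DANCE_WINDOW = 5          # seconds per detection window
FOLLOW_RADIUS = 600.0     # px, ~one bee length
MIN_FOLLOW = 3            # s
MIN_TRIP_GAP = 60         # s
FORAGER_WINDOW = (600.0, 1000.0)   # s before the burst peak
ROLE_WINDOW = 1000.0      # s before the peak for dancer/follower attachment


def detect_dances(table: TrackingTable) -> pd.DataFrame:
    """Detect waggle-dance events; returns columns ``bee_id,start,end``.

    A window [t, t+4] with headings at all five seconds is a dance window
    iff (A) all four consecutive dot products n_τ·n_{τ+1} are negative and
    (B) the signs of the four scalar cross products strictly alternate
    (a zero cross product — collinear headings — breaks alternation).
    """
    events = []
    for bee_id, sub in table.df.groupby("bee_id", sort=True):
        t = sub["t"].to_numpy()
        if t.size < DANCE_WINDOW:
            continue
        nx = sub["nx"].to_numpy()
        ny = sub["ny"].to_numpy()
        dot = nx[:-1] * nx[1:] + ny[:-1] * ny[1:]
        cross = nx[:-1] * ny[1:] - ny[:-1] * nx[1:]
        consecutive = np.diff(t) == table.sampling_period
        ok_step = consecutive & (dot < 0)
        sign = np.sign(cross)
        alt = (sign[:-1] * sign[1:]) < 0  # strict alternation, zeros fail
        # window starting at index i uses steps i..i+3 and alternations i..i+2
        m = t.size - DANCE_WINDOW + 1
        if m <= 0:
            continue
        win_ok = np.ones(m, dtype=bool)
        for off in range(DANCE_WINDOW - 1):
            win_ok &= ok_step[off : off + m]
        for off in range(DANCE_WINDOW - 2):
            win_ok &= alt[off : off + m]
        starts = t[:m][win_ok]
        for s0, e0 in _merge_windows(starts, DANCE_WINDOW):
            events.append((bee_id, s0, e0))
    return pd.DataFrame(events, columns=["bee_id", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}, errors="ignore"
    )


def _merge_windows(starts: np.ndarray, width: int) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent fixed-width windows into maximal events."""
    if starts.size == 0:
        return []
    out = []
    cur_start = int(starts[0])
    cur_end = cur_start + width - 1
    for s in starts[1:]:
        s = int(s)
        if s <= cur_end + 1:
            cur_end = max(cur_end, s + width - 1)
        else:
            out.append((cur_start, cur_end))
            cur_start, cur_end = s, s + width - 1
    out.append((cur_start, cur_end))
    return out


def detect_followers(
    table: TrackingTable,
    dances: pd.DataFrame,
    radius: float = FOLLOW_RADIUS,
    min_follow: int = MIN_FOLLOW,
) -> pd.DataFrame:
    """Detect dance-follow events; columns ``follower_id,dancer_id,start,end``.

    Over every tracked second of a maximal sub-interval of a dance, the
    candidate must be within ``radius`` px of the dancer and its heading
    must make a nonnegative dot product with the unit vector toward the
    dancer; sub-intervals of length ≥ ``min_follow`` become events.
    Seconds where the candidate is not detected do not break a
    sub-interval (bees blink out of tracking) but do not count toward it.
    """
    cols = ["follower_id", "dancer_id", "start", "end"]
    if len(dances) == 0:
        return pd.DataFrame(columns=cols)
    df = table.df
    by_t: dict[int, pd.DataFrame] = {}
    events = []
    for _, dance in dances.iterrows():
        dancer = dance["bee_id"]
        dsub = table.bee(dancer)
        dsub = dsub[(dsub["t"] >= dance["start"]) & (dsub["t"] <= dance["end"])]
        dpos = dict(zip(dsub["t"], zip(dsub["x"], dsub["y"])))
        span = df[(df["t"] >= dance["start"]) & (df["t"] <= dance["end"])]
        span = span[span["bee_id"] != dancer]
        ok_records: dict[str, list[int]] = {}
        bad_records: dict[str, list[int]] = {}
        for row in span.itertuples(index=False):
            if row.t not in dpos:
                continue
            dx = dpos[row.t][0] - row.x
            dy = dpos[row.t][1] - row.y
            dist = np.hypot(dx, dy)
            facing = (row.nx * dx + row.ny * dy) >= 0.0
            if dist <= radius and facing and dist > 0:
                ok_records.setdefault(row.bee_id, []).append(int(row.t))
            else:
                bad_records.setdefault(row.bee_id, []).append(int(row.t))
        for bee, ts in ok_records.items():
            ts = np.array(sorted(ts))
            bad = np.array(sorted(bad_records.get(bee, [])))
            # split the ok-seconds at any violating detection between them
            segs = [[ts[0]]]
            for a, b in zip(ts[:-1], ts[1:]):
                if bad.size and np.any((bad > a) & (bad < b)):
                    segs.append([b])
                else:
                    segs[-1].append(b)
            for seg in segs:
                if len(seg) >= min_follow:
                    events.append((bee, dancer, int(seg[0]), int(seg[-1])))
    return pd.DataFrame(events, columns=cols)


def detect_trips(
    table: TrackingTable,
    meta: TrialMetadata,
    min_gap: int = MIN_TRIP_GAP,
) -> pd.DataFrame:
    """Detect out-of-hive trips; columns ``bee_id,exit_t,entry_t,is_orientation``.

    A trip is a detection gap of duration ≥ ``min_gap`` whose gap starts
    at or after the entrance opened; ``exit_t`` is the last detection
    before the gap and ``entry_t`` the first after.  The
    ``is_orientation`` column is filled by :func:`flag_orientation_trips`
    (False here).
    """
    rows = []
    for bee in table.roster:
        times = table.times_of(bee)
        if times.size < 2:
            continue
        gaps = np.diff(times)
        idx = np.flatnonzero(gaps - table.sampling_period >= min_gap)
        for i in idx:
            exit_t = int(times[i])
            entry_t = int(times[i + 1])
            if exit_t + table.sampling_period < meta.entrance_open_t:
                continue  # door still closed when the gap started
            rows.append((bee, exit_t, entry_t, False))
    return pd.DataFrame(
        rows, columns=["bee_id", "exit_t", "entry_t", "is_orientation"]
    )


def first_foraging_day(
    trips: pd.DataFrame, meta: TrialMetadata
) -> pd.Timestamp | None:
    """First calendar day qualifying a bee as a forager.

    The day must have at least 6 trips of which more than 25 % exit before
    12:00 local wall-clock.  Returns the day (normalized Timestamp) or
    None if no day qualifies.  ``trips`` must belong to a single bee.
    """
    if len(trips) == 0:
        return None
    exits = trips["exit_t"].to_numpy()
    clock = meta.start_datetime + pd.to_timedelta(exits, unit="s")
    days = pd.DatetimeIndex(clock).normalize()
    before_noon = pd.DatetimeIndex(clock).hour < 12
    frame = pd.DataFrame({"day": days, "am": before_noon})
    for day, grp in frame.groupby("day", sort=True):
        if len(grp) >= 6 and grp["am"].mean() > 0.25:
            return day
    return None


def flag_orientation_trips(
    trips: pd.DataFrame,
    meta: TrialMetadata,
    rule: str = "first-day",
    skip_first_n: int = 6,
) -> pd.DataFrame:
    """Mark orientation flights per bee.

    ``rule='first-day'`` (default): all trips strictly before the bee's
    first foraging day (see :func:`first_foraging_day`) are orientation
    flights; if no day qualifies, all its trips are.  ``rule='skip-n'``:
    the bee's first ``skip_first_n`` trips are orientation flights.
    """
    if len(trips) == 0:
        return trips.copy()
    out = trips.sort_values(["bee_id", "exit_t"]).reset_index(drop=True).copy()
    flags = np.zeros(len(out), dtype=bool)
    for bee, grp in out.groupby("bee_id", sort=False):
        if rule == "skip-n":
            flags[grp.index[:skip_first_n]] = True
            continue
        day = first_foraging_day(grp, meta)
        if day is None:
            flags[grp.index] = True
        else:
            clock = meta.start_datetime + pd.to_timedelta(
                grp["exit_t"].to_numpy(), unit="s"
            )
            flags[grp.index] = pd.DatetimeIndex(clock).normalize() < day
    out["is_orientation"] = flags
    return out


def label_burst_roles(
    bursts: list[Burst],
    trips: pd.DataFrame,
    dances: pd.DataFrame,
    follows: pd.DataFrame,
    forager_window: tuple[float, float] = FORAGER_WINDOW,
    role_window: float = ROLE_WINDOW,
) -> pd.DataFrame:
    """Attach forager/dancer/follower roles to each burst.

    Returns long-format columns ``burst_id,role,bee_id`` with role F
    (non-orientation trip entry in [peak−1000, peak−600]), W (dance event
    overlapping [peak−1000, peak]) and DF (follow event overlapping the
    same window).
    """
    lo_off, hi_off = forager_window
    rows = []
    for b in bursts:
        peak = b.peak_t
        if len(trips):
            sel = (
                (~trips["is_orientation"].astype(bool))
                & (trips["entry_t"] >= peak - hi_off)
                & (trips["entry_t"] <= peak - lo_off)
            )
            for bee in sorted(set(trips.loc[sel, "bee_id"])):
                rows.append((b.burst_id, "F", bee))
        if len(dances):
            sel = (dances["start"] <= peak) & (dances["end"] >= peak - role_window)
            for bee in sorted(set(dances.loc[sel, "bee_id"])):
                rows.append((b.burst_id, "W", bee))
        if len(follows):
            sel = (follows["start"] <= peak) & (follows["end"] >= peak - role_window)
            for bee in sorted(set(follows.loc[sel, "follower_id"])):
                rows.append((b.burst_id, "DF", bee))
    return pd.DataFrame(rows, columns=["burst_id", "role", "bee_id"])
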