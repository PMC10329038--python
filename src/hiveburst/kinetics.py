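"""Per-bee and hive-level kinetic energy, diurnal detrending, K/D/O binning.

A bee's activity at second ``t`` is its kinetic energy
``K_i(t) = Δx² + Δy²`` (squared displacement per second, pixels²/s²).
Hive activity ``K_G(t)`` is the unweighted mean of the individual kinetic
energies that are defined at ``t`` — the averaging set is the bees tracked
at both ``t`` and ``t+1``, so rosters shrinking through deaths or tag loss
do not create spurious dips.

The diurnal rhythm is removed before burst detection by subtracting a
centered 12-hour moving average (edges truncated, not NA-padded, so the
series keeps its full length).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .tracking_io import TrackingTable

__all__ = [
    "KineticSeries",
    "KDOSeries",
    "individual_ke",
    "global_ke",
    "detrend_diurnal",
    "clamp_positive",
    "bin_kdo",
]

#: Default detrending window: 12 h in seconds.
DIURNAL_WINDOW = 43200


@dataclass
class KineticSeries:
    """Regularly sampled kinetic-energy series.

    ``t`` are sample times (seconds, step = ``period``), ``K`` the values
    with NaN marking absent samples.  ``kind`` is ``raw``, ``detrended``
    or ``binned``; ``n`` (optional) is the per-sample averaging count for
    hive-level series.
    """

    t: np.ndarray
    K: np.ndarray
    bee_id: str = "GLOBAL"
    kind: str = "raw"
    period: float = 1.0
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.t.shape != self.K.shape:
            raise ValueError("t and K must have equal shape")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.K)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "K": self.K})


@dataclass
class KDOSeries:
    """Binned hive state: mean activity K, dancer count D, out-of-hive count O."""

    bin_start: np.ndarray
    K: np.ndarray
    D: np.ndarray
    O: np.ndarray
    bin_width: int

    def __len__(self) -> int:
        return len(self.bin_start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start": self.bin_start, "K": self.K, "D": self.D, "O": self.O}
        )


def _ke_frame(table: TrackingTable) -> pd.DataFrame:
    """Long frame of defined K_i values: columns bee_id, t, K."""
    df = table.df
    dt = df.groupby("bee_id", sort=False)["t"].diff(-1).to_numpy()
    dx = df.groupby("bee_id", sort=False)["x"].diff(-1).to_numpy()
    dy = df.groupby("bee_id", sort=False)["y"].diff(-1).to_numpy()
    ok = dt == -table.sampling_period  # next detection exactly one step later
    return pd.DataFrame(
        {
            "bee_id": df["bee_id"].to_numpy()[ok],
            "t": df["t"].to_numpy()[ok],
            "K": dx[ok] ** 2 + dy[ok] ** 2,
        }
    )


def individual_ke(table: TrackingTable, bee_id: str) -> KineticSeries:
    """K_i(t) = (x_{t+1}−x_t)² + (y_{t+1}−y_t)² for one bee.

    The series covers the bee's detection span; samples where the bee is
    missing at ``t`` or ``t+1`` are NaN (absent, never zero).
    """
    sub = table.bee(bee_id)  # raises KeyError for unknown bees
    t = sub["t"].to_numpy()
    if t.size < 2:
        return KineticSeries(t=t[:0].astype(float), K=np.empty(0), bee_id=bee_id)
    grid = np.arange(t[0], t[-1], table.sampling_period)
    K = np.full(grid.size, np.nan)
    dt = np.diff(t)
    ok = dt == table.sampling_period
    idx = ((t[:-1] - t[0]) // table.sampling_period)[ok]
    dx = np.diff(sub["x"].to_numpy())[ok]
    dy = np.diff(sub["y"].to_numpy())[ok]
    K[idx] = dx**2 + dy**2
    return KineticSeries(t=grid.astype(float), K=K, bee_id=bee_id)


def global_ke(table: TrackingTable) -> KineticSeries:
    """Hive activity K_G(t): mean of the defined K_i(t), with counts.

    Defined over the full trial span [0, T_total−1]; seconds with no
    defined individual value are NaN.
    """
    ke = _ke_frame(table)
    T = table.meta.T_total
    grid = np.arange(T, dtype=float)
    K = np.full(T, np.nan)
    n = np.zeros(T, dtype=np.int64)
    if len(ke):
        grp = ke.groupby("t")["K"].agg(["mean", "size"])
        idx = grp.index.to_numpy().astype(int)
        inside = (idx >= 0) & (idx < T)
        K[idx[inside]] = grp["mean"].to_numpy()[inside]
        n[idx[inside]] = grp["size"].to_numpy()[inside]
    return KineticSeries(t=grid, K=K, bee_id="GLOBAL", n=n)


def detrend_diurnal(series: KineticSeries, window: int = DIURNAL_WINDOW) -> KineticSeries:
    """Subtract a centered moving average (default 12 h) from the series.

    Edges are truncated (the average uses whatever part of the window is
    in range), keeping the output full length.  Linear in its input.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(series.K) <= window / series.period:
        raise ValueError("series must be longer than the detrending window")
    w = max(1, int(round(window / series.period)))
    ma = (
        pd.Series(series.K)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(series, K=series.K - ma, kind="detrended")


def clamp_positive(series: KineticSeries, eps_frac: float = 1e-6) -> KineticSeries:
    """Floor a detrended series at ``eps_frac`` times its positive mean.

    The inverse-rate conversion feeding burst detection needs strictly
    positive rates; detrended activity can dip below zero.  NaN samples
    are also set to the floor (no activity evidence ≈ minimal rate).
    """
    K = series.K.copy()
    pos = K[np.isfinite(K) & (K > 0)]
    floor = eps_frac * (pos.mean() if pos.size else 1.0)
    K[~np.isfinite(K)] = floor
    np.maximum(K, floor, out=K)
    return replace(series, K=K)


def bin_kdo(
    k: KineticSeries,
    dances: pd.DataFrame | None,
    trips: pd.DataFrame | None,
    bin_width: int,
) -> KDOSeries:
    """Bin hive state into a K/D/O series.

    K is the mean of ``K_G`` over each bin (NaN-aware); D the number of
    *distinct* bees with a dance event overlapping the bin; O the number
    of distinct bees whose trip interval overlaps the bin.  A partial
    trailing bin is dropped for comparability across widths.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t0 = float(k.t[0]) if len(k.t) else 0.0
    span = len(k.K) * k.period
    n_bins = int(span // bin_width)
    starts = t0 + bin_width * np.arange(n_bins)
    K = np.full(n_bins, np.nan)
    samples_per_bin = int(round(bin_width / k.period))
    for b in range(n_bins):
        chunk = k.K[b * samples_per_bin : (b + 1) * samples_per_bin]
        if np.isfinite(chunk).any():
            K[b] = np.nanmean(chunk)
    D = _distinct_overlap_counts(dances, "bee_id", "start", "end", starts, bin_width)
    O = _distinct_overlap_counts(trips, "bee_id", "exit_t", "entry_t", starts, bin_width)
    return KDOSeries(bin_start=starts, K=K, D=D, O=O, bin_width=bin_width)


def group_binned_ke(
    table: TrackingTable,
    groups: dict[str, tuple[str, ...]],
    bin_width: int,
) -> dict[str, np.ndarray]:
    """Mean kinetic energy per bin for each named group of bees.

    The per-bin value is the mean of all defined K_i samples of the
    group's members in that bin (bins with no defined sample are NaN);
    a partial trailing bin is dropped.  Used for the group-level
    information-flow analysis (e.g. FP/NFP/NP partitions).
    """
    ke = _ke_frame(table)
    T = table.meta.T_total
    n_bins = T // bin_width
    ke = ke[ke["t"] < n_bins * bin_width]
    ke = ke.assign(bin=(ke["t"] // bin_width).astype(int))
    out = {}
    for name, members in groups.items():
        sub = ke[ke["bee_id"].isin(set(members))]
        series = np.full(n_bins, np.nan)
        if len(sub):
            agg = sub.groupby("bin")["K"].mean()
            series[agg.index.to_numpy()] = agg.to_numpy()
        out[name] = series
    return out


def _distinct_overlap_counts(
    events: pd.DataFrame | None,
    id_col: str,
    start_col: str,
    end_col: str,
    bin_starts: np.ndarray,
    bin_width: int,
) -> np.ndarray:
    counts = np.zeros(len(bin_starts), dtype=np.int64)
    if events is None or len(events) == 0:
        return counts
    per_bin: list[set] = [set() for _ in bin_starts]
    if len(bin_starts) == 0:
        return counts
    t0 = bin_starts[0]
    for bee, ev_start, ev_end in zip(
        events[id_col], events[start_col], events[end_col]
    ):
        lo = int(np.floor((ev_start - t0) / bin_width))
        hi = int(np.floor((ev_end - t0) / bin_width))
        for b in range(max(lo, 0), min(hi, len(bin_starts) - 1) + 1):
            per_bin[b].add(bee)
    for b, s in enumerate(per_bin):
        counts[b] = len(s)
    return counts
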