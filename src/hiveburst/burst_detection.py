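"""Kleinberg burst detection on a continuous activity series, plus a
maximum-likelihood power-law fit of inter-burst intervals.

The hive activity series is converted into pseudo-event intervals: a
kinetic-energy value of ``K`` at second ``t`` is read as an event rate of
``K`` events/s, i.e. one event every ``1/K`` seconds.  One gap ``x_t =
1/K(t)`` is attached per second, which keeps the burst-level sequence
aligned with the original series so that burst periods can be read off
directly.

Burst levels come from Kleinberg's infinite-state automaton: state ``i``
emits gaps ~ Exp(λ̄·sⁱ); raising the level from ``j`` to ``i`` costs
``γ·(i−j)·ln n`` while lowering is free.  The optimal level sequence is
found exactly by dynamic programming.  A burst is a maximal run with
level ≥ 1.

Inter-burst (peak-to-peak) intervals are fitted with the continuous
power-law MLE of Clauset–Shalizi–Newman: ``α̂ = 1 + n·[Σ ln(x_i/x_min)]⁻¹``
over the tail, ``x_min`` chosen to minimize the Kolmogorov–Smirnov
distance, with a semi-parametric bootstrap goodness-of-fit p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import KineticSeries
from .tracking_io import TrialMetadata

__all__ = [
    "GapSeries",
    "BurstLevels",
    "Burst",
    "PowerLawFit",
    "rate_to_gaps",
    "kleinberg_levels",
    "extract_bursts",
    "mark_artificial",
    "inter_burst_intervals",
    "fit_ibi_powerlaw",
]


@dataclass
class GapSeries:
    """Pseudo-event intervals derived from an activity series.

    ``gaps[i] = 1 / K(t_i)`` with ``t`` retained for alignment;
    ``lambda_bar = N / T`` where ``N = Σ K(t)`` is the implied total event
    count and ``T`` the series span in seconds.
    """

    gaps: np.ndarray
    t: np.ndarray
    lambda_bar: float
    N: float
    T: float

    def __post_init__(self) -> None:
        self.gaps = np.asarray(self.gaps, dtype=float)
        if np.any(self.gaps <= 0):
            raise ValueError("all gaps must be positive (clamp the series upstream)")
        if self.lambda_bar <= 0:
            raise ValueError("lambda_bar must be positive")


@dataclass
class BurstLevels:
    """Optimal Kleinberg level sequence with its parameters."""

    bl: np.ndarray
    t: np.ndarray
    s: float
    gamma: float
    max_level: int
    cost: float


@dataclass
class Burst:
    burst_id: int
    start: float
    end: float
    peak_t: float
    peak_value: float
    artificial: bool = False


@dataclass
class PowerLawFit:
    alpha: float
    xmin: float
    ks: float
    p_boot: float | None
    n_tail: int
    n_boot: int = 0


def rate_to_gaps(series: KineticSeries) -> GapSeries:
    """Convert an activity series into one pseudo-event gap per second.

    ``K(t)`` is an event rate: K = 1 means one event per second, K = 10
    one event every 0.1 s.  N = Σ K(t), T = span, λ̄ = N/T.
    """
    K = series.K
    if np.any(~np.isfinite(K)) or np.any(K <= 0):
        raise ValueError("series must be finite and strictly positive; clamp first")
    gaps = 1.0 / K
    N = float(K.sum() * series.period)
    T = float(len(K) * series.period)
    return GapSeries(gaps=gaps, t=series.t.copy(), lambda_bar=N / T, N=N, T=T)


def default_max_level(gaps: GapSeries, s: float) -> int:
    lam_max = 1.0 / gaps.gaps.min()
    ratio = max(lam_max / gaps.lambda_bar, 1.0)
    return int(np.ceil(np.log(ratio) / np.log(s))) + 1


def kleinberg_levels(
    gaps: GapSeries,
    s: float = 2.0,
    gamma: float = 1.0,
    max_level: int | None = None,
) -> BurstLevels:
    """Exact DP solution of Kleinberg's automaton on a gap sequence.

    State ``i`` (0 ≤ i ≤ max_level) emits gap ``x`` with cost
    ``−ln(λ_i e^{−λ_i x})`` where ``λ_i = λ̄ sⁱ``; moving up ``d`` levels
    costs ``γ·d·ln n`` (n = number of gaps), moving down is free.  The
    default level cap is ``ceil(log_s(max λ_t / λ̄)) + 1`` — one above the
    highest emission-optimal state, so the cap never binds.
    """
    if s <= 1:
        raise ValueError("s must exceed 1")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    x = gaps.gaps
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 gaps")
    if max_level is None:
        max_level = default_max_level(gaps, s)
    L = max_level + 1
    lam = gaps.lambda_bar * s ** np.arange(L)  # (L,)
    # emission costs, shape (n, L)
    emit = -(np.log(lam)[None, :] - lam[None, :] * x[:, None])
    trans_up = gamma * np.log(n)
    levels_idx = np.arange(L)
    # up_cost[j, i] = cost of moving from level j to level i before emission
    up_cost = trans_up * np.maximum(levels_idx[None, :] - levels_idx[:, None], 0)

    cost = np.full(L, np.inf)
    cost[0] = 0.0  # automaton starts at level 0
    back = np.empty((n, L), dtype=np.int32)
    for tt in range(n):
        total = cost[:, None] + up_cost  # (from, to)
        prev = np.argmin(total, axis=0)
        cost = total[prev, levels_idx] + emit[tt]
        back[tt] = prev
    best_final = int(np.argmin(cost))
    bl = np.empty(n, dtype=np.int64)
    cur = best_final
    for tt in range(n - 1, -1, -1):
        bl[tt] = cur
        cur = int(back[tt, cur])
    return BurstLevels(
        bl=bl, t=gaps.t.copy(), s=s, gamma=gamma, max_level=max_level,
        cost=float(cost[best_final]),
    )


def extract_bursts(levels: BurstLevels, series: KineticSeries) -> list[Burst]:
    """Maximal runs with level ≥ 1 become bursts; peak = argmax of the
    series inside the period (earliest on ties)."""
    if len(levels.bl) != len(series.K):
        raise ValueError("levels and series must be aligned")
    hot = levels.bl >= 1
    if not hot.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], hot.view(np.int8), [0]))))
    bursts = []
    for bid, (a, b) in enumerate(zip(edges[::2], edges[1::2])):
        seg = series.K[a:b]
        seg = np.where(np.isfinite(seg), seg, -np.inf)
        pk = a + int(np.argmax(seg))
        bursts.append(
            Burst(
                burst_id=bid,
                start=float(series.t[a]),
                end=float(series.t[b - 1]),
                peak_t=float(series.t[pk]),
                peak_value=float(series.K[pk]),
            )
        )
    return bursts


def mark_artificial(
    bursts: list[Burst], meta: TrialMetadata, tol: float = 300.0
) -> list[Burst]:
    """Flag bursts whose period intersects [c−tol, c+tol] for a recorded
    glass-cleaning time c; the rest are spontaneous."""
    out = []
    for b in bursts:
        art = any(
            b.start <= c + tol and b.end >= c - tol for c in meta.cleaning_times
        )
        out.append(
            Burst(
                burst_id=b.burst_id, start=b.start, end=b.end,
                peak_t=b.peak_t, peak_value=b.peak_value, artificial=art,
            )
        )
    return out


def inter_burst_intervals(bursts: list[Burst], spontaneous_only: bool = True) -> np.ndarray:
    """Peak-to-peak intervals of consecutive (by default spontaneous) bursts."""
    sel = [b for b in bursts if not (spontaneous_only and b.artificial)]
    peaks = np.sort(np.array([b.peak_t for b in sel], dtype=float))
    return np.diff(peaks)


def _fit_fixed_candidates(x_sorted: np.ndarray, candidates: np.ndarray):
    """(alpha, xmin, ks) minimizing the KS distance over candidate xmins."""
    n = x_sorted.size
    logx = np.log(x_sorted)
    cum = np.concatenate((np.cumsum(logx[::-1])[::-1], [0.0]))
    best = (np.inf, np.nan, np.nan)  # ks, alpha, xmin
    for xm in candidates:
        j = np.searchsorted(x_sorted, xm, side="left")
        n_tail = n - j
        if n_tail < 2:
            continue
        alpha = 1.0 + n_tail / (cum[j] - n_tail * np.log(xm))
        if not np.isfinite(alpha) or alpha <= 1.0:
            continue
        tail = x_sorted[j:]
        theo = 1.0 - (tail / xm) ** (1.0 - alpha)
        emp_hi = np.arange(1, n_tail + 1) / n_tail
        emp_lo = np.arange(0, n_tail) / n_tail
        ks = max(np.abs(emp_hi - theo).max(), np.abs(emp_lo - theo).max())
        if ks < best[0]:
            best = (ks, alpha, xm)
    return best[1], best[2], best[0]


def _powerlaw_fit_once(x: np.ndarray, max_candidates: int = 200):
    xs = np.sort(x)
    uniq = np.unique(xs)[:-1]  # xmin = max leaves an empty tail
    if uniq.size > max_candidates:
        take = np.unique(
            (np.linspace(0, uniq.size - 1, max_candidates)).astype(int)
        )
        uniq = uniq[take]
    return _fit_fixed_candidates(xs, uniq), xs


def fit_ibi_powerlaw(
    intervals: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    max_candidates: int = 200,
) -> PowerLawFit:
    """Continuous Clauset power-law fit with bootstrap goodness of fit.

    ``x_min`` is scanned over (up to ``max_candidates`` quantile-spaced)
    unique data values, ``α̂`` is the closed-form tail MLE, and ``p_boot``
    is the fraction of semi-parametric bootstrap replicates whose refitted
    KS distance is at least the observed one.  Set ``n_boot=0`` to skip
    the bootstrap.
    """
    x = np.asarray(intervals, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 10:
        raise ValueError(f"need at least 10 positive intervals, got {x.size}")
    (alpha, xmin, ks), xs = _powerlaw_fit_once(x, max_candidates)
    if not np.isfinite(alpha):
        raise ValueError("power-law fit failed: no admissible xmin")
    p_boot = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = x.size
        body = xs[xs < xmin]
        p_tail = 1.0 - body.size / n
        exceed = 0
        for _ in range(n_boot):
            from_tail = rng.random(n) < p_tail
            k_tail = int(from_tail.sum())
            samp = np.empty(n)
            # inverse-CDF draw from the fitted Pareto tail
            samp[:k_tail] = xmin * rng.random(k_tail) ** (-1.0 / (alpha - 1.0))
            if n - k_tail > 0:
                if body.size:
                    samp[k_tail:] = rng.choice(body, size=n - k_tail, replace=True)
                else:
                    samp[k_tail:] = xmin * rng.random(n - k_tail) ** (
                        -1.0 / (alpha - 1.0)
                    )
            (_, _, ks_b), _ = _powerlaw_fit_once(samp, max_candidates)
            if np.isfinite(ks_b) and ks_b >= ks:
                exceed += 1
        p_boot = exceed / n_boot
    n_tail = int((xs >= xmin).sum())
    return PowerLawFit(
        alpha=float(alpha), xmin=float(xmin), ks=float(ks),
        p_boot=p_boot, n_tail=n_tail, n_boot=n_boot,
    )
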