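"""NMF decomposition of per-burst activity windows and pioneer-bee
classification.

For each burst a nonnegative matrix A (rows = seconds in a window around
the burst peak, default ±1000 s; columns = bees; entries = raw K_i, 0
where missing) is factorized as A ≅ G·B with Kullback–Leibler loss and
Lee–Seung multiplicative updates: G holds the basis time courses, B the
bee memberships.  Each bee is assigned to its dominant basis (argmax of
its membership column).  Bases whose time course peaks strictly before
the burst onset are "pioneer bases"; bees dominated by a pioneer basis
and passing the amplitude filter (maximum reconstructed activity at
least the window-matrix mean) form the burst's pioneer set P_b.

The factorization rank is chosen by Brunet's consensus procedure: per
candidate rank, several random-restart factorizations are reduced to
connectivity matrices (bees co-assigned to the same dominant basis),
averaged into a consensus matrix, and the cophenetic correlation between
consensus distances and their average-linkage dendrogram is computed;
the chosen rank is the one preceding the first drop of that coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from .burst_detection import Burst
from .kinetics import _ke_frame
from .tracking_io import TrackingTable

__all__ = [
    "BurstWindowMatrix",
    "NMFResult",
    "extract_window",
    "run_nmf",
    "select_rank",
    "classify_pioneers",
    "build_pioneer_matrix",
    "pioneer_partition",
    "role_overlap",
]

WINDOW_HALF_WIDTH = 1000
N_ITER = 500
N_RESTARTS = 50
EPS = 1e-12


@dataclass
class BurstWindowMatrix:
    """Nonnegative activity window around one burst peak."""

    burst_id: int
    A: np.ndarray            # (time, bees)
    row_times: np.ndarray
    col_bees: tuple[str, ...]
    truncated: bool = False


@dataclass
class NMFResult:
    """Best-of-restarts KL factorization A ≅ G·B."""

    G: np.ndarray            # (time, r) basis time courses
    B: np.ndarray            # (r, bees) memberships
    r: int
    kl_loss: float
    loss_trajectory: np.ndarray   # per-iteration loss of the best restart
    n_iter: int
    restart_index: int


def extract_window(
    table: TrackingTable,
    burst: Burst,
    half_width: int = WINDOW_HALF_WIDTH,
    ke: pd.DataFrame | None = None,
) -> BurstWindowMatrix:
    """Per-bee raw K_i matrix over peak ± half_width seconds.

    Missing K_i entries are 0; bees absent for the whole window keep a
    zero column.  Windows extending past the trial span are truncated and
    flagged.  ``ke`` may pass a precomputed long K_i frame (bee_id, t, K)
    to avoid recomputation across bursts.
    """
    if not np.isfinite(burst.peak_t):
        raise ValueError("burst peak undefined")
    peak = int(burst.peak_t)
    lo = peak - half_width
    hi = peak + half_width
    truncated = False
    if lo < 0:
        lo, truncated = 0, True
    if hi > table.meta.T_total - 1:
        hi, truncated = table.meta.T_total - 1, True
    if ke is None:
        ke = _ke_frame(table)
    roster = table.roster
    times = np.arange(lo, hi + 1)
    A = np.zeros((times.size, len(roster)))
    sub = ke[(ke["t"] >= lo) & (ke["t"] <= hi)]
    col = {b: j for j, b in enumerate(roster)}
    rows = (sub["t"].to_numpy() - lo).astype(int)
    cols = np.array([col[b] for b in sub["bee_id"]], dtype=int)
    A[rows, cols] = sub["K"].to_numpy()
    return BurstWindowMatrix(
        burst_id=burst.burst_id, A=A, row_times=times.astype(float),
        col_bees=roster, truncated=truncated,
    )


def _kl_divergence(A: np.ndarray, R: np.ndarray) -> float:
    """Generalized KL divergence D(A || R), with 0·log0 = 0."""
    mask = A > 0
    return float(
        np.sum(A[mask] * np.log(A[mask] / R[mask])) - A.sum() + R.sum()
    )


def run_nmf(
    A: np.ndarray,
    r: int,
    n_iter: int = N_ITER,
    n_restarts: int = N_RESTARTS,
    seed: int | np.random.Generator | None = None,
    track_loss: bool = True,
) -> NMFResult:
    """KL-loss NMF by multiplicative updates, best of random restarts.

    Initial factors are uniform-random positive; updates are the Lee–Seung
    rules, which never increase the generalized KL loss.  Denominators are
    floored at 1e-12 so zero rows/columns of A are harmless.  Returns the
    restart with minimal final loss and, with ``track_loss``, its full
    per-iteration loss trajectory.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("A must be nonnegative")
    m, n = A.shape
    if not (0 < r < min(m, n)):
        raise ValueError(f"rank must satisfy 0 < r < min{A.shape}; got {r}")
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        G = rng.uniform(0.1, 1.0, size=(m, r))
        B = rng.uniform(0.1, 1.0, size=(r, n))
        traj = np.empty(n_iter) if track_loss else None
        for it in range(n_iter):
            R = G @ B
            np.maximum(R, EPS, out=R)
            ratio = A / R
            B *= (G.T @ ratio) / np.maximum(G.sum(axis=0)[:, None], EPS)
            R = G @ B
            np.maximum(R, EPS, out=R)
            ratio = A / R
            G *= (ratio @ B.T) / np.maximum(B.sum(axis=1)[None, :], EPS)
            if track_loss:
                R = G @ B
                np.maximum(R, EPS, out=R)
                traj[it] = _kl_divergence(A, R)
        R = np.maximum(G @ B, EPS)
        loss = _kl_divergence(A, R)
        if best is None or loss < best.kl_loss:
            best = NMFResult(
                G=G, B=B, r=r, kl_loss=loss,
                loss_trajectory=traj if track_loss else np.empty(0),
                n_iter=n_iter, restart_index=restart,
            )
    return best


def _connectivity(B: np.ndarray) -> np.ndarray:
    dom = np.argmax(B, axis=0)
    return (dom[:, None] == dom[None, :]).astype(float)


def select_rank(
    A: np.ndarray,
    r_range: range | tuple[int, int] = (2, 10),
    runs_per_rank: int = 20,
    n_iter: int = N_ITER,
    seed: int | np.random.Generator | None = None,
    return_profile: bool = False,
):
    """Brunet cophenetic rank selection.

    Per candidate rank, ``runs_per_rank`` single-restart factorizations
    from random starts yield connectivity matrices averaged into a
    consensus matrix; the cophenetic correlation between consensus
    distances (1 − consensus) and their average-linkage dendrogram is
    recorded.  Returns the rank preceding the first decrease of the
    coefficient (argmax if it never decreases).
    """
    if runs_per_rank < 2:
        raise ValueError("runs_per_rank must be >= 2 for a consensus matrix")
    if isinstance(r_range, tuple):
        ranks = list(range(r_range[0], r_range[1] + 1))
    else:
        ranks = list(r_range)
    ranks = [r for r in ranks if r < min(A.shape)]
    if not ranks:
        return (2, {}) if return_profile else 2
    rng = np.random.default_rng(seed)
    coph = {}
    for r in ranks:
        consensus = np.zeros((A.shape[1], A.shape[1]))
        for _ in range(runs_per_rank):
            res = run_nmf(
                A, r, n_iter=n_iter, n_restarts=1, seed=rng, track_loss=False
            )
            consensus += _connectivity(res.B)
        consensus /= runs_per_rank
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        if condensed.size == 0 or np.allclose(condensed, condensed[0]):
            coph[r] = 0.0
            continue
        Z = average(condensed)
        c, _ = cophenet(Z, condensed)
        coph[r] = float(c) if np.isfinite(c) else 0.0
    chosen = ranks[-1]
    for prev, cur in zip(ranks[:-1], ranks[1:]):
        if coph[cur] < coph[prev]:
            chosen = prev
            break
    else:
        chosen = max(coph, key=coph.get)
    return (chosen, coph) if return_profile else chosen


def classify_pioneers(
    nmf: NMFResult,
    burst: Burst,
    window: BurstWindowMatrix,
    mode: str = "union",
    amplitude_filter: str = "matrix-mean",
) -> set[str]:
    """Pioneer set P_b of one burst.

    1. Each bee is assigned its dominant basis (argmax membership).
    2. Pioneer bases are those whose time course peaks strictly before
       the burst-period onset (``mode='earliest'`` keeps only the
       earliest-peaking one).
    3. Candidates are bees dominated by a pioneer basis.
    4. Amplitude filter: drop a bee if the maximum of its reconstructed
       activity (column of G·B) is below the mean of all window-matrix
       entries (``amplitude_filter='per-bee'``: below the mean of its own
       column of A instead).

    An empty set (no basis peaking pre-onset) is a valid outcome.
    """
    peaks = window.row_times[np.argmax(nmf.G, axis=0)]
    pioneer_bases = np.flatnonzero(peaks < burst.start)
    if pioneer_bases.size == 0:
        return set()
    if mode == "earliest":
        pioneer_bases = np.array([pioneer_bases[np.argmin(peaks[pioneer_bases])]])
    elif mode != "union":
        raise ValueError("mode must be 'union' or 'earliest'")
    dom = np.argmax(nmf.B, axis=0)
    candidates = np.flatnonzero(np.isin(dom, pioneer_bases))
    if candidates.size == 0:
        return set()
    recon = nmf.G @ nmf.B[:, candidates]
    max_recon = recon.max(axis=0)
    if amplitude_filter == "matrix-mean":
        threshold = window.A.mean()
        keep = max_recon >= threshold
    elif amplitude_filter == "per-bee":
        keep = max_recon >= window.A[:, candidates].mean(axis=0)
    else:
        raise ValueError("amplitude_filter must be 'matrix-mean' or 'per-bee'")
    return {window.col_bees[j] for j in candidates[keep]}


def build_pioneer_matrix(
    pioneer_sets: dict[int, set[str]], roster: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Binary bees × bursts incidence matrix of pioneer membership."""
    burst_ids = sorted(pioneer_sets)
    if roster is None:
        roster = sorted(set().union(*pioneer_sets.values()) if pioneer_sets else set())
    pm = pd.DataFrame(0, index=list(roster), columns=burst_ids, dtype=np.int8)
    for bid in burst_ids:
        members = [b for b in pioneer_sets[bid] if b in pm.index]
        pm.loc[members, bid] = 1
    pm.index.name = "bee_id"
    return pm


def pioneer_partition(
    pioneer_set: set[str], forager_set: set[str], roster: tuple[str, ...]
) -> dict[str, set[str]]:
    """FP/NFP/NP partition of the roster for one burst."""
    fp = pioneer_set & forager_set
    return {
        "FP": fp,
        "NFP": pioneer_set - forager_set,
        "NP": set(roster) - pioneer_set,
    }


def role_overlap(
    pioneer_sets: dict[int, set[str]],
    roles: pd.DataFrame,
    roster: tuple[str, ...],
) -> tuple[pd.DataFrame, dict]:
    """Per-burst and trial-level overlap between roles and pioneers.

    Per burst and role X ∈ {F, W, DF}: |X_b ∩ P_b| / |P_b| and
    |X_b ∩ NP_b| / |NP_b| (NaN when the denominator set is empty).
    Trial level: X_trial = bees with role X at least once, P_trial
    likewise; reports |X_trial ∩ P_trial| / |X_trial| per role plus the
    mean per-bee dance/follow event counts in the P_trial and NP_trial
    groups.
    """
    rows = []
    roster_set = set(roster)
    for bid in sorted(pioneer_sets):
        p = pioneer_sets[bid]
        np_ = roster_set - p
        burst_roles = roles[roles["burst_id"] == bid]
        for role in ("F", "W", "DF"):
            x = set(burst_roles.loc[burst_roles["role"] == role, "bee_id"])
            rows.append(
                dict(
                    burst_id=bid, role=role,
                    frac_of_pioneers=(len(x & p) / len(p)) if p else np.nan,
                    frac_of_nonpioneers=(len(x & np_) / len(np_)) if np_ else np.nan,
                )
            )
    per_burst = pd.DataFrame(rows)
    p_trial = set().union(*pioneer_sets.values()) if pioneer_sets else set()
    np_trial = roster_set - p_trial
    trial = {"P_trial_size": len(p_trial)}
    for role in ("F", "W", "DF"):
        x_trial = set(roles.loc[roles["role"] == role, "bee_id"])
        trial[f"{role}_trial_size"] = len(x_trial)
        trial[f"{role}_and_P_over_{role}"] = (
            len(x_trial & p_trial) / len(x_trial) if x_trial else np.nan
        )
    for role, key in (("W", "dance"), ("DF", "follow")):
        counts = roles.loc[roles["role"] == role, "bee_id"].value_counts()
        trial[f"{key}_rate_P_trial"] = (
            float(np.mean([counts.get(b, 0) for b in p_trial])) if p_trial else np.nan
        )
        trial[f"{key}_rate_NP_trial"] = (
            float(np.mean([counts.get(b, 0) for b in np_trial])) if np_trial else np.nan
        )
    return per_burst, trial
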