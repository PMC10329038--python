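"""Burst-to-burst similarity over pioneer membership.

Bursts are compared through their pioneer sets: the Jaccard distance
``d(a, b) = 1 − |P_a ∩ P_b| / |P_a ∪ P_b|`` between the binary columns of
the pioneer matrix, embedded in 2-D by non-metric MDS (Kruskal stress-1,
random restarts until stress < 0.2).  Whether late bursts share pioneers
more than chance is tested by comparing the dispersion (mean squared
distance to the centroid) of late-burst points against a null built by
redrawing each burst's pioneer set uniformly from the roster with the
original cardinality and recomputing distances + embedding per draw.
Group comparisons use the Brunner–Munzel rank test (no normality or
equal-variance assumption).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, t as t_dist
from sklearn.manifold import MDS

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "jaccard_distances",
    "nmds_embed",
    "dispersion",
    "null_dispersion",
    "brunner_munzel",
    "BrunnerMunzelResult",
]

STRESS_TARGET = 0.2
MAX_RESTARTS = 100
N_NULL_DRAWS = 500


@dataclass
class DistanceMatrix:
    D: np.ndarray
    ids: tuple
    metric_name: str = "jaccard"
    excluded: tuple = ()

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if not np.allclose(self.D, self.D.T) or np.any(np.diag(self.D) != 0):
            raise ValueError("D must be symmetric with zero diagonal")


@dataclass
class Embedding:
    coords: np.ndarray
    ids: tuple
    stress: float
    converged: bool
    n_restarts_used: int


def jaccard_distances(pm: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distances between the burst columns of a pioneer matrix.

    Bursts with an empty pioneer set are excluded (their distance is
    undefined) and listed in ``excluded``.
    """
    col_sums = pm.sum(axis=0)
    keep = col_sums[col_sums > 0].index
    excluded = tuple(c for c in pm.columns if c not in set(keep))
    if len(keep) < 2:
        raise ValueError("need at least 2 bursts with a non-empty pioneer set")
    X = pm[keep].to_numpy().T.astype(bool)
    D = squareform(pdist(X, metric="jaccard"))
    return DistanceMatrix(D=D, ids=tuple(keep), excluded=excluded)


def nmds_embed(
    dm: DistanceMatrix,
    dim: int = 2,
    stress_target: float = STRESS_TARGET,
    max_restarts: int = MAX_RESTARTS,
    seed: int | np.random.Generator | None = None,
) -> Embedding:
    """Non-metric MDS with random restarts until Kruskal stress-1 <
    ``stress_target`` (best-effort embedding flagged otherwise)."""
    if dm.D.shape[0] < 4:
        raise ValueError("need at least 4 points for a stable 2-D embedding")
    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    for attempt in range(1, max_restarts + 1):
        mds = MDS(
            n_components=dim,
            metric="precomputed",
            metric_mds=False,
            init="random",
            n_init=1,
            max_iter=300,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=True,
        )
        coords = mds.fit_transform(dm.D)
        if mds.stress_ < best_stress:
            best_coords, best_stress = coords, float(mds.stress_)
        if best_stress < stress_target:
            return Embedding(
                coords=best_coords, ids=dm.ids, stress=best_stress,
                converged=True, n_restarts_used=attempt,
            )
    return Embedding(
        coords=best_coords, ids=dm.ids, stress=best_stress,
        converged=False, n_restarts_used=max_restarts,
    )


def dispersion(embedding: Embedding, subset=None) -> float:
    """Mean squared Euclidean distance of (a subset of) the embedded
    points to their centroid — the sum of per-coordinate population
    variances."""
    coords = embedding.coords
    if subset is not None:
        index = {b: i for i, b in enumerate(embedding.ids)}
        rows = [index[b] for b in subset]
        if not rows:
            raise ValueError("subset is empty")
        coords = coords[rows]
    centroid = coords.mean(axis=0)
    return float(np.mean(np.sum((coords - centroid) ** 2, axis=1)))


def null_dispersion(
    pm: pd.DataFrame,
    subset,
    n_draws: int = N_NULL_DRAWS,
    seed: int | np.random.Generator | None = None,
    stress_target: float = STRESS_TARGET,
    max_restarts: int = 5,
) -> np.ndarray:
    """Null distribution of the subset dispersion under random pioneer
    draws.

    Each draw resamples every burst's pioneer set uniformly without
    replacement from the roster, keeping the original cardinality, then
    recomputes Jaccard distances, a fresh nMDS embedding and the subset
    dispersion.
    """
    rng = np.random.default_rng(seed)
    roster = list(pm.index)
    sizes = pm.sum(axis=0)
    if (sizes > len(roster)).any():
        raise ValueError("pioneer count exceeds roster size")
    out = np.empty(n_draws)
    for d in range(n_draws):
        null_pm = pd.DataFrame(0, index=pm.index, columns=pm.columns, dtype=np.int8)
        for col in pm.columns:
            k = int(sizes[col])
            if k:
                members = rng.choice(len(roster), size=k, replace=False)
                null_pm.iloc[members, null_pm.columns.get_loc(col)] = 1
        dm = jaccard_distances(null_pm)
        emb = nmds_embed(
            dm, stress_target=stress_target, max_restarts=max_restarts, seed=rng
        )
        sub = [b for b in subset if b in set(dm.ids)]
        out[d] = dispersion(emb, sub if sub else None)
    return out


@dataclass
class BrunnerMunzelResult:
    statistic: float
    df: float
    pvalue: float
    p_hat: float  # stochastic superiority P(A < B) + 0.5 P(A = B)


def brunner_munzel(sample_a, sample_b) -> BrunnerMunzelResult:
    """Brunner–Munzel rank test with Satterthwaite degrees of freedom.

    Tests the null P(A < B) + ½P(A = B) = ½ without assuming normality or
    equal variances; two-sided p from the t distribution.  Samples of
    fewer than ~10 observations make the t approximation rough.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = a.size, b.size
    if min(n1, n2) < 5:
        raise ValueError("each sample needs at least 5 observations")
    pooled = np.concatenate((a, b))
    R = rankdata(pooled)
    Ra, Rb = R[:n1], R[n1:]
    ra_within = rankdata(a)
    rb_within = rankdata(b)
    ma, mb = Ra.mean(), Rb.mean()
    p_hat = (mb - (n2 + 1) / 2) / n1
    Sa2 = np.sum((Ra - ra_within - ma + (n1 + 1) / 2) ** 2) / (n1 - 1)
    Sb2 = np.sum((Rb - rb_within - mb + (n2 + 1) / 2) ** 2) / (n2 - 1)
    if Sa2 == 0 and Sb2 == 0:
        # both samples internally constant relative to the other
        return BrunnerMunzelResult(
            statistic=0.0, df=np.nan,
            pvalue=1.0 if p_hat == 0.5 else 0.0, p_hat=float(p_hat),
        )
    se = np.sqrt(Sa2 / (n1 * n2**2) + Sb2 / (n2 * n1**2)) * (n1 + n2)
    statistic = (mb - ma) / se
    df = (Sa2 / n2 + Sb2 / n1) ** 2 / (
        (Sa2 / n2) ** 2 / (n1 - 1) + (Sb2 / n1) ** 2 / (n2 - 1)
    )
    pvalue = 2 * t_dist.sf(abs(statistic), df)
    return BrunnerMunzelResult(
        statistic=float(statistic), df=float(df),
        pvalue=float(pvalue), p_hat=float(p_hat),
    )
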