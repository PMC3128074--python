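"""Temporal co-expression clustering of sex-biased genes.

Quality-threshold (QT) clustering explores how many well-separated
temporal profiles exist and so suggests a cluster count; K-means under
the same missing-aware distance then produces the final partition.
Clusters are grouped by their adult-stage centroid into M (adult
male-biased), F (adult female-biased) and E (biased only at earlier
stages).

The distance between two 5-stage profiles is the mean of squared
differences over the stages observed in both; on fully observed
profiles this is squared Euclidean distance divided by 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ontosex.core_io import STAGES, BiasProfile

GROUP_M, GROUP_F, GROUP_E = "M", "F", "E"
ADULT_INDEX = len(STAGES) - 1


@dataclass
class TemporalProfile:
    """A cluster-eligible 5-stage mean-ratio vector (NaN = missing)."""

    gene: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(STAGES),):
            raise ValueError("temporal profile must have one value per stage")

    @property
    def n_observed(self) -> int:
        return int((~np.isnan(self.values)).sum())


@dataclass
class GeneCluster:
    """A K-means cluster: members, stage-wise centroid, M/F/E group."""

    id: str
    members: list[str]
    centroid: np.ndarray
    group: str = ""


@dataclass
class KMeansResult:
    clusters: list[GeneCluster]
    objective: float
    objective_history: list[float] = field(default_factory=list)


def eligible_profiles(
    profiles: list[BiasProfile], min_observed: int = 3
) -> list[TemporalProfile]:
    """Sex-biased genes with stage means at >= ``min_observed`` of 5 stages."""
    out = []
    for p in profiles:
        if not p.is_biased:
            continue
        v = p.vector()
        if (~np.isnan(v)).sum() >= min_observed:
            out.append(TemporalProfile(p.gene, v))
    return out


def profile_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference over jointly observed stages (inf if none)."""
    both = ~(np.isnan(x) | np.isnan(y))
    if not both.any():
        return float("inf")
    d = x[both] - y[both]
    return float(np.mean(d * d))


def _distance_matrix(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = X - X[i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            D[i] = np.nanmean(diff * diff, axis=1)
    D[np.isnan(D)] = np.inf
    np.fill_diagonal(D, 0.0)
    return D


def qt_cluster(
    profiles: list[TemporalProfile],
    diameter: float,
    min_size: int = 5,
    return_clusters: bool = False,
):
    """Quality-threshold clustering; returns the suggested cluster count.

    Repeatedly grows, from every remaining profile as a seed, the
    candidate cluster that stays within the diameter (maximum pairwise
    distance) bound, extracts the largest, and stops when no candidate
    of at least ``min_size`` members remains.  The count of extracted
    clusters is the suggested K for K-means.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if not profiles:
        raise ValueError("no profiles to cluster")
    X = np.vstack([p.values for p in profiles])
    D = _distance_matrix(X)
    remaining = list(range(len(profiles)))
    clusters: list[list[int]] = []
    while remaining:
        best: list[int] = []
        for seed in remaining:
            cand = [seed]
            # max distance from each remaining point to the candidate so far
            maxd = D[seed, remaining].copy()
            in_cand = {seed}
            while True:
                admissible = [
                    (maxd[j], idx)
                    for j, idx in enumerate(remaining)
                    if idx not in in_cand and maxd[j] <= diameter
                ]
                if not admissible:
                    break
                _, nxt = min(admissible)
                cand.append(nxt)
                in_cand.add(nxt)
                maxd = np.maximum(maxd, D[nxt, remaining])
            if len(cand) > len(best):
                best = cand
        if len(best) < min_size and clusters:
            break
        clusters.append(best)
        removed = set(best)
        remaining = [i for i in remaining if i not in removed]
        if len(remaining) < min_size:
            break
    k = sum(1 for c in clusters if len(c) >= min_size) or 1
    if return_clusters:
        return k, [[profiles[i].gene for i in c] for c in clusters]
    return k


def _assign(X: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each profile to the nearest centroid under the missing-aware
    distance; returns (labels, distances)."""
    diff = X[:, None, :] - C[None, :, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = np.nanmean(diff * diff, axis=2)
    d[np.isnan(d)] = np.inf
    labels = np.argmin(d, axis=1)
    return labels, d[np.arange(len(X)), labels]


def _centroids(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    C = np.full((k, X.shape[1]), np.nan)
    for j in range(k):
        members = X[labels == j]
        if len(members):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                C[j] = np.nanmean(members, axis=0)
    return C


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style spreading under the missing-aware distance."""
    n = X.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    d = np.array([profile_distance(X[i], X[first]) for i in range(n)])
    for _ in range(1, k):
        finite = np.where(np.isfinite(d), d, 0.0)
        if finite.sum() <= 0:
            nxt = int(rng.integers(n))
        else:
            nxt = int(rng.choice(n, p=finite / finite.sum()))
        chosen.append(nxt)
        d = np.minimum(d, [profile_distance(X[i], X[nxt]) for i in range(n)])
    return X[chosen].copy()


def kmeans_cluster(
    profiles: list[TemporalProfile],
    k: int,
    seed: int,
    n_restarts: int = 50,
    max_iter: int = 100,
) -> KMeansResult:
    """Seeded K-means under the missing-aware profile distance.

    The objective (sum of member-to-centroid distances) is
    non-increasing across iterations; empty clusters are re-seeded from
    the farthest point; the best of ``n_restarts`` runs is returned.
    Fully deterministic for a fixed seed.
    """
    n = len(profiles)
    if k <= 0 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    X = np.vstack([p.values for p in profiles])
    master = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        C = _plusplus_init(X, k, rng)
        history: list[float] = []
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            labels, dmin = _assign(X, C)
            # re-seed empty clusters from the farthest point
            for j in range(k):
                if not (labels == j).any():
                    far = int(np.argmax(np.where(np.isfinite(dmin), dmin, -1)))
                    labels[far] = j
                    dmin[far] = 0.0
            obj = float(dmin.sum())
            history.append(obj)
            newC = _centroids(X, labels, k)
            same = np.allclose(
                np.nan_to_num(newC, nan=np.inf), np.nan_to_num(C, nan=np.inf)
            )
            C = newC
            if same:
                break
        labels, dmin = _assign(X, C)
        obj = float(dmin.sum())
        if best is None or obj < best.objective:
            clusters = [
                GeneCluster(
                    id=f"C{j + 1}",
                    members=[profiles[i].gene for i in np.flatnonzero(labels == j)],
                    centroid=C[j].copy(),
                )
                for j in range(k)
            ]
            best = KMeansResult(clusters, obj, history)
    assert best is not None
    return best


def assign_group(cluster: GeneCluster, threshold: float = 0.8) -> str:
    """M / F / E by the adult centroid; 'undetermined' with no adult info.

    E requires bias somewhere earlier; a cluster unbiased everywhere is
    still labelled E, with a warning.
    """
    adult = cluster.centroid[ADULT_INDEX]
    if np.isnan(adult):
        return "undetermined"
    if adult > threshold:
        return GROUP_M
    if adult < -threshold:
        return GROUP_F
    earlier = cluster.centroid[:ADULT_INDEX]
    if not (np.abs(earlier[~np.isnan(earlier)]) > threshold).any():
        warnings.warn(
            f"cluster {cluster.id} matches no M/F/E definition; labelled E",
            stacklevel=2,
        )
    return GROUP_E


def assign_groups(clusters: list[GeneCluster], threshold: float = 0.8) -> None:
    for c in clusters:
        c.group = assign_group(c, threshold)
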