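"""Soft clustering of kinetic profiles with fuzzy c-means.

Profiles that pass the shape filter are standardized (mean 0, sd 1 per
profile — the analysis clusters shapes, not amplitudes), gaps are filled
by linear interpolation in time, and the complete 15-point vectors are
clustered with fuzzy c-means. The fuzzifier m is set analytically from
the data dimensions; the cluster number k is chosen by scanning k over a
range and locating the elbow of the minimum-centroid-distance curve.
Profiles whose maximum cluster membership exceeds 0.7 form the "dynamic"
set used by all downstream analyses.

The fuzzy c-means objective is J = sum_ij u_ij^m ||x_i - c_j||^2 with
memberships u_ij in [0,1] summing to 1 over clusters j; alternating
updates of u and c decrease J monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError

# ---------------------------------------------------------------------------
# preprocessing


def standardize(values) -> np.ndarray:
    """Scale a complete profile to mean 0, sample standard deviation 1."""
    v = np.asarray(values, dtype=float)
    sd = np.std(v, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise InsufficientDataError("cannot standardize a constant profile")
    return (v - np.mean(v)) / sd


def impute_missing(times, values) -> np.ndarray:
    """Fill gaps: linear interpolation inside, nearest value at the edges."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    if mask.sum() < 2:
        raise InsufficientDataError("need >= 2 observed points to impute")
    if mask.all():
        return v.copy()
    # np.interp clamps to the end values outside the observed range,
    # which is exactly the nearest-observed edge rule.
    return np.interp(t, t[mask], v[mask])


def estimate_fuzzifier(n_profiles: int, n_dims: int) -> float:
    """Analytic fuzzifier for fuzzy c-means from dataset dimensions.

    m = 1 + (1418/N + 22.05) D^-2
          + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)

    with N profiles in D dimensions. m decreases toward 1 (hard
    clustering) as N and D grow.
    """
    if n_profiles < 2 or n_dims < 2:
        raise ParameterError("estimate_fuzzifier needs N >= 2 and D >= 2")
    N = float(n_profiles)
    D = float(n_dims)
    return float(
        1.0
        + (1418.0 / N + 22.05) * D ** -2.0
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )


# ---------------------------------------------------------------------------
# fuzzy c-means


@dataclass
class ClusterModel:
    k: int
    m: float
    centroids: np.ndarray           # (k, D)
    memberships: np.ndarray         # (n, k), rows sum to 1
    objective: float
    converged: bool
    seed: int
    restarts: int
    n_iter: int = 0
    objective_trace: np.ndarray | None = None  # per-iteration J of the best run

    def labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ij = 1 / sum_l (d_ij/d_il)^(2/(m-1)); coincident points get 1.

    Computed as a softmax over -log(d2)/(m-1), which is algebraically
    identical but stays finite as m -> 1+ (where the exponent blows up and
    the partition becomes hard assignment).
    """
    power = 1.0 / (m - 1.0)
    zero_rows = np.any(d2 <= 0.0, axis=1)
    safe = np.where(d2 > 0.0, d2, 1.0)
    logits = -power * np.log(safe)
    logits -= logits.max(axis=1, keepdims=True)
    u = np.exp(logits)
    u /= u.sum(axis=1, keepdims=True)
    if np.any(zero_rows):
        for i in np.where(zero_rows)[0]:
            u[i] = 0.0
            hits = np.where(d2[i] <= 0.0)[0]
            u[i, hits] = 1.0 / len(hits)
    return u


def _sq_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - C[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def _cmeans_single(X: np.ndarray, k: int, m: float, rng: np.random.Generator,
                   tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    n = X.shape[0]
    # Dirichlet(1,...,1) rows: uniform random memberships
    u = rng.dirichlet(np.ones(k), size=n)
    converged = False
    it = 0
    trace = []
    for it in range(1, max_iter + 1):
        um = u ** m
        C = (um.T @ X) / np.sum(um, axis=0)[:, None]
        d2 = _sq_distances(X, C)
        u_new = _memberships_from_distances(d2, m)
        trace.append(float(np.sum((u_new ** m) * d2)))
        delta = np.max(np.abs(u_new - u))
        u = u_new
        if delta < tol:
            converged = True
            break
    um = u ** m
    C = (um.T @ X) / np.sum(um, axis=0)[:, None]
    d2 = _sq_distances(X, C)
    objective = float(np.sum((u ** m) * d2))
    return C, u, objective, converged, it, np.array(trace)


def cmeans(vectors, k: int, m: float, seed: int = 0, restarts: int = 20,
           tol: float = 1e-6, max_iter: int = 500) -> ClusterModel:
    """Fuzzy c-means with multiple seeded restarts; best run by objective.

    k = 1 is the closed form: the centroid is the mean and every profile
    has membership 1.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ParameterError("vectors must be a 2-D array (profiles x time points)")
    n = X.shape[0]
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k >= n:
        raise ParameterError(f"need more vectors ({n}) than clusters ({k})")
    if k == 1:
        C = X.mean(axis=0, keepdims=True)
        u = np.ones((n, 1))
        obj = float(np.sum(_sq_distances(X, C)))
        return ClusterModel(k=1, m=m, centroids=C, memberships=u, objective=obj,
                            converged=True, seed=seed, restarts=restarts)
    if m <= 1.0:
        raise ParameterError("fuzzifier m must be > 1")

    master = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        rng = np.random.default_rng(master.integers(0, 2 ** 31 - 1))
        C, u, obj, conv, it, trace = _cmeans_single(X, k, m, rng, tol, max_iter)
        if best is None or obj < best[2]:
            best = (C, u, obj, conv, it, trace)
    C, u, obj, conv, it, trace = best
    return ClusterModel(k=k, m=m, centroids=C, memberships=u, objective=obj,
                        converged=conv, seed=seed, restarts=restarts, n_iter=it,
                        objective_trace=trace)


def min_centroid_distance(model: ClusterModel) -> float:
    """Smallest pairwise Euclidean distance between cluster centers."""
    if model.k < 2:
        raise ParameterError("min_centroid_distance needs k >= 2")
    C = model.centroids
    d2 = _sq_distances(C, C)
    iu = np.triu_indices(model.k, k=1)
    return float(np.sqrt(np.min(d2[iu])))


@dataclass
class MCDCurve:
    k_values: np.ndarray
    mcd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "mcd": self.mcd})


def select_cluster_number(vectors, m: float, k_range=range(6, 31), seed: int = 0,
                          restarts: int = 20, tol: float = 1e-6,
                          max_iter: int = 500,
                          k_override: int | None = None
                          ) -> tuple[int, MCDCurve, dict[int, ClusterModel]]:
    """Scan k, record the minimum-centroid-distance curve, pick the elbow.

    The elbow is the interior k where the curve bends down most sharply —
    the most negative discrete second difference MCD(k-1) - 2 MCD(k) +
    MCD(k+1) — i.e. the last k whose centroids are still well separated
    before adding one more cluster collapses the minimum distance.
    ``k_override`` bypasses the rule but still records the scan.
    """
    X = np.asarray(vectors, dtype=float)
    ks = np.array(sorted(k_range), dtype=int)
    if ks[0] < 2 or ks[-1] >= X.shape[0]:
        raise ParameterError("k_range must lie within (2, n_vectors)")
    models: dict[int, ClusterModel] = {}
    mcd = np.empty(len(ks))
    for i, k in enumerate(ks):
        model = cmeans(X, int(k), m, seed=seed + int(k), restarts=restarts,
                       tol=tol, max_iter=max_iter)
        models[int(k)] = model
        mcd[i] = min_centroid_distance(model)
    curve = MCDCurve(k_values=ks, mcd=mcd)
    if k_override is not None:
        if k_override not in models:
            models[k_override] = cmeans(X, k_override, m, seed=seed + k_override,
                                        restarts=restarts, tol=tol, max_iter=max_iter)
        return int(k_override), curve, models
    if len(ks) < 3:
        return int(ks[0]), curve, models
    second_diff = mcd[:-2] - 2.0 * mcd[1:-1] + mcd[2:]
    k_star = int(ks[1:-1][int(np.argmin(second_diff))])
    return k_star, curve, models


def filter_by_membership(model: ClusterModel, profile_ids: list,
                         threshold: float = 0.7) -> pd.DataFrame:
    """Profiles whose maximum membership strictly exceeds the threshold.

    Returns a frame with the retained profile ids, their argmax cluster
    (1-based, for reporting) and the membership value.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold must lie in [0, 1]")
    if len(profile_ids) != model.memberships.shape[0]:
        raise ParameterError("profile_ids length must match the membership matrix")
    max_u = model.memberships.max(axis=1)
    labels = model.labels()
    keep = max_u > threshold
    return pd.DataFrame({
        "profile_id": [profile_ids[i] for i in np.where(keep)[0]],
        "cluster": labels[keep] + 1,
        "membership": max_u[keep],
    })
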