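"""Fuzzy c-means clustering.

Both levels of chromaticity-base construction use this clusterer: once per
image on skin-pixel (a, b) coordinates, and once per color class on the
pooled dominant/subdominant centers.  The implementation is the standard
alternating scheme: centers are membership^m-weighted means, memberships
follow the inverse-distance-ratio rule, and the objective

    J = sum_k sum_i  u_ik^m * ||x_k - v_i||^2

is non-increasing across iterations.  Centers are sorted lexicographically
on return so results are invariant (up to nothing) to input permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FcmResult", "fcm", "largest_cluster"]


@dataclass
class FcmResult:
    """Result of one fuzzy c-means run.

    Attributes
    ----------
    centers : (c, d) array, sorted lexicographically by coordinates.
    membership : (N, c) array; rows sum to 1.
    objective_trace : per-iteration objective values (non-increasing).
    hard_counts : per-cluster count of points whose maximal membership is
        that cluster.
    fuzzy_counts : per-cluster sum of memberships (fuzzy cardinality); used
        to break exact hard-count ties, which arise structurally when two
        tight clusters split the data evenly.
    """

    centers: np.ndarray
    membership: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    hard_counts: np.ndarray = None
    fuzzy_counts: np.ndarray = None

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.membership, axis=1)


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """Inverse-distance-ratio update; a point coincident with one or more
    centers splits full membership equally among the coincident centers."""
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.where(any_zero)[0]
        z = zero[rows].astype(float)
        u[rows] = z / z.sum(axis=1, keepdims=True)
    return u


def fcm(
    points,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FcmResult:
    """Cluster ``points`` (N, d) into ``c`` fuzzy clusters.

    Parameters follow the usual convention: fuzzifier ``m`` > 1 controls
    membership softness; iteration stops when the objective improves by less
    than ``tol``.  Deterministic for a given ``seed`` (random initial
    memberships).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if not c >= 2:
        raise ValueError("cluster count c must be >= 2")
    if n <= c:
        raise ValueError(f"need more points than clusters; got N={n}, c={c}")
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")

    rng = np.random.default_rng(seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)

    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = _memberships_from_distances(d2, m)
        obj = float((u**m * d2).sum())
        trace.append(obj)
        if abs(prev - obj) < tol:
            break
        prev = obj

    # Canonical ordering: sort centers lexicographically, permute memberships.
    order = np.lexsort(centers.T[::-1])
    centers = centers[order]
    u = u[:, order]

    labels = np.argmax(u, axis=1)
    hard = np.bincount(labels, minlength=c)
    return FcmResult(
        centers=centers,
        membership=u,
        objective_trace=trace,
        hard_counts=hard,
        fuzzy_counts=u.sum(axis=0),
    )


def largest_cluster(result: FcmResult) -> np.ndarray:
    """Center of the cluster with the greater number of members.

    Membership count is the hard count; exact hard-count ties (common when
    two clusters split pooled points evenly) are broken by the larger fuzzy
    cardinality, then by lower index among the lexicographically sorted
    centers.
    """
    hard = np.asarray(result.hard_counts)
    best = np.flatnonzero(hard == hard.max())
    if len(best) > 1:
        fz = np.asarray(result.fuzzy_counts)[best]
        best = best[np.flatnonzero(fz >= fz.max() - 1e-12)]
    return result.centers[best[0]].copy()
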