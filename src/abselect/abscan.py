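"""AbScan density clustering of antibody ROI sequences.

The procedure: reduce ROI strings to the 11-letter physicochemical alphabet,
compute pairwise Levenshtein distances, estimate the working epsilon from the
knee of the k-nearest-neighbour distance curve, run OPTICS (min_pts=2,
max_eps = 10 x epsilon) with xi steepness extraction, and repeat over a
descending relative-abundance schedule: each iteration re-clusters one
exemplar per existing cluster together with the not-yet-assigned values whose
abundance clears the next threshold.  Remaining noise is rescued by pooled
count (>= 2 on the reduced-space representation) into singleton clusters, or
by 90% same-length identity to an existing cluster member; what is left is
discarded as true noise.

Traditional clonotyping (same length, same scaffold call, >= 90% identity,
single linkage) and 100%-identity grouping are provided as baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import OPTICS

from .annotation import (
    DEFAULT_ALPHABET,
    AnnotatedClone,
    ReducedAlphabet,
    RoiSpec,
    roi_string,
)

logger = logging.getLogger(__name__)

NOISE = -1

DEFAULT_SCHEDULE = (0.005, 0.0005, 0.00005, 0.0)


@dataclass(frozen=True)
class OpticsParams:
    """Density-clustering hyperparameters.

    ``eps_opt`` comes from the k-distance knee; reachability is capped at
    ``max_eps`` (10 x eps_opt by default) and clusters are cut from the
    reachability plot at steepness ``xi``.
    """

    min_pts: int = 2
    eps_opt: float = 1.0
    max_eps: float | None = None
    xi: float = 0.01

    def __post_init__(self) -> None:
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.eps_opt <= 0:
            raise ValueError("eps_opt must be positive")
        if self.max_eps is not None and self.max_eps < self.eps_opt:
            raise ValueError("max_eps must be >= eps_opt")
        if not 0 < self.xi < 1:
            raise ValueError("xi must lie in (0, 1)")

    @property
    def effective_max_eps(self) -> float:
        return 10.0 * self.eps_opt if self.max_eps is None else self.max_eps


@dataclass(frozen=True)
class ClusterAssignment:
    roi_value: str
    cluster_id: int | None
    method: str  # abscan | clonotype | identity
    status: str  # core | member | rescued_count | rescued_identity | discarded_noise


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def pairwise_distance_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of pairwise Levenshtein distances (zero diagonal)."""
    if len(seqs) == 0:
        raise ValueError("need at least one sequence")
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        si = seqs[i]
        for j in range(i + 1, n):
            d = edlib.align(si, seqs[j])["editDistance"]
            D[i, j] = D[j, i] = d
    return D


def _knee_index(curve: np.ndarray) -> int:
    """Index of maximal perpendicular distance to the chord joining the curve
    endpoints; ties break to the smallest index."""
    n = len(curve)
    x = np.arange(n, dtype=float)
    x0, y0, x1, y1 = 0.0, float(curve[0]), float(n - 1), float(curve[-1])
    num = np.abs((y1 - y0) * x - (x1 - x0) * curve + x1 * y0 - y1 * x0)
    return int(np.argmax(num))


def elbow_epsilon(matrix: np.ndarray, k: int = 2, fallback_eps: float = 1.0) -> float:
    """Optimal epsilon from the knee of the sorted k-distance curve.

    The k-distance of a point is its OPTICS core distance at min_pts = k:
    the distance to the k-th closest point counting the point itself (so
    k = 2 reads the first true neighbour).  The curve is sorted ascending and
    the knee located by maximum perpendicular distance to the endpoint chord.
    The result is floored at the smallest positive pairwise distance; a fully
    degenerate (all-zero) matrix yields ``fallback_eps``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2 (min_pts semantics)")
    positive = matrix[matrix > 0]
    if positive.size == 0:
        logger.info("elbow_epsilon: all pairwise distances zero; using fallback %g", fallback_eps)
        return fallback_eps
    floor = float(positive.min())
    if n == 2:
        return max(float(matrix[0, 1]), floor)
    k = min(k, n)
    kdist = np.sort(np.sort(matrix, axis=1)[:, 1:], axis=1)[:, k - 2]
    kdist = np.sort(kdist)
    eps = float(kdist[_knee_index(kdist)])
    return max(eps, floor)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def density_cluster(matrix: np.ndarray, params: OpticsParams) -> np.ndarray:
    """Density clustering over a precomputed distance matrix; noise marked -1.

    Clusters are extracted from the OPTICS reachability ordering (capped at
    ``max_eps``) at steepness ``xi`` and then consolidated at the core scale:
    with min_pts = 2 every point that has a neighbour within ``eps_opt`` is a
    core point, so any two points within ``eps_opt`` are density-connected
    and their clusters are merged, and xi-noise with an ``eps_opt`` neighbour
    is absorbed.  Points unreachable at ``eps_opt`` and unclaimed by the xi
    extraction stay noise.  Deterministic given the input order (callers
    pre-sort by descending abundance then lexicographic ROI value).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n == 1:
        return np.array([NOISE])
    max_eps = params.effective_max_eps
    if n == 2:
        if matrix[0, 1] <= max_eps:
            return np.zeros(2, dtype=int)
        return np.full(2, NOISE, dtype=int)
    opt = OPTICS(
        min_samples=params.min_pts,
        max_eps=max_eps,
        metric="precomputed",
        cluster_method="xi",
        xi=params.xi,
    )
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # all-points-isolated inputs legitimately yield an all-inf reachability
        warnings.filterwarnings("ignore", message="All reachability values are inf")
        xi_labels = opt.fit_predict(matrix)

    uf = _UnionFind(n)
    close = matrix <= params.eps_opt
    np.fill_diagonal(close, False)
    for i, j in zip(*np.nonzero(np.triu(close))):
        uf.union(int(i), int(j))
    for lab in set(xi_labels) - {NOISE}:
        members = np.nonzero(xi_labels == lab)[0]
        for j in members[1:]:
            uf.union(int(members[0]), int(j))

    has_close_neighbor = close.any(axis=1)
    labels = np.full(n, NOISE, dtype=int)
    remap: dict[int, int] = {}
    for i in range(n):
        if xi_labels[i] == NOISE and not has_close_neighbor[i]:
            continue
        root = uf.find(i)
        labels[i] = remap.setdefault(root, len(remap))
    return labels


def _hamming_identity(a: str, b: str) -> float:
    """Fraction of matching positions for equal-length strings (else 0)."""
    if len(a) != len(b) or not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


class AbScanClusterer(BaseEstimator, ClusterMixin):
    """Iterative abundance-seeded OPTICS clustering of ROI sequences.

    Parameters
    ----------
    min_pts, xi, max_eps_factor
        OPTICS hyperparameters; the working epsilon is re-estimated from the
        k-distance knee of each iteration's point set (``recompute_epsilon=False``
        freezes the first estimate) and reachability capped at
        ``max_eps_factor`` times it.
    iteration_schedule
        Strictly decreasing percent relative-abundance thresholds ending at 0.
        The first element is the seed threshold.
    rescue_min_count, rescue_identity
        Noise-rescue rules: pooled count on the reduced-space representation,
        and same-length amino-acid identity to an existing cluster member.
    alphabet
        Reduced amino-acid alphabet applied before distance computation.

    Attributes
    ----------
    labels_ : ndarray of cluster ids aligned with the fitted values (-1 = discarded).
    assignments_ : list[ClusterAssignment]
    eps_history_ : list of (threshold, eps_opt, n_points) per executed iteration.
    """

    def __init__(
        self,
        min_pts: int = 2,
        xi: float = 0.01,
        max_eps_factor: float = 10.0,
        iteration_schedule: Sequence[float] = DEFAULT_SCHEDULE,
        rescue_min_count: int = 2,
        rescue_identity: float = 0.90,
        alphabet: ReducedAlphabet | None = None,
        recompute_epsilon: bool = True,
        fallback_eps: float = 1.0,
    ):
        self.min_pts = min_pts
        self.xi = xi
        self.max_eps_factor = max_eps_factor
        self.iteration_schedule = iteration_schedule
        self.rescue_min_count = rescue_min_count
        self.rescue_identity = rescue_identity
        self.alphabet = alphabet
        self.recompute_epsilon = recompute_epsilon
        self.fallback_eps = fallback_eps

    def _validate(self) -> None:
        sched = list(self.iteration_schedule)
        if sched != sorted(sched, reverse=True) or len(set(sched)) != len(sched):
            raise ValueError("iteration_schedule must be strictly decreasing")
        if sched[-1] != 0:
            raise ValueError("iteration_schedule must end at 0")
        if not 0 < self.rescue_identity <= 1:
            raise ValueError("rescue_identity must lie in (0, 1]")

    def fit(self, X: Sequence[str], y=None, counts: Sequence[int] | None = None):
        """Cluster unique ROI values.

        Parameters
        ----------
        X : unique ROI strings.
        counts : pooled read counts aligned with ``X`` (default: all 1).
        """
        self._validate()
        values = list(X)
        if len(set(values)) != len(values):
            raise ValueError("ROI values must be unique")
        counts = [1] * len(values) if counts is None else list(counts)
        if len(counts) != len(values):
            raise ValueError("counts must align with ROI values")
        alphabet = self.alphabet or DEFAULT_ALPHABET

        # canonical order: descending abundance, then lexicographic
        order = sorted(range(len(values)), key=lambda i: (-counts[i], values[i]))
        vals = [values[i] for i in order]
        cnts = [counts[i] for i in order]
        total = sum(cnts) or 1
        abundance = {v: 100.0 * c / total for v, c in zip(vals, cnts)}
        count_of = dict(zip(vals, cnts))
        pseudo = {v: alphabet.reduce(v) for v in vals}

        cluster_of: dict[str, int] = {}
        status: dict[str, str] = {}
        next_id = 0
        eps_opt: float | None = None
        self.eps_history_ = []
        tried: set[str] = set()

        for threshold in self.iteration_schedule:
            exemplars = self._exemplars(cluster_of, count_of)
            newcomers = [v for v in vals
                         if v not in cluster_of and abundance[v] >= threshold]
            points = list(dict.fromkeys(list(exemplars) + newcomers))
            points.sort(key=lambda v: (-count_of[v], v))
            # an iteration whose candidates were all seen before adds no
            # information: its elbow would be estimated from exemplar spacing
            if len(points) < 2 or all(v in tried for v in newcomers):
                continue
            tried.update(points)
            D = pairwise_distance_matrix([pseudo[v] for v in points])
            if eps_opt is None or self.recompute_epsilon:
                eps_opt = elbow_epsilon(D, k=self.min_pts, fallback_eps=self.fallback_eps)
            params = OpticsParams(
                min_pts=self.min_pts,
                eps_opt=eps_opt,
                max_eps=self.max_eps_factor * eps_opt,
                xi=self.xi,
            )
            labels = density_cluster(D, params)
            self.eps_history_.append((threshold, eps_opt, len(points)))
            next_id = self._attach_iteration(
                points, labels, D, exemplars, cluster_of, status, next_id
            )

        next_id = self._rescue(vals, pseudo, count_of, cluster_of, status, next_id)

        # densify ids in canonical order
        remap: dict[int, int] = {}
        for v in vals:
            cid = cluster_of.get(v)
            if cid is not None and cid not in remap:
                remap[cid] = len(remap)
        self.roi_values_ = vals
        self.labels_ = np.array(
            [remap[cluster_of[v]] if v in cluster_of else NOISE for v in vals]
        )
        self.assignments_ = self._assignments(vals, cluster_of, status, remap, count_of)
        self.n_clusters_ = len(remap)
        return self

    def fit_predict(self, X, y=None, counts=None) -> np.ndarray:
        return self.fit(X, counts=counts).labels_

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _exemplars(cluster_of: Mapping[str, int], count_of: Mapping[str, int]) -> dict[str, int]:
        """Most abundant member per existing cluster (ties: lexicographic smallest)."""
        best: dict[int, str] = {}
        for v, cid in cluster_of.items():
            cur = best.get(cid)
            if cur is None or (-count_of[v], v) < (-count_of[cur], cur):
                best[cid] = v
        return {v: cid for cid, v in best.items()}

    def _attach_iteration(self, points, labels, D, exemplars, cluster_of, status, next_id):
        """Fold one iteration's OPTICS labels into the running partition.

        New values co-clustered with exemplars inherit the nearest exemplar's
        cluster id (ties to the smaller id); clusters without an exemplar get
        fresh ids.  Existing clusters are never merged, so exemplar-heavy
        later iterations cannot fuse the partition built from denser data.
        """
        idx = {v: i for i, v in enumerate(points)}
        for raw in sorted(set(labels) - {NOISE}):
            members = [points[i] for i in range(len(points)) if labels[i] == raw]
            ex_members = [v for v in members if v in exemplars]
            if not ex_members:
                target = next_id
                next_id += 1
                for v in members:
                    if v not in cluster_of:
                        cluster_of[v] = target
                        status[v] = "member"
                continue
            for v in members:
                if v in cluster_of:
                    continue
                nearest = min(
                    ex_members,
                    key=lambda e: (D[idx[v], idx[e]], exemplars[e]),
                )
                cluster_of[v] = exemplars[nearest]
                status[v] = "member"
        return next_id

    def _rescue(self, vals, pseudo, count_of, cluster_of, status, next_id):
        noise = [v for v in vals if v not in cluster_of]
        # count rescue on the reduced-space representation
        groups: dict[str, list[str]] = {}
        for v in noise:
            groups.setdefault(pseudo[v], []).append(v)
        for key in sorted(groups):
            members = groups[key]
            if sum(count_of[v] for v in members) >= self.rescue_min_count:
                for v in members:
                    cluster_of[v] = next_id
                    status[v] = "rescued_count"
                next_id += 1
        # identity rescue against existing cluster members (amino-acid space)
        members_by_cluster: dict[int, list[str]] = {}
        for v, cid in cluster_of.items():
            members_by_cluster.setdefault(cid, []).append(v)
        remaining = [v for v in vals if v not in cluster_of]
        for v in remaining:
            best: tuple[float, int] | None = None
            for cid, members in members_by_cluster.items():
                for m in members:
                    ident = _hamming_identity(v, m)
                    if ident >= self.rescue_identity and (
                        best is None or (-ident, cid) < (-best[0], best[1])
                    ):
                        best = (ident, cid)
            if best is not None:
                cluster_of[v] = best[1]
                status[v] = "rescued_identity"
        for v in vals:
            if v not in cluster_of:
                status[v] = "discarded_noise"
        return next_id

    def _assignments(self, vals, cluster_of, status, remap, count_of):
        # the most abundant member of each cluster is its core
        core: dict[int, str] = {}
        for v in vals:
            cid = cluster_of.get(v)
            if cid is not None and cid not in core:
                core[cid] = v  # vals already in canonical (abundance) order
        out = []
        for v in vals:
            cid = cluster_of.get(v)
            if cid is None:
                out.append(ClusterAssignment(v, None, "abscan", "discarded_noise"))
            else:
                st = "core" if core[cid] == v and status[v] == "member" else status[v]
                out.append(ClusterAssignment(v, remap[cid], "abscan", st))
        return out


class TraditionalClonotyper(BaseEstimator, ClusterMixin):
    """Clonotyping baseline: same ROI length, same scaffold (V/J surrogate)
    call and pairwise identity >= threshold, single linkage."""

    def __init__(self, identity: float = 0.90):
        self.identity = identity

    def fit(self, X: Sequence[str], y=None, scaffolds: Sequence[str] | None = None):
        values = list(X)
        if len(set(values)) != len(values):
            raise ValueError("ROI values must be unique")
        scaffolds = ["" for _ in values] if scaffolds is None else list(scaffolds)
        n = len(values)
        rows, cols = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (
                    len(values[i]) == len(values[j])
                    and scaffolds[i] == scaffolds[j]
                    and _hamming_identity(values[i], values[j]) >= self.identity
                ):
                    rows.append(i)
                    cols.append(j)
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, comp = connected_components(graph, directed=False)
        # deterministic ids: order components by their lexicographically smallest member
        smallest = {}
        for i, c in enumerate(comp):
            if c not in smallest or values[i] < smallest[c]:
                smallest[c] = values[i]
        order = {c: rank for rank, c in enumerate(sorted(smallest, key=smallest.get))}
        self.roi_values_ = values
        self.labels_ = np.array([order[c] for c in comp])
        self.assignments_ = [
            ClusterAssignment(v, int(lab), "clonotype", "member")
            for v, lab in zip(values, self.labels_)
        ]
        self.n_clusters_ = len(order)
        return self

    def fit_predict(self, X, y=None, scaffolds=None) -> np.ndarray:
        return self.fit(X, scaffolds=scaffolds).labels_


class IdentityClusterer(BaseEstimator, ClusterMixin):
    """100%-identity baseline: one cluster per distinct ROI string."""

    def fit(self, X: Sequence[str], y=None):
        values = list(X)
        ids = {v: i for i, v in enumerate(sorted(set(values)))}
        self.roi_values_ = values
        self.labels_ = np.array([ids[v] for v in values])
        self.assignments_ = [
            ClusterAssignment(v, ids[v], "identity", "member") for v in values
        ]
        self.n_clusters_ = len(ids)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


# -- clone-level wrappers ----------------------------------------------------

def _roi_counts(clones: Sequence[AnnotatedClone], roi: RoiSpec | str):
    counts: dict[str, int] = {}
    scaffold_of: dict[str, str] = {}
    for clone in clones:
        v = roi_string(clone, roi)
        counts[v] = counts.get(v, 0) + clone.total_count
        scaffold_of.setdefault(v, clone.scaffold)
    values = sorted(counts, key=lambda v: (-counts[v], v))
    return values, [counts[v] for v in values], [scaffold_of[v] for v in values]


def abscan_cluster(
    clones: Sequence[AnnotatedClone],
    roi: RoiSpec | str = "HCDR3",
    **params,
) -> list[ClusterAssignment]:
    """AbScan-cluster the pooled ROI values of a clone collection."""
    if not clones:
        return []
    values, counts, _ = _roi_counts(clones, roi)
    return AbScanClusterer(**params).fit(values, counts=counts).assignments_


def traditional_clonotype(
    clones: Sequence[AnnotatedClone],
    roi: RoiSpec | str = "HCDR3",
    identity: float = 0.90,
) -> list[ClusterAssignment]:
    if not clones:
        return []
    values, _, scaffolds = _roi_counts(clones, roi)
    return TraditionalClonotyper(identity).fit(values, scaffolds=scaffolds).assignments_


def identity_cluster(
    clones: Sequence[AnnotatedClone],
    roi: RoiSpec | str = "HCDR3",
) -> list[ClusterAssignment]:
    if not clones:
        return []
    values, _, _ = _roi_counts(clones, roi)
    return IdentityClusterer().fit(values).assignments_
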