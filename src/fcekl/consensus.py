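"""KL-divergence consensus over soft partitions (FCE_KL and FCE_sKL).

The ensemble's basic partitions are concatenated column-wise and divided by
the ensemble size r, so that every pixel becomes a discrete probability
vector over the s = sum(c_f) concatenated membership dimensions. The
consensus then clusters these probability profiles by minimizing

    J = sum_k sum_i u_ik^m  D_KL(y_k. || o_i.),

where the centers o_i live on the probability simplex. Setting the
Lagrangian's derivatives to zero gives closed-form alternating updates: the
center update is a membership-weighted convex combination of profile rows,
and the membership update weighs clusters by inverse KL divergence raised
to 1/(m-1).

The spatial variant (FCE_sKL) smooths the memberships over an image
neighborhood after every membership update, exactly like the spatial FCM
base clusterer; the smoothed memberships feed both the center update and
the reported objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, EmptyClusterError
from .fcm import spatial_smooth_memberships

__all__ = [
    "concatenate_normalize",
    "kl_divergence",
    "update_centers",
    "update_memberships",
    "consensus_objective",
    "KLConsensus",
    "ConsensusResults",
]

#: Floor applied to center entries inside the log ratio; basic partitions
#: routinely contain exact zeros and D_KL is otherwise undefined.
DEFAULT_KL_FLOOR = 1e-12

#: Divergences below this are treated as exact zero in the membership
#: update (the pixel profile sits on a center).
_ZERO_DIV = 1e-12

_ROW_SUM_TOL = 1e-8


def _check_rows_stochastic(mat: np.ndarray, what: str, tol: float = _ROW_SUM_TOL) -> None:
    if np.any(mat < -1e-12):
        raise ValueError(f"{what} has negative entries")
    err = np.abs(mat.sum(axis=1) - 1.0)
    if err.max() > tol:
        raise ValueError(f"{what} rows must sum to 1 (max deviation {err.max():.3g})")


def concatenate_normalize(partitions) -> np.ndarray:
    """Stack r row-stochastic membership matrices side by side and divide by r.

    The result is an ``n x s`` matrix (s = sum of member cluster counts)
    whose rows are probability vectors: each pixel's profile over all
    clusters of all ensemble members.
    """
    mats = [np.asarray(p, dtype=float) for p in partitions]
    if not mats:
        raise ValueError("need at least one partition")
    n = mats[0].shape[0]
    for i, u in enumerate(mats):
        if u.ndim != 2 or u.shape[0] != n:
            raise ValueError(f"partition {i} has {u.shape[0]} rows, expected {n}")
        _check_rows_stochastic(u, f"partition {i}")
    y = np.hstack(mats) / len(mats)
    return y


def kl_divergence(p, q, kl_floor: float = DEFAULT_KL_FLOOR) -> float:
    """Kullback-Leibler divergence sum(p log(p/q)), natural log, 0·log0 = 0.

    ``q`` entries are floored at ``kl_floor`` inside the ratio so that
    exact zeros in a center never produce infinities.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probability vectors must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("inputs must sum to 1")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], kl_floor))))


def _kl_matrix(y: np.ndarray, centers: np.ndarray, kl_floor: float) -> np.ndarray:
    """Pairwise D_KL(y_k. || o_i.) as an (n, c) matrix."""
    logy = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
    self_term = (y * logy).sum(axis=1)  # sum p log p, with 0 log 0 = 0
    cross = y @ np.log(np.maximum(centers, kl_floor)).T
    return self_term[:, None] - cross


def update_centers(y: np.ndarray, u: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Center update: o_ij = sum_k u_ik^m y_kj / sum_h sum_k u_ik^m y_kh.

    Because every profile row sums to one, each center is a convex
    combination of profile rows and lands back on the simplex.
    """
    w = np.asarray(u, dtype=float) ** m
    num = w.T @ np.asarray(y, dtype=float)
    denom = num.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        dead = list(np.flatnonzero(denom.ravel() <= 0))
        raise EmptyClusterError(f"cluster(s) {dead} have no membership mass")
    return num / denom


def update_memberships(y: np.ndarray, centers: np.ndarray, m: float = 2.0,
                       kl_floor: float = DEFAULT_KL_FLOOR) -> np.ndarray:
    """Membership update: u_ik = 1 / sum_l (D_ik / D_lk)^(1/(m-1)).

    Pixels whose profile matches a center exactly (zero divergence) split
    their mass equally among the matching centers.
    """
    d = _kl_matrix(np.asarray(y, dtype=float), np.asarray(centers, dtype=float), kl_floor)
    if not np.all(np.isfinite(d)):
        raise FloatingPointError("non-finite KL divergence in membership update")
    u = np.zeros_like(d)
    zero = d < _ZERO_DIV
    singular = zero.any(axis=1)
    if singular.any():
        z = zero[singular]
        u[singular] = z / z.sum(axis=1, keepdims=True)
    reg = ~singular
    if reg.any():
        w = d[reg] ** (-1.0 / (m - 1.0))
        u[reg] = w / w.sum(axis=1, keepdims=True)
    return u


def consensus_objective(y: np.ndarray, u: np.ndarray, centers: np.ndarray,
                        m: float = 2.0, kl_floor: float = DEFAULT_KL_FLOOR) -> float:
    """J = sum_k sum_i u_ik^m D_KL(y_k. || o_i.)."""
    d = _kl_matrix(y, centers, kl_floor)
    return float((u**m * d).sum())


@dataclass
class ConsensusResults:
    """Fitted consensus partition.

    Attributes
    ----------
    memberships : ndarray, shape (n, c)
        Final row-stochastic memberships (the spatially smoothed ones for
        the spatial variant).
    centers : ndarray, shape (c, s)
        Consensus centers on the probability simplex.
    objective_trace : list of float
        J after each completed iteration.
    n_iter : int
        Iterations performed.
    converged : bool
        True if |J(t) - J(t-1)| < tol fired before the iteration cap.
    """

    memberships: np.ndarray
    centers: np.ndarray
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    method: str = "fce_kl"

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def labels(self, grid_shape=None) -> np.ndarray:
        lab = np.argmax(self.memberships, axis=1)
        if grid_shape is not None:
            lab = lab.reshape(grid_shape)
        return lab

    def summary(self) -> str:
        n, c = self.memberships.shape
        sizes = np.bincount(np.argmax(self.memberships, axis=1), minlength=c)
        lines = [
            f"{self.method} consensus: n={n}, c={c}, s={self.centers.shape[1]}",
            f"  iterations: {self.n_iter} (converged={self.converged})",
            f"  objective J: {self.objective:.6g}",
            "  hard cluster sizes: " + ", ".join(str(int(v)) for v in sizes),
        ]
        return "\n".join(lines)


class KLConsensus:
    """Consensus clustering of probability profiles under KL divergence.

    Parameters
    ----------
    profiles : ndarray, shape (n, s)
        Row-stochastic probability profiles, normally the concatenated and
        normalized ensemble memberships from :func:`concatenate_normalize`.
    n_clusters : int
        Number of consensus clusters c.
    m : float
        Fuzzification coefficient (> 1).
    spatial : bool
        If True, run the spatial variant: smooth memberships over the image
        neighborhood each iteration (requires ``grid_shape``).
    grid_shape : (int, int), optional
        Image height/width; mandatory when ``spatial`` is True.
    window : int
        Odd neighborhood side for the spatial variant.
    tol : float
        Convergence threshold on |ΔJ|.
    max_iter : int
        Iteration cap.
    kl_floor : float
        Floor on center entries inside the log ratio.

    Notes
    -----
    The plain variant is an exact alternating minimization, so its
    objective trace is non-increasing. The spatial variant's smoothing step
    sits outside the Lagrangian derivation, so monotone descent is not
    guaranteed there; the run still terminates by |ΔJ| < tol or the
    iteration cap.
    """

    def __init__(self, profiles, n_clusters: int, m: float = 2.0, spatial: bool = False,
                 grid_shape=None, window: int = 5, tol: float = 1e-5, max_iter: int = 100,
                 kl_floor: float = DEFAULT_KL_FLOOR):
        y = np.asarray(profiles, dtype=float)
        if y.ndim != 2:
            raise ValueError("profiles must be a 2-D matrix")
        _check_rows_stochastic(y, "profiles")
        n = y.shape[0]
        if n_clusters < 1 or n_clusters > n:
            raise ConfigurationError(f"n_clusters must be in [1, {n}]")
        if m <= 1:
            raise ConfigurationError("fuzzification coefficient m must be > 1")
        if tol <= 0 or max_iter < 1:
            raise ConfigurationError("tol must be > 0 and max_iter >= 1")
        if not (0 < kl_floor <= 1e-6):
            raise ConfigurationError("kl_floor must lie in (0, 1e-6]")
        if spatial:
            if grid_shape is None:
                raise ConfigurationError("spatial variant requires grid_shape")
            h, w = grid_shape
            if h * w != n:
                raise ValueError(f"grid {grid_shape} has {h * w} pixels, profiles have {n} rows")
            if window < 1 or window % 2 == 0:
                raise ConfigurationError("window must be an odd integer >= 1")
        self.y = y
        self.n_clusters = int(n_clusters)
        self.m = float(m)
        self.spatial = bool(spatial)
        self.grid_shape = tuple(grid_shape) if grid_shape is not None else None
        self.window = int(window)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.kl_floor = float(kl_floor)

    @classmethod
    def from_partitions(cls, partitions, n_clusters: int, **kwargs) -> "KLConsensus":
        """Build the model directly from the ensemble's membership matrices."""
        return cls(concatenate_normalize(partitions), n_clusters, **kwargs)

    def _init_centers(self, seed) -> np.ndarray:
        # sample c distinct profile rows; drawing from the unique rows avoids
        # coincident initial centers, which would lock the fit in a symmetric
        # fixed point (np.unique also makes the draw order-independent)
        rng = np.random.default_rng(seed)
        pool = np.unique(self.y, axis=0)
        if pool.shape[0] < self.n_clusters:
            raise DegenerateInputError(
                f"only {pool.shape[0]} distinct profiles for {self.n_clusters} clusters")
        idx = rng.choice(pool.shape[0], size=self.n_clusters, replace=False)
        return pool[idx].copy()

    def fit(self, seed: int = 0, init_centers=None) -> ConsensusResults:
        """Alternate membership and center updates until |ΔJ| < tol.

        Deterministic given ``seed``; ``init_centers`` (c x s, rows on the
        simplex) overrides the seeded row-sampling initialization.
        """
        if init_centers is not None:
            centers = np.asarray(init_centers, dtype=float).copy()
            _check_rows_stochastic(centers, "init_centers")
        else:
            centers = self._init_centers(seed)
        trace: list[float] = []
        prev = np.inf
        converged = False
        t = 0
        for t in range(1, self.max_iter + 1):
            u = update_memberships(self.y, centers, self.m, self.kl_floor)
            if self.spatial:
                u = spatial_smooth_memberships(u, self.grid_shape, self.window)
            try:
                centers = update_centers(self.y, u, self.m)
            except EmptyClusterError as exc:
                raise EmptyClusterError(f"{exc} (iteration {t})", iteration=t) from exc
            j = consensus_objective(self.y, u, centers, self.m, self.kl_floor)
            trace.append(j)
            if abs(j - prev) < self.tol:
                converged = True
                break
            prev = j
        return ConsensusResults(
            memberships=u,
            centers=centers,
            objective_trace=trace,
            n_iter=t,
            converged=converged,
            method="fce_skl" if self.spatial else "fce_kl",
        )
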