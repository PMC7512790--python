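"""Fuzzy c-means and its local-spatial variant on grayscale intensities.

These are the base clusterers that feed the KL consensus ensemble. Both
operate on a single intensity feature per pixel and return soft partitions:
an ``n x c`` membership matrix whose rows sum to one.

The spatial variant averages each pixel's membership with the mean
membership of a square neighborhood after every iteration, which pulls
isolated noisy pixels toward the label of their surroundings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "FuzzyCMeans",
    "SpatialFuzzyCMeans",
    "FCMResults",
    "spatial_smooth_memberships",
    "generate_basic_partitions",
    "DEFAULT_MEMBERS",
]


def _as_data_vector(data) -> np.ndarray:
    """Flatten an image grid (row-major) or 1-D sequence to a float vector."""
    x = np.asarray(data, dtype=float)
    if x.ndim == 2:
        x = x.ravel()
    elif x.ndim != 1:
        raise ValueError(f"expected a 1-D data vector or 2-D image grid, got ndim={x.ndim}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data contains non-finite values")
    return x


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership update: inverse-distance weighting with exponent 2/(m-1).

    Pixels coinciding exactly with one or more centers get their mass split
    equally among the coincident centers (the zero-distance limit).
    """
    d2 = (x[:, None] - centers[None, :]) ** 2
    u = np.zeros_like(d2)
    zero = d2 == 0.0
    singular = zero.any(axis=1)
    if singular.any():
        z = zero[singular]
        u[singular] = z / z.sum(axis=1, keepdims=True)
    reg = ~singular
    if reg.any():
        w = d2[reg] ** (-1.0 / (m - 1.0))
        u[reg] = w / w.sum(axis=1, keepdims=True)
    return u


def _fcm_centers(x: np.ndarray, u: np.ndarray, m: float) -> np.ndarray:
    w = u**m
    return (w * x[:, None]).sum(axis=0) / w.sum(axis=0)


def _fcm_objective(x: np.ndarray, u: np.ndarray, centers: np.ndarray, m: float) -> float:
    d2 = (x[:, None] - centers[None, :]) ** 2
    return float((u**m * d2).sum())


@dataclass
class FCMResults:
    """Converged soft partition from a fuzzy c-means style fit.

    Attributes
    ----------
    memberships : ndarray, shape (n, c)
        Row-stochastic soft assignment of each datum to each cluster.
    centers : ndarray, shape (c,)
        Cluster centers in intensity space.
    objective_trace : list of float
        Objective value after each completed iteration.
    n_iter : int
        Iterations performed.
    converged : bool
        Whether the |ΔJ| < tol criterion fired before max_iter.
    """

    memberships: np.ndarray
    centers: np.ndarray
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    method: str = "fcm"

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def labels(self, grid_shape=None) -> np.ndarray:
        """Hard labels by per-datum argmax (ties go to the lowest index)."""
        lab = np.argmax(self.memberships, axis=1)
        if grid_shape is not None:
            lab = lab.reshape(grid_shape)
        return lab

    def summary(self) -> str:
        c = self.memberships.shape[1]
        lines = [
            f"{self.method} fit: n={self.memberships.shape[0]}, c={c}",
            f"  iterations: {self.n_iter} (converged={self.converged})",
            f"  objective J: {self.objective:.6g}",
            "  centers: " + ", ".join(f"{v:.4g}" for v in np.atleast_1d(self.centers)),
        ]
        return "\n".join(lines)


class FuzzyCMeans:
    """Fuzzy c-means on a single intensity feature.

    Minimizes ``J = sum_k sum_i u_ik^m (x_k - v_i)^2`` subject to rows of
    ``u`` summing to one, by alternating the closed-form center and
    membership updates. ``fit`` is deterministic for a given seed.

    Parameters
    ----------
    data : array-like
        1-D intensity vector or 2-D image grid (flattened row-major).
    n_clusters : int
        Number of clusters ``c`` (>= 1, <= n).
    m : float
        Fuzzification coefficient, > 1. Larger values blur cluster
        boundaries; m=2 is the conventional choice.
    tol : float
        Convergence threshold on successive objective values.
    max_iter : int
        Iteration cap.
    """

    method_name = "fcm"

    def __init__(self, data, n_clusters: int, m: float = 2.0, tol: float = 1e-5, max_iter: int = 100):
        self.x = _as_data_vector(data)
        n = self.x.size
        if n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if n_clusters > n:
            raise ConfigurationError(f"n_clusters={n_clusters} exceeds n={n}")
        if m <= 1:
            raise ConfigurationError("fuzzification coefficient m must be > 1")
        if tol <= 0:
            raise ConfigurationError("tol must be positive")
        if max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        uniq = np.unique(self.x)
        if uniq.size == 1 and n_clusters > 1:
            raise DegenerateInputError("all data identical: cluster centers would coincide")
        if uniq.size < n_clusters:
            raise DegenerateInputError(
                f"only {uniq.size} distinct values but {n_clusters} clusters requested"
            )
        self.n_clusters = n_clusters
        self.m = float(m)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    # -- hooks overridden by the spatial variant -------------------------
    def _post_membership(self, u: np.ndarray) -> np.ndarray:
        return u

    def _init_centers(self, seed) -> np.ndarray:
        # sample c distinct intensity values: reproducible and permutation
        # invariant (np.unique sorts), so reordering the data permutes
        # membership rows identically
        rng = np.random.default_rng(seed)
        uniq = np.unique(self.x)
        return rng.choice(uniq, size=self.n_clusters, replace=False)

    def fit(self, seed: int = 0, init_centers=None) -> FCMResults:
        if init_centers is not None:
            centers = np.asarray(init_centers, dtype=float).copy()
        else:
            centers = self._init_centers(seed)
        trace: list[float] = []
        prev = np.inf
        converged = False
        t = 0
        for t in range(1, self.max_iter + 1):
            u = _fcm_memberships(self.x, centers, self.m)
            u = self._post_membership(u)
            centers = _fcm_centers(self.x, u, self.m)
            j = _fcm_objective(self.x, u, centers, self.m)
            trace.append(j)
            if abs(j - prev) < self.tol:
                converged = True
                break
            prev = j
        return FCMResults(
            memberships=u,
            centers=centers,
            objective_trace=trace,
            n_iter=t,
            converged=converged,
            method=self.method_name,
        )


def _window_mean(field2d: np.ndarray, window: int) -> np.ndarray:
    """Mean over a centered square window, truncated at the image border.

    The window always includes the center pixel; near the border the
    divisor is the actual number of in-image neighbors, keeping the
    operator an exact average everywhere.
    """
    if window == 1:
        return field2d
    sums = uniform_filter(field2d, size=window, mode="constant", cval=0.0) * window**2
    counts = uniform_filter(np.ones_like(field2d), size=window, mode="constant", cval=0.0) * window**2
    return sums / counts


def spatial_smooth_memberships(u: np.ndarray, grid_shape, window: int) -> np.ndarray:
    """Average each pixel's membership with its neighborhood mean.

    Returns ``(window-mean of u + u) / 2`` per cluster, computed on the
    image grid with truncated borders. Row sums are preserved exactly
    because the window mean of a row-stochastic field is row-stochastic.
    """
    u = np.asarray(u, dtype=float)
    h, w = grid_shape
    if u.shape[0] != h * w:
        raise ValueError(f"membership rows {u.shape[0]} != grid pixels {h * w}")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    out = np.empty_like(u)
    for i in range(u.shape[1]):
        grid = u[:, i].reshape(h, w)
        out[:, i] = ((_window_mean(grid, window) + grid) / 2.0).ravel()
    return out


class SpatialFuzzyCMeans(FuzzyCMeans):
    """Fuzzy c-means with per-iteration neighborhood membership smoothing.

    After every membership update each pixel's membership vector is
    averaged with the mean over a ``window x window`` neighborhood before
    the centers are recomputed. With window=1 this reduces exactly to
    plain fuzzy c-means. The smoothing step sits outside the alternating
    minimization, so the objective is not guaranteed monotone.
    """

    method_name = "sfcm"

    def __init__(self, image, n_clusters: int, m: float = 2.0, window: int = 3,
                 tol: float = 1e-5, max_iter: int = 100):
        img = np.asarray(image, dtype=float)
        if img.ndim != 2:
            raise ValueError("spatial FCM requires a 2-D image grid")
        if window < 1 or window % 2 == 0:
            raise ConfigurationError("window must be an odd integer >= 1")
        super().__init__(img, n_clusters, m=m, tol=tol, max_iter=max_iter)
        self.grid_shape = img.shape
        self.window = int(window)

    def _post_membership(self, u: np.ndarray) -> np.ndarray:
        return spatial_smooth_memberships(u, self.grid_shape, self.window)


#: Default four-member ensemble: two independently seeded plain FCM runs
#: plus spatial FCM at two neighborhood scales.
DEFAULT_MEMBERS = (
    ("fcm", {}),
    ("fcm", {}),
    ("sfcm", {"window": 3}),
    ("sfcm", {"window": 5}),
)


def _parse_member(spec):
    """Accept ('fcm', {...}), 'fcm', or 'sfcm:5' forms."""
    if isinstance(spec, str):
        if ":" in spec:
            name, arg = spec.split(":", 1)
            return name.strip(), {"window": int(arg)}
        return spec.strip(), {}
    name, kwargs = spec
    return name, dict(kwargs)


def generate_basic_partitions(image, n_clusters: int, members=DEFAULT_MEMBERS,
                              seed: int = 0, m: float = 2.0, tol: float = 1e-5,
                              max_iter: int = 100) -> list:
    """Run each ensemble member on the image and collect its soft partition.

    Each member receives an independent seed derived from ``seed``, so two
    'fcm' entries yield differently initialized (hence diverse) partitions
    while the whole ensemble stays reproducible. Members may override
    ``n_clusters`` per entry via a ``c`` key.
    """
    members = list(members)
    if not members:
        raise ConfigurationError("ensemble needs at least one member")
    img = np.asarray(image, dtype=float)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(members))
    partitions = []
    for spec, s in zip(members, child_seeds):
        name, kwargs = _parse_member(spec)
        c_f = int(kwargs.pop("c", n_clusters))
        if name == "fcm":
            model = FuzzyCMeans(img, c_f, m=m, tol=tol, max_iter=max_iter, **kwargs)
        elif name == "sfcm":
            model = SpatialFuzzyCMeans(img, c_f, m=m, tol=tol, max_iter=max_iter, **kwargs)
        else:
            raise ConfigurationError(f"unknown ensemble member {name!r} (expected 'fcm' or 'sfcm')")
        partitions.append(model.fit(seed=int(s)).memberships)
    return partitions
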