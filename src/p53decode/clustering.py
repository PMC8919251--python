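"""Fuzzy c-means clustering of z-scored time courses and direction labeling.

The partition follows the standard Bezdek alternating updates with Euclidean
distance on z-scores over the 0-9 h window and a fuzzifier of m = 1.3 (five
clusters for mRNA, three for protein).  Initialization is a seeded random
membership matrix with multiple restarts, keeping the best objective; the
objective J = sum_ik u_ik^m ||x_i - c_k||^2 is non-increasing across
iterations.

A cluster is labeled *induced* when the mean z of its center over 1-9 h
exceeds the center's z at t=0 (an upward-shifted profile), *repressed*
otherwise - an explicit operationalization of what is otherwise assigned by
visual inspection of cluster means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import TimeGrid


@dataclass(frozen=True)
class ClusterConfig:
    n_clusters: int = 5          # 5 for mRNA, 3 for protein
    fuzzifier: float = 1.3       # exponent of the fuzzy partition matrix
    max_iter: int = 300
    tol: float = 1e-9
    seed: int = 0
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must exceed 1")


MRNA_CLUSTER_CONFIG = ClusterConfig(n_clusters=5)
PROTEIN_CLUSTER_CONFIG = ClusterConfig(n_clusters=3)


@dataclass
class FCMResult:
    centers: np.ndarray      # (c, T)
    memberships: np.ndarray  # (n, c), rows sum to 1
    objective: float
    n_iter: int

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def _fcm_objective(X: np.ndarray, centers: np.ndarray, U: np.ndarray, m: float) -> float:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(np.sum((U ** m) * d2))


def _fcm_memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    # points coincident with a center get crisp membership there
    zero = d2 < 1e-30
    U = np.empty_like(d2)
    exp = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-exp)
        U = inv / inv.sum(axis=1, keepdims=True)
    rows_with_zero = zero.any(axis=1)
    if rows_with_zero.any():
        U[rows_with_zero] = zero[rows_with_zero] / zero[rows_with_zero].sum(
            axis=1, keepdims=True)
    return U


def fuzzy_cmeans(z_matrix: np.ndarray, cfg: ClusterConfig = MRNA_CLUSTER_CONFIG) -> FCMResult:
    """Cluster rows of a genes x time z-score matrix.

    Deterministic given ``cfg.seed``; memberships are row-stochastic and the
    returned partition is the best of ``cfg.n_init`` random restarts.
    """
    X = np.asarray(z_matrix, float)
    if X.ndim != 2:
        raise ValueError("z_matrix must be 2-D (genes x time)")
    n, _ = X.shape
    if n < cfg.n_clusters:
        raise ValueError(f"need at least {cfg.n_clusters} rows, got {n}")
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite entries in z_matrix")
    m = cfg.fuzzifier
    rng = np.random.default_rng(cfg.seed)
    best: FCMResult | None = None
    for _ in range(cfg.n_init):
        U = rng.dirichlet(np.ones(cfg.n_clusters), size=n)
        prev = np.inf
        for it in range(1, cfg.max_iter + 1):
            Um = U ** m
            centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
            U = _fcm_memberships(X, centers, m)
            J = _fcm_objective(X, centers, U, m)
            if prev - J < cfg.tol:
                break
            prev = J
        cand = FCMResult(centers, U, J, it)
        if best is None or cand.objective < best.objective:
            best = cand
    return best


def label_direction(center: np.ndarray, grid: TimeGrid | None = None,
                    window: tuple[float, float] = (1.0, 9.0)) -> str:
    """Label a cluster center profile as induced or repressed.

    ``center`` is a z-profile over the clustering window; with a grid, the
    mean is taken over window points, otherwise over all points after the
    first.  A constant center is labeled "unchanged".
    """
    c = np.asarray(center, float)
    if grid is not None:
        mask = grid.window_mask(*window)
        later = c[mask]
    else:
        later = c[1:]
    if np.std(c) < 1e-12:
        import logging
        logging.getLogger(__name__).warning("constant cluster center")
        return "unchanged"
    return "induced" if float(later.mean()) > float(c[0]) else "repressed"


@dataclass
class ClusterAssignment:
    species: str
    memberships: np.ndarray
    cluster: int
    direction: str

    def __post_init__(self) -> None:
        if self.cluster != int(np.argmax(self.memberships)):
            raise ValueError("hard label inconsistent with argmax membership")


def assign_clusters(
    species: list[str],
    result: FCMResult,
    grid: TimeGrid | None = None,
) -> list[ClusterAssignment]:
    directions = [label_direction(c, grid) for c in result.centers]
    return [
        ClusterAssignment(s, result.memberships[i], int(result.hard_labels[i]),
                          directions[result.hard_labels[i]])
        for i, s in enumerate(species)
    ]


def select_induced_clusters(assignments: list[ClusterAssignment]) -> set[str]:
    """Union of genes whose hard-label cluster is induced."""
    return {a.species for a in assignments if a.direction == "induced"}
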