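"""K-means with v-fold cross-validated cluster-count selection.

The clustering stage takes category-level coordinates from the MCA and
groups them with Lloyd's algorithm (random distinct initial centers,
nearest-center assignment by Euclidean distance, mean update, best of
several restarts).  The *clustering cost* of a solution is the mean
Euclidean distance of points to their assigned centers (``metric=
"distance"``, the default) or the mean squared distance (``metric=
"squared"``, the within-cluster sum-of-squares variant).

To pick the number of clusters k, points are split once into v folds by
a seeded shuffle (the same folds are reused across every k so the costs
are comparable).  For each fold, centers are fit on the complement and
the cost of the held-out points to their nearest trained center is
recorded; the cross-validated cost D̄_k is the mean over folds.  Two
selection rules are provided:

``cost_plateau``
    Scan k upward and stop at the first k with |D̄_{k+1} - D̄_k| below
    the cost tolerance (default 0.01) — further splitting no longer
    changes the held-out cost, so by parsimony k suffices.
``fold_significance``
    Return the smallest k whose per-fold costs are not significantly
    better at k+1 under a paired two-sided t-test at alpha = 0.05.

If no k in range satisfies the rule, the k with the global minimum
cross-validated cost is returned and the selection trace carries a
warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import cdist

__all__ = [
    "ClusteringConfig",
    "ClusterSolution",
    "SelectionResult",
    "kmeans",
    "vfold_cost",
    "select_k",
    "classify_categories",
    "cost_table",
]


@dataclass(frozen=True)
class ClusteringConfig:
    k_min: int = 2
    k_max: int = 10
    v: int = 5
    cost_tolerance: float = 0.01
    max_iter: int = 100
    n_restarts: int = 10
    seed: int = 0
    selection_rule: str = "cost_plateau"
    metric: str = "distance"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.v < 2:
            raise ValueError("v must be >= 2")
        if self.cost_tolerance <= 0:
            raise ValueError("cost_tolerance must be positive")
        if self.metric not in ("distance", "squared"):
            raise ValueError("metric must be 'distance' or 'squared'")
        if self.selection_rule not in ("cost_plateau", "fold_significance"):
            raise ValueError("unknown selection_rule")


@dataclass
class ClusterSolution:
    k: int
    centers: np.ndarray
    assignment: np.ndarray
    within_cost: float
    cv_cost: float | None = None
    fold_costs: np.ndarray | None = None
    labels: list | None = None


def _cost(points: np.ndarray, centers: np.ndarray, assignment: np.ndarray, metric: str) -> float:
    d = np.linalg.norm(points - centers[assignment], axis=1)
    return float(np.mean(d if metric == "distance" else d**2))


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment (ties -> lowest index) with empty-cluster repair.

    An emptied cluster is repaired by moving in the point currently
    farthest from its assigned center; a point is moved at most once.
    """
    k = len(centers)
    dist = cdist(points, centers)
    assignment = dist.argmin(axis=1)
    inner = dist[np.arange(len(points)), assignment]
    for empty in range(k):
        if not np.any(assignment == empty):
            sizes = np.bincount(assignment, minlength=k)
            movable = sizes[assignment] > 1  # never empty a donor cluster
            candidates = np.where(movable, inner, -np.inf)
            farthest = int(np.argmax(candidates))
            assignment[farthest] = empty
            inner[farthest] = -np.inf
    return assignment


def _lloyd(points: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    """One Lloyd run from random distinct initial centers.

    Iterates assignment/mean-update until assignments stabilize or the
    iteration cap is hit; the within-cluster sum of squares is checked
    to be non-increasing across iterations.
    """
    unique = np.unique(points, axis=0)
    centers = unique[rng.choice(len(unique), size=k, replace=False)].copy()
    assignment = None
    prev_ssq = np.inf
    for _ in range(max_iter):
        new_assignment = _assign(points, centers)
        if assignment is not None and np.array_equal(new_assignment, assignment):
            return centers, assignment
        assignment = new_assignment
        for j in range(k):
            centers[j] = points[assignment == j].mean(axis=0)
        ssq = float(((points - centers[assignment]) ** 2).sum())
        if ssq > prev_ssq + 1e-9 * (1 + prev_ssq):
            raise AssertionError("within-cluster sum of squares increased")
        prev_ssq = ssq
    return centers, _assign(points, centers)


def kmeans(
    points,
    k: int,
    config: ClusteringConfig | None = None,
    seed: int | None = None,
) -> ClusterSolution:
    """Best-of-restarts Lloyd clustering; deterministic given the seed."""
    config = config or ClusteringConfig()
    labels = list(points.index) if isinstance(points, pd.DataFrame) else None
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be 2-D")
    n_distinct = len(np.unique(pts, axis=0))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    best: ClusterSolution | None = None
    for _ in range(max(1, config.n_restarts)):
        centers, assignment = _lloyd(pts, k, rng, config.max_iter)
        cost = _cost(pts, centers, assignment, config.metric)
        if best is None or cost < best.within_cost - 1e-15:
            best = ClusterSolution(
                k=k, centers=centers, assignment=assignment, within_cost=cost, labels=labels
            )
    return best


def _fold_indices(n: int, v: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), v)]


def vfold_cost(
    points,
    k: int,
    config: ClusteringConfig | None = None,
    folds: list[np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Cross-validated clustering cost: mean held-out distance over folds."""
    config = config or ClusteringConfig()
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if config.v > n:
        raise ValueError(f"v={config.v} exceeds the {n} points")
    if folds is None:
        folds = _fold_indices(n, config.v, config.seed)
    fold_costs = []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train = pts[train_mask]
        if len(np.unique(train, axis=0)) < k:
            raise ValueError(
                f"training complement of fold {i} has fewer than k={k} distinct "
                "points; use a smaller k or fewer folds"
            )
        sub_seed = (config.seed * 1_000_003 + 7919 * i + k) % (2**31)
        sol = kmeans(train, k, config, seed=sub_seed)
        d = np.linalg.norm(pts[test_idx][:, None, :] - sol.centers[None], axis=2).min(axis=1)
        fold_costs.append(float(np.mean(d if config.metric == "distance" else d**2)))
    fold_costs = np.asarray(fold_costs)
    return float(fold_costs.mean()), fold_costs


@dataclass
class SelectionResult:
    optimal_k: int
    solutions: dict[int, ClusterSolution]
    trace: list[dict]
    fallback: bool = False


def select_k(points, config: ClusteringConfig | None = None) -> SelectionResult:
    """Scan k_min..k_max and apply the configured stopping rule."""
    config = config or ClusteringConfig()
    labels = list(points.index) if isinstance(points, pd.DataFrame) else None
    pts = np.asarray(points, dtype=float)
    n_distinct = len(np.unique(pts, axis=0))
    k_max = min(config.k_max, n_distinct - 1)
    if k_max < config.k_min:
        raise ValueError(
            f"k range [{config.k_min}, {config.k_max}] infeasible with only "
            f"{n_distinct} distinct points"
        )
    ks = list(range(config.k_min, k_max + 1))
    folds = _fold_indices(len(pts), config.v, config.seed)

    solutions: dict[int, ClusterSolution] = {}
    cv: dict[int, float] = {}
    fold_costs: dict[int, np.ndarray] = {}
    for k in ks:
        sol = kmeans(pts, k, config, seed=(config.seed * 31 + k) % (2**31))
        sol.labels = labels
        cv[k], fold_costs[k] = vfold_cost(pts, k, config, folds=folds)
        sol.cv_cost, sol.fold_costs = cv[k], fold_costs[k]
        solutions[k] = sol

    trace: list[dict] = []
    chosen: int | None = None
    for k in ks:
        entry = {"k": k, "cv_cost": cv[k], "fold_costs": fold_costs[k].tolist()}
        if k + 1 in cv and chosen is None:
            if config.selection_rule == "cost_plateau":
                diff = abs(cv[k + 1] - cv[k])
                entry["diff_next"] = diff
                if diff < config.cost_tolerance:
                    entry["decision"] = "plateau: stop"
                    chosen = k
            else:
                d = fold_costs[k] - fold_costs[k + 1]
                if np.allclose(d, 0):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = scipy.stats.ttest_rel(fold_costs[k], fold_costs[k + 1])
                entry["p_vs_next"] = float(p)
                if p >= config.alpha or d.mean() <= 0:
                    entry["decision"] = "k+1 not significantly better: stop"
                    chosen = k
        trace.append(entry)

    fallback = chosen is None
    if fallback:
        chosen = min(cv, key=cv.get)
        trace.append({"warning": f"no k satisfied the rule; global-minimum k={chosen} used"})
    return SelectionResult(optimal_k=chosen, solutions=solutions, trace=trace, fallback=fallback)


def classify_categories(G: pd.DataFrame, solution: ClusterSolution) -> pd.DataFrame:
    """Category-to-cluster table, clusters renumbered 1..k by first appearance."""
    if len(G) != len(solution.assignment):
        raise ValueError("coordinate rows and assignment length differ")
    renumber: dict[int, int] = {}
    for a in solution.assignment:
        if a not in renumber:
            renumber[a] = len(renumber) + 1
    idx = G.index
    table = pd.DataFrame(
        {
            "variable": [t[0] for t in idx],
            "level": [t[1] for t in idx],
            "cluster": [renumber[a] for a in solution.assignment],
        }
    )
    return table.sort_values(["cluster", "variable", "level"], kind="stable").reset_index(drop=True)


def cost_table(result: SelectionResult) -> pd.DataFrame:
    """Cost-vs-k table (the data behind a cluster-cost curve)."""
    rows = [
        {
            "k": k,
            "cv_cost": sol.cv_cost,
            "within_cost": sol.within_cost,
            "selected": k == result.optimal_k,
        }
        for k, sol in sorted(result.solutions.items())
    ]
    return pd.DataFrame(rows)
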