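"""Across-study meta-microstate maps by weighted, polarity-invariant k-means.

Each study contributes its template maps, spline-resampled onto one
user-chosen common montage and weighted by the study's subject count w.
The modified k-means of microstate analysis clusters these maps ignoring
polarity: item i is assigned to the class whose map t_k maximises the
squared correlation (x_i . t_k)^2, and each class map is updated to the
dominant eigenvector of the weighted outer-product sum

    S_k = sum_{i in class k} w_i x_i x_i^T,

which maximises the class's weighted explained variance.  The objective is
the total weighted explained variance fraction

    sum_i w_i (x_i . t_{L_i})^2 / sum_i w_i   in [0, 1].

Because the objective surface is multimodal the algorithm is restarted
from multiple seeded initializations and the best restart kept.  Solutions
for a range of K (default 4..7, the usual microstate range) are aligned
class-by-class across K by optimal (Hungarian) matching on shared
variance, so class j of the K-solution corresponds to class j of the
K+1-solution wherever a good match exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .spline import OperatorCache, SplineConfig, resample_map
from .templates import Atlas, ElectrodeMontage, TemplateMap

__all__ = [
    "MetaClusterSolution",
    "MetaClusterRun",
    "prepare_items",
    "modified_kmeans",
    "run_range",
    "align_solutions",
    "solution_from_maps",
]

DEFAULT_RESTARTS = 50
CONVERGENCE_TOL = 1e-9
MAX_ITER = 500


@dataclass
class MetaClusterSolution:
    """One K-class meta-microstate solution on a common montage.

    ``maps`` is (K, n_channels), each row canonical (zero-mean, unit norm,
    sign fixed so the largest-magnitude element is positive).
    ``assignments`` gives each input item's class index (0-based);
    ``objective`` is the weighted explained-variance fraction.
    """

    K: int
    montage: ElectrodeMontage
    maps: np.ndarray
    assignments: np.ndarray
    objective: float
    item_index: list[tuple[str, str]] = field(default_factory=list)
    seed: int | None = None
    restarts: int = 0
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.maps.shape != (self.K, self.montage.n_channels):
            raise ValidationError(
                f"maps shape {self.maps.shape} != (K={self.K}, "
                f"n_channels={self.montage.n_channels})"
            )
        if self.assignments.size and (
            self.assignments.min() < 0 or self.assignments.max() >= self.K
        ):
            raise ValidationError("assignments out of range 0..K-1")

    @property
    def template_maps(self) -> list[TemplateMap]:
        """The meta-maps as TemplateMap objects labeled "1".."K"."""
        return [
            TemplateMap(label=str(k + 1), values=self.maps[k], montage=self.montage)
            for k in range(self.K)
        ]

    def permuted(self, order: Sequence[int]) -> "MetaClusterSolution":
        """The same solution with classes reordered by ``order`` (new k = order[k])."""
        order = list(order)
        if sorted(order) != list(range(self.K)):
            raise ValidationError(f"invalid class permutation {order}")
        inverse = np.empty(self.K, dtype=int)
        inverse[np.asarray(order)] = np.arange(self.K)
        return MetaClusterSolution(
            K=self.K,
            montage=self.montage,
            maps=self.maps[np.asarray(order)],
            assignments=inverse[self.assignments] if self.assignments.size else self.assignments,
            objective=self.objective,
            item_index=self.item_index,
            seed=self.seed,
            restarts=self.restarts,
            n_iterations=self.n_iterations,
        )


@dataclass
class MetaClusterRun:
    """Solutions for a range of K, aligned class-by-class across K."""

    solutions: dict[int, MetaClusterSolution]
    alignment: dict[int, list[int]] = field(default_factory=dict)

    @property
    def k_values(self) -> list[int]:
        return sorted(self.solutions)


def solution_from_maps(
    maps: Sequence[TemplateMap] | np.ndarray,
    montage: ElectrodeMontage,
) -> MetaClusterSolution:
    """Wrap a fixed set of canonical maps as a solution (e.g. for backfitting)."""
    if isinstance(maps, np.ndarray):
        arr = np.asarray(maps, dtype=float)
    else:
        arr = np.stack([m.values for m in maps])
    return MetaClusterSolution(
        K=arr.shape[0],
        montage=montage,
        maps=arr,
        assignments=np.zeros(0, dtype=int),
        objective=float("nan"),
    )


def prepare_items(
    atlas: Atlas | Sequence,
    common_montage: ElectrodeMontage,
    spline_config: SplineConfig = SplineConfig(),
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Resample every study map to the common montage and collect weights.

    Returns (items, weights, index): items is (n_maps, n_channels) of
    canonical maps, weights[i] is the owning study's n_subjects, and index
    lists (study_id, map_label) in item order.
    """
    studies = list(atlas)
    cache = OperatorCache(spline_config)
    rows: list[np.ndarray] = []
    weights: list[float] = []
    index: list[tuple[str, str]] = []
    for study in studies:
        for m in study.maps:
            if m.montage == common_montage:
                resampled = m
            else:
                resampled = resample_map(m, cache.get(m.montage, common_montage))
            rows.append(resampled.values)
            weights.append(float(study.n_subjects))
            index.append((study.study_id, m.label))
    if not rows:
        raise ValidationError("no maps to cluster")
    return np.stack(rows), np.asarray(weights), index


def _canonical_sign(vec: np.ndarray) -> np.ndarray:
    """Fix polarity so the largest-magnitude element is positive."""
    peak = int(np.argmax(np.abs(vec)))
    return -vec if vec[peak] < 0 else vec


def _dominant_map(X_k: np.ndarray, w_k: np.ndarray) -> np.ndarray:
    """Dominant eigenvector (unit norm, sign-fixed) of S_k = sum w x x^T."""
    S = (X_k * w_k[:, None]).T @ X_k
    S = (S + S.T) / 2.0
    eigval, eigvec = np.linalg.eigh(S)
    t = eigvec[:, -1]
    t = t - t.mean()  # items are zero-mean, so S's range is too; guard rounding
    t /= np.linalg.norm(t)
    return _canonical_sign(t)


def modified_kmeans(
    items: np.ndarray,
    weights: np.ndarray | None,
    K: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
    tol: float = CONVERGENCE_TOL,
    max_iter: int = MAX_ITER,
    item_index: list[tuple[str, str]] | None = None,
    montage: ElectrodeMontage | None = None,
) -> MetaClusterSolution:
    """Weighted, polarity-invariant modified k-means over canonical maps.

    Each restart initializes the K class maps as K distinct items drawn
    without replacement, then alternates polarity-invariant assignment
    (argmax of squared correlation, ties to the lowest class index) with
    the dominant-eigenvector map update until assignments stabilize, the
    relative objective change drops below ``tol``, or ``max_iter`` is hit.
    An emptied class is reseeded with the currently worst-fit item.  The
    restart with the highest objective wins.
    """
    X = np.asarray(items, dtype=float)
    n, n_ch = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValidationError(f"weights shape {w.shape} != ({n},)")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    if K < 1 or K > n:
        raise ValidationError(f"K={K} must be in 1..{n} (number of items)")
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")

    rng = np.random.default_rng(seed)
    w_total = float(w.sum())
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None

    for _ in range(restarts):
        init = rng.choice(n, size=K, replace=False)
        T = X[init].copy()
        prev_L = None
        prev_obj = -np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            corr = X @ T.T  # (n, K)
            fit = corr * corr
            L = np.argmax(fit, axis=1)  # ties -> lowest k
            # reseed any emptied class with the worst-fit item
            for k in range(K):
                if not np.any(L == k):
                    worst = int(np.argmin(fit[np.arange(n), L]))
                    L[worst] = k
                    T[k] = X[worst]
            for k in range(K):
                members = L == k
                T[k] = _dominant_map(X[members], w[members])
            corr = X @ T.T
            obj = float(np.sum(w * corr[np.arange(n), L] ** 2) / w_total)
            if prev_L is not None and np.array_equal(L, prev_L):
                break
            if obj - prev_obj < tol * max(abs(obj), 1.0) and prev_L is not None:
                break
            prev_L, prev_obj = L.copy(), obj
        if best is None or obj > best[0]:
            best = (obj, T.copy(), L.copy(), n_iter)

    obj, T, L, n_iter = best
    if montage is None:
        montage = _array_montage(n_ch)
    return MetaClusterSolution(
        K=K,
        montage=montage,
        maps=T,
        assignments=L,
        objective=obj,
        item_index=item_index or [],
        seed=seed,
        restarts=restarts,
        n_iterations=n_iter,
    )


def _array_montage(n_channels: int) -> ElectrodeMontage:
    """Placeholder montage when clustering plain arrays (tests, oracles)."""
    from .synthetic import make_montage

    return make_montage(n_channels, seed=0)


def run_range(
    atlas: Atlas | Sequence,
    common_montage: ElectrodeMontage,
    k_min: int = 4,
    k_max: int = 7,
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
    spline_config: SplineConfig = SplineConfig(),
    reference_maps: Sequence[TemplateMap] | None = None,
) -> MetaClusterRun:
    """Cluster an atlas for each K in [k_min, k_max] and align the solutions.

    Each K gets an independent substream of the run seed, so adding or
    removing K values does not perturb the other solutions.
    """
    if k_min < 1 or k_max < k_min:
        raise ValidationError(f"invalid K range {k_min}..{k_max}")
    X, w, index = prepare_items(atlas, common_montage, spline_config)
    if k_max > X.shape[0]:
        raise ValidationError(f"k_max={k_max} exceeds item count {X.shape[0]}")
    seq = np.random.SeedSequence(seed)
    child_seeds = seq.spawn(k_max - k_min + 1)
    solutions: dict[int, MetaClusterSolution] = {}
    for K, child in zip(range(k_min, k_max + 1), child_seeds):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sol = modified_kmeans(
            X, w, K, restarts=restarts, seed=sub_seed,
            item_index=index, montage=common_montage,
        )
        sol.seed = seed
        solutions[K] = sol
    run = MetaClusterRun(solutions=solutions)
    return align_solutions(run, reference_maps=reference_maps)


def save_run(run: MetaClusterRun, path) -> None:
    """Write a clustering run (all K solutions + alignment) as JSON."""
    import json
    from pathlib import Path

    def sol_doc(sol: MetaClusterSolution) -> dict:
        return {
            "K": sol.K,
            "montage": {
                "labels": list(sol.montage.labels),
                "positions": sol.montage.positions.tolist(),
            },
            "maps": sol.maps.tolist(),
            "assignments": sol.assignments.tolist(),
            "objective": sol.objective,
            "item_index": [list(p) for p in sol.item_index],
            "seed": sol.seed,
            "restarts": sol.restarts,
            "n_iterations": sol.n_iterations,
        }

    doc = {
        "solutions": {str(k): sol_doc(s) for k, s in run.solutions.items()},
        "alignment": {str(k): [int(i) for i in v] for k, v in run.alignment.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_run(path) -> MetaClusterRun:
    """Read a clustering run written by :func:`save_run`."""
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    solutions: dict[int, MetaClusterSolution] = {}
    for k_str, s in doc["solutions"].items():
        montage = ElectrodeMontage(
            labels=tuple(s["montage"]["labels"]),
            positions=np.asarray(s["montage"]["positions"], dtype=float),
        )
        solutions[int(k_str)] = MetaClusterSolution(
            K=int(s["K"]),
            montage=montage,
            maps=np.asarray(s["maps"], dtype=float),
            assignments=np.asarray(s["assignments"], dtype=int),
            objective=float(s["objective"]),
            item_index=[tuple(p) for p in s.get("item_index", [])],
            seed=s.get("seed"),
            restarts=int(s.get("restarts", 0)),
            n_iterations=int(s.get("n_iterations", 0)),
        )
    alignment = {int(k): list(v) for k, v in doc.get("alignment", {}).items()}
    return MetaClusterRun(solutions=solutions, alignment=alignment)


def _sv_table(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise shared variance (percent) between rows of A and rows of B."""
    corr = A @ B.T
    return 100.0 * corr * corr


def align_solutions(
    run: MetaClusterRun,
    reference_maps: Sequence[TemplateMap] | None = None,
    overrides: dict[int, Sequence[int]] | None = None,
) -> MetaClusterRun:
    """Order classes consistently across K.

    The smallest-K solution is ordered against ``reference_maps`` by
    optimal shared-variance matching if given, else by descending total
    assigned weight (most prevalent class first; weight 1 per item when
    the solution has no stored items).  Each subsequent solution is then
    reordered by maximum-total-SV one-to-one matching against the previous
    (already ordered) solution, with unmatched (new) classes appended last.
    Explicit permutations in ``overrides`` (K -> new order) win over the
    automatic ordering and are recorded in ``run.alignment``.
    """
    ks = run.k_values
    if not ks:
        raise ValidationError("empty run")
    overrides = overrides or {}
    alignment: dict[int, list[int]] = {}

    base = run.solutions[ks[0]]
    if ks[0] in overrides:
        order = list(overrides[ks[0]])
    elif reference_maps is not None:
        ref = np.stack([m.values for m in reference_maps])
        sv = _sv_table(ref, base.maps)  # (n_ref, K)
        rows, cols = linear_sum_assignment(-sv)
        matched = [int(c) for c in cols[np.argsort(rows)]]
        order = matched + [k for k in range(base.K) if k not in matched]
    else:
        if base.assignments.size:
            wt = np.bincount(base.assignments, minlength=base.K).astype(float)
        else:
            wt = np.zeros(base.K)
        order = [int(k) for k in np.argsort(-wt, kind="stable")]
    run.solutions[ks[0]] = base.permuted(order)
    alignment[ks[0]] = order

    for k_prev, k_next in zip(ks, ks[1:]):
        prev = run.solutions[k_prev]
        nxt = run.solutions[k_next]
        if k_next in overrides:
            order = list(overrides[k_next])
        else:
            sv = _sv_table(prev.maps, nxt.maps)  # (K_prev, K_next)
            rows, cols = linear_sum_assignment(-sv)
            matched = [int(c) for c in cols[np.argsort(rows)]]
            order = matched + [k for k in range(nxt.K) if k not in matched]
        run.solutions[k_next] = nxt.permuted(order)
        alignment[k_next] = order

    run.alignment = alignment
    return run
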