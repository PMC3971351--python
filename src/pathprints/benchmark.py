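"""Fingerprint quality benchmarks: cross-validation, cluster validity, retrieval.

These are the measures used to choose the ternary threshold: nearest-mean
tissue classification error under repeated stratified k-fold CV, the ratio
of intra- to inter-class variance of the fingerprint vectors, and ranked
retrieval summarized by interpolated precision-recall curves and mean
average precision (MAP). A random-gene-set comparator (same size
distribution, membership drawn from the pooled gene universe) provides the
null ordering for the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .background import EMConfig
from .fingerprint import ternarize
from .genesets import GeneSetCollection, random_genesets
from .pipeline import compute_poe
from .scoring import DEFAULT_MIN_GENES, ExpressionMatrix

__all__ = [
    "CVResult",
    "PRResult",
    "nearest_centroid_cv",
    "cluster_validity",
    "retrieval_pr",
    "threshold_sweep",
    "threshold_sweep_from_expression",
]


def _as_arrays(prints: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(prints.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    return prints.to_numpy(dtype=float).T, labels.to_numpy()  # samples x pathways


def _dist_to_centroids(x: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    diff = x[:, None, :] - centroids[None, :, :]
    if metric == "manhattan":
        return np.abs(diff).sum(axis=2)
    if metric == "euclidean":
        return np.sqrt((diff**2).sum(axis=2))
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class CVResult:
    mean_error: float
    sd_error: float
    per_repeat: list[float]
    scheme: str  # "stratified-kfold" or "leave-one-out"


def nearest_centroid_cv(
    prints: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    repeats: int = 10,
    metric: str = "euclidean",
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV with nearest class-mean assignment.

    Each held-out sample is assigned to the class whose mean training
    fingerprint is closest; the error rate is the misassignment fraction.
    Falls back to leave-one-out when any class has fewer members than k.
    """
    x, y = _as_arrays(prints, labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("cross-validation needs at least 2 classes")

    def _fold_error(train: np.ndarray, test: np.ndarray) -> tuple[int, int]:
        cents = np.vstack([x[train][y[train] == c].mean(axis=0) for c in classes])
        pred = classes[np.argmin(_dist_to_centroids(x[test], cents, metric), axis=1)]
        return int((pred != y[test]).sum()), len(test)

    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        # leave-one-out: deterministic, a single pass
        errs = 0
        for i in range(len(y)):
            train = np.delete(np.arange(len(y)), i)
            if np.unique(y[train]).size < classes.size:
                continue  # a singleton class cannot be its own training data
            e, _ = _fold_error(train, np.array([i]))
            errs += e
        rate = errs / len(y)
        return CVResult(rate, 0.0, [rate], "leave-one-out")

    rng = np.random.default_rng(seed)
    per_repeat = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
        errs = total = 0
        for train, test in skf.split(x, y):
            e, n = _fold_error(train, test)
            errs += e
            total += n
        per_repeat.append(errs / total)
    arr = np.array(per_repeat)
    return CVResult(float(arr.mean()), float(arr.std(ddof=1)) if repeats > 1 else 0.0,
                    per_repeat, "stratified-kfold")


def cluster_validity(prints: pd.DataFrame, labels: pd.Series) -> float:
    """Intra/inter class variance ratio of fingerprint vectors (lower = tighter).

    Intra: summed squared Euclidean distance of each sample to its own class
    mean (singleton classes excluded, with a warning). Inter: summed over
    samples of the mean squared Euclidean distance to the other classes'
    means. Returns +inf when the inter term vanishes.
    """
    x, y = _as_arrays(prints, labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("cluster validity needs at least 2 classes")
    means = {c: x[y == c].mean(axis=0) for c in classes}
    singletons = {c for c in classes if (y == c).sum() < 2}
    if singletons:
        warnings.warn(f"classes with a single member excluded from intra term: {sorted(singletons)}")
    intra = sum(
        float(((x[y == c] - means[c]) ** 2).sum()) for c in classes if c not in singletons
    )
    inter = 0.0
    for i in range(len(y)):
        others = [c for c in classes if c != y[i]]
        inter += float(np.mean([((x[i] - means[c]) ** 2).sum() for c in others]))
    if inter == 0.0:
        return float("inf")
    return intra / inter


@dataclass
class PRResult:
    map: float
    ap_per_query: pd.Series  # indexed by sample id
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)  # class -> (recall, precision)


def _average_precision(relevant_in_rank_order: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Interpolated AP for one ranked query.

    Returns (AP, recall points, interpolated precision at those points) where
    interpolated precision at recall r is the max precision at recall >= r.
    """
    rel = relevant_in_rank_order.astype(bool)
    n_rel = int(rel.sum())
    ranks = np.arange(1, rel.size + 1)
    precision = np.cumsum(rel) / ranks
    interp = np.maximum.accumulate(precision[::-1])[::-1]
    at_rel = interp[rel]
    recall_pts = np.arange(1, n_rel + 1) / n_rel
    return float(at_rel.mean()), recall_pts, at_rel


def retrieval_pr(
    prints: pd.DataFrame,
    labels: pd.Series,
    metric: str = "manhattan",
    recall_grid: np.ndarray | None = None,
) -> PRResult:
    """Per-class interpolated precision-recall curves and MAP.

    Every sample queries the rest of the corpus, ranked by fingerprint
    distance (ties broken by sample id); its true matches are the samples
    sharing its label. AP averages interpolated precision at each true
    match's recall point; MAP averages AP over all queries. Per-class curves
    average each query's interpolated precision on a common recall grid.
    """
    if recall_grid is None:
        recall_grid = np.linspace(0.0, 1.0, 101)
    x, y = _as_arrays(prints, labels)
    samples = np.array(prints.columns)
    order_by_name = np.argsort(samples, kind="mergesort")
    name_rank = np.empty(len(samples), dtype=int)
    name_rank[order_by_name] = np.arange(len(samples))

    if metric == "manhattan":
        dmat = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    elif metric == "euclidean":
        dmat = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")

    aps: dict[str, float] = {}
    class_curves: dict[str, list[np.ndarray]] = {}
    for i in range(len(samples)):
        mask = np.ones(len(samples), dtype=bool)
        mask[i] = False
        rel_all = (y == y[i]) & mask
        if not rel_all.any():
            warnings.warn(f"query {samples[i]!r} skipped: no other sample shares its class")
            continue
        idx = np.where(mask)[0]
        order = idx[np.lexsort((name_rank[idx], dmat[i, idx]))]
        ap, recall_pts, interp = _average_precision((y[order] == y[i]))
        aps[samples[i]] = ap
        # step-function interpolated precision on the common grid
        grid_prec = np.zeros_like(recall_grid)
        pos = np.searchsorted(recall_pts, recall_grid, side="left")
        valid = pos < len(recall_pts)
        grid_prec[valid] = interp[pos[valid]]
        grid_prec[~valid] = 0.0
        grid_prec[recall_grid == 0.0] = interp[0]
        class_curves.setdefault(y[i], []).append(grid_prec)

    if not aps:
        raise ValueError("no valid retrieval queries (all classes are singletons)")
    curves = {
        c: pd.DataFrame({"recall": recall_grid, "precision": np.mean(v, axis=0)})
        for c, v in class_curves.items()
    }
    ap_series = pd.Series(aps)
    return PRResult(map=float(ap_series.mean()), ap_per_query=ap_series, curves=curves)


def threshold_sweep(
    poe: pd.DataFrame,
    labels: pd.Series,
    thresholds: list[float],
    poe_random: pd.DataFrame | None = None,
    k: int = 5,
    repeats: int = 10,
    metric: str = "manhattan",
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate CV error, cluster validity, and MAP at each ternary threshold.

    All metrics are computed from the same POE matrix, re-thresholded per
    value; when ``poe_random`` (the random-gene-set comparator pipeline
    output) is given, its MAP is reported alongside for the null ordering.
    """
    rows = []
    for t in thresholds:
        prints = ternarize(poe, threshold=t)
        cv = nearest_centroid_cv(prints, labels, k=k, repeats=repeats, metric="euclidean", seed=seed)
        row = {
            "threshold": t,
            "cv_error": cv.mean_error,
            "cv_sd": cv.sd_error,
            "validity_ratio": cluster_validity(prints, labels),
            "map": retrieval_pr(prints, labels, metric=metric).map,
        }
        if poe_random is not None:
            row["map_random"] = retrieval_pr(
                ternarize(poe_random, threshold=t), labels, metric=metric
            ).map
        rows.append(row)
    return pd.DataFrame(rows)


def threshold_sweep_from_expression(
    em: ExpressionMatrix,
    background_em: ExpressionMatrix,
    col: GeneSetCollection,
    labels: pd.Series,
    thresholds: list[float],
    seed: int = 0,
    min_genes: int = DEFAULT_MIN_GENES,
    em_config: EMConfig = EMConfig(),
    **kwargs,
) -> pd.DataFrame:
    """Threshold sweep from expression, building the random-gene-set comparator.

    The comparator re-runs the entire pipeline (scoring, background fit, POE)
    on gene sets randomized with the run seed, so both arms see identical
    expression data and identical processing.
    """
    poe, _ = compute_poe(em, background_em, col, min_genes=min_genes, em_config=em_config)
    rand_col = random_genesets(col, seed=seed)
    poe_rand, _ = compute_poe(em, background_em, rand_col, min_genes=min_genes, em_config=em_config)
    return threshold_sweep(poe, labels, thresholds, poe_random=poe_rand, seed=seed, **kwargs)
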