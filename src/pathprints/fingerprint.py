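"""Ternary pathway fingerprints: thresholding, consensus, distance, retrieval.

A fingerprint (pathprint) is a vector over the pathway collection with
entries in {-1, 0, +1}: significantly under-expressed, intermediate, or
over-expressed relative to the platform background. Throughout this module a
single fingerprint is a pandas Series indexed by pathway name and a
fingerprint matrix is a pathways-by-samples DataFrame of ints.

The ternary transform of signed POE values uses inclusive boundaries

    F = +1  if  POE >=  T,    F = -1  if  POE <= -T,    F = 0 otherwise,

with default threshold T = 0.001 (a deliberately low stringency: subtle but
coordinated pathway-level shifts carry signal). The consensus of a group
uses strict inequalities on the mean ternary score:

    C = +1  if  mean > t,     C = -1  if  mean < -t,    C = 0 otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_CONSENSUS_T",
    "DistanceReport",
    "ternarize",
    "unmeasured_pathways",
    "consensus",
    "pathprint_distance",
    "consensus_distance",
    "distance_pvalue",
    "rank_corpus",
]

DEFAULT_THRESHOLD = 0.001
DEFAULT_CONSENSUS_T = 0.75

#: Phi^-1(0.75) * 2 -- the factor converting an IQR to a normal SD
_IQR_TO_SD = 2.0 * norm.ppf(0.75)  # 1.3489795...


@dataclass
class DistanceReport:
    """A normalized fingerprint distance and the coordinates it used."""

    distance: float
    n_compared: int
    p_value: float | None = None


def ternarize(
    poe: pd.DataFrame | pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = True,
) -> pd.DataFrame | pd.Series:
    """Convert signed POE values to ternary fingerprint scores.

    Boundaries are inclusive by default (POE == T maps to +1). Absent (NaN)
    POE values map to 0; use :func:`unmeasured_pathways` to recover which
    coordinates were unmeasured rather than genuinely intermediate.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("ternary threshold must lie in (0, 1)")
    vals = poe.to_numpy() if hasattr(poe, "to_numpy") else np.asarray(poe)
    vals = np.asarray(vals, dtype=float)
    if inclusive:
        out = np.where(vals >= threshold, 1, np.where(vals <= -threshold, -1, 0))
    else:
        out = np.where(vals > threshold, 1, np.where(vals < -threshold, -1, 0))
    out = np.where(np.isnan(vals), 0, out).astype(np.int64)
    if isinstance(poe, pd.Series):
        return pd.Series(out, index=poe.index)
    return pd.DataFrame(out, index=poe.index, columns=poe.columns)


def unmeasured_pathways(poe: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Boolean mask of coordinates with no POE (unscored pathway or no fit)."""
    return poe.isna()


def consensus(prints: pd.DataFrame, t: float = DEFAULT_CONSENSUS_T) -> pd.Series:
    """Consensus fingerprint of a group: mean ternary score thresholded at +/-t.

    Strict inequalities: a pathway enters the consensus only when its mean
    score strictly exceeds t in magnitude, i.e. it is consistently called in
    the same direction across the group.
    """
    if prints.shape[1] < 1:
        raise ValueError("consensus requires at least one fingerprint")
    if not 0.0 < t <= 1.0:
        raise ValueError("consensus threshold must lie in (0, 1]")
    mu = prints.mean(axis=1)
    return pd.Series(
        np.where(mu > t, 1, np.where(mu < -t, -1, 0)).astype(np.int64), index=prints.index
    )


def _check_aligned(a: pd.Series, b: pd.Series) -> None:
    if len(a) != len(b) or not a.index.equals(b.index):
        raise ValueError("fingerprints are not indexed by the same pathways")


def pathprint_distance(
    a: pd.Series, b: pd.Series, metric: str = "manhattan"
) -> DistanceReport:
    """Normalized distance between two ternary fingerprints, in [0, 1].

    Manhattan (default, the contractual metric): sum |a_i - b_i| / (2N), i.e.
    0 when every pathway score matches and 1 when every score is maximally
    mismatched (+1 vs -1). Euclidean is offered for benchmarking and is
    normalized by its own maximum, sqrt(4N).
    """
    _check_aligned(a, b)
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    n = len(av)
    if metric == "manhattan":
        d = float(np.abs(av - bv).sum() / (2 * n))
    elif metric == "euclidean":
        d = float(np.sqrt(((av - bv) ** 2).sum() / (4 * n)))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceReport(distance=d, n_compared=n)


def consensus_distance(
    c: pd.Series, v: pd.Series, metric: str = "manhattan"
) -> DistanceReport:
    """Distance from a consensus fingerprint, restricted to its non-zero pathways.

    Only the pathways the consensus actually calls (+1 or -1) are compared,
    so disagreement is measured on the consistently expressed functions that
    define the group, not on its uninformative coordinates.
    """
    _check_aligned(c, v)
    mask = c != 0
    n = int(mask.sum())
    if n == 0:
        raise ValueError("consensus has no informative (non-zero) pathways")
    rep = pathprint_distance(c[mask], v[mask], metric=metric)
    return DistanceReport(distance=rep.distance, n_compared=n)


def distance_pvalue(distances: np.ndarray | pd.Series) -> np.ndarray:
    """Lower-tail match significance for distances from one consensus.

    Assumes the corpus is dominated by non-matching samples whose distances
    are normally distributed; that null is estimated robustly as
    N(median, (IQR/1.349)^2) so the small matched population does not
    contaminate it. Small distances give small p-values.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 20:
        raise ValueError("need at least 20 corpus distances to estimate the null")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError("distance distribution has zero IQR; null is degenerate")
    s = iqr / _IQR_TO_SD
    return norm.cdf((d - med) / s)


def rank_corpus(
    c: pd.Series,
    corpus: pd.DataFrame,
    metric: str = "manhattan",
    with_pvalues: bool = True,
) -> pd.DataFrame:
    """Rank every corpus sample by consensus distance (ascending).

    Returns a DataFrame with columns (sample, distance, p_value), sorted by
    distance with ties broken by sample id for determinism. p-values come
    from :func:`distance_pvalue` when the corpus is large enough, else NaN.
    """
    if corpus.shape[1] == 0:
        raise ValueError("empty corpus")
    dists = np.array(
        [consensus_distance(c, corpus[s], metric=metric).distance for s in corpus.columns]
    )
    pvals = np.full(dists.shape, np.nan)
    if with_pvalues:
        try:
            pvals = distance_pvalue(dists)
        except ValueError as exc:
            warnings.warn(f"no retrieval p-values: {exc}")
    table = pd.DataFrame(
        {"sample": list(corpus.columns), "distance": dists, "p_value": pvals}
    )
    return table.sort_values(["distance", "sample"], kind="mergesort").reset_index(drop=True)
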