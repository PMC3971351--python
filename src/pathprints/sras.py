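"""Stem-cell signature extraction and survival stratification.

A self renewal-associated signature (SRAS) is the set of pathways whose
consensus fingerprint agrees between leukemic and normal stem cells but
differs in committed progenitors, intersected across species (signs must
match). Patients are scored by the sum of their ternary fingerprint values
over the signature pathways, split into high/low groups by exact 1-D
2-means, and compared by the Kaplan-Meier log-rank test; significance of the
observed signature is judged against a background of p-values from random
same-size pathway sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .fingerprint import DEFAULT_CONSENSUS_T, consensus

__all__ = [
    "Signature",
    "GROUPS",
    "differential_signature",
    "intersect_signatures",
    "sras_score",
    "stratify_two_groups",
    "LogrankResult",
    "logrank_test",
    "kaplan_meier_curves",
    "PermutationResult",
    "permutation_background",
    "read_survival_table",
    "write_signature",
    "read_signature",
]

GROUPS = ("leukemic_stem", "normal_stem", "progenitor")


@dataclass
class Signature:
    """An ordered list of pathways with their expected activation direction."""

    pathways: list[str]
    signs: list[int]

    def __post_init__(self) -> None:
        if len(self.pathways) != len(self.signs):
            raise ValueError("pathways and signs must have equal length")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signature signs must be -1 or +1")
        if len(set(self.pathways)) != len(self.pathways):
            raise ValueError("duplicate pathways in signature")

    def __len__(self) -> int:
        return len(self.pathways)

    def as_series(self) -> pd.Series:
        return pd.Series(self.signs, index=self.pathways, dtype=int)


def differential_signature(
    prints: pd.DataFrame,
    groups: pd.Series,
    t_cons: float = DEFAULT_CONSENSUS_T,
) -> Signature:
    """Pathways consistently called in both stem groups but not in progenitors.

    A pathway enters with sign s when the leukemic-stem and normal-stem
    consensus both equal s != 0 and the progenitor consensus differs from s.
    Returns an empty signature (with a warning) when nothing qualifies.
    """
    groups = groups.reindex(prints.columns)
    missing = set(GROUPS) - set(groups.dropna().unique())
    if missing:
        raise ValueError(f"missing sample groups: {sorted(missing)}")
    cons = {g: consensus(prints.loc[:, groups == g], t=t_cons) for g in GROUPS}
    pathways, signs = [], []
    for p in prints.index:
        s = cons["leukemic_stem"][p]
        if s != 0 and cons["normal_stem"][p] == s and cons["progenitor"][p] != s:
            pathways.append(p)
            signs.append(int(s))
    if not pathways:
        warnings.warn("differential signature is empty at this consensus threshold")
    return Signature(pathways=pathways, signs=signs)


def intersect_signatures(a: Signature, b: Signature) -> Signature:
    """Pathways present in both signatures with the same sign; order from ``a``."""
    b_signs = dict(zip(b.pathways, b.signs))
    pathways, signs = [], []
    for p, s in zip(a.pathways, a.signs):
        if b_signs.get(p) == s:
            pathways.append(p)
            signs.append(s)
    return Signature(pathways=pathways, signs=signs)


def sras_score(
    prints: pd.DataFrame | pd.Series, sig: Signature, sign_weighted: bool = False
) -> pd.Series | int:
    """Sum of ternary fingerprint scores over the signature pathways.

    The contractual score is the plain (unsigned) sum; ``sign_weighted``
    multiplies each term by its expected direction first. For a single
    fingerprint (Series) an int is returned, for a matrix a per-sample Series.
    """
    index = prints.index
    missing = [p for p in sig.pathways if p not in index]
    if missing:
        raise ValueError(f"signature pathways absent from fingerprint: {missing[:5]}")
    sub = prints.loc[sig.pathways]
    if sign_weighted:
        w = np.array(sig.signs)
        sub = sub.mul(w, axis=0) if isinstance(sub, pd.DataFrame) else sub * w
    total = sub.sum(axis=0) if isinstance(sub, pd.DataFrame) else sub.sum()
    return total.astype(int) if isinstance(total, pd.Series) else int(total)


def stratify_two_groups(scores: pd.Series) -> pd.Series:
    """Exact 1-D 2-means split of signature scores into "high"/"low" groups.

    All n-1 sorted split points are scanned and the one minimizing the
    within-group sum of squares is taken (ties resolved to the smallest split
    index), removing any initialization nondeterminism; the group with the
    larger mean is labeled "high".
    """
    s = pd.Series(scores)
    vals = s.to_numpy(dtype=float)
    if np.unique(vals).size < 2:
        raise ValueError("all scores identical; cannot stratify into two groups")
    order = np.argsort(vals, kind="mergesort")
    x = vals[order]
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    ks = np.arange(1, n)
    left = csq[:-1] - csum[:-1] ** 2 / ks
    right = (csq[-1] - csq[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - ks)
    wss = left + right
    # exact ties broken toward the smallest split index; the tolerance keeps
    # that deterministic against accumulation noise in the running sums
    tol = 1e-9 * (1.0 + abs(float(wss.min())))
    k = int(np.flatnonzero(wss <= wss.min() + tol)[0]) + 1  # first index of the upper group
    labels = np.empty(n, dtype=object)
    labels[order[:k]] = "low"
    labels[order[k:]] = "high"
    return pd.Series(labels, index=s.index)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    n_high: int
    n_low: int


def logrank_test(groups: pd.Series, surv: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank test of the survival table split by ``groups``.

    ``surv`` has columns (sample_id, time, event); ``groups`` maps sample_id
    to "high"/"low". The statistic is the standard (O-E)^2/V chi-square with
    one degree of freedom, computed by lifelines.
    """
    surv = validate_survival_table(surv)
    g = groups.reindex(surv["sample_id"]).to_numpy()
    if pd.isna(g).any():
        raise ValueError("group assignment missing for some survival samples")
    hi = g == "high"
    lo = g == "low"
    if not hi.any() or not lo.any():
        raise ValueError("both groups must be non-empty")
    if surv["event"].sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    res = _lifelines_logrank(
        surv.loc[hi, "time"],
        surv.loc[lo, "time"],
        event_observed_A=surv.loc[hi, "event"],
        event_observed_B=surv.loc[lo, "event"],
    )
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_high=int(hi.sum()),
        n_low=int(lo.sum()),
    )


def kaplan_meier_curves(groups: pd.Series, surv: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier survival curves per group, long-form (group, time, survival)."""
    surv = validate_survival_table(surv)
    g = groups.reindex(surv["sample_id"]).to_numpy()
    frames = []
    for name in ("high", "low"):
        mask = g == name
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask, "time"], surv.loc[mask, "event"], label=name)
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"group": name, "time": sf.index.to_numpy(), "survival": sf[name].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class PermutationResult:
    """Background p-value distribution from random same-size pathway sets."""

    p_values: np.ndarray
    n_skipped: int
    observed_p: float | None = None

    @property
    def observed_percentile(self) -> float | None:
        """Fraction of background p-values strictly below the observed one."""
        if self.observed_p is None:
            return None
        return float(np.mean(self.p_values < self.observed_p))


def permutation_background(
    prints: pd.DataFrame,
    surv: pd.DataFrame,
    sig_size: int,
    n_perm: int = 1000,
    seed: int = 0,
    observed_p: float | None = None,
) -> PermutationResult:
    """Log-rank p-value background from random pathway sets of the SRAS size.

    Each permutation draws ``sig_size`` pathways uniformly without
    replacement, scores every patient by the ternary sum, stratifies by exact
    2-means, and records the log-rank p-value. Permutations whose
    stratification or test degenerates (constant scores, empty group, no
    events) are skipped and counted.
    """
    if sig_size > prints.shape[0]:
        raise ValueError("sig_size exceeds the number of pathways")
    rng = np.random.default_rng(seed)
    pathway_names = list(prints.index)
    pvals = []
    skipped = 0
    for _ in range(n_perm):
        chosen = rng.choice(pathway_names, size=sig_size, replace=False)
        sig = Signature(pathways=list(chosen), signs=[1] * sig_size)
        try:
            scores = sras_score(prints, sig)
            groups = stratify_two_groups(scores)
            pvals.append(logrank_test(groups, surv).p_value)
        except ValueError:
            skipped += 1
    return PermutationResult(
        p_values=np.array(pvals), n_skipped=skipped, observed_p=observed_p
    )


# --- I/O -------------------------------------------------------------------

def validate_survival_table(surv: pd.DataFrame) -> pd.DataFrame:
    need = {"sample_id", "time", "event"}
    if not need.issubset(surv.columns):
        raise ValueError(f"survival table needs columns {sorted(need)}")
    if (surv["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicators must be 0 or 1")
    return surv


def read_survival_table(path: str | Path) -> pd.DataFrame:
    return validate_survival_table(pd.read_csv(path, sep="\t", comment="#"))


def write_signature(sig: Signature, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p, s in zip(sig.pathways, sig.signs):
            fh.write(f"{p}\t{s:+d}\n")


def read_signature(path: str | Path) -> Signature:
    df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "sign"], comment="#")
    return Signature(pathways=df["pathway"].astype(str).tolist(), signs=df["sign"].astype(int).tolist())
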