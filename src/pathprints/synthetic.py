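"""Synthetic multi-platform, multi-species corpora with known ground truth.

The generator emulates the situation the fingerprinting method is built for:
several array platforms measuring overlapping but non-identical gene panels
on different monotone intensity scales, tissue classes defined by coordinated
up/down activation of many pathways, heterogeneous background corpora whose
per-pathway score distributions have a genuine outlier component, planted
lineage trees over ternary characters, and survival times whose hazard is
tied to a planted signature score.

Expression is built on a latent quantile scale: every gene in every sample
draws a uniform rank quantile u, and an activated pathway compresses its
member genes' quantiles toward the top (direction +1) or bottom (-1) of the
within-sample ranking by the design's effect size. A per-platform strictly
monotone transform plus per-gene platform offsets then map quantiles to
intensities: the monotone part must be invisible to rank-based scoring, and
the per-platform background fit must absorb the offsets -- precisely the
claims the pipeline is supposed to satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .genesets import GeneSet, GeneSetCollection, HomologyMap, map_collection
from .phylo import CharacterMatrix, Tree
from .scoring import ExpressionMatrix

__all__ = ["CorpusDesign", "SyntheticCorpus", "make_corpus", "make_lineage", "make_survival"]

# strictly monotone per-platform intensity scales, cycled over platforms
_PLATFORM_TRANSFORMS: list[Callable[[np.ndarray], np.ndarray]] = [
    lambda x: x,
    lambda x: np.exp(x / 2.0),
    lambda x: 3.0 * x + 7.0,
    lambda x: x**3 + x,
]


@dataclass(frozen=True)
class CorpusDesign:
    """Study conditions for a synthetic corpus.

    Classes are +/-1 activation patterns over a shared subset of
    ``n_informative`` pathways: at the default low ternary threshold the
    fingerprint is sensitive to many coordinated calls, so class identity is
    carried (as in real tissue contrasts) by a broad pattern rather than a
    single pathway. ``effect_size`` is on the rank-quantile scale: 0.9 forces
    an up-activated gene's quantile into the top tenth of the sample.
    """

    n_platforms: int = 2
    genes_per_platform: int = 2500
    platform_gene_overlap: float = 0.8  # fraction of each platform's genes from the shared core
    n_pathways: int = 50
    pathway_size: tuple[int, int] = (10, 20)
    n_classes: int = 4
    n_informative: int = 30
    effect_size: float = 0.9
    n_samples: int = 10  # per class per platform
    n_background: int = 60  # per platform
    background_outlier_fraction: float = 0.3
    outlier_pathways: int = 10  # random activations per background outlier sample
    species: tuple[str, ...] = ("human", "mouse")
    homology_fraction: float = 0.9
    gene_offset_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.platform_gene_overlap, self.homology_fraction,
                     self.background_outlier_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.effect_size < 0 or self.effect_size >= 1:
            raise ValueError("effect_size must lie in [0, 1)")
        if self.n_informative > self.n_pathways:
            raise ValueError("n_informative cannot exceed n_pathways")


@dataclass
class SyntheticCorpus:
    """Everything the pipeline consumes, plus the planted truth."""

    design: CorpusDesign
    collections: dict[str, GeneSetCollection]  # species -> collection
    homology: dict[str, HomologyMap]  # target species -> map from primary
    expression: dict[str, ExpressionMatrix]  # platform -> class samples
    background: dict[str, ExpressionMatrix]  # platform -> background samples
    labels: pd.Series  # sample id -> class name
    sample_meta: pd.DataFrame  # sample id -> (platform, species, label)
    class_patterns: pd.DataFrame  # informative pathways x classes, entries +/-1
    platform_species: dict[str, str]


def _compress_quantiles(u: np.ndarray, direction: int, effect: float) -> np.ndarray:
    """Shift uniform quantiles toward 1 (direction +1) or 0 (-1) by ``effect``."""
    if direction > 0:
        return u * (1.0 - effect) + effect
    return u * (1.0 - effect)


def make_corpus(design: CorpusDesign) -> SyntheticCorpus:
    """Generate a complete corpus; a pure function of the design (incl. seed)."""
    d = design
    rng = np.random.default_rng(d.seed)
    n_core = int(d.genes_per_platform * d.platform_gene_overlap)
    if d.pathway_size[1] > n_core:
        raise ValueError("pathway sizes exceed the shared gene core")

    core = [f"G{i:05d}" for i in range(n_core)]
    pathway_names = [f"PW{i:03d}" for i in range(d.n_pathways)]
    sets = []
    for name in pathway_names:
        size = int(rng.integers(d.pathway_size[0], d.pathway_size[1] + 1))
        members = rng.choice(core, size=size, replace=False)
        sets.append(GeneSet(name=name, source="synthetic", members=frozenset(members)))
    primary = d.species[0]
    collections = {primary: GeneSetCollection(sets=sets, species=primary, version="synthetic")}

    homology: dict[str, HomologyMap] = {}
    for sp in d.species[1:]:
        n_hom = int(round(d.homology_fraction * n_core))
        hom_genes = rng.choice(core, size=n_hom, replace=False)
        pairs = {g: f"{sp}:{g}" for g in sorted(hom_genes)}
        homology[sp] = HomologyMap(pairs=pairs, source_species=primary, target_species=sp)
        collections[sp] = map_collection(collections[primary], homology[sp])

    class_names = [f"class{i}" for i in range(d.n_classes)]
    informative = pathway_names[: d.n_informative]
    while True:
        pat = rng.choice([-1, 1], size=(d.n_informative, d.n_classes))
        if len({tuple(col) for col in pat.T}) == d.n_classes:
            break
    class_patterns = pd.DataFrame(pat, index=informative, columns=class_names)

    members_of = {s.name: s.members for s in sets}
    expression: dict[str, ExpressionMatrix] = {}
    background: dict[str, ExpressionMatrix] = {}
    platform_species: dict[str, str] = {}
    label_rows = []

    for p in range(d.n_platforms):
        platform = f"PLAT{p}"
        sp = d.species[p % len(d.species)]
        platform_species[platform] = sp
        transform = _PLATFORM_TRANSFORMS[p % len(_PLATFORM_TRANSFORMS)]

        if sp == primary:
            local = dict(zip(core, core))  # base id -> platform-local id
        else:
            local = dict(homology[sp].pairs)
        measured_core = sorted(local.values())
        n_private = d.genes_per_platform - len(measured_core)
        private = [f"{sp}:PRIV{p}_{i:05d}" for i in range(max(n_private, 0))]
        gene_ids = measured_core + private
        base_of = {v: k for k, v in local.items()}  # local id -> base id
        row_of = {g: i for i, g in enumerate(gene_ids)}
        offsets = rng.normal(0.0, d.gene_offset_sd, size=len(gene_ids))

        # rows of member genes measured on this platform, per pathway
        member_rows = {
            name: np.array(
                [row_of[local[g]] for g in sorted(members_of[name]) if g in local],
                dtype=int,
            )
            for name in pathway_names
        }

        def _samples(n: int, activations: list[list[tuple[str, int]]], ids: list[str]):
            u = rng.uniform(size=(len(gene_ids), n))
            for j, acts in enumerate(activations):
                for name, direction in acts:
                    rows = member_rows[name]
                    if rows.size:
                        u[rows, j] = _compress_quantiles(u[rows, j], direction, d.effect_size)
            z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12)) + offsets[:, None]
            return pd.DataFrame(transform(z), index=gene_ids, columns=ids)

        # class samples: every informative pathway activated per the class pattern
        acts, ids = [], []
        for cname in class_names:
            pattern = [(nm, int(class_patterns.loc[nm, cname])) for nm in informative]
            for i in range(d.n_samples):
                sid = f"{platform}_{cname}_s{i}"
                ids.append(sid)
                acts.append(pattern)
                label_rows.append((sid, platform, sp, cname))
        expression[platform] = ExpressionMatrix(
            values=_samples(len(ids), acts, ids), platform=platform, species=sp
        )

        # background: mostly quiet samples plus heterogeneous "outliers"
        n_out = int(round(d.background_outlier_fraction * d.n_background))
        bacts, bids = [], []
        for i in range(d.n_background):
            bids.append(f"{platform}_bg{i}")
            if i < n_out and d.outlier_pathways > 0:
                chosen = rng.choice(pathway_names, size=d.outlier_pathways, replace=False)
                dirs = rng.choice([-1, 1], size=d.outlier_pathways)
                bacts.append(list(zip(chosen, (int(x) for x in dirs))))
            else:
                bacts.append([])
        background[platform] = ExpressionMatrix(
            values=_samples(d.n_background, bacts, bids), platform=platform, species=sp
        )

    meta = pd.DataFrame(label_rows, columns=["sample_id", "platform", "species", "label"])
    meta = meta.set_index("sample_id")
    return SyntheticCorpus(
        design=d,
        collections=collections,
        homology=homology,
        expression=expression,
        background=background,
        labels=meta["label"],
        sample_meta=meta,
        class_patterns=class_patterns,
        platform_species=platform_species,
    )


def make_lineage(
    tree: Tree, base: pd.Series, flips_per_edge: int, seed: int
) -> CharacterMatrix:
    """Evolve a ternary fingerprint down a tree; leaves become taxa.

    Each edge mutates ``flips_per_edge`` distinct randomly chosen characters
    by a +/-1 step; a step that clamping would turn into a no-op at a
    boundary state is applied in the opposite direction instead, so every
    requested flip changes state.
    """
    if flips_per_edge < 0:
        raise ValueError("flips_per_edge must be >= 0")
    if flips_per_edge > len(base):
        raise ValueError("flips_per_edge exceeds the number of characters")
    rng = np.random.default_rng(seed)
    internals = [n for n in sorted(tree.adj) if n not in tree.labels]
    root = internals[0] if internals else min(tree.adj)
    states: dict[int, np.ndarray] = {root: base.to_numpy(dtype=int).copy()}
    rows: dict[str, np.ndarray] = {}
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        if parent is not None:
            s = states[parent].copy()
            idx = rng.choice(len(base), size=flips_per_edge, replace=False)
            steps = rng.choice([-1, 1], size=flips_per_edge)
            for i, st in zip(idx, steps):
                nxt = s[i] + st
                if not -1 <= nxt <= 1:
                    nxt = s[i] - st
                s[i] = nxt
            states[node] = s
        if node in tree.labels:
            rows[tree.labels[node]] = states[node]
        for child in sorted(tree.adj[node]):
            if child != parent:
                stack.append((child, node))
    data = pd.DataFrame.from_dict(rows, orient="index", columns=list(base.index))
    return CharacterMatrix(data=data.sort_index())


def make_survival(
    scores: pd.Series,
    beta: float,
    censor_rate: float = 0.2,
    seed: int = 0,
    base_hazard: float = 0.1,
) -> pd.DataFrame:
    """Exponential survival times with hazard exp(beta * centered score).

    Censoring is independent uniform C ~ U(0, tau), with tau calibrated by
    root-finding so the expected censored fraction matches ``censor_rate``.
    Returns a (sample_id, time, event) table.
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    s = scores.to_numpy(dtype=float)
    lam = base_hazard * np.exp(beta * (s - s.mean()))
    t = rng.exponential(scale=1.0 / lam)
    event = np.ones(len(s), dtype=int)
    if censor_rate > 0:
        def expected_censored(tau: float) -> float:
            x = lam * tau
            return float(np.mean((1.0 - np.exp(-x)) / x)) - censor_rate

        hi = 1.0 / lam.min()
        while expected_censored(hi) > 0:
            hi *= 2.0
        tau = brentq(expected_censored, 1e-12, hi)
        c = rng.uniform(0.0, tau, size=len(s))
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    return pd.DataFrame({"sample_id": list(scores.index), "time": t, "event": event})
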