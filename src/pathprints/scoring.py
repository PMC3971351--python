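"""Single-sample pathway expression scoring.

Expression values are converted to within-sample ranks (1 = lowest of the T
genes measured on the array) and each pathway is summarized per sample by
the mean squared rank of its represented member genes,

    En(P) = (1/n) * sum_i R_i**2 ,

where n counts pathway members present on the platform. Because only ranks
enter, the score is invariant to any strictly monotone transform of a
sample's expression values, which is what makes it portable across
normalization schemes and array technologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection, collection_id

__all__ = [
    "ExpressionMatrix",
    "RankMatrix",
    "PathwayScoreMatrix",
    "collapse_probes",
    "rank_transform",
    "pathway_scores",
    "read_expression_tsv",
    "read_gct",
    "write_expression_tsv",
]

DEFAULT_MIN_GENES = 3


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values for one platform and species."""

    values: pd.DataFrame  # genes x samples
    platform: str = ""
    species: str = "human"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("expression matrix needs at least one gene and one sample")
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RankMatrix:
    """Per-sample ascending ranks; ``total_genes`` is T, the array size."""

    ranks: pd.DataFrame
    total_genes: int
    platform: str = ""
    species: str = ""


@dataclass
class PathwayScoreMatrix:
    """Pathway-by-sample En(P) scores; NaN marks pathways with too few genes.

    Row order follows the collection; ``collection_hash`` ties the scores to
    the exact collection they were computed against so a background fitted on
    a different collection can never be applied silently.
    """

    scores: pd.DataFrame  # pathways x samples, NaN where unscored
    platform: str
    min_genes: int
    collection_hash: str
    n_genes_used: pd.Series = field(default=None)  # per pathway, genes present


def collapse_probes(
    probe_values: pd.DataFrame,
    annotation: Mapping[str, str],
    platform: str = "",
    species: str = "human",
) -> ExpressionMatrix:
    """Collapse a probe-by-sample matrix to genes by mean probe intensity.

    Probes without an annotation entry are dropped; each gene's row is the
    arithmetic mean of its probes' values per sample.
    """
    ann = pd.Series(dict(annotation), dtype=str)
    mapped = probe_values.index.intersection(ann.index)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is covered by the annotation")
    genes = ann.loc[mapped]
    collapsed = probe_values.loc[mapped].groupby(genes).mean()
    collapsed.index.name = probe_values.index.name
    return ExpressionMatrix(values=collapsed, platform=platform, species=species)


def rank_transform(em: ExpressionMatrix) -> RankMatrix:
    """Rank genes within each sample, 1 = lowest expression, T = highest.

    Ties receive the average of the tied rank positions, which keeps the
    per-column rank sum at exactly T(T+1)/2.
    """
    ranks = em.values.rank(axis=0, method="average")
    return RankMatrix(
        ranks=ranks,
        total_genes=em.values.shape[0],
        platform=em.platform,
        species=em.species,
    )


def pathway_scores(
    rm: RankMatrix, col: GeneSetCollection, min_genes: int = DEFAULT_MIN_GENES
) -> PathwayScoreMatrix:
    """Mean-squared-rank score for every pathway in every sample.

    A pathway is scored only when at least ``min_genes`` of its members are
    measured on the platform; otherwise its row is NaN (never imputed).
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if len(col) == 0:
        raise ValueError("empty gene set collection")
    sq = rm.ranks.to_numpy() ** 2
    gene_pos = {g: i for i, g in enumerate(rm.ranks.index)}
    out = np.full((len(col), rm.ranks.shape[1]), np.nan)
    n_used = np.zeros(len(col), dtype=int)
    for i, gs in enumerate(col):
        idx = [gene_pos[g] for g in sorted(gs.members) if g in gene_pos]
        n_used[i] = len(idx)
        if len(idx) >= min_genes:
            out[i] = sq[idx].mean(axis=0)
    scores = pd.DataFrame(out, index=col.names, columns=rm.ranks.columns)
    return PathwayScoreMatrix(
        scores=scores,
        platform=rm.platform,
        min_genes=min_genes,
        collection_hash=collection_id(col),
        n_genes_used=pd.Series(n_used, index=col.names),
    )


# --- I/O -------------------------------------------------------------------

def read_expression_tsv(
    path: str | Path, platform: str = "", species: str = "human"
) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (header row of sample ids, first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, platform=platform, species=species)


def read_gct(path: str | Path, platform: str = "", species: str = "human") -> ExpressionMatrix:
    """Read a GCT 1.2 file (version line, dimensions line, Name/Description columns)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        n_genes, n_samples = (int(x) for x in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != n_genes or df.shape[1] - 2 != n_samples:
        raise ValueError(f"{path}: dimension line does not match table shape")
    df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, platform=platform, species=species)


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t")
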