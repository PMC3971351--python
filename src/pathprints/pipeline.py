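"""Convenience chains: expression -> ranks -> scores -> background -> POE -> fingerprints."""

from __future__ import annotations

import pandas as pd

from .background import EMConfig, PlatformBackground, build_background, poe_transform
from .fingerprint import DEFAULT_THRESHOLD, ternarize
from .genesets import GeneSetCollection
from .scoring import DEFAULT_MIN_GENES, ExpressionMatrix, pathway_scores, rank_transform

__all__ = ["compute_poe", "fingerprint_expression", "corpus_poe", "fingerprint_corpus"]


def compute_poe(
    em: ExpressionMatrix,
    background_em: ExpressionMatrix,
    col: GeneSetCollection,
    min_genes: int = DEFAULT_MIN_GENES,
    em_config: EMConfig = EMConfig(),
) -> tuple[pd.DataFrame, PlatformBackground]:
    """Score two same-platform matrices, fit the background on one, POE the other.

    Returns the POE frame for ``em`` and the fitted :class:`PlatformBackground`.
    """
    if em.platform != background_em.platform:
        raise ValueError("sample and background matrices are from different platforms")
    bg_scores = pathway_scores(rank_transform(background_em), col, min_genes=min_genes)
    bg = build_background(bg_scores, col, config=em_config)
    scores = pathway_scores(rank_transform(em), col, min_genes=min_genes)
    return poe_transform(scores, bg), bg


def fingerprint_expression(
    em: ExpressionMatrix,
    background_em: ExpressionMatrix,
    col: GeneSetCollection,
    threshold: float = DEFAULT_THRESHOLD,
    min_genes: int = DEFAULT_MIN_GENES,
    em_config: EMConfig = EMConfig(),
) -> pd.DataFrame:
    """Full single-platform pipeline: ternary fingerprint matrix for ``em``."""
    poe, _ = compute_poe(em, background_em, col, min_genes=min_genes, em_config=em_config)
    return ternarize(poe, threshold=threshold)


def corpus_poe(
    corpus,
    min_genes: int = DEFAULT_MIN_GENES,
    em_config: EMConfig = EMConfig(),
    collections: dict | None = None,
) -> pd.DataFrame:
    """POE for every class sample of a multi-platform corpus, on shared pathways.

    Each platform is scored against its own species' collection and its own
    background; the per-platform POE frames are then joined on the pathways
    every platform could score, in primary-collection order. ``corpus`` is
    any object with ``expression``, ``background``, ``platform_species`` and
    ``collections`` attributes (e.g. :class:`~pathprints.synthetic.SyntheticCorpus`).
    """
    cols = collections or corpus.collections
    frames = []
    for platform, em in corpus.expression.items():
        col = cols[corpus.platform_species[platform]]
        poe, _ = compute_poe(
            em, corpus.background[platform], col, min_genes=min_genes, em_config=em_config
        )
        frames.append(poe.dropna(axis=0, how="any"))
    primary_order = list(frames[0].index)
    common = [p for p in primary_order if all(p in f.index for f in frames)]
    if not common:
        raise ValueError("no pathway is scoreable on every platform")
    return pd.concat([f.loc[common] for f in frames], axis=1)


def fingerprint_corpus(
    corpus,
    threshold: float = DEFAULT_THRESHOLD,
    min_genes: int = DEFAULT_MIN_GENES,
    em_config: EMConfig = EMConfig(),
    collections: dict | None = None,
) -> pd.DataFrame:
    """Ternary fingerprints for a whole corpus on its shared pathways."""
    poe = corpus_poe(corpus, min_genes=min_genes, em_config=em_config, collections=collections)
    return ternarize(poe, threshold=threshold)
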