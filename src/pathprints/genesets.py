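"""Gene-set collections: GMT I/O, homology mapping, randomization, summaries.

A fingerprint is indexed by an ordered :class:`GeneSetCollection`; pathway
order in the collection defines coordinate order everywhere downstream, so
collections are treated as immutable, ordered, and identified by a content
hash (see :func:`collection_id`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "HomologyMap",
    "read_gmt",
    "write_gmt",
    "read_homology_map",
    "map_collection",
    "random_genesets",
    "collection_summary",
    "collection_id",
]

#: default minimum surviving size when mapping across species
DEFAULT_MIN_SIZE = 5


@dataclass(frozen=True)
class GeneSet:
    """A named, flat set of gene identifiers with a provenance label.

    Gene identifiers are opaque strings (typically Entrez-style); nothing
    downstream inspects them beyond equality.
    """

    name: str
    source: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets for one species."""

    sets: list[GeneSet]
    species: str = "human"
    version: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene set names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def sizes(self) -> list[int]:
        return [s.size for s in self.sets]

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)


@dataclass(frozen=True)
class HomologyMap:
    """One-to-one-or-many mapping of gene ids from one species to another."""

    pairs: Mapping[str, str]
    source_species: str
    target_species: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", dict(self.pairs))


def collection_id(col: GeneSetCollection) -> str:
    """Content hash identifying a collection (order, names, members, species).

    Used to guarantee a platform background is only ever applied to scores
    computed against the identical collection.
    """
    h = hashlib.sha256()
    h.update(col.species.encode())
    for s in col.sets:
        h.update(b"\0" + s.name.encode())
        for g in sorted(s.members):
            h.update(b"\1" + g.encode())
    return h.hexdigest()[:16]


def read_gmt(path: str | Path, species: str = "human", version: str = "") -> GeneSetCollection:
    """Read a GMT file (one set per line: name, description, members...).

    The description column is stored as the set's source label ("custom"
    when empty); duplicate members within a line are silently de-duplicated.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in seen:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            seen.add(name)
            members = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=name, source=desc or "custom", members=members))
    return GeneSetCollection(sets=sets, species=species, version=version)


def write_gmt(col: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members sorted for byte-stable output."""
    with open(path, "w") as fh:
        for s in col.sets:
            fh.write("\t".join([s.name, s.source, *sorted(s.members)]) + "\n")


def read_homology_map(
    path: str | Path, source_species: str, target_species: str
) -> HomologyMap:
    """Read a 2-column headerless TSV of (source gene id, target gene id)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: homology map must have exactly 2 columns")
    pairs = dict(zip(df[0], df[1]))
    return HomologyMap(pairs=pairs, source_species=source_species, target_species=target_species)


def write_homology_map(hmap: HomologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k in sorted(hmap.pairs):
            fh.write(f"{k}\t{hmap.pairs[k]}\n")


def map_collection(
    col: GeneSetCollection, hmap: HomologyMap, min_size: int = DEFAULT_MIN_SIZE
) -> GeneSetCollection:
    """Project a collection into another species through a homology map.

    Members without a homolog are dropped; many-to-one targets collapse to a
    single gene; sets shrinking below ``min_size`` are removed entirely.
    """
    if hmap.source_species != col.species:
        raise ValueError(
            f"homology map source species {hmap.source_species!r} does not match "
            f"collection species {col.species!r}"
        )
    mapped: list[GeneSet] = []
    for s in col.sets:
        members = frozenset(hmap.pairs[g] for g in s.members if g in hmap.pairs)
        if len(members) >= min_size:
            mapped.append(replace(s, members=members))
    return GeneSetCollection(sets=mapped, species=hmap.target_species, version=col.version)


def random_genesets(col: GeneSetCollection, seed: int) -> GeneSetCollection:
    """Draw random gene sets matching the collection's size distribution.

    Each random set is sampled without replacement from the union of all
    member genes, preserving the original multiset of set sizes exactly.
    Used as the null comparator in the retrieval benchmarks.
    """
    if seed is None:
        raise ValueError("random_genesets requires an explicit seed")
    universe = sorted(col.universe)
    if max(col.sizes) > len(universe):
        raise ValueError("largest set exceeds the size of the gene universe")
    rng = np.random.default_rng(seed)
    sets = [
        replace(s, members=frozenset(rng.choice(universe, size=s.size, replace=False)))
        for s in col.sets
    ]
    return GeneSetCollection(sets=sets, species=col.species, version=f"randomized(seed={seed})")


def collection_summary(col: GeneSetCollection) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize a collection per source.

    Returns ``(summary, overlap)``: per-source counts/size statistics with an
    "All" row, and the symmetric source-by-source matrix of shared distinct
    genes (diagonal = per-source distinct gene totals).
    """
    if len(col) == 0:
        raise ValueError("cannot summarize an empty collection")
    by_source: dict[str, list[GeneSet]] = {}
    for s in col.sets:
        by_source.setdefault(s.source, []).append(s)

    def _row(sets: list[GeneSet]) -> dict:
        sizes = np.array([s.size for s in sets])
        genes = set().union(*(s.members for s in sets))
        return {
            "n_sets": len(sets),
            "mean_size": float(sizes.mean()),
            "median_size": float(np.median(sizes)),
            "min_size": int(sizes.min()),
            "max_size": int(sizes.max()),
            "n_genes": len(genes),
        }

    rows = {src: _row(sets) for src, sets in by_source.items()}
    rows["All"] = _row(col.sets)
    summary = pd.DataFrame.from_dict(rows, orient="index")

    sources = list(by_source)
    genes_by_source = {src: set().union(*(s.members for s in by_source[src])) for src in sources}
    overlap = pd.DataFrame(
        [
            [len(genes_by_source[a] & genes_by_source[b]) for b in sources]
            for a in sources
        ],
        index=sources,
        columns=sources,
        dtype=int,
    )
    return summary, overlap
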