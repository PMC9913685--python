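"""Rank-labelled taxonomy: loading, lineage queries, and lowest common ancestors.

The classifier, the rank-consolidation step and the read simulator all share
one taxonomy object: a rooted tree of taxa in which every node carries a rank
drawn from the eight canonical Linnaean levels (species up to root).  Reference
sequences known only to genus or family attach at that rank directly — lineages
may legally skip intermediate ranks, which is common for COI references pulled
from public databases.

The taxonomy is supplied as a flat four-column TSV (``taxid``, ``parent_taxid``,
``rank``, ``name``) rather than an NCBI taxdump; identity is the taxid string,
names are display metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RANKS",
    "RANK_INDEX",
    "ABSENT",
    "TaxonomyError",
    "Taxon",
    "Taxonomy",
    "load_taxonomy",
    "load_refmap",
]

#: Ranks in ascending order: species is the lowest, root the highest.
RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
    "root",
)

RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

#: Sentinel returned when a lineage skips the requested rank.
ABSENT = None


class TaxonomyError(ValueError):
    """Structural or format problem in a taxonomy table or refmap."""


@dataclass(frozen=True)
class Taxon:
    taxid: str
    parent: str
    rank: str
    name: str


class Taxonomy:
    """Immutable rooted tree of taxa with rank-aware lineage queries."""

    def __init__(self, nodes: Iterable[Taxon]):
        self._nodes: dict[str, Taxon] = {}
        for n in nodes:
            if n.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {n.taxid!r}")
            self._nodes[n.taxid] = n
        self._validate()
        # Cache root-paths lazily; trees here are small (tens to hundreds).
        self._path_cache: dict[str, tuple[str, ...]] = {}

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        roots = [n for n in self._nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        if root.rank != "root":
            raise TaxonomyError(f"root node {root.taxid!r} has rank {root.rank!r}")
        self._root = root.taxid
        for n in self._nodes.values():
            if n.rank not in RANK_INDEX:
                raise TaxonomyError(f"unknown rank {n.rank!r} for taxid {n.taxid!r}")
            if n.parent not in self._nodes:
                raise TaxonomyError(
                    f"taxid {n.taxid!r} has absent parent {n.parent!r}"
                )
        # Walk every node to the root, checking for cycles and that ranks
        # strictly ascend along the path (missing intermediates are fine).
        for n in self._nodes.values():
            seen = {n.taxid}
            cur = n
            while cur.taxid != self._root:
                parent = self._nodes[cur.parent]
                if parent.taxid in seen:
                    raise TaxonomyError(f"cycle detected at taxid {cur.taxid!r}")
                if RANK_INDEX[parent.rank] <= RANK_INDEX[cur.rank]:
                    raise TaxonomyError(
                        f"rank of {parent.taxid!r} ({parent.rank}) not above "
                        f"child {cur.taxid!r} ({cur.rank})"
                    )
                seen.add(parent.taxid)
                cur = parent

    # -- basic accessors ----------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self):
        return iter(self._nodes.values())

    def node(self, taxid: str) -> Taxon:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxid {taxid!r}") from None

    def rank(self, taxid: str) -> str:
        return self.node(taxid).rank

    def name(self, taxid: str) -> str:
        return self.node(taxid).name

    def root_path(self, taxid: str) -> tuple[str, ...]:
        """Path from *taxid* (inclusive) up to the root (inclusive)."""
        cached = self._path_cache.get(taxid)
        if cached is not None:
            return cached
        node = self.node(taxid)
        path = [node.taxid]
        while node.taxid != self._root:
            node = self._nodes[node.parent]
            path.append(node.taxid)
        out = tuple(path)
        self._path_cache[taxid] = out
        return out

    # -- lineage queries ----------------------------------------------------

    def ancestor_at_rank(self, taxid: str, rank: str) -> str | None:
        """The unique ancestor-or-self of *taxid* at *rank*, or ``ABSENT``.

        Returns ``ABSENT`` (None) when the lineage skips that rank or when the
        node itself already sits above it.
        """
        if rank not in RANK_INDEX:
            raise TaxonomyError(f"unknown rank {rank!r}")
        want = RANK_INDEX[rank]
        for tid in self.root_path(taxid):
            idx = RANK_INDEX[self._nodes[tid].rank]
            if idx == want:
                return tid
            if idx > want:
                return ABSENT
        return ABSENT

    def lca(self, taxids: Iterable[str]) -> str:
        """Deepest node ancestral to (or equal to) every input taxid."""
        ids = list(taxids)
        if not ids:
            raise ValueError("lca of an empty set is undefined")
        common = set(self.root_path(ids[0]))
        for tid in ids[1:]:
            common &= set(self.root_path(tid))
        # The common ancestors of any set form a chain; the deepest one is the
        # first encountered walking up from any member.
        for tid in self.root_path(ids[0]):
            if tid in common:
                return tid
        raise AssertionError("unreachable: root is always common")

    def descendants(self, taxid: str) -> set[str]:
        """All strict descendants of *taxid*."""
        self.node(taxid)
        out = set()
        for tid in self._nodes:
            if tid != taxid and taxid in self.root_path(tid):
                out.add(tid)
        return out

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        """True when *ancestor* lies strictly above *descendant*."""
        return ancestor != descendant and ancestor in self.root_path(descendant)


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load and validate a taxonomy from a 4-column TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["taxid", "parent_taxid", "rank", "name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table missing columns: {missing}")
    nodes = [
        Taxon(row.taxid, row.parent_taxid, row.rank, row.name)
        for row in df.itertuples(index=False)
    ]
    return Taxonomy(nodes)


def load_refmap(path: str | Path, tax: Taxonomy) -> dict[str, str]:
    """Load a seqid → taxid map (TSV, header required) and validate it."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "seqid" not in df.columns or "taxid" not in df.columns:
        raise TaxonomyError("refmap must have columns seqid, taxid")
    refmap: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.taxid not in tax:
            raise TaxonomyError(
                f"refmap entry {row.seqid!r} maps to unknown taxid {row.taxid!r}"
            )
        refmap[row.seqid] = row.taxid
    return refmap


def write_refmap(refmap: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"seqid": list(refmap), "taxid": [refmap[k] for k in refmap]}
    ).to_csv(path, sep="\t", index=False)
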