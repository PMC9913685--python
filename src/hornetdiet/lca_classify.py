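"""Hit filtering and 75%-agreement rank-descending LCA taxonomic assignment.

Each read's hits are filtered in two stages before voting:

1. identity/coverage: keep hits with ≥85% identity whose alignment spans
   ≥80% of the (trimmed) read length — the standard metabarcoding guard
   against short spurious matches;
2. bitscore window: among the survivors, keep hits whose bitscore is within
   3% of the best survivor (inclusive, i.e. ≥ 0.97 × max).

The surviving hits then vote rank by rank, starting at species and ascending
genus → family → order → class → phylum → kingdom.  At each rank every hit is
mapped to its reference taxon's ancestor at that rank; if a single label
accounts for at least 75% of the *filtered hits* (not distinct taxa), the read
is assigned that label at that rank.  Hits whose lineage lacks the rank under
consideration abstain but stay in the denominator, so missing annotation
cannot manufacture agreement.  A read whose ascent reaches kingdom without
agreement — or that has no surviving hits — is Unresolved; the ascent does not
fall back to the root, which carries no dietary information.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .reference_search import HitRecord
from .taxonomy import RANKS, Taxonomy

__all__ = [
    "UNRESOLVED",
    "HitFilterParams",
    "Assignment",
    "filter_hits",
    "assign_read",
    "classify_sample",
    "write_assignments",
    "read_assignments",
]

#: Label for reads whose hits never reach agreement at any rank.
UNRESOLVED = "Unresolved"

#: Ranks the LCA ascent walks, lowest first; root is deliberately excluded.
ASSIGNABLE_RANKS: tuple[str, ...] = RANKS[:-1]

# floating-point guard so that e.g. 3/4 passes an agreement of 0.75 exactly
_EPS = 1e-9


@dataclass(frozen=True)
class HitFilterParams:
    min_pident: float = 85.0          # percent
    min_query_cov: float = 0.80       # fraction of trimmed read length
    bitscore_window: float = 0.03     # fraction below the best survivor
    agreement: float = 0.75           # fraction of filtered hits that must agree

    def __post_init__(self):
        if not 0 < self.min_pident <= 100:
            raise ValueError("min_pident must be in (0, 100]")
        for name in ("min_query_cov", "bitscore_window", "agreement"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class Assignment:
    """Per-read taxonomic call: a taxid at some rank, or Unresolved."""

    read_id: str
    label: str          # taxid, or UNRESOLVED
    rank: str | None    # None iff label == UNRESOLVED
    n_hits_used: int

    def __post_init__(self):
        if (self.label == UNRESOLVED) != (self.rank is None):
            raise ValueError("label is UNRESOLVED iff rank is None")

    @property
    def resolved(self) -> bool:
        return self.label != UNRESOLVED


def filter_hits(
    hits: Sequence[HitRecord], read_len: int, p: HitFilterParams = HitFilterParams()
) -> list[HitRecord]:
    """Identity/coverage filter followed by the top-bitscore window.

    All hits must share one qseqid.  The best-bitscore survivor always
    survives the window (the window is anchored on it).  At most one hit per
    reference is kept (the best), so multi-HSP references cannot vote twice.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    qids = {h.qseqid for h in hits}
    if len(qids) > 1:
        raise ValueError(f"hits span multiple reads: {sorted(qids)}")
    passing = [
        h
        for h in hits
        if h.pident >= p.min_pident and h.align_len >= p.min_query_cov * read_len
    ]
    if not passing:
        return []
    # best hit per reference, then the bitscore window over those
    best_by_ref: dict[str, HitRecord] = {}
    for h in passing:
        prev = best_by_ref.get(h.sseqid)
        if prev is None or h.bitscore > prev.bitscore:
            best_by_ref[h.sseqid] = h
    survivors = list(best_by_ref.values())
    top = max(h.bitscore for h in survivors)
    cutoff = (1.0 - p.bitscore_window) * top
    kept = [h for h in survivors if h.bitscore >= cutoff - _EPS]
    kept.sort(key=lambda h: (-h.bitscore, h.sseqid))
    return kept


def assign_read(
    filtered_hits: Sequence[HitRecord],
    tax: Taxonomy,
    refmap: Mapping[str, str],
    agreement: float = 0.75,
    read_id: str = "",
) -> Assignment:
    """Rank-ascending majority vote over the filtered hits.

    Ascends species → … → kingdom; returns the first rank at which one label
    gathers ≥ *agreement* of all filtered hits.  Unresolved when no rank
    agrees or when there are no hits.
    """
    if not filtered_hits:
        return Assignment(read_id, UNRESOLVED, None, 0)
    rid = filtered_hits[0].qseqid or read_id
    taxids = []
    for h in filtered_hits:
        try:
            taxids.append(refmap[h.sseqid])
        except KeyError:
            raise KeyError(f"reference {h.sseqid!r} not present in refmap") from None
    n = len(taxids)
    need = agreement * n - _EPS
    for rank in ASSIGNABLE_RANKS:
        votes = Counter()
        for tid in taxids:
            anc = tax.ancestor_at_rank(tid, rank)
            if anc is not None:  # lineages lacking the rank abstain
                votes[anc] += 1
        if not votes:
            continue
        label, count = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        if count >= need:
            return Assignment(rid, label, rank, n)
    return Assignment(rid, UNRESOLVED, None, n)


def classify_sample(
    hits: Iterable[HitRecord],
    read_lens: Mapping[str, int],
    tax: Taxonomy,
    refmap: Mapping[str, str],
    p: HitFilterParams = HitFilterParams(),
) -> tuple[list[Assignment], list[dict]]:
    """Classify every read of one sample from its hit table.

    ``read_lens`` maps read id → trimmed read length for every read that
    passed QC; reads with no hits in the table are still assigned
    (Unresolved).  Returns the assignments plus a per-read provenance log
    (hits in, hits surviving each filter stage, the rank assigned).
    """
    by_read: dict[str, list[HitRecord]] = {rid: [] for rid in read_lens}
    for h in hits:
        if h.qseqid not in by_read:
            raise KeyError(f"hit for unknown read {h.qseqid!r}")
        by_read[h.qseqid].append(h)
    assignments: list[Assignment] = []
    provenance: list[dict] = []
    for rid in read_lens:
        read_hits = by_read[rid]
        kept = filter_hits(read_hits, read_lens[rid], p)
        a = assign_read(kept, tax, refmap, p.agreement, read_id=rid)
        assignments.append(a)
        provenance.append(
            {
                "read_id": rid,
                "n_hits_in": len(read_hits),
                "n_hits_filtered": len(kept),
                "label": a.label,
                "rank": a.rank or "NA",
            }
        )
    return assignments, provenance


def write_assignments(
    assignments: Sequence[Assignment], tax: Taxonomy, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttaxid\trank\tlabel_name\tn_hits_used\n")
        for a in assignments:
            name = tax.name(a.label) if a.resolved else UNRESOLVED
            fh.write(
                f"{a.read_id}\t{a.label}\t{a.rank or 'NA'}\t{name}\t{a.n_hits_used}\n"
            )


def read_assignments(path: str | Path) -> list[Assignment]:
    out: list[Assignment] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: missing assignments header")
        for line in fh:
            rid, taxid, rank, _name, n = line.rstrip("\n").split("\t")
            out.append(
                Assignment(rid, taxid, None if rank == "NA" else rank, int(n))
            )
    return out
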