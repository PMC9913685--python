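"""Samples × taxa abundance matrix: thresholding, consolidation, summaries.

The classifier's per-read assignments are tabulated into a samples × taxa
read-count matrix (Unresolved reads tallied separately per sample).  Three
transforms then clean the matrix the way a metabarcoding analysis does:

* **1%-of-max threshold** — per sample, the taxon with the most reads sets
  the bar; any taxon with at least 1% of that count is accepted as a true
  presence, the rest are zeroed.  This absorbs barcode misassignment and
  low-level contamination noise while keeping small but real prey signals.
* **rank consolidation** — one species often ends up split across ranks
  (some reads at species, some at genus or family).  A higher-rank taxon
  whose surviving descendants within a sample comprise exactly one taxon is
  merged into that descendant; with zero or two-plus surviving descendants
  it stays where it is.
* **relabelling** — a config-driven map that redirects counts from known
  database errors (e.g. insect records that are actually bacterial) into a
  replacement bucket such as "uncultured bacterium".

Nest-level reporting then gives mean reads per sample, distinct taxa per
nest and per gut, per-taxon percentage of nest reads, per-taxon incidence,
and the most abundant taxon — the usual columns of a diet study's summary
table.  Host (*Vespa velutina*) reads are retained and flagged, not
discarded; an option excludes the host from the most-abundant-taxon call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lca_classify import UNRESOLVED, Assignment
from .taxonomy import RANK_INDEX, Taxonomy

__all__ = [
    "AbundanceMatrix",
    "ThresholdParams",
    "build_matrix",
    "apply_threshold",
    "consolidate_ranks",
    "relabel",
    "nest_summaries",
]


@dataclass(frozen=True)
class ThresholdParams:
    frac_of_max: float = 0.01

    def __post_init__(self):
        if not 0 < self.frac_of_max < 1:
            raise ValueError("frac_of_max must be in (0, 1)")


@dataclass
class AbundanceMatrix:
    """Read counts per sample × taxon, plus sample metadata.

    ``counts`` is a samples × taxa integer DataFrame (columns are taxids, or
    free-text bucket labels introduced by relabelling); ``sample_meta`` has
    columns ``nest_id`` and ``platform`` indexed by sample; ``unresolved``
    holds each sample's Unresolved read tally.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    unresolved: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.unresolved is None:
            self.unresolved = pd.Series(0, index=self.counts.index, dtype=int)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not self.counts.index.equals(self.sample_meta.index):
            raise ValueError("counts and sample_meta indexes differ")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> pd.Series:
        """Assigned reads per sample, Unresolved included."""
        return self.counts.sum(axis=1) + self.unresolved

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.counts.copy(), self.sample_meta.copy(), self.unresolved.copy()
        )

    def drop_empty_taxa(self) -> "AbundanceMatrix":
        keep = self.counts.columns[(self.counts != 0).any(axis=0)]
        return AbundanceMatrix(
            self.counts[keep].copy(), self.sample_meta.copy(), self.unresolved.copy()
        )

    def equals(self, other: "AbundanceMatrix") -> bool:
        a = self.drop_empty_taxa()
        b = other.drop_empty_taxa()
        cols = sorted(set(a.counts.columns) | set(b.counts.columns))
        return (
            a.counts.reindex(columns=cols, fill_value=0).equals(
                b.counts.reindex(columns=cols, fill_value=0)
            )
            and a.unresolved.equals(b.unresolved)
            and a.sample_meta.equals(b.sample_meta)
        )


def build_matrix(
    assignments: Mapping[str, Sequence[Assignment]],
    sample_meta: Mapping[str, tuple[str, str]],
) -> AbundanceMatrix:
    """Tabulate per-sample assignments; Unresolved reads tallied separately."""
    samples = list(assignments)
    missing = [s for s in samples if s not in sample_meta]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    rows: dict[str, dict[str, int]] = {}
    unresolved: dict[str, int] = {}
    for sid, assigned in assignments.items():
        seen: set[str] = set()
        row: dict[str, int] = {}
        n_unres = 0
        for a in assigned:
            if a.read_id in seen:
                raise ValueError(f"duplicate read id {a.read_id!r} in sample {sid!r}")
            seen.add(a.read_id)
            if a.resolved:
                row[a.label] = row.get(a.label, 0) + 1
            else:
                n_unres += 1
        rows[sid] = row
        unresolved[sid] = n_unres
    taxa = sorted({t for row in rows.values() for t in row})
    counts = pd.DataFrame(
        [[rows[s].get(t, 0) for t in taxa] for s in samples],
        index=pd.Index(samples, name="sample_id"),
        columns=taxa,
        dtype=int,
    )
    meta = pd.DataFrame(
        [sample_meta[s] for s in samples],
        index=counts.index,
        columns=["nest_id", "platform"],
    )
    return AbundanceMatrix(counts, meta, pd.Series(unresolved, dtype=int)[samples])


def apply_threshold(
    m: AbundanceMatrix, p: ThresholdParams = ThresholdParams()
) -> AbundanceMatrix:
    """Zero out, per sample, taxa below ``frac_of_max`` of the sample's max.

    Inclusive at the cutoff (a count equal to 1% of the max survives); the
    max taxon itself always survives, so a non-empty row stays non-empty.
    Unresolved reads take no part in the max.
    """
    counts = m.counts.copy()
    for sid in counts.index:
        row = counts.loc[sid]
        mx = row.max() if len(row) else 0
        if mx <= 0:
            continue
        cutoff = p.frac_of_max * mx
        counts.loc[sid, row < cutoff] = 0
    return AbundanceMatrix(counts, m.sample_meta.copy(), m.unresolved.copy())


def consolidate_ranks(
    m: AbundanceMatrix, tax: Taxonomy, scope: str = "sample"
) -> AbundanceMatrix:
    """Merge higher-rank taxa into their single surviving descendant.

    Per sample (default) or per nest, a taxon whose surviving descendants
    comprise exactly one taxon absorbs into that descendant (counts summed);
    with zero or ≥2 surviving descendants it keeps its own rank.  Processing
    ascends the rank order so chains (species ← genus ← family) collapse in
    one pass; the result is order-independent and idempotent.  Bucket labels
    not present in the taxonomy are left untouched.
    """
    if scope not in ("sample", "nest"):
        raise ValueError("scope must be 'sample' or 'nest'")
    counts = m.counts.copy()
    tax_cols = [c for c in counts.columns if c in tax]
    by_rank = sorted(tax_cols, key=lambda c: RANK_INDEX[tax.rank(c)])

    if scope == "sample":
        groups = [[sid] for sid in counts.index]
    else:
        groups = [
            list(idx)
            for _, idx in m.sample_meta.groupby("nest_id").groups.items()
        ]

    for group in groups:
        block = counts.loc[group]
        for t in by_rank:
            if tax.rank(t) == "species":
                continue
            col_total = int(block[t].sum())
            if col_total == 0:
                continue
            surviving = [
                c
                for c in tax_cols
                if c != t and int(block[c].sum()) > 0 and tax.is_ancestor(t, c)
            ]
            if len(surviving) == 1:
                dest = surviving[0]
                counts.loc[group, dest] = counts.loc[group, dest] + counts.loc[group, t]
                counts.loc[group, t] = 0
                block = counts.loc[group]
    return AbundanceMatrix(counts, m.sample_meta.copy(), m.unresolved.copy())


def relabel(m: AbundanceMatrix, relabel_map: Mapping[str, str]) -> AbundanceMatrix:
    """Move counts from mis-annotated taxa to replacement labels.

    Replacement labels may be existing columns or new buckets (e.g.
    'uncultured bacterium').  Totals are conserved.  A source taxid absent
    from the matrix is a configuration error.
    """
    counts = m.counts.copy()
    for src, dst in relabel_map.items():
        if src not in counts.columns:
            raise KeyError(f"relabel source {src!r} not present in the matrix")
        if dst not in counts.columns:
            counts[dst] = 0
        counts[dst] = counts[dst] + counts[src]
        counts = counts.drop(columns=[src])
    return AbundanceMatrix(counts, m.sample_meta.copy(), m.unresolved.copy())


def _display_name(label: str, tax: Taxonomy) -> str:
    return tax.name(label) if label in tax else label


def nest_summaries(
    m: AbundanceMatrix,
    tax: Taxonomy,
    focal_taxon: str | None = None,
    host_taxid: str | None = None,
    exclude_host_from_most_abundant: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-nest and per-sample diet summary tables.

    Returns a dict with:

    * ``nest_summary`` — per nest: number of samples with reads, mean reads
      per sample, distinct taxa ("species per nest"), most abundant taxon,
      and — when ``focal_taxon`` is given (taxid or display name, e.g. the
      honey bee) — both the mean of per-sample percentages and the
      pooled-read percentage for it, which are different conventions and can
      legitimately differ.
    * ``taxon_percent`` — taxa × nests, pooled percentage of nest reads per
      taxon, with an Unresolved row; columns sum to 100.
    * ``sample_richness`` — per sample: distinct taxa and total reads.
    * ``incidence`` — per taxon: number of samples in which it appears.

    ``host_taxid`` flags the host's rows in outputs; with
    ``exclude_host_from_most_abundant`` the host cannot be called the most
    abundant taxon.  Nests whose samples all lack reads are omitted with a
    warning.
    """
    focal = None
    if focal_taxon is not None:
        if focal_taxon in m.counts.columns:
            focal = focal_taxon
        else:
            by_name = {
                _display_name(c, tax): c for c in m.counts.columns
            }
            focal = by_name.get(focal_taxon)

    totals = m.total_reads()
    richness = (m.counts > 0).sum(axis=1)
    sample_rows = pd.DataFrame(
        {
            "nest_id": m.sample_meta["nest_id"],
            "n_taxa": richness,
            "total_reads": totals,
        }
    )

    incidence = (m.counts > 0).sum(axis=0)
    incidence_df = pd.DataFrame(
        {
            "taxon": [_display_name(c, tax) for c in m.counts.columns],
            "n_samples": incidence.values,
            "is_host": [c == host_taxid for c in m.counts.columns],
        },
        index=pd.Index(m.counts.columns, name="taxid"),
    )

    nest_rows = []
    pct_cols: dict[str, pd.Series] = {}
    for nest, samples in m.sample_meta.groupby("nest_id").groups.items():
        samples = list(samples)
        nest_totals = totals[samples]
        if nest_totals.sum() == 0:
            warnings.warn(f"nest {nest!r} has no reads in any sample; omitted")
            continue
        pooled = m.counts.loc[samples].sum(axis=0)
        pooled_all = pooled.sum() + m.unresolved[samples].sum()
        pct = 100.0 * pooled / pooled_all
        pct[UNRESOLVED] = 100.0 * m.unresolved[samples].sum() / pooled_all
        pct_cols[nest] = pct

        cand = pooled.copy()
        if exclude_host_from_most_abundant and host_taxid in cand.index:
            cand = cand.drop(host_taxid)
        most_abundant = (
            _display_name(cand.idxmax(), tax) if cand.sum() > 0 else "NA"
        )

        row = {
            "nest_id": nest,
            "n_samples": int((nest_totals > 0).sum()),
            "mean_reads_per_sample": float(nest_totals.mean()),
            "taxa_per_nest": int((pooled > 0).sum()),
            "mean_taxa_per_sample": float(richness[samples].mean()),
            "most_abundant_taxon": most_abundant,
        }
        if focal is not None:
            per_sample_pct = np.where(
                totals[samples] > 0,
                100.0 * m.counts.loc[samples, focal] / totals[samples],
                0.0,
            )
            row["mean_pct_focal"] = float(np.mean(per_sample_pct))
            row["pooled_pct_focal"] = float(pct.get(focal, 0.0))
        nest_rows.append(row)

    taxon_percent = pd.DataFrame(pct_cols)
    if not taxon_percent.empty:
        order = [c for c in m.counts.columns] + [UNRESOLVED]
        taxon_percent = taxon_percent.reindex(order).fillna(0.0)
        taxon_percent.insert(
            0, "taxon", [_display_name(c, tax) for c in m.counts.columns] + [UNRESOLVED]
        )
        taxon_percent.index.name = "taxid"

    return {
        "nest_summary": pd.DataFrame(nest_rows),
        "taxon_percent": taxon_percent,
        "sample_richness": sample_rows,
        "incidence": incidence_df,
    }


# -- TSV I/O -----------------------------------------------------------------


def write_matrix(m: AbundanceMatrix, path: str | Path, form: str = "wide") -> None:
    """Write the count matrix as TSV, wide (samples × taxa) or long."""
    if form == "wide":
        out = m.counts.copy()
        out[UNRESOLVED] = m.unresolved
        out.to_csv(path, sep="\t")
    elif form == "long":
        long = (
            m.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_1": "taxid"})
        )
        long = long[long["count"] > 0]
        unres = pd.DataFrame(
            {
                "sample_id": m.unresolved.index,
                "taxid": UNRESOLVED,
                "count": m.unresolved.values,
            }
        )
        pd.concat([long, unres[unres["count"] > 0]]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError("form must be 'wide' or 'long'")


def read_matrix(
    path: str | Path, sample_meta: pd.DataFrame
) -> AbundanceMatrix:
    """Read a wide-form matrix TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    unresolved = df.pop(UNRESOLVED) if UNRESOLVED in df.columns else None
    if unresolved is not None:
        unresolved = unresolved.astype(int)
    return AbundanceMatrix(df.astype(int), sample_meta.loc[df.index], unresolved)
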