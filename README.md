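# hornetdiet

Metabarcoding diet analysis for Asian hornet (*Vespa velutina nigrithorax*)
larval gut contents — a tested, reusable implementation of the COI amplicon
pipeline used to identify the prey a hornet nest has been feeding on.

Adult hornets butcher prey (honey bees, flies, spiders, …) into flesh
pellets and feed them to larvae, so each larval gut is a mixed DNA sample of
recent nest-level foraging. Sequencing the ~650 nt Folmer fragment of
mitochondrial COI from gut contents on a Nanopore device (MinION or Flongle)
and matching reads against a curated COI reference set recovers that diet —
provided the analysis copes with 5–15% per-read error. The pipeline:

1. **Read QC** — both primers (LCO1490/HCO2198) are located by edit
   distance (≤10% of primer length), the insert between them extracted,
   then reads outside 550–750 nt or with mean quality below the platform
   threshold (Q10 MinION, Q7 Flongle) are removed. Per-read quality is
   −10·log₁₀(mean per-base error probability).
2. **Reference search** — an affine-gap Smith–Waterman (+2/−3 match/
   mismatch, 5/2 gap open/extend, numba-compiled, banded by an
   edit-distance prescreen) writes BLAST outfmt-6 hit tables; bitscores are
   (λS − ln K)/ln 2. Externally produced BLASTn tables are accepted
   interchangeably.
3. **LCA classification** — per read, hits are kept at ≥85% identity and
   ≥80% query coverage, then only hits with a bitscore within 3% of the
   best survivor vote. Starting at species and ascending to kingdom, a
   taxonomic label is applied at the first rank where ≥75% of the hits
   agree; otherwise the read is *Unresolved*.
4. **Diet profiling** — per-sample read counts per taxon are thresholded at
   1% of the sample's most-abundant taxon (inclusive), split ranks are
   consolidated (a higher-rank taxon with exactly one surviving descendant
   merges into it), database errors can be redirected to buckets such as
   "uncultured bacterium", and per-nest summary tables (mean reads per
   sample, taxa per nest and per gut, per-taxon percentage and incidence,
   most abundant taxon) are emitted.
5. **Synthetic communities** — a simulator generates tiered COI reference
   sets (congeners ~3% divergent, genera ~10%, families ~15%), per-larva
   Dirichlet prey compositions, and primer-flanked Nanopore-like reads with
   i.i.d. substitution/insertion/deletion errors and matching quality
   strings, with full ground truth — so every claim the pipeline makes is
   testable without downloading anything.

## Worked example

```python
import hornetdiet as hd
from hornetdiet.simulate import SimParams, simulate_nest

# one nest, 3 larvae, Flongle-like depth scaled down for the example
sp = SimParams(n_species=8, n_genera=4, n_families=2,
               n_larvae=3, reads_per_larva=400, seed=42)
ds = simulate_nest(sp, nest_id="demo")

qc = hd.QCParams()
assignments = {}
for sid, reads in ds.reads.items():
    trimmed = [t for r in reads if (t := hd.trim_primers(r, qc)) is not None]
    kept, report = hd.filter_reads(trimmed, qc)
    hits = hd.search_reads(kept, ds.refdb, hd.ScoringParams())
    lens = {r.read_id: len(r) for r in kept}
    assigned, _ = hd.classify_sample(hits, lens, ds.taxonomy, ds.refmap)
    assignments[sid] = assigned
    print(sid, f"{report.n_kept}/{len(reads)} reads kept,",
          f"{sum(a.resolved for a in assigned)} assigned")

m = hd.build_matrix(assignments, {s: ("demo", "flongle") for s in ds.reads})
m = hd.consolidate_ranks(hd.apply_threshold(m), ds.taxonomy)
summary = hd.nest_summaries(m.drop_empty_taxa(), ds.taxonomy)["nest_summary"]
print(summary[["nest_id", "mean_reads_per_sample", "taxa_per_nest",
               "most_abundant_taxon"]].to_string(index=False))
```

prints (seed 42):

```
demo_larva01 232/400 reads kept, 232 assigned
demo_larva02 240/400 reads kept, 240 assigned
demo_larva03 232/400 reads kept, 232 assigned
nest_id  mean_reads_per_sample  taxa_per_nest most_abundant_taxon
   demo             234.333333              7          species_08
```

Roughly 40% of simulated reads are rejected at trimming because at 6.9%
per-base error one of the two primers often carries more than the tolerated
10% edits; every surviving read classifies, and after the 1%-of-max
threshold the nest profile lists 7 of the 8 simulated species (the eighth
drew a negligible true proportion in every larva), with the dominant
simulated species correctly called most abundant.

The same chain is available from the shell:

```bash
hornetdiet simulate --seed 42 --n-species 8 --n-larvae 3 \
    --reads-per-larva 400 --out demo/
hornetdiet run-all config.yaml     # qc -> search -> classify -> profile
```

`run-all` writes, per sample, trimmed FASTQ, QC report, hit table,
assignments and provenance, plus raw and filtered matrices, nest summary
tables and a machine-readable stage log in which read accounting balances
exactly at every stage.

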