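# finsynt

Comparative genome-architecture analyses for lineages shaped by the two
rounds of early-vertebrate whole-genome duplication (1R and 2R), modelled on
the kind of questions raised by chromosome-scale cartilaginous-fish genomes:

* **karyotype** — assign chromosomes (or sub-chromosomal runs) to ancestral
  chordate linkage groups (CLGs) and to their 1R/2R duplication copies
  (1/2 × α/β) by Fisher-exact enrichment of shared single-copy orthologues,
  and quantify the asymmetric post-2R gene retention of α vs β segments.
* **synbreaks** — detect synteny breaks as junctions between pairwise
  alignment blocks, coalesce them across species, classify each break by
  distance to the nearest TAD boundary (strictly < 50 kb = "at boundary"),
  test the excess of at-boundary breaks with a boundary-shuffling
  permutation test, and nominate genes whose promoter loops cross a
  TAD-interrupting break.
* **microsynteny** — call deeply conserved consecutive gene pairs (orthologues
  still near-adjacent, allowing 4 intervening gene models), test their TAD
  co-residence against other consecutive pairs (χ²), and compare TADs
  with/without conserved pairs (Mann–Whitney U).
* **landscapes** — build HiChIP enhancer–promoter regulatory landscapes with
  the three-step filter: keep promoter–distal loops only; group by promoter
  and drop single-anchor landscapes; trim at interaction gaps larger than
  Q3 + 2·IQR of per-landscape biggest gaps. Fuse distal anchors closer than
  20 kb and export replicate count tables for external differential testing.
* **hicstats** — interchromosomal observed/expected maps (expectation
  proportional to the product of per-chromosome interchromosomal totals),
  Crane-style insulation scores (500-kb window), boundary/TAD calls at a
  boundary-score cutoff of 1, virtual 4C profiles, macro/meso/micro
  chromosome classes (> 40 / 20–40 / < 20 Mb) and per-WGD-segment TAD
  statistics.
* **simgenome** — a synthetic-data generator producing all of the above
  inputs with ground truth: a CLG-labelled outgroup, a 1R+2R descendant with
  per-copy Bernoulli loss (β > α), rearrangements placed at controlled
  distances from TAD boundaries, and block contact matrices with distance
  decay, TAD enrichment and negative-binomial noise.

The statistics at the core are standard: one-sided Fisher exact tests with
Benjamini–Hochberg correction across chromosome pairs; empirical permutation
p-values with the (r+1)/(n+1) estimator (so p ≥ 1/(n+1)); Pearson χ² without
continuity correction; two-sided Mann–Whitney U. Coordinates are 0-based
half-open internally, GFF3 is read/written 1-based closed.

## Worked example

```python
import numpy as np
from finsynt import SimConfig, simgenome as sg, synbreaks as sb

cfg = SimConfig(seed=5, n_clg=3, genes_per_clg=2000, n_breaks=50,
                frac_breaks_at_boundary=0.4, tad_size_mean=1_000_000,
                loop_rate=0)
anc = sg.simulate_ancestor(cfg)
genome = sg.SpeciesGenome("skatelike", anc.genes.assign(
    ancestor_id=anc.genes["gene_id"], r1="1", r2="a"))
tads = sg.simulate_tads(genome, cfg)
species, truth = sg.apply_rearrangements(genome, tads, cfg)
boundaries = sg.boundaries_from_tads(truth.tads, cfg.bin_size)
res = sb.permutation_enrichment(truth.breaks, boundaries,
                                species.chrom_sizes(),
                                n_shuffles=10_000, seed=5)
print(f"observed {res.observed} near-boundary breaks, "
      f"expected {res.expected_mean:.1f}, ratio {res.ratio:.2f}, p {res.p:.2e}")
```

prints

```
observed 53 near-boundary breaks, expected 11.3, ratio 4.69, p 1.00e-04
```

Out of 100 simulated breakpoints (40% planted within 50 kb of a TAD
boundary, the rest uniform), 53 land near a boundary against ~11 expected
when boundary positions are shuffled — a ~4.7-fold enrichment whose
empirical p is at the floor 1/(10,000+1) of the permutation test, mirroring
how lineage-specific rearrangements concentrate at domain boundaries.

A command-line interface covers the same ground
(`finsynt simulate | karyotype | breaks | microsynteny | landscapes | hic`);
`finsynt simulate --seed 3 --out DIR` writes a complete GFF3/BED/BEDPE/TSV
dataset plus contact-matrix text files and a record-count manifest.

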