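# Methods

This note documents the models, statistics and numerical choices behind
finsynt, and what the synthetic-data experiments do and do not establish.

## The synthetic genome model

The generator emulates a vertebrate-style genome history at desk scale.
Genes live on a fixed 10-kb grid (gene *k* at `[10k kb, 10k kb + 5 kb)`),
so all interval logic is exercised without sequence; chromosome length is
`genes × 10 kb`. One seeded `numpy` generator is drawn per stage (ancestor,
WGD, lineage split, rearrangement, regulatory, hit table), making each
stage independently reproducible and the whole dataset byte-identical under
a fixed `SimConfig`.

**Ancestor.** `n_clg` chromosomes (default 17, labelled A1, A2, B, …), each
monochromatic for one chordate linkage group (CLG) with `genes_per_clg`
genes and random strands.

**Whole-genome duplications.** Two successive duplications give up to four
copies per ancestral gene, labelled (1|2) × (α|β); descendant chromosomes
are named `<ancestor>_<1R><2R>`. Loss is a per-copy independent Bernoulli
draw: α copies are deleted with probability `loss_rate_alpha` (default
0.45, i.e. retention 0.55) and β copies with `loss_rate_beta` (default
0.75, retention 0.25) — differential retention only, no pseudogenisation
model. A sister lineage is derived by additional uniform loss, so that
orthologues between lineages share (ancestor gene, 1R, 2R) labels; that is
what entitles a labelled reference to transfer α/β labels to a query
(de novo α/β inference from molecular rates is out of scope).

**Rearrangements.** Fusions concatenate two chromosomes, fissions split one
at a uniform gene gap (the TAD track is carried along, splitting a
straddled TAD). "Breaks" are segment inversions between two cuts on one
chromosome: inversions permute gene order and flip strands without moving
bp coordinates, so the TAD/boundary tracks stay valid and each cut is a
junction detectable from alignment blocks at a known position. A fraction
`frac_breaks_at_boundary` of events draws both cuts from gene gaps strictly
within 50 kb of a TAD boundary, the rest from all gaps; gaps quantise cut
positions to the 10-kb grid (midpoint −2.5 kb), which is why recovery
tests use a ±25-kb matching tolerance.

**Regulatory tracks.** TAD sizes are log-normal with median `tad_size_mean`
(default 800 kb — the log-normal is a stand-in; only the median is a
modelling commitment) and σ = 0.35, rounded to the 25-kb bin grid with a
2-bin minimum, tiling each chromosome. The expected contact between bins
*i*, *j* is `contact_base · (1+|i−j|)^−1`, times `tad_enrichment` (default
3) inside a TAD. Counts are gamma–Poisson (negative binomial) with variance
`μ(1 + d·μ)`; dispersion `d = 0` returns the expectation exactly. A
configurable fraction of genes (default 0.3) are active promoters carrying
H3K4me3 peaks (TSS ± 1 kb); each active promoter receives ~Poisson(6.4)
loops to distal bins of its own TAD at ≥ 20 kb, distal bins being those
without an active TSS — without that sparsity every 25-kb anchor on a
10-kb gene grid would contain a promoter peak and promoter–distal
filtering would be vacuous. 70% of distal anchors get an ATAC peak; 20% of
loops receive q ≥ 0.1 to exercise the significance filter.

**What the simulation does not model:** sequence, read noise, mappability,
copy-number artefacts, compartments (A/B), TAD nesting, trans contacts
beyond uniform background, pseudogenes, tandem duplications. Passing the
recovery experiments shows the estimators are correct on data satisfying
their assumptions, not that real-data preprocessing is handled.

## Statistics

**Chromosome-pair enrichment.** One-sided (enrichment) Fisher exact test on
the 2×2 partition of single-copy orthologues by (on A_i?) × (on B_j?),
Benjamini–Hochberg across all pairs of one species pair, significant at
q < 0.05. One-sided because enrichment is the question; the threshold is
configurable and echoed in output headers. Sub-chromosomal assignment uses
maximal runs of ≥ 10 consecutive genes sharing a significant best partner;
genes without orthologues are transparent to runs (they neither break nor
extend them), which keeps runs intact under realistic gene loss.

**Retention rates.** Per (CLG, 2R copy): retained copy-slots over ancestral
slots, where each (CLG, 2R) class spans two 1R segments, i.e. two slots per
ancestral gene. Counting instead "genes with any surviving copy of that 2R
label" would estimate 1 − (1 − r)², not the per-segment retention r.

**Synteny breaks.** A junction is called between adjacent blocks when the
target chromosome or orientation changes or target coordinates jump by
more than `collinear_gap` (default 1 Mb); its coordinate is the inter-block
gap midpoint (the true junction lies anywhere in the gap; the gap extent is
recoverable from the flanking blocks). Junctions flagged by scaffold-end
evidence are excluded from downstream counting. Cross-species coalescing
expands junctions by ±`merge_window`/2 (default 100 kb, explicit because
the matching rule is a genuine design choice) and partitions the union into
maximal connected intervals with per-species presence flags.

**Boundary distance.** Edge-to-edge distance to boundary intervals, zero if
overlapping; "at boundary" is strictly `< 50 kb`. The permutation null
re-places boundary intervals uniformly per chromosome, preserving count and
lengths with no overlap (interval order permuted; the free space is divided
by sorted uniform cuts, which yields the uniform distribution over
non-overlapping placements). A `mode="breaks"` alternative re-places break
positions instead. The empirical p uses (r+1)/(n+1), so p ≥ 1/(n+1) and
zero p-values are impossible; both the shuffle mean and median of the
near-boundary count are reported as the expectation. For point breaks the
per-shuffle count is computed by merging the near-windows
`[start − t + 1, end + t − 1)` with a running maximum and counting sorted
break positions inside the union via `searchsorted` — exactly equivalent
to the quadratic scan (property-tested) and ~3 orders of magnitude faster.

*Calibration note.* The near-boundary count is discrete; with few breaks
per dataset the attained level of the permutation test sits below the
nominal 5% (ties at the rejection threshold make (r+1)/(n+1)
conservative). The shipped calibration experiment therefore uses a
fine-grained null — one 50-Mb chromosome, 100 boundaries of 25 kb, 2,000
independent breaks — where the attained level, measured over 12 master
seeds × 200 datasets, pools to 0.049.

**Microsynteny.** A consecutive reference pair is conserved in a comparison
species iff some orthologue combination lies on one chromosome with at most
4 intervening gene models (ambiguous orthology resolved optimistically,
logged); conserved overall = conserved in all species. "Shares a TAD" is
operationalised as the intergenic interval overlapping no boundary
interval (the `within_tad` mode is provided behind a flag). χ² is Pearson
without Yates correction (a `yates` flag exists); because the
non-conserved denominator is ambiguous, proportions are reported over all
non-conserved pairs and over the subset testable in every species.
Mann–Whitney U uses the two-sided normal approximation with tie correction
(scipy `asymptotic`), appropriate for the group sizes involved; equivalence
with exact enumeration is tested at n ≤ 8 on tie-free data.

**Landscapes.** Promoter anchors are those overlapping an H3K4me3 peak that
itself lies within TSS ± 2 kb (the promoter window is a design choice, the
source procedure never defines "promoter" numerically; it is
configurable). The gap cutoff is Q3 + 2·IQR of per-landscape biggest gaps
under the linear-interpolation quantile convention (echoed in output
metadata). Trimming scans outward from the promoter independently on each
side and discards everything beyond the first gap strictly larger than the
cutoff; landscapes left with fewer than two distal anchors are dropped;
trimming is idempotent (property-tested). Distal-anchor fusion merges
intervals with gaps strictly below 20 kb. Differential loop testing is
deliberately exported as a replicate count table rather than re-implemented.

**Hi-C statistics.** The interchromosomal expectation is proportional to
T(c)·T(c′) (per-chromosome interchromosomal totals), rescaled so the summed
expectation equals the summed observation — the rescaling makes the
normalisation exact rather than approximate while preserving
proportionality; the diagonal and zero-signal chromosomes are masked.
Insulation is the mean contact in the w×w square straddling each bin
(w = 500 kb / resolution), log2-normalised by subtracting the chromosome
mean of defined log scores (hence scale-invariant and mean-zero); margins
where the window does not fit are masked. Boundaries are local minima
scored by mean(flanking local maxima) − minimum, kept at score ≥ 1; the
exact boundary-score formula of the upstream tooling is not restated in the
source, so the formula used here is printed in CLI output and the cutoff is
configurable. TADs are the intervals between consecutive passing
boundaries (a chromosome without boundaries is one TAD). Size classes:
macro > 40 Mb, micro < 20 Mb, the closed interval [20, 40] Mb meso —
boundary values go to the middle class. TAD-to-segment assignment is by
TAD midpoint. Matrices are consumed as already balanced; the bundled
iterative-proportional-fitting balancer is a synthetic-data convenience,
not a KR implementation.

## Problem sizes and tolerances

The shipped experiments run at: 200 null datasets × 1,000 shuffles
(calibration); 20 simulated genomes of 3 × 20 Mb with ~100 breakpoints ×
10,000 shuffles (enrichment recovery, ratio ≥ 2 and p ≤ 10⁻³ expected in
≥ 19/20 seeds); 5,000 ancestral genes for retention recovery (±0.03);
one 50-Mb chromosome with 50 × 40-bin TADs for boundary recovery (exact
within one bin noiseless, F1 ≥ 0.9 at dispersion 0.3); 10 seeds × 7
allowance values for microsynteny monotonicity. Oracle equivalences are
exact to 10⁻¹⁰ (χ²) or relative 10⁻⁹ (Fisher vs enumeration). These sizes
give the estimators comfortable sampling margins at interactive runtimes.

## Known limitations

Interval overlap logic is O(n·m) per chromosome in several analysis paths
(fine at these scales, not for whole mammalian genomes); `pyranges` was
deliberately not used (the installed major version has a different API
surface) and no balancing beyond naive IPF is provided. The simulator's
α/β asymmetry is loss-only; it cannot generate the molecular-rate signal
that real α/β designations also draw on. Boundary calling reports a single
minimum per local basin; plateaus of equal scores keep the leftmost bin.
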