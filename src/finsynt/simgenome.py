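"""Synthetic multi-species genome simulator.

Generates desk-scale genomes that carry the statistical structure the
downstream comparative-architecture analyses assume:

* an unduplicated outgroup ("ancestor") whose chromosomes are monochromatic
  for one chordate linkage group (CLG) each;
* a descendant genome shaped by two rounds of whole-genome duplication
  (1R copies labelled 1/2, 2R copies labelled alpha/beta) with asymmetric,
  per-copy Bernoulli gene loss (beta segments lose more genes);
* lineage-specific rearrangements (fusions, fissions and inversion breaks)
  whose breakpoints are placed at a controlled rate within 50 kb of TAD
  boundaries;
* regulatory tracks: TADs, boundary intervals, H3K4me3/ATAC peaks,
  promoter-distal loops, and a binned contact matrix with power-law distance
  decay, within-TAD enrichment and negative-binomial noise.

Every stochastic stage draws from its own seeded generator so stages are
independently reproducible, and every emitted feature is mirrored in a
:class:`TruthSet` for parameter-recovery tests.

Genes live on a fixed 10-kb coordinate grid (gene k occupies
``[k*spacing, k*spacing + spacing//2)``); interval logic is exercised
without any sequence. Coordinates are 0-based half-open internally; GFF3
output is 1-based closed per the standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SimulationError",
    "SimConfig",
    "AncestralGenome",
    "SpeciesGenome",
    "TruthSet",
    "SimulatedDataset",
    "simulate_ancestor",
    "apply_wgd",
    "split_lineage",
    "shuffle_gene_order",
    "apply_rearrangements",
    "simulate_regulatory",
    "make_ortholog_table",
    "make_hit_table",
    "simulate_dataset",
    "write_dataset",
]

R1_COPIES = ("1", "2")
R2_COPIES = ("a", "b")  # alpha / beta


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """A requested event set cannot be realised on the simulated genome."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the simulator.

    Defaults follow the scales of the skate-like study system: 17 CLGs,
    TADs with a median size of 800 kb binned at 25 kb, ~6.4 loops per
    promoter, and 2R retention asymmetry (alpha kept at ~0.55, beta at
    ~0.25, i.e. loss rates 0.45/0.75).
    """

    seed: int = 0
    n_clg: int = 17
    genes_per_clg: int = 60
    loss_rate_alpha: float = 0.45
    loss_rate_beta: float = 0.75
    n_fusions: int = 0
    n_fissions: int = 0
    n_breaks: int = 0
    frac_breaks_at_boundary: float = 0.4
    tad_size_mean: int = 800_000
    tad_size_sigma: float = 0.35
    tad_enrichment: float = 3.0
    bin_size: int = 25_000
    loop_rate: float = 6.4
    active_promoter_rate: float = 0.3
    noise_dispersion: float = 0.3
    gene_spacing: int = 10_000
    boundary_window: int = 50_000
    contact_base: float = 100.0
    contact_decay: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_clg", "genes_per_clg"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_fusions", "n_fissions", "n_breaks"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("loss_rate_alpha", "loss_rate_beta", "frac_breaks_at_boundary"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.bin_size <= 0 or self.gene_spacing <= 0 or self.tad_size_mean <= 0:
            raise ConfigError("bin_size, gene_spacing and tad_size_mean must be positive")
        if self.noise_dispersion < 0:
            raise ConfigError("noise_dispersion must be non-negative")

    def rng(self, stage: str) -> np.random.Generator:
        """One independent, reproducible stream per simulation stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, _STAGES[stage])))


_STAGES = {name: i for i, name in enumerate(
    ["ancestor", "wgd", "lineage", "rearrange", "regulatory", "shuffle", "hits"])}


def _clg_labels(n: int) -> list[str]:
    """CLG labels in the A1, A2, B, C, ... style (A is historically split)."""
    letters = [chr(ord("A") + i) for i in range(max(n - 1, 1))]
    labels = ["A1", "A2"] + letters[1:] if n >= 2 else ["A1"]
    return labels[:n]


@dataclass
class AncestralGenome:
    """Unduplicated outgroup: one chromosome per CLG, genes on a fixed grid."""

    genes: pd.DataFrame  # gene_id chrom start end strand clg

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.genes["chrom"]))

    def chrom_sizes(self) -> dict[str, int]:
        return _sizes_from_genes(self.genes)


@dataclass
class SpeciesGenome:
    """Post-WGD genome; each gene remembers its ancestral gene and copy labels."""

    name: str
    genes: pd.DataFrame  # gene_id ancestor_id clg r1 r2 chrom start end strand

    def chrom_sizes(self) -> dict[str, int]:
        return _sizes_from_genes(self.genes)


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic genome."""

    retention: pd.DataFrame = field(default_factory=pd.DataFrame)
    # ancestor_id r1 r2 retained
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)
    # chrom start end clg r1 r2
    breaks: pd.DataFrame = field(default_factory=pd.DataFrame)
    # chrom pos at_boundary
    tads: pd.DataFrame = field(default_factory=pd.DataFrame)
    # chrom start end
    loops: pd.DataFrame = field(default_factory=pd.DataFrame)


def _sizes_from_genes(genes: pd.DataFrame, spacing: int | None = None) -> dict[str, int]:
    sizes = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        end = int(sub["end"].max())
        # round the tail up to the gene grid so the last gene has its gap
        step = spacing if spacing else int(np.diff(np.sort(sub["start"].unique())).min()) \
            if len(sub) > 1 else end
        sizes[chrom] = int(np.ceil(end / step) * step) if step else end
    return sizes


def _lay_out(genes: pd.DataFrame, spacing: int) -> pd.DataFrame:
    """Re-place genes on the fixed grid in their current per-chromosome order."""
    out = genes.copy()
    slot = out.groupby("chrom", sort=False).cumcount()
    out["start"] = slot * spacing
    out["end"] = out["start"] + spacing // 2
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage 1: ancestor


def simulate_ancestor(config: SimConfig) -> AncestralGenome:
    """Build the unduplicated outgroup: ``n_clg`` chromosomes, each
    monochromatic for one CLG with ``genes_per_clg`` genes."""
    rng = config.rng("ancestor")
    labels = _clg_labels(config.n_clg)
    rows = []
    for ci, clg in enumerate(labels):
        chrom = f"anc{ci + 1}"
        for gi in range(config.genes_per_clg):
            rows.append((f"anc_g{ci * config.genes_per_clg + gi:05d}", chrom, clg))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "clg"])
    genes["strand"] = rng.choice(["+", "-"], size=len(genes))
    genes["start"] = 0
    genes["end"] = 0
    genes = _lay_out(genes, config.gene_spacing)
    return AncestralGenome(genes[["gene_id", "chrom", "start", "end", "strand", "clg"]])


# ---------------------------------------------------------------------------
# stage 2: whole-genome duplications and asymmetric loss


def apply_wgd(ancestor: AncestralGenome, config: SimConfig,
              rng: np.random.Generator | None = None,
              name: str = "sim") -> tuple[SpeciesGenome, TruthSet]:
    """Two successive duplications (1R then 2R) followed by per-copy loss.

    Every ancestral gene acquires up to four descendants labelled
    (1|2) x (alpha|beta); each alpha copy is deleted independently with
    probability ``loss_rate_alpha`` and each beta copy with
    ``loss_rate_beta``. Descendant chromosomes are named
    ``<ancestral chromosome>_<r1><r2>``.
    """
    rng = config.rng("wgd") if rng is None else rng
    anc = ancestor.genes
    copies = []
    for r1 in R1_COPIES:
        for r2 in R2_COPIES:
            c = anc.copy()
            c["ancestor_id"] = c["gene_id"]
            c["r1"], c["r2"] = r1, r2
            c["chrom"] = c["chrom"] + f"_{r1}{r2}"
            c["gene_id"] = c["gene_id"].str.replace("anc_", f"{name}_", regex=False) + f"_{r1}{r2}"
            copies.append(c)
    genome = pd.concat(copies, ignore_index=True)
    loss_p = np.where(genome["r2"] == "a", config.loss_rate_alpha, config.loss_rate_beta)
    retained = rng.random(len(genome)) >= loss_p
    truth = TruthSet(retention=pd.DataFrame({
        "ancestor_id": genome["ancestor_id"],
        "clg": genome["clg"],
        "r1": genome["r1"],
        "r2": genome["r2"],
        "retained": retained,
    }))
    kept = _lay_out(genome.loc[retained].reset_index(drop=True), config.gene_spacing)
    kept = kept[["gene_id", "ancestor_id", "clg", "r1", "r2", "chrom", "start", "end", "strand"]]
    sp = SpeciesGenome(name, kept)
    truth.segments = segments_from_genes(sp, config.gene_spacing)
    return sp, truth


def segments_from_genes(genome: SpeciesGenome, spacing: int) -> pd.DataFrame:
    """Maximal runs of genes sharing (clg, r1, r2), with bp extents."""
    rows = []
    for chrom, sub in genome.genes.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        key = sub["clg"] + "|" + sub["r1"] + "|" + sub["r2"]
        run_id = (key != key.shift()).cumsum()
        for _, run in sub.groupby(run_id):
            clg, r1, r2 = run.iloc[0][["clg", "r1", "r2"]]
            rows.append((chrom, int(run["start"].min()),
                         int(run["end"].max() + spacing // 2), clg, r1, r2))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "clg", "r1", "r2"])


def split_lineage(genome: SpeciesGenome, config: SimConfig, name: str,
                  extra_loss: float = 0.1,
                  rng: np.random.Generator | None = None) -> SpeciesGenome:
    """Derive a sister lineage by additional uniform gene loss.

    Descendants of the same post-WGD gene copy in two lineages are
    orthologues carrying identical (clg, r1, r2) labels, which is what lets
    a labelled reference transfer segment labels to a query genome.
    """
    rng = config.rng("lineage") if rng is None else rng
    keep = rng.random(len(genome.genes)) >= extra_loss
    genes = _lay_out(genome.genes.loc[keep].reset_index(drop=True), config.gene_spacing)
    genes = genes.copy()
    genes["gene_id"] = genes["gene_id"].str.replace(
        f"{genome.name}_", f"{name}_", regex=False)
    return SpeciesGenome(name, genes)


def shuffle_gene_order(genome: SpeciesGenome, config: SimConfig,
                       frac: float = 1.0,
                       rng: np.random.Generator | None = None) -> SpeciesGenome:
    """Permute a fraction of gene positions genome-wide (synteny destroyer)."""
    rng = config.rng("shuffle") if rng is None else rng
    genes = genome.genes.copy().reset_index(drop=True)
    n = len(genes)
    idx = rng.choice(n, size=int(round(frac * n)), replace=False)
    perm = rng.permutation(idx)
    order = np.arange(n)
    order[idx] = perm
    genes = genes.iloc[order].reset_index(drop=True)
    # keep the original chromosome sizes: chromosome is a property of the slot
    genes["chrom"] = genome.genes["chrom"].to_numpy()
    return SpeciesGenome(genome.name, _lay_out(genes, config.gene_spacing))


# ---------------------------------------------------------------------------
# stage 3: rearrangements


def _gap_midpoints(n_genes: int, spacing: int) -> np.ndarray:
    """bp midpoints of the internal inter-gene gaps of an n-gene chromosome.

    Gene k occupies [k*s, k*s + s/2), so the gap before gene k is
    [k*s - s/2, k*s) with midpoint k*s - s/4.
    """
    k = np.arange(1, n_genes)
    return k * spacing - spacing // 2 + spacing // 4


def apply_rearrangements(genome: SpeciesGenome, tads: pd.DataFrame,
                         config: SimConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[SpeciesGenome, TruthSet]:
    """Apply fusions, fissions and inversion breaks; record ground truth.

    Fusions concatenate two chromosomes and fissions split one at a uniform
    gene gap; both re-lay coordinates and carry the TAD track along.  Breaks
    are segment inversions between two cut points on one chromosome: a
    fraction ``frac_breaks_at_boundary`` of events draws both cuts from gene
    gaps lying (strictly) within ``boundary_window`` of a TAD boundary, the
    rest uniformly.  Inversions permute genes without changing chromosome
    lengths, so the TAD track remains valid and every cut is a detectable
    synteny junction at a known position.
    """
    rng = config.rng("rearrange") if rng is None else rng
    spacing = config.gene_spacing
    genes = genome.genes.copy().reset_index(drop=True)
    tads = tads.copy() if tads is not None else pd.DataFrame(columns=["chrom", "start", "end"])

    # --- fusions
    for _ in range(config.n_fusions):
        chroms = list(dict.fromkeys(genes["chrom"]))
        if len(chroms) < 2:
            raise SimulationError("not enough chromosomes left to fuse")
        a, b = rng.choice(len(chroms), size=2, replace=False)
        ca, cb = chroms[a], chroms[b]
        offset = int(genes.loc[genes["chrom"] == ca, "start"].count()) * spacing
        fused = f"{ca}+{cb.split('_', 1)[-1] if '_' in cb else cb}"
        sel_b = tads["chrom"] == cb
        tads.loc[sel_b, ["start", "end"]] += offset
        tads.loc[tads["chrom"].isin([ca, cb]), "chrom"] = fused
        # order: others, then all of a, then all of b
        part_a, part_b = genes[genes["chrom"] == ca], genes[genes["chrom"] == cb]
        genes = pd.concat([genes[~genes["chrom"].isin([ca, cb])], part_a, part_b],
                          ignore_index=True)
        genes.loc[genes["chrom"].isin([ca, cb]), "chrom"] = fused
        genes = _lay_out(genes, spacing)

    # --- fissions
    for _ in range(config.n_fissions):
        chroms = [c for c, s in genes.groupby("chrom", sort=False) if len(s) >= 2]
        if not chroms:
            raise SimulationError("no chromosome long enough to split")
        chrom = chroms[rng.integers(len(chroms))]
        sub = genes[genes["chrom"] == chrom]
        cut_slot = int(rng.integers(1, len(sub)))
        cut_bp = cut_slot * spacing
        left, right = f"{chrom}.1", f"{chrom}.2"
        idx = sub.index.to_numpy()
        genes.loc[idx[:cut_slot], "chrom"] = left
        genes.loc[idx[cut_slot:], "chrom"] = right
        sel = tads["chrom"] == chrom
        t = tads.loc[sel]
        new_rows = []
        for _, row in t.iterrows():
            if row["end"] <= cut_bp:
                new_rows.append((left, row["start"], row["end"]))
            elif row["start"] >= cut_bp:
                new_rows.append((right, row["start"] - cut_bp, row["end"] - cut_bp))
            else:  # straddles the cut: split in two
                new_rows.append((left, row["start"], cut_bp))
                new_rows.append((right, 0, row["end"] - cut_bp))
        tads = pd.concat([tads.loc[~sel],
                          pd.DataFrame(new_rows, columns=["chrom", "start", "end"])],
                         ignore_index=True)
        genes = _lay_out(genes, spacing)

    # --- inversion breaks
    boundaries = boundaries_from_tads(tads, config.bin_size)
    break_rows = []
    if config.n_breaks:
        gap_by_chrom: dict[str, np.ndarray] = {}
        near_by_chrom: dict[str, np.ndarray] = {}
        for chrom, sub in genes.groupby("chrom", sort=False):
            mids = _gap_midpoints(len(sub), spacing)
            gap_by_chrom[chrom] = mids
            b = boundaries[boundaries["chrom"] == chrom]
            if len(b) and len(mids):
                d = _point_interval_distance(mids, b["start"].to_numpy(), b["end"].to_numpy())
                near_by_chrom[chrom] = mids[d < config.boundary_window]
            else:
                near_by_chrom[chrom] = np.empty(0)
        at_boundary_flags = rng.random(config.n_breaks) < config.frac_breaks_at_boundary
        for flag in at_boundary_flags:
            pool = {c: (near_by_chrom if flag else gap_by_chrom)[c]
                    for c in gap_by_chrom}
            eligible = [c for c, v in pool.items() if len(v) >= 2]
            if not eligible:
                raise SimulationError(
                    "no chromosome offers two eligible cut positions "
                    f"({'near-boundary' if flag else 'uniform'} draw)")
            chrom = eligible[rng.integers(len(eligible))]
            cuts = np.sort(rng.choice(pool[chrom], size=2, replace=False))
            # cut bp -> gene slot: gap midpoint m belongs to slot round(m/spacing)
            s0, s1 = (int(round((c + spacing // 4) / spacing)) for c in cuts)
            sub_idx = genes.index[genes["chrom"] == chrom].to_numpy()
            seg = sub_idx[s0:s1][::-1]
            new_order = np.concatenate([sub_idx[:s0], seg, sub_idx[s1:]])
            strands = genes.loc[seg, "strand"].map({"+": "-", "-": "+"}).to_numpy()
            genes.loc[seg, "strand"] = strands
            chrom_genes = genes.loc[new_order].copy()
            chrom_genes.index = sub_idx
            genes.loc[sub_idx] = chrom_genes
            for c, f in zip(cuts, [flag, flag]):
                break_rows.append((chrom, int(c), bool(f)))
        genes = _lay_out(genes, spacing)

    out = SpeciesGenome(genome.name, genes.reset_index(drop=True))
    truth = TruthSet(
        segments=segments_from_genes(out, spacing),
        breaks=pd.DataFrame(break_rows, columns=["chrom", "pos", "at_boundary"]),
        tads=tads.sort_values(["chrom", "start"]).reset_index(drop=True),
    )
    return out, truth


def _point_interval_distance(points: np.ndarray, starts: np.ndarray,
                             ends: np.ndarray) -> np.ndarray:
    """Edge-to-edge distance from each point to its nearest interval (sorted)."""
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    d = np.full(len(points), np.inf)
    for s, e in zip(starts, ends):  # boundary sets are small here
        d = np.minimum(d, np.maximum(np.maximum(s - points, points - e + 1), 0))
    return d


def boundaries_from_tads(tads: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """One-bin boundary intervals centred on internal TAD junctions."""
    rows = []
    half = bin_size // 2
    for chrom, sub in tads.groupby("chrom", sort=False):
        edges = np.sort(sub["start"].to_numpy())
        for j in edges[1:]:  # internal junctions only
            rows.append((chrom, max(int(j) - half, 0), int(j) + half))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# stage 4: regulatory tracks and contact matrix


def simulate_tads(genome: SpeciesGenome, config: SimConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Tile each chromosome with TADs; sizes are log-normal with median
    ``tad_size_mean``, rounded to the bin grid (>= 2 bins)."""
    rng = config.rng("regulatory") if rng is None else rng
    rows = []
    mu = np.log(config.tad_size_mean)
    for chrom, size in genome.chrom_sizes().items():
        pos = 0
        while pos < size:
            raw = rng.lognormal(mu, config.tad_size_sigma)
            w = max(2, int(round(raw / config.bin_size))) * config.bin_size
            end = min(pos + w, size)
            if size - end < 2 * config.bin_size:
                end = size
            rows.append((chrom, pos, int(end)))
            pos = int(end)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_regulatory(genome: SpeciesGenome, config: SimConfig,
                        tads: pd.DataFrame | None = None,
                        rng: np.random.Generator | None = None):
    """TADs, boundaries, peaks, loops and a noisy block contact matrix.

    The expected contact count between bins i and j on one chromosome is
    ``contact_base * (1+|i-j|)**-contact_decay``, multiplied by
    ``tad_enrichment`` when both bins fall in the same TAD. Counts are
    negative-binomial with variance ``mu*(1 + noise_dispersion*mu)``;
    ``noise_dispersion = 0`` returns the expectation exactly.

    Loops connect each gene promoter to ~Poisson(``loop_rate``) distal bins
    in the same TAD; H3K4me3 peaks sit on every promoter, ATAC peaks on a
    70% subset of distal anchors.  Returns
    ``(tads, boundaries, peaks, loops, matrix)`` where ``peaks`` is a dict
    with BED frames under ``"h3k4me3"`` and ``"atac"``.
    """
    from .hicstats import ContactMatrix  # local import to avoid a cycle

    rng = config.rng("regulatory") if rng is None else rng
    if tads is None:
        tads = simulate_tads(genome, config, rng)
    boundaries = boundaries_from_tads(tads, config.bin_size)
    sizes = genome.chrom_sizes()
    bs = config.bin_size

    import warnings

    bin_frames, pair_frames = [], []
    offset = 0
    for chrom, size in sizes.items():
        n = size // bs
        if n < 2:
            warnings.warn(f"chromosome {chrom} shorter than 2 bins; skipped")
            continue
        starts = np.arange(n) * bs
        bin_frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + bs,
            "bin_id": offset + np.arange(n)}))
        # expected matrix: distance decay x within-TAD enrichment
        iu, ju = np.triu_indices(n)
        mu = config.contact_base * (1.0 + (ju - iu)) ** (-config.contact_decay)
        t = tads[tads["chrom"] == chrom]
        tad_id = np.full(n, -1)
        for k, (_, row) in enumerate(t.iterrows()):
            lo, hi = int(row["start"]) // bs, min(int(row["end"]) // bs, n)
            tad_id[lo:hi] = k
        same = (tad_id[iu] == tad_id[ju]) & (tad_id[iu] >= 0)
        mu = np.where(same, mu * config.tad_enrichment, mu)
        if config.noise_dispersion == 0:
            vals = mu
        else:
            r = 1.0 / config.noise_dispersion
            lam = rng.gamma(shape=r, scale=mu / r)
            vals = rng.poisson(lam).astype(float)
        nz = vals > 0
        pair_frames.append(pd.DataFrame({
            "bin1_id": offset + iu[nz], "bin2_id": offset + ju[nz],
            "count": vals[nz]}))
        offset += n

    bins = pd.concat(bin_frames, ignore_index=True)
    pairs = pd.concat(pair_frames, ignore_index=True)
    matrix = ContactMatrix.from_pairs(bins, pairs, resolution=bs)

    # loops + peaks: only a subset of genes are active promoters (H3K4me3),
    # and distal anchors are drawn from promoter-free bins so that the
    # promoter/distal distinction is recoverable downstream
    loop_rows, k4_rows, atac_rows = [], [], []
    tads_by_chrom = {c: s.sort_values("start").to_numpy()[:, 1:3].astype(int)
                     for c, s in tads.groupby("chrom", sort=False)}
    active = rng.random(len(genome.genes)) < config.active_promoter_rate
    gg = genome.genes.reset_index(drop=True)
    tss_all = np.where(gg["strand"] == "+", gg["start"], gg["end"]).astype(int)
    active_bins = {c: set() for c in sizes}
    for chrom, tss in zip(gg.loc[active, "chrom"], tss_all[active]):
        active_bins.setdefault(chrom, set()).add(int(tss) // bs)
    for gi, g in gg[active].iterrows():
        chrom = g["chrom"]
        tss = int(tss_all[gi])
        k4_rows.append((chrom, max(tss - 1000, 0), tss + 1000, g["gene_id"]))
        if config.loop_rate == 0:
            continue
        t = tads_by_chrom.get(chrom)
        if t is None:
            continue
        hit = t[(t[:, 0] <= tss) & (tss < t[:, 1])]
        if not len(hit):
            continue
        lo, hi = hit[0]
        n_loops = rng.poisson(config.loop_rate)
        cand = np.arange(lo // bs, hi // bs)
        cand = cand[np.abs(cand * bs + bs // 2 - tss) >= 20_000]
        cand = cand[[c not in active_bins.get(chrom, ()) for c in cand]]
        if not len(cand):
            continue
        for b in rng.choice(cand, size=min(n_loops, len(cand)), replace=False):
            a1s, a1e = max(tss - bs // 2, 0), tss + bs // 2
            a2s, a2e = int(b) * bs, int(b + 1) * bs
            count = int(rng.poisson(10) + 1)
            q = float(rng.uniform(0, 0.1)) if rng.random() < 0.8 else float(rng.uniform(0.1, 1))
            loop_rows.append((chrom, a1s, a1e, chrom, a2s, a2e, count, q, g["gene_id"]))
            if rng.random() < 0.7:
                atac_rows.append((chrom, a2s + bs // 4, a2e - bs // 4, "."))
    loops = pd.DataFrame(loop_rows, columns=[
        "chrom1", "start1", "end1", "chrom2", "start2", "end2", "count", "q", "gene_id"])
    peaks = {
        "h3k4me3": pd.DataFrame(k4_rows, columns=["chrom", "start", "end", "name"]),
        "atac": pd.DataFrame(atac_rows, columns=["chrom", "start", "end", "name"])
        .drop_duplicates(["chrom", "start", "end"]).reset_index(drop=True),
    }
    return tads, boundaries, peaks, loops, matrix


# ---------------------------------------------------------------------------
# orthologue / hit tables


def make_ortholog_table(a: SpeciesGenome | AncestralGenome,
                        b: SpeciesGenome | AncestralGenome,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Orthologue pairs between two simulated genomes.

    Post-WGD genomes match on (ancestor gene, 1R copy, 2R copy); a pair with
    an ancestral genome matches every surviving descendant of each ancestral
    gene. ``unique`` flags single-copy pairs (exactly one match on each side).
    """
    rng = np.random.default_rng(0) if rng is None else rng

    def frame(g):
        if isinstance(g, AncestralGenome):
            f = g.genes.copy()
            f["ancestor_id"] = f["gene_id"]
            f["key"] = f["ancestor_id"]
            f["species"] = "anc"
        else:
            f = g.genes.copy()
            f["key"] = f["ancestor_id"] + "|" + f["r1"] + "|" + f["r2"]
            f["species"] = g.name
        return f

    fa, fb = frame(a), frame(b)
    if isinstance(a, AncestralGenome) or isinstance(b, AncestralGenome):
        fa["key"], fb["key"] = fa["ancestor_id"], fb["ancestor_id"]
    merged = fa.merge(fb, on="key", suffixes=("_a", "_b"))
    out = pd.DataFrame({
        "species_a": merged["species_a"],
        "gene_a": merged["gene_id_a"],
        "species_b": merged["species_b"],
        "gene_b": merged["gene_id_b"],
        "score": np.round(100.0 - rng.random(len(merged)) * 10.0, 3),
    })
    na = out.groupby("gene_a")["gene_b"].transform("size")
    nb = out.groupby("gene_b")["gene_a"].transform("size")
    out["unique"] = (na == 1) & (nb == 1)
    return out.reset_index(drop=True)


def make_hit_table(orth: pd.DataFrame, config: SimConfig,
                   n_noise: int = 200,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Symmetric similarity-hit table whose mutual best hits are ``orth``.

    True pairs score in [90, 100); noise hits between random gene pairs
    score in [10, 60), so the reciprocal-best-hit scan recovers exactly the
    orthologue set.
    """
    rng = config.rng("hits") if rng is None else rng
    rows = [orth[["species_a", "gene_a", "species_b", "gene_b", "score"]]]
    ga = orth["gene_a"].unique()
    gb = orth["gene_b"].unique()
    noise = pd.DataFrame({
        "species_a": orth["species_a"].iloc[0],
        "gene_a": rng.choice(ga, size=n_noise),
        "species_b": orth["species_b"].iloc[0],
        "gene_b": rng.choice(gb, size=n_noise),
        "score": np.round(10 + rng.random(n_noise) * 50, 3),
    })
    hits = pd.concat(rows + [noise], ignore_index=True)
    hits = hits.drop_duplicates(["gene_a", "gene_b"], keep="first")
    back = hits.rename(columns={"species_a": "species_b", "species_b": "species_a",
                                "gene_a": "gene_b", "gene_b": "gene_a"})
    return pd.concat([hits, back], ignore_index=True)


# ---------------------------------------------------------------------------
# bundling and serialisation


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, plus its ground truth."""

    config: SimConfig
    ancestor: AncestralGenome
    species: SpeciesGenome
    reference: SpeciesGenome
    truth: TruthSet
    tads: pd.DataFrame
    boundaries: pd.DataFrame
    peaks: dict[str, pd.DataFrame]
    loops: pd.DataFrame
    matrix: "object"
    orthologs_anc: pd.DataFrame
    orthologs_ref: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full pipeline: ancestor -> WGD -> sister lineage -> TADs ->
    rearrangements -> regulatory tracks, with one seeded stream per stage."""
    ancestor = simulate_ancestor(config)
    post_wgd, truth_wgd = apply_wgd(ancestor, config)
    reference = split_lineage(post_wgd, config, name="ref", extra_loss=0.05)
    tads0 = simulate_tads(post_wgd, config)
    species, truth_re = apply_rearrangements(post_wgd, tads0, config)
    tads, boundaries, peaks, loops, matrix = simulate_regulatory(
        species, config, tads=truth_re.tads)
    truth = TruthSet(retention=truth_wgd.retention,
                     segments=truth_re.segments,
                     breaks=truth_re.breaks, tads=tads, loops=loops)
    rng = config.rng("hits")
    return SimulatedDataset(
        config=config, ancestor=ancestor, species=species, reference=reference,
        truth=truth, tads=tads, boundaries=boundaries, peaks=peaks, loops=loops,
        matrix=matrix,
        orthologs_anc=make_ortholog_table(ancestor, species, rng),
        orthologs_ref=make_ortholog_table(reference, species, rng),
    )


def write_dataset(ds: SimulatedDataset, directory: str | Path) -> dict:
    """Write the dataset as plain-text files; return a manifest of record
    counts. Formats: GFF3 (genes), BED (TADs/boundaries/peaks), BEDPE
    (loops), TSV (orthologues, truth), bin table + bin-pair triplets."""
    from . import io as fio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def note(name, n):
        manifest[name] = int(n)

    fio.write_gff3(ds.species.genes, d / "genes.gff3")
    note("genes.gff3", len(ds.species.genes))
    fio.write_gff3(ds.ancestor.genes, d / "ancestor.gff3")
    note("ancestor.gff3", len(ds.ancestor.genes))
    fio.write_gff3(ds.reference.genes, d / "reference.gff3")
    note("reference.gff3", len(ds.reference.genes))
    fio.write_bed(ds.tads, d / "tads.bed")
    note("tads.bed", len(ds.tads))
    fio.write_bed(ds.boundaries, d / "boundaries.bed")
    note("boundaries.bed", len(ds.boundaries))
    for key, df in ds.peaks.items():
        fio.write_bed(df, d / f"peaks_{key}.bed")
        note(f"peaks_{key}.bed", len(df))
    fio.write_bedpe(ds.loops, d / "loops.bedpe")
    note("loops.bedpe", len(ds.loops))
    for name, df in [("orthologs_anc.tsv", ds.orthologs_anc),
                     ("orthologs_ref.tsv", ds.orthologs_ref),
                     ("truth_retention.tsv", ds.truth.retention),
                     ("truth_segments.tsv", ds.truth.segments),
                     ("truth_breaks.tsv", ds.truth.breaks)]:
        df.to_csv(d / name, sep="\t", index=False)
        note(name, len(df))
    fio.write_matrix(ds.matrix, d / "matrix_bins.tsv", d / "matrix_pairs.tsv")
    note("matrix_bins.tsv", len(ds.matrix.bins))
    note("matrix_pairs.tsv", len(ds.matrix.pairs))
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
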