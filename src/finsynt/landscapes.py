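"""HiChIP enhancer-promoter regulatory landscapes.

Starting from significant loop calls (upstream caller q < 0.1, anchors at
20 kb-2 Mb), the landscape pipeline applies three filters:

1. keep only promoter-distal loops — anchors are promoter-type when they
   overlap an H3K4me3 peak lying within a promoter window (TSS ± 2 kb by
   default); loops with two promoter anchors (promoter-promoter) or none
   (enhancer-enhancer and others) are removed;
2. group loops by promoter gene into regulatory landscapes (one promoter
   anchor plus its distal anchors in genomic order) and drop landscapes
   with a single distal anchor;
3. trim landscapes at implausible interaction gaps: the per-sample cutoff
   is Q3 + 2*IQR of the per-landscape biggest gap (classic outlier rule,
   linear-interpolation quantiles), and anchors beyond the first
   larger-than-cutoff gap on each side of the promoter are discarded;
   landscapes falling under two distal anchors are dropped.

Downstream utilities fuse distal anchors across conditions when closer
than 20 kb, extract per-replicate supporting counts for the union loop set
(for external differential testing), and compute the intra/inter-TAD and
ATAC-overlap enrichment statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .synbreaks import _place_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "retain_significant",
    "classify_anchors",
    "filter_promoter_distal",
    "RegulatoryLandscape",
    "build_landscapes",
    "GapCutoff",
    "gap_cutoff",
    "trim_landscapes",
    "merge_distal_and_count",
    "intertad_loop_stats",
    "atac_overlap_test",
    "landscapes_to_bedpe",
]

PROMOTER_WINDOW = 2_000  # bp around the TSS for peak-to-gene assignment


def retain_significant(loops: pd.DataFrame, q_max: float = 0.1) -> pd.DataFrame:
    """Keep loops with caller FDR strictly below ``q_max``."""
    if "q" not in loops.columns:
        return loops.copy()
    return loops[loops["q"] < q_max].reset_index(drop=True)


def _anchor_types(chrom: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                  peaks: pd.DataFrame, tss: pd.DataFrame,
                  promoter_window: int) -> tuple[np.ndarray, np.ndarray]:
    """Type each anchor (promoter iff it overlaps a promoter-proximal peak)
    and attach the nearest TSS gene."""
    types = np.array(["distal"] * len(starts), dtype=object)
    genes = np.array([None] * len(starts), dtype=object)
    for c in np.unique(chrom):
        pk = peaks[peaks["chrom"] == c]
        tc = tss[tss["chrom"] == c]
        if pk.empty or tc.empty:
            continue
        tpos = tc["pos"].to_numpy()
        tgene = tc["gene_id"].to_numpy()
        # promoter-proximal peaks: peak within the promoter window of a TSS
        ps, pe = pk["start"].to_numpy(), pk["end"].to_numpy()
        prox = np.zeros(len(pk), dtype=bool)
        for i in range(len(pk)):
            d = np.minimum(np.abs(tpos - ps[i]), np.abs(tpos - pe[i]))
            d[(tpos >= ps[i]) & (tpos < pe[i])] = 0
            prox[i] = bool((d <= promoter_window).any())
        ps, pe = ps[prox], pe[prox]
        if not len(ps):
            continue
        sel = np.flatnonzero(chrom == c)
        for k in sel:
            hit = (ps < ends[k]) & (pe > starts[k])
            if not hit.any():
                continue
            types[k] = "promoter"
            mid = (starts[k] + ends[k]) // 2
            near = np.argmin(np.abs(tpos - mid))
            cand = np.abs(tpos - mid)
            if (cand == cand[near]).sum() > 1:
                logger.info("anchor matches several genes; nearest TSS wins")
            genes[k] = tgene[near]
    return types, genes


def classify_anchors(loops: pd.DataFrame, peaks: pd.DataFrame,
                     tss: pd.DataFrame,
                     promoter_window: int = PROMOTER_WINDOW) -> pd.DataFrame:
    """Type both anchors of every loop as promoter or distal.

    ``peaks`` are H3K4me3 intervals; ``tss`` has chrom/pos/gene_id. An
    anchor is promoter-type iff it overlaps a peak lying within
    ``promoter_window`` of a TSS; the gene of the nearest TSS is attached.
    Adds columns type1/gene1_assigned/type2/gene2_assigned.
    """
    out = loops.copy().reset_index(drop=True)
    t1, g1 = _anchor_types(out["chrom1"].to_numpy(), out["start1"].to_numpy(),
                           out["end1"].to_numpy(), peaks, tss, promoter_window)
    t2, g2 = _anchor_types(out["chrom2"].to_numpy(), out["start2"].to_numpy(),
                           out["end2"].to_numpy(), peaks, tss, promoter_window)
    out["type1"], out["gene1_assigned"] = t1, g1
    out["type2"], out["gene2_assigned"] = t2, g2
    return out


def filter_promoter_distal(typed: pd.DataFrame) -> pd.DataFrame:
    """Keep loops with exactly one promoter anchor, oriented so the
    promoter is anchor 1 (removes promoter-promoter and distal-distal)."""
    p1 = typed["type1"] == "promoter"
    p2 = typed["type2"] == "promoter"
    keep = typed[p1 ^ p2].copy()
    flip = keep["type2"] == "promoter"
    for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2"),
                 ("type1", "type2"), ("gene1_assigned", "gene2_assigned")):
        keep.loc[flip, [a, b]] = keep.loc[flip, [b, a]].to_numpy()
    return keep.reset_index(drop=True)


@dataclass
class RegulatoryLandscape:
    """One promoter anchor plus its retained distal anchors, in genomic order."""

    gene_id: str
    chrom: str
    promoter: tuple[int, int]
    anchors: list[tuple[int, int]] = field(default_factory=list)
    trimmed: bool = False

    def sorted_elements(self) -> list[tuple[int, int]]:
        return sorted(self.anchors + [self.promoter])

    def gaps(self) -> list[int]:
        """Distances between consecutive elements (promoter included)."""
        els = self.sorted_elements()
        return [max(b[0] - a[1], 0) for a, b in zip(els[:-1], els[1:])]

    def max_gap(self) -> int:
        g = self.gaps()
        return max(g) if g else 0


def build_landscapes(filtered: pd.DataFrame) -> list[RegulatoryLandscape]:
    """Group promoter-distal loops by promoter gene; drop landscapes with a
    single distal anchor."""
    out = []
    if filtered.empty:
        return out
    for gene, sub in filtered.groupby("gene1_assigned", sort=False):
        anchors = sorted({(int(s), int(e))
                          for s, e in zip(sub["start2"], sub["end2"])})
        if len(anchors) < 2:
            continue
        row = sub.iloc[0]
        out.append(RegulatoryLandscape(
            gene_id=str(gene), chrom=str(row["chrom1"]),
            promoter=(int(row["start1"]), int(row["end1"])), anchors=anchors))
    return out


@dataclass
class GapCutoff:
    sample_id: str
    q3: float
    iqr: float

    @property
    def cutoff(self) -> float:
        return self.q3 + 2.0 * self.iqr


def gap_cutoff(landscapes: list[RegulatoryLandscape],
               sample_id: str = "sample") -> GapCutoff:
    """Per-sample interaction-gap cutoff: Q3 + 2*IQR of the distribution of
    per-landscape biggest gaps (linear-interpolation quantiles)."""
    if not landscapes:
        raise ValueError("no landscapes: cannot derive a gap cutoff")
    biggest = np.array([ls.max_gap() for ls in landscapes], dtype=float)
    q1, q3 = np.quantile(biggest, [0.25, 0.75])  # linear interpolation
    return GapCutoff(sample_id=sample_id, q3=float(q3), iqr=float(q3 - q1))


def trim_landscapes(landscapes: list[RegulatoryLandscape],
                    cutoff: GapCutoff | float) -> list[RegulatoryLandscape]:
    """Scan outward from the promoter on each side; at the first gap
    strictly bigger than the cutoff all more-distal anchors on that side are
    discarded. Landscapes left with < 2 distal anchors are dropped.
    Idempotent at a fixed cutoff."""
    cut = cutoff.cutoff if isinstance(cutoff, GapCutoff) else float(cutoff)
    out = []
    for ls in landscapes:
        ps, pe = ls.promoter
        left = sorted([a for a in ls.anchors if a[1] <= ps], reverse=True)
        right = sorted([a for a in ls.anchors if a[0] >= pe])
        middle = [a for a in ls.anchors if a[1] > ps and a[0] < pe]

        def scan(side: list, from_pos: int, leftward: bool) -> list:
            kept = []
            prev = from_pos
            for a in side:
                gap = (prev - a[1]) if leftward else (a[0] - prev)
                if gap > cut:
                    break
                kept.append(a)
                prev = a[0] if leftward else a[1]
            return kept

        kept = middle + scan(left, ps, True) + scan(right, pe, False)
        dropped = len(kept) < len(ls.anchors)
        if len(kept) < 2:
            continue
        out.append(replace(ls, anchors=sorted(kept),
                           trimmed=ls.trimmed or dropped))
    return out


# ---------------------------------------------------------------------------
# anchor fusion and replicate count table


def _fuse(intervals: list[tuple[int, int]], fuse_distance: int) -> list[tuple[int, int]]:
    """Interval union merging neighbours with gap strictly < fuse_distance."""
    if not intervals:
        return []
    out = []
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s - cur_e < fuse_distance:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return out


def merge_distal_and_count(landscapes_by_condition: dict[str, list[RegulatoryLandscape]],
                           replicate_loops: dict[str, pd.DataFrame],
                           fuse_distance: int = 20_000) -> pd.DataFrame:
    """Union loop set over fused distal anchors, with per-replicate counts.

    Distal anchors of each promoter across conditions are fused when closer
    than ``fuse_distance`` (strict); the union loops are all (promoter gene,
    fused anchor) pairs. For every replicate loop file (promoter-distal
    typed, with a ``count`` column), supporting reads are summed over the
    replicate's loops whose distal-anchor midpoint falls in the fused
    anchor. Missing chromosomes yield zero counts (logged).
    """
    if len(replicate_loops) < 2:
        raise ValueError("need >= 2 replicates/conditions for a count table")
    per_gene: dict[str, dict] = {}
    for cond, lss in landscapes_by_condition.items():
        for ls in lss:
            g = per_gene.setdefault(ls.gene_id, {
                "chrom": ls.chrom, "promoter": ls.promoter, "anchors": []})
            g["anchors"].extend(ls.anchors)
    rows = []
    for gene, info in per_gene.items():
        fused = _fuse(sorted(info["anchors"]), fuse_distance)
        for s, e in fused:
            rows.append((gene, info["chrom"], info["promoter"][0],
                         info["promoter"][1], s, e))
    table = pd.DataFrame(rows, columns=["gene_id", "chrom", "p_start", "p_end",
                                        "a_start", "a_end"])
    for rep, loops in replicate_loops.items():
        counts = np.zeros(len(table), dtype=int)
        if "gene1_assigned" not in loops.columns:
            raise ValueError(f"replicate {rep}: loops must be promoter-distal typed")
        for i, row in table.iterrows():
            sub = loops[(loops["gene1_assigned"] == row["gene_id"])
                        & (loops["chrom2"] == row["chrom"])]
            if sub.empty:
                continue
            mid = ((sub["start2"] + sub["end2"]) // 2).to_numpy()
            inside = (mid >= row["a_start"]) & (mid < row["a_end"])
            counts[i] = int(sub["count"].to_numpy()[inside].sum())
        if not (loops["chrom2"].isin(table["chrom"])).any():
            logger.warning("replicate %s shares no chromosome with the union set", rep)
        table[rep] = counts
    return table


# ---------------------------------------------------------------------------
# enrichment statistics


def intertad_loop_stats(loops: pd.DataFrame, tads: pd.DataFrame,
                        n_shuffles: int = 1000, seed: int = 0,
                        chrom_sizes: dict[str, int] | None = None) -> dict:
    """Intra- vs inter-TAD loop classification with shuffled-TAD controls.

    A loop is inter-TAD when its span intersects more than one TAD. Each
    shuffle re-places the TAD intervals uniformly per chromosome (lengths
    preserved, no overlap) and reclassifies; the empirical p for intra-TAD
    enrichment is (r+1)/(n+1) over shuffles with at least as many intra
    loops as observed. ``chrom_sizes`` defaults to the TAD extent per
    chromosome; note that a TAD set tiling its chromosome with equal sizes
    leaves the shuffle no freedom.
    """
    rng = np.random.default_rng(seed)
    span = pd.DataFrame({
        "chrom": loops["chrom1"],
        "start": np.minimum(loops["start1"], loops["start2"]),
        "end": np.maximum(loops["end1"], loops["end2"]),
    })

    def n_intra(tad_starts: dict[str, np.ndarray], tad_ends: dict[str, np.ndarray]) -> int:
        total = 0
        for chrom, sub in span.groupby("chrom", sort=False):
            ts = tad_starts.get(chrom)
            if ts is None:
                continue
            te = tad_ends[chrom]
            s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
            hits = (ts[None, :] < e[:, None]) & (te[None, :] > s[:, None])
            total += int((hits.sum(axis=1) == 1).sum())
        return total

    ts0 = {c: s["start"].to_numpy() for c, s in tads.groupby("chrom", sort=False)}
    te0 = {c: s["end"].to_numpy() for c, s in tads.groupby("chrom", sort=False)}
    observed = n_intra(ts0, te0)
    chrom_len = {c: int(tads[tads["chrom"] == c]["end"].max()) for c in ts0}
    if chrom_sizes:
        chrom_len.update({c: int(v) for c, v in chrom_sizes.items()
                          if c in chrom_len})
    shuffle_counts = np.zeros(n_shuffles, dtype=int)
    placed = {}
    for c in ts0:
        lens = (te0[c] - ts0[c]).astype(np.int64)
        ss, se = _place_intervals(rng, lens, chrom_len[c], n_shuffles)
        placed[c] = (ss, se)
    for k in range(n_shuffles):
        shuffle_counts[k] = n_intra({c: placed[c][0][k] for c in placed},
                                    {c: placed[c][1][k] for c in placed})
    r = int((shuffle_counts >= observed).sum())
    n = len(span)
    return {
        "n_loops": n, "intra": observed, "inter": n - observed,
        "frac_intra": observed / n if n else np.nan,
        "expected_intra": float(shuffle_counts.mean()),
        "p": (r + 1) / (n_shuffles + 1), "n_shuffles": n_shuffles, "seed": seed,
    }


def atac_overlap_test(loops: pd.DataFrame, distal_peaks: pd.DataFrame,
                      chrom_sizes: dict[str, int], seed: int = 0) -> dict:
    """Are distal loop anchors enriched for distal ATAC peaks?

    2x2 chi-square: (anchor overlaps a peak?) x (real distal anchors vs
    matched random spans of the same lengths on the same chromosomes).
    """
    if distal_peaks.empty:
        raise ValueError("no peaks provided")
    rng = np.random.default_rng(seed)

    def overlaps(frame: pd.DataFrame) -> int:
        total = 0
        for chrom, sub in frame.groupby("chrom", sort=False):
            pk = distal_peaks[distal_peaks["chrom"] == chrom]
            if pk.empty:
                continue
            ps, pe = pk["start"].to_numpy(), pk["end"].to_numpy()
            s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
            total += int(((ps[None, :] < e[:, None]) & (pe[None, :] > s[:, None]))
                         .any(axis=1).sum())
        return total

    anchors = pd.DataFrame({"chrom": loops["chrom2"], "start": loops["start2"],
                            "end": loops["end2"]}).drop_duplicates()
    rand_rows = []
    for chrom, sub in anchors.groupby("chrom", sort=False):
        L = chrom_sizes.get(chrom)
        if L is None:
            continue
        lens = (sub["end"] - sub["start"]).to_numpy()
        starts = rng.integers(0, np.maximum(L - lens, 1))
        rand_rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                       "end": starts + lens}))
    rand = pd.concat(rand_rows, ignore_index=True)
    a_on = overlaps(anchors)
    r_on = overlaps(rand)
    table = np.array([[a_on, len(anchors) - a_on], [r_on, len(rand) - r_on]])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "chi2": float(chi2), "p": float(p),
            "frac_anchor_on_peak": a_on / len(anchors) if len(anchors) else np.nan,
            "frac_random_on_peak": r_on / len(rand) if len(rand) else np.nan}


def landscapes_to_bedpe(landscapes: list[RegulatoryLandscape]) -> pd.DataFrame:
    """One BEDPE row per promoter-distal anchor pair."""
    rows = []
    for ls in landscapes:
        for s, e in ls.anchors:
            rows.append((ls.chrom, ls.promoter[0], ls.promoter[1],
                         ls.chrom, s, e, ls.gene_id, ls.trimmed))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                       "start2", "end2", "gene_id", "trimmed"])


def landscapes_to_json(landscapes: list[RegulatoryLandscape], path) -> None:
    with open(path, "w") as fh:
        for ls in landscapes:
            fh.write(json.dumps({
                "gene_id": ls.gene_id, "chrom": ls.chrom,
                "promoter": list(ls.promoter),
                "anchors": [list(a) for a in ls.anchors],
                "trimmed": ls.trimmed}) + "\n")
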