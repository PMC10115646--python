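"""Synteny breaks and their relationship to TAD boundaries.

A synteny break is the junction between two adjacent alignment blocks on
the reference genome where the target chromosome, the orientation, or the
target collinearity changes; junctions attributable to scaffold ends are
flagged and excluded. Junctions from several species are coalesced into
merged break intervals with a per-species presence vector (upset-style
counting); breaks present in every non-reference species are the
lineage-derived candidate set. Each break is classified by its
edge-to-edge distance to the nearest TAD boundary — strictly closer than
50 kb counts as "at boundary", the rest are TAD-interrupting — and the
excess of at-boundary breaks is tested by a permutation scheme that
re-places the boundary intervals uniformly per chromosome (counts and
lengths preserved, no overlap), with the (r+1)/(n+1) empirical p-value.
Finally, genes inside interrupted TADs whose promoter loops across the
break are nominated as rewiring candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "blocks_from_gene_orders",
    "breaks_from_blocks",
    "MultiSpeciesBreakSet",
    "intersect_breaks",
    "boundary_distance_and_classify",
    "EnrichmentResult",
    "permutation_enrichment",
    "candidate_genes",
]


# ---------------------------------------------------------------------------
# block construction from simulated gene orders (desk-scale stand-in for
# chain/net alignment, which is consumed, not computed, on real data)


def blocks_from_gene_orders(ref_ann: pd.DataFrame, target_ann: pd.DataFrame,
                            orth: pd.DataFrame, max_skip: int = 2) -> pd.DataFrame:
    """Chain single-copy orthologues into synteny blocks.

    Walks the reference gene order and extends a block while the partner
    genes stay on one target chromosome, in a consistent orientation, and
    within ``max_skip`` target gene models of the previous partner. Returns
    the standard block table (refChrom refStart refEnd targetChrom
    targetStart targetEnd level strand endFlag).
    """
    o = orth[orth["unique"]] if "unique" in orth.columns else orth
    partner = o.drop_duplicates("gene_a").set_index("gene_a")["gene_b"]
    t = target_ann.sort_values(["chrom", "start"]).reset_index(drop=True)
    t_idx = {g: (c, i) for i, (g, c) in enumerate(zip(t["gene_id"], t["chrom"]))}
    # per-chromosome ordinal index on the target
    t["ord"] = t.groupby("chrom", sort=False).cumcount()
    t_ord = t.set_index("gene_id")[["chrom", "ord", "start", "end"]]

    rows = []
    for chrom, sub in ref_ann.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        cur = None
        for _, g in sub.iterrows():
            pg = partner.get(g["gene_id"])
            if pg is None or pg not in t_ord.index:
                continue
            tc, to, ts, te = t_ord.loc[pg]
            if cur is None:
                cur = dict(rc=chrom, rs=g["start"], re=g["end"], tc=tc,
                           lo=to, hi=to, ts=ts, te=te, dir=0)
                continue
            step = to - (cur["hi"] if cur["dir"] >= 0 else cur["lo"])
            ok = tc == cur["tc"]
            if ok:
                if cur["dir"] == 0:
                    ok = abs(step) <= max_skip + 1 and step != 0
                    newdir = 1 if step > 0 else -1
                else:
                    newdir = cur["dir"]
                    ok = 0 < step * newdir <= max_skip + 1
            if ok:
                cur["dir"] = newdir
                cur["re"] = g["end"]
                cur["lo"], cur["hi"] = min(cur["lo"], to), max(cur["hi"], to)
                cur["ts"], cur["te"] = min(cur["ts"], ts), max(cur["te"], te)
            else:
                rows.append(cur)
                cur = dict(rc=chrom, rs=g["start"], re=g["end"], tc=tc,
                           lo=to, hi=to, ts=ts, te=te, dir=0)
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame([{
        "refChrom": r["rc"], "refStart": int(r["rs"]), "refEnd": int(r["re"]),
        "targetChrom": r["tc"], "targetStart": int(r["ts"]),
        "targetEnd": int(r["te"]), "level": 1,
        "strand": "-" if r["dir"] < 0 else "+", "endFlag": False,
    } for r in rows])
    return out


# ---------------------------------------------------------------------------
# junctions


def breaks_from_blocks(blocks: pd.DataFrame,
                       scaffold_ends: pd.DataFrame | None = None,
                       species: str = "query",
                       end_margin: int = 50_000,
                       collinear_gap: int = 1_000_000) -> pd.DataFrame:
    """Junctions between adjacent synteny blocks on the reference.

    A junction is emitted at the midpoint of the inter-block gap wherever
    the target chromosome or orientation changes, or the target coordinates
    jump by more than ``collinear_gap`` (collinearity loss). Junctions
    within ``end_margin`` of a scaffold end (or flanked by an
    ``endFlag``-marked block) are flagged ``excluded`` with a reason.
    Overlapping same-level blocks are an input error.
    """
    rows = []
    for chrom, sub in blocks.groupby("refChrom", sort=False):
        sub = sub.sort_values("refStart").reset_index(drop=True)
        for level, lsub in sub.groupby("level"):
            s = lsub.sort_values("refStart")
            bad = s["refStart"].to_numpy()[1:] < s["refEnd"].to_numpy()[:-1]
            if bad.any():
                offenders = s.iloc[1:][bad][["refStart", "refEnd"]].to_records(index=False)
                raise ValueError(f"{chrom} level {level}: overlapping blocks {list(offenders)}")
        ends_here = None
        if scaffold_ends is not None:
            e = scaffold_ends[scaffold_ends["chrom"] == chrom]
            ends_here = e[["start", "end"]].to_numpy() if len(e) else None
        for i in range(len(sub) - 1):
            a, b = sub.iloc[i], sub.iloc[i + 1]
            is_junction = (a["targetChrom"] != b["targetChrom"]
                           or a["strand"] != b["strand"])
            if not is_junction:
                gap = (b["targetStart"] - a["targetEnd"] if a["strand"] == "+"
                       else a["targetStart"] - b["targetEnd"])
                is_junction = gap < 0 or gap > collinear_gap
            if not is_junction:
                continue
            pos = int((a["refEnd"] + b["refStart"]) // 2)
            excluded, reason = False, ""
            if bool(a.get("endFlag", False)) or bool(b.get("endFlag", False)):
                excluded, reason = True, "flanking block at scaffold end"
            elif ends_here is not None and len(ends_here):
                d = np.maximum(np.maximum(ends_here[:, 0] - pos,
                                          pos - ends_here[:, 1] + 1), 0).min()
                if d < end_margin:
                    excluded, reason = True, "near scaffold end"
            rows.append((chrom, pos, species,
                         a["targetChrom"], b["targetChrom"], excluded, reason))
    return pd.DataFrame(rows, columns=["chrom", "pos", "species", "target_left",
                                       "target_right", "excluded", "reason"])


# ---------------------------------------------------------------------------
# cross-species coalescing


@dataclass
class MultiSpeciesBreakSet:
    """Merged break intervals with per-species presence and upset counts."""

    intervals: pd.DataFrame          # chrom start end + one bool column per species
    species: list[str]
    upset: dict[frozenset, int] = field(default_factory=dict)

    @property
    def shared_all(self) -> pd.DataFrame:
        """Intervals present in every species (candidate lineage-derived set
        when the input species are the non-reference clade)."""
        mask = np.ones(len(self.intervals), dtype=bool)
        for sp in self.species:
            mask &= self.intervals[sp].to_numpy()
        return self.intervals[mask].reset_index(drop=True)


def intersect_breaks(per_species: dict[str, pd.DataFrame],
                     merge_window: int = 100_000) -> MultiSpeciesBreakSet:
    """Coalesce per-species junctions into disjoint merged intervals.

    Junctions (non-excluded) are expanded to ±``merge_window``/2 and the
    union is partitioned into maximal connected intervals; each carries a
    presence flag per species and the upset counter tallies each presence
    combination.
    """
    if len(per_species) < 2:
        raise ValueError("need >= 2 species to intersect breaks")
    species = []
    pieces = []
    for sp, df in per_species.items():
        if df is None or df.empty:
            logger.warning("species %s has no junctions; dropped", sp)
            continue
        d = df[~df["excluded"]] if "excluded" in df.columns else df
        half = merge_window // 2
        pieces.append(pd.DataFrame({
            "chrom": d["chrom"], "start": d["pos"] - half,
            "end": d["pos"] + half, "species": sp}))
        species.append(sp)
    allp = pd.concat(pieces, ignore_index=True)
    rows = []
    for chrom, sub in allp.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        cur_s, cur_e, members = None, None, set()
        for _, r in sub.iterrows():
            if cur_s is None or r["start"] > cur_e:
                if cur_s is not None:
                    rows.append((chrom, int(cur_s), int(cur_e), frozenset(members)))
                cur_s, cur_e, members = r["start"], r["end"], {r["species"]}
            else:
                cur_e = max(cur_e, r["end"])
                members.add(r["species"])
        if cur_s is not None:
            rows.append((chrom, int(cur_s), int(cur_e), frozenset(members)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "members"])
    for sp in species:
        out[sp] = out["members"].apply(lambda m: sp in m)
    upset: dict[frozenset, int] = {}
    for m in out["members"]:
        upset[m] = upset.get(m, 0) + 1
    return MultiSpeciesBreakSet(intervals=out.drop(columns="members"),
                                species=species, upset=upset)


# ---------------------------------------------------------------------------
# boundary distance and classification


def _interval_distances(bstart: np.ndarray, bend: np.ndarray,
                        istart: np.ndarray, iend: np.ndarray) -> np.ndarray:
    """Edge-to-edge distance from each query interval to the nearest of a
    sorted set of intervals (0 if overlapping), via searchsorted."""
    if len(istart) == 0:
        return np.full(len(bstart), np.inf)
    order = np.argsort(istart)
    istart, iend = istart[order], iend[order]
    idx = np.searchsorted(istart, bstart)
    d = np.full(len(bstart), np.inf)
    for off in (-1, 0, 1):
        k = np.clip(idx + off, 0, len(istart) - 1)
        cand = np.maximum(np.maximum(istart[k] - bend, bstart - iend[k]), 0)
        d = np.minimum(d, cand)
    return d


def boundary_distance_and_classify(breaks: pd.DataFrame, boundaries: pd.DataFrame,
                                   threshold: int = 50_000) -> pd.DataFrame:
    """Distance of each break to its nearest TAD boundary, and the
    near-boundary (< threshold, strict) vs TAD-interrupting classification.

    Breaks may be points (``pos``) or intervals (``start``/``end``).
    Chromosomes absent from the boundary set get infinite distance and are
    classed interrupting (logged).
    """
    br = breaks.copy().reset_index(drop=True)
    if "pos" in br.columns and "start" not in br.columns:
        br["start"], br["end"] = br["pos"], br["pos"] + 1
    dist = np.full(len(br), np.inf)
    for chrom, sub in br.groupby("chrom", sort=False):
        b = boundaries[boundaries["chrom"] == chrom]
        if b.empty:
            logger.info("chromosome %s absent from boundary set", chrom)
            continue
        dist[sub.index] = _interval_distances(
            sub["start"].to_numpy(), sub["end"].to_numpy() - 1,
            b["start"].to_numpy(), b["end"].to_numpy() - 1)
    br["boundary_distance"] = dist
    br["at_boundary"] = dist < threshold
    br["class"] = np.where(br["at_boundary"], "near-boundary", "interrupting")
    return br


# ---------------------------------------------------------------------------
# permutation enrichment


@dataclass
class EnrichmentResult:
    observed: int
    expected_mean: float
    expected_median: float
    shuffle_counts: np.ndarray
    p: float
    n_shuffles: int
    threshold: int
    seed: int
    mode: str

    @property
    def ratio(self) -> float:
        return self.observed / self.expected_mean if self.expected_mean else np.inf


def _place_intervals(rng: np.random.Generator, lengths: np.ndarray,
                     chrom_len: int, n_shuffles: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform non-overlapping placement of intervals of fixed lengths.

    Draws the free space between intervals from a uniform simplex (sorted
    uniforms), permuting interval order each shuffle. Returns (starts, ends)
    arrays of shape (n_shuffles, n); starts are sorted within each row.
    """
    n = len(lengths)
    free = chrom_len - lengths.sum()
    if free < 0:
        raise ValueError("boundary set too dense to shuffle without overlap")
    cuts = np.sort(rng.random((n_shuffles, n)), axis=1) * free
    perm = np.argsort(rng.random((n_shuffles, n)), axis=1)
    lperm = lengths[perm]
    starts = cuts + np.concatenate(
        [np.zeros((n_shuffles, 1)), np.cumsum(lperm[:, :-1], axis=1)], axis=1)
    starts = np.floor(starts).astype(np.int64)
    return starts, starts + lperm


def _near_counts(bstart: np.ndarray, bend: np.ndarray,
                 istarts: np.ndarray, iends: np.ndarray,
                 threshold: int) -> np.ndarray:
    """Per shuffle row: number of query intervals strictly closer than
    ``threshold`` to any placed interval. Shapes: queries (k,), rows (S,n)."""
    # (S, n, k) broadcast; chunked by caller if large
    d = np.maximum(
        np.maximum(istarts[:, :, None] - bend[None, None, :],
                   bstart[None, None, :] - iends[:, :, None] + 1), 0)
    return (d.min(axis=1) < threshold).sum(axis=1)


def permutation_enrichment(breaks: pd.DataFrame, boundaries: pd.DataFrame,
                           chrom_sizes: dict[str, int], threshold: int = 50_000,
                           n_shuffles: int = 1000, seed: int = 0,
                           mode: str = "boundaries",
                           chunk: int | None = None) -> EnrichmentResult:
    """Empirical enrichment of breaks near TAD boundaries.

    Each shuffle re-places either the boundary intervals
    (``mode="boundaries"``, the default, mirroring shuffled-boundary
    controls) or the break positions (``mode="breaks"``, the random-break
    null) uniformly per chromosome, preserving counts and lengths with no
    overlap, then counts breaks strictly closer than ``threshold`` to a
    boundary. p = (r+1)/(n+1) where r is the number of shuffles reaching
    the observed count, so p >= 1/(n_shuffles+1).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    classified = boundary_distance_and_classify(breaks, boundaries, threshold)
    observed = int(classified["at_boundary"].sum())

    totals = np.zeros(n_shuffles, dtype=np.int64)
    br = breaks.copy()
    if "pos" in br.columns and "start" not in br.columns:
        br["start"], br["end"] = br["pos"], br["pos"] + 1
    for chrom, L in chrom_sizes.items():
        bsub = br[br["chrom"] == chrom]
        bo = boundaries[boundaries["chrom"] == chrom]
        if bsub.empty or bo.empty:
            continue
        qs = bsub["start"].to_numpy()
        qe = bsub["end"].to_numpy() - 1
        lens = (bo["end"] - bo["start"]).to_numpy()
        fs = bo["start"].to_numpy()
        fe = bo["end"].to_numpy() - 1
        point_breaks = bool(np.all(qe - qs <= 0))
        # keep the (shuffles x boundaries x breaks) broadcast under ~2e7 cells
        step = chunk or max(1, int(2e7 / max(len(lens) * len(qs), 1)))
        done = 0
        while done < n_shuffles:
            m = min(step, n_shuffles - done) if not (mode == "boundaries"
                                                     and point_breaks) \
                else n_shuffles - done
            if mode == "boundaries":
                ss, se = _place_intervals(rng, lens, int(L), m)
                if point_breaks:
                    totals[done:done + m] += _union_window_counts(
                        np.sort(qs), ss, se, threshold)
                else:
                    totals[done:done + m] += _near_counts(qs, qe, ss, se - 1,
                                                          threshold)
            elif mode == "breaks":
                pos = rng.integers(0, int(L), size=(m, len(bsub)))
                totals[done:done + m] += _near_counts_points(pos, fs, fe, threshold)
            else:
                raise ValueError(f"unknown shuffle mode {mode!r}")
            done += m
    r = int((totals >= observed).sum())
    p = (r + 1) / (n_shuffles + 1)
    return EnrichmentResult(
        observed=observed, expected_mean=float(totals.mean()),
        expected_median=float(np.median(totals)), shuffle_counts=totals,
        p=float(p), n_shuffles=n_shuffles, threshold=threshold, seed=seed,
        mode=mode)


def _union_window_counts(points: np.ndarray, starts: np.ndarray,
                         ends: np.ndarray, threshold: int) -> np.ndarray:
    """Per shuffle row, count sorted points strictly closer than
    ``threshold`` to any interval, by counting inside the union of the
    near-windows [start - threshold + 1, end + threshold - 1).

    Rows of ``starts``/``ends`` must be sorted (as `_place_intervals`
    returns them); overlapping windows are de-overlapped with a running
    maximum so no point is counted twice. O(rows * n * log k).
    """
    ws = starts - (threshold - 1)
    we = ends + (threshold - 1)
    prev = np.concatenate([np.full((ws.shape[0], 1), np.iinfo(np.int64).min),
                           np.maximum.accumulate(we, axis=1)[:, :-1]], axis=1)
    eff = np.minimum(np.maximum(ws, prev), we)
    hi = np.searchsorted(points, we, side="left")
    lo = np.searchsorted(points, eff, side="left")
    return (hi - lo).sum(axis=1)


def _near_counts_points(points: np.ndarray, fstart: np.ndarray,
                        fend: np.ndarray, threshold: int) -> np.ndarray:
    """points (S,k) vs fixed sorted intervals: count per row within threshold."""
    order = np.argsort(fstart)
    fs, fe = fstart[order], fend[order]
    idx = np.searchsorted(fs, points)
    d = np.full(points.shape, np.inf)
    for off in (-1, 0, 1):
        k = np.clip(idx + off, 0, len(fs) - 1)
        d = np.minimum(d, np.maximum(np.maximum(fs[k] - points, points - fe[k]), 0))
    return (d < threshold).sum(axis=1)


# ---------------------------------------------------------------------------
# candidate genes in interrupted TADs


def candidate_genes(interrupting: pd.DataFrame, tads: pd.DataFrame,
                    genes: pd.DataFrame, loops: pd.DataFrame) -> pd.DataFrame:
    """Genes of TADs containing each interrupting break, with the subset
    whose promoter loop crosses the break flagged as candidates.

    ``loops`` must carry a promoter gene per loop (``gene_id`` column) and
    anchor coordinates; a loop crosses a break when its two anchor midpoints
    lie on opposite sides of the break position. Returns one row per
    (break, gene) with a ``candidate`` flag.
    """
    rows = []
    for bi, brk in interrupting.reset_index(drop=True).iterrows():
        chrom = brk["chrom"]
        pos = int(brk["pos"]) if "pos" in brk.index and pd.notna(brk.get("pos")) \
            else int((brk["start"] + brk["end"]) // 2)
        t = tads[(tads["chrom"] == chrom) & (tads["start"] <= pos)
                 & (pos < tads["end"])]
        if t.empty:
            logger.info("break %s:%d outside all TADs", chrom, pos)
            continue
        t0 = t.iloc[0]
        in_tad = genes[(genes["chrom"] == chrom) & (genes["start"] < t0["end"])
                       & (genes["end"] > t0["start"])]
        lsub = loops[loops["chrom1"] == chrom]
        m1 = (lsub["start1"] + lsub["end1"]) // 2
        m2 = (lsub["start2"] + lsub["end2"]) // 2
        crossing = lsub[((m1 < pos) & (m2 > pos)) | ((m2 < pos) & (m1 > pos))]
        crossing_genes = set(crossing["gene_id"]) if "gene_id" in crossing.columns else set()
        for g in in_tad["gene_id"]:
            rows.append((bi, chrom, pos, g, g in crossing_genes))
    return pd.DataFrame(rows, columns=["break_id", "chrom", "pos", "gene_id",
                                       "candidate"])
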