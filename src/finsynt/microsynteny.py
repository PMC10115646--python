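"""Microsyntenic gene pairs and their TAD co-residence.

For every pair of consecutive genes in the reference genome, the pair is
called conserved in a comparison species when both orthologues exist, lie
on one chromosome, and are separated by at most ``max_intervening``
annotated gene models (default 4); a pair is conserved overall when it is
conserved in every comparison species. Conserved pairs are then tested for
sharing a TAD more often than other consecutive pairs (2x2 Pearson
chi-square on the intergenic interval overlapping no boundary), and TADs
with vs without conserved pairs are compared on size, distal peak count
and loop count with two-sided Mann-Whitney U tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "consecutive_pairs",
    "conservation_calls",
    "tad_sharing_test",
    "classify_and_compare_tads",
]


def consecutive_pairs(ann: pd.DataFrame) -> pd.DataFrame:
    """All pairs of consecutive genes per chromosome, with the intergenic
    interval [end of gene 1, start of gene 2) (empty-flagged if the genes
    overlap). n_genes - n_chromosomes rows."""
    rows = []
    for chrom, sub in ann.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        for i in range(len(sub) - 1):
            g1, g2 = sub.loc[i], sub.loc[i + 1]
            s, e = int(g1["end"]), int(g2["start"])
            rows.append((f"{chrom}:{i}", g1["gene_id"], g2["gene_id"], chrom,
                         min(s, e), max(s, e), e <= s))
    return pd.DataFrame(rows, columns=["pair_id", "gene_1", "gene_2", "chrom",
                                       "inter_start", "inter_end", "empty_interval"])


def _ortholog_map(orth: pd.DataFrame) -> dict[str, list[str]]:
    m: dict[str, list[str]] = {}
    for a, b in zip(orth["gene_a"], orth["gene_b"]):
        m.setdefault(a, []).append(b)
    return m


def conservation_calls(pairs: pd.DataFrame,
                       orthologs: dict[str, pd.DataFrame],
                       other_anns: dict[str, pd.DataFrame],
                       max_intervening: int = 4) -> pd.DataFrame:
    """Conservation of each consecutive pair in each comparison species.

    A pair is conserved in species s iff some orthologue of gene 1 and some
    orthologue of gene 2 lie on the same chromosome of s with at most
    ``max_intervening`` annotated genes between them (ambiguous orthology is
    resolved optimistically over all combinations, logged). ``overall`` is
    the AND over species; ``testable`` marks pairs with orthologues present
    in every species.
    """
    ord_maps = {}
    for sp, ann in other_anns.items():
        a = ann.sort_values(["chrom", "start"]).reset_index(drop=True)
        a["ord"] = a.groupby("chrom", sort=False).cumcount()
        ord_maps[sp] = a.set_index("gene_id")[["chrom", "ord"]]
    orth_maps = {sp: _ortholog_map(o) for sp, o in orthologs.items()}

    out = pairs.copy()
    n_ambig = 0
    for sp in other_anns:
        om, ords = orth_maps[sp], ord_maps[sp]
        conserved, counts, testable = [], [], []
        for g1, g2 in zip(pairs["gene_1"], pairs["gene_2"]):
            o1 = [g for g in om.get(g1, []) if g in ords.index]
            o2 = [g for g in om.get(g2, []) if g in ords.index]
            testable.append(bool(o1) and bool(o2))
            if len(o1) > 1 or len(o2) > 1:
                n_ambig += 1
            best = None
            for a in o1:
                ca, ia = ords.loc[a]
                for b in o2:
                    cb, ib = ords.loc[b]
                    if ca != cb:
                        continue
                    between = abs(int(ia) - int(ib)) - 1
                    best = between if best is None else min(best, between)
            conserved.append(best is not None and best <= max_intervening)
            counts.append(best if best is not None else -1)
        out[f"conserved_{sp}"] = conserved
        out[f"intervening_{sp}"] = counts
        out[f"testable_{sp}"] = testable
    if n_ambig:
        logger.info("conservation_calls: %d genes with multiple orthologues "
                    "(optimistic resolution)", n_ambig)
    csp = [f"conserved_{sp}" for sp in other_anns]
    tsp = [f"testable_{sp}" for sp in other_anns]
    out["conserved"] = out[csp].all(axis=1)
    out["testable"] = out[tsp].all(axis=1)
    return out


def tad_sharing_test(calls: pd.DataFrame, boundaries: pd.DataFrame,
                     tads: pd.DataFrame | None = None,
                     mode: str = "boundary_overlap",
                     yates: bool = False) -> dict:
    """Do conserved pairs share TADs more often than other consecutive pairs?

    A pair shares a TAD when its intergenic interval overlaps no boundary
    interval (``mode="boundary_overlap"``, the default) or, alternatively,
    when the interval lies inside a single TAD (``mode="within_tad"``,
    requires ``tads``). Pearson chi-square on the 2x2 (conserved x shares)
    table, without Yates correction unless requested.

    Returns proportions for both classes (with counts over all non-conserved
    pairs and over the testable subset) plus chi2/p.
    """
    shares = np.ones(len(calls), dtype=bool)
    for chrom, sub in calls.groupby("chrom", sort=False):
        if mode == "boundary_overlap":
            b = boundaries[boundaries["chrom"] == chrom]
            if b.empty:
                continue
            bs, be = b["start"].to_numpy(), b["end"].to_numpy()
            for i, (s, e) in zip(sub.index, zip(sub["inter_start"], sub["inter_end"])):
                shares[calls.index.get_loc(i)] = not bool(
                    ((bs < max(e, s + 1)) & (be > s)).any())
        elif mode == "within_tad":
            t = tads[tads["chrom"] == chrom]
            ts, te = t["start"].to_numpy(), t["end"].to_numpy()
            for i, (s, e) in zip(sub.index, zip(sub["inter_start"], sub["inter_end"])):
                inside = ((ts <= s) & (max(e, s + 1) <= te)).any()
                shares[calls.index.get_loc(i)] = bool(inside)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    c = calls["conserved"].to_numpy()
    table = np.array([[int((c & shares).sum()), int((c & ~shares).sum())],
                      [int((~c & shares).sum()), int((~c & ~shares).sum())]])
    if table.sum() == 0 or (table.sum(axis=1) == 0).any():
        chi2, p = np.nan, np.nan
    elif (table.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    n_cons = int(c.sum())
    n_other = int((~c).sum())
    testable = calls["testable"].to_numpy() if "testable" in calls.columns \
        else np.ones(len(calls), dtype=bool)
    n_other_testable = int((~c & testable).sum())
    return {
        "table": table,
        "prop_conserved": table[0, 0] / n_cons if n_cons else np.nan,
        "prop_other": table[1, 0] / n_other if n_other else np.nan,
        "prop_other_testable": (int((~c & testable & shares).sum()) / n_other_testable
                                if n_other_testable else np.nan),
        "n_conserved": n_cons, "n_other": n_other,
        "n_other_testable": n_other_testable,
        "chi2": float(chi2), "p": float(p), "mode": mode, "yates": yates,
    }


def classify_and_compare_tads(tads: pd.DataFrame, calls: pd.DataFrame,
                              distal_peaks: pd.DataFrame,
                              loops: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Split TADs by presence of a conserved pair and compare size, distal
    peak count and loop count between the classes (two-sided Mann-Whitney U,
    normal approximation with tie correction).

    A TAD contains a pair when the pair's intergenic interval overlaps the
    TAD; peaks count by midpoint containment; loops by both anchor midpoints
    inside the TAD. Tests are skipped (logged) when a class is empty.
    """
    t = tads.reset_index(drop=True).copy()
    t["tad_id"] = np.arange(len(t))
    t["size"] = t["end"] - t["start"]
    t["contains_conserved_pair"] = False
    cons = calls[calls["conserved"]]
    for chrom, sub in t.groupby("chrom", sort=False):
        cc = cons[cons["chrom"] == chrom]
        if cc.empty:
            continue
        s = cc["inter_start"].to_numpy()
        e = np.maximum(cc["inter_end"].to_numpy(), s + 1)
        for i in sub.index:
            ts, te = t.loc[i, "start"], t.loc[i, "end"]
            if ((s < te) & (e > ts)).any():
                t.loc[i, "contains_conserved_pair"] = True

    def count_inside(points: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(t), dtype=int)
        for chrom, sub in t.groupby("chrom", sort=False):
            pp = points[points["chrom"] == chrom]
            if pp.empty:
                continue
            mid = ((pp["start"] + pp["end"]) // 2).to_numpy()
            for i in sub.index:
                out[i] = int(((mid >= t.loc[i, "start"]) & (mid < t.loc[i, "end"])).sum())
        return out

    t["distal_peaks"] = count_inside(distal_peaks)
    loop_pts = pd.DataFrame({
        "chrom": loops["chrom1"],
        "start": np.minimum((loops["start1"] + loops["end1"]) // 2,
                            (loops["start2"] + loops["end2"]) // 2),
        "end": np.maximum((loops["start1"] + loops["end1"]) // 2,
                          (loops["start2"] + loops["end2"]) // 2) + 1,
    }) if len(loops) else pd.DataFrame(columns=["chrom", "start", "end"])
    # a loop counts for a TAD when its whole span sits inside it
    lc = np.zeros(len(t), dtype=int)
    for chrom, sub in t.groupby("chrom", sort=False):
        lp = loop_pts[loop_pts["chrom"] == chrom]
        if lp.empty:
            continue
        ls, le = lp["start"].to_numpy(), lp["end"].to_numpy()
        for i in sub.index:
            lc[i] = int(((ls >= t.loc[i, "start"]) & (le <= t.loc[i, "end"])).sum())
    t["loops"] = lc

    results = {}
    a = t[t["contains_conserved_pair"]]
    b = t[~t["contains_conserved_pair"]]
    for feature in ("size", "distal_peaks", "loops"):
        if a.empty or b.empty:
            logger.warning("one TAD class empty; %s test skipped", feature)
            results[feature] = {"U": np.nan, "p": np.nan, "skipped": True}
            continue
        U, p = stats.mannwhitneyu(a[feature], b[feature], alternative="two-sided",
                                  method="asymptotic")
        results[feature] = {"U": float(U), "p": float(p), "skipped": False,
                            "median_conserved": float(a[feature].median()),
                            "median_other": float(b[feature].median())}
    return t, results
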