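"""Ancestral linkage groups, WGD segment assignment and gene retention.

The macrosynteny logic: chromosomes of two species that descend from the
same ancestral chordate linkage group (CLG) share an excess of single-copy
orthologues. For every chromosome pair a 2x2 contingency table over the
single-copy orthologue set is tested with a one-sided Fisher exact test
(enrichment), Benjamini-Hochberg corrected across all pairs; a query
chromosome (or sub-chromosomal run of genes, to handle fusions) then
inherits the CLG — and the 1R/2R copy labels, when the reference is a
labelled post-duplication genome — of its most significant enriched
partner. Per-(CLG, 2R-copy) retention rates quantify the alpha/beta loss
asymmetry, and a 20-gene windowed CLG-fraction track paints chromosomes by
ancestral origin.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simgenome import AncestralGenome, SpeciesGenome

logger = logging.getLogger(__name__)

__all__ = [
    "reciprocal_best_hits",
    "chrom_pair_enrichment",
    "assign_segments",
    "retention_rates",
    "clg_fraction_track",
]


def reciprocal_best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Mutual-best-scoring pairs from a two-directional similarity hit table.

    ``hits`` columns: species_a gene_a species_b gene_b score. Ties are
    broken deterministically: highest score first, then lexicographically
    smaller partner id. Output is symmetric in the two species and carries
    ``unique=True`` (RBH pairs are single-copy by construction).
    """
    species = sorted(set(hits["species_a"]) | set(hits["species_b"]))
    if len(species) != 2:
        raise ValueError(f"expected exactly two species, got {species}")
    sa, sb = species
    fwd = hits[(hits["species_a"] == sa) & (hits["species_b"] == sb)]
    rev = hits[(hits["species_a"] == sb) & (hits["species_b"] == sa)]
    if fwd.empty or rev.empty:
        raise ValueError(f"missing hit direction for species pair ({sa}, {sb})")

    def best(frame: pd.DataFrame) -> dict[str, str]:
        f = frame.sort_values(["gene_a", "score", "gene_b"],
                              ascending=[True, False, True])
        return f.drop_duplicates("gene_a").set_index("gene_a")["gene_b"].to_dict()

    best_fwd = best(fwd)
    best_rev = best(rev)
    rows = [(sa, a, sb, b) for a, b in best_fwd.items() if best_rev.get(b) == a]
    out = pd.DataFrame(rows, columns=["species_a", "gene_a", "species_b", "gene_b"])
    scores = fwd.set_index(["gene_a", "gene_b"])["score"]
    out["score"] = [scores.get((a, b), np.nan)
                    for a, b in zip(out["gene_a"], out["gene_b"])]
    out["unique"] = True
    return out.sort_values("gene_a").reset_index(drop=True)


def _chrom_map(ann: pd.DataFrame) -> pd.Series:
    return ann.set_index("gene_id")["chrom"]


def chrom_pair_enrichment(orth: pd.DataFrame, ann_a: pd.DataFrame,
                          ann_b: pd.DataFrame, alpha: float = 0.05
                          ) -> pd.DataFrame:
    """One-sided Fisher enrichment of shared single-copy orthologues for
    every chromosome pair, BH-corrected across all pairs.

    For chromosomes (A_i, B_j) the 2x2 table partitions the orthologue set
    by (gene on A_i?) x (gene on B_j?). Columns: chrom_a chrom_b shared
    a_only b_only neither odds_ratio p q significant.
    """
    orth = orth[orth.get("unique", True) == True] if "unique" in orth.columns else orth
    if orth.empty:
        return pd.DataFrame(columns=["chrom_a", "chrom_b", "shared", "a_only",
                                     "b_only", "neither", "odds_ratio", "p", "q",
                                     "significant"])
    ca = _chrom_map(ann_a).reindex(orth["gene_a"]).to_numpy()
    cb = _chrom_map(ann_b).reindex(orth["gene_b"]).to_numpy()
    if pd.isna(ca).any() or pd.isna(cb).any():
        raise ValueError("orthologue gene absent from an annotation")
    table = pd.crosstab(pd.Series(ca, name="chrom_a"), pd.Series(cb, name="chrom_b"))
    total = table.to_numpy().sum()
    rows = []
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    for a in table.index:
        for b in table.columns:
            shared = int(table.loc[a, b])
            a_only = int(row_sums[a] - shared)
            b_only = int(col_sums[b] - shared)
            neither = int(total - shared - a_only - b_only)
            odds, p = stats.fisher_exact([[shared, a_only], [b_only, neither]],
                                         alternative="greater")
            rows.append((a, b, shared, a_only, b_only, neither, odds, p))
    out = pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "shared", "a_only",
                                      "b_only", "neither", "odds_ratio", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out


def assign_segments(enrich: pd.DataFrame, reference_labels: pd.DataFrame,
                    orth: pd.DataFrame | None = None,
                    ann_query: pd.DataFrame | None = None,
                    ann_ref: pd.DataFrame | None = None,
                    min_run: int = 10) -> pd.DataFrame:
    """Label query chromosomes (or sub-chromosomal runs) from a labelled
    reference via enrichment partners.

    ``enrich`` comes from :func:`chrom_pair_enrichment` with the query as
    species A and the labelled reference as species B.
    ``reference_labels`` maps reference chromosomes to (clg, r1, r2) —
    ``r1``/``r2`` may be ``unassigned`` for an unduplicated reference.

    Each query chromosome inherits the labels of its most significant
    enriched partner (smallest q, ties by largest shared count; an exact
    tie leaves the chromosome unassigned with a logged conflict). When the
    per-gene tables are supplied, maximal runs of >= ``min_run`` consecutive
    query genes whose orthologues lie on a common significant partner are
    labelled separately, so fused chromosomes resolve into their parts.

    Returns chrom/start/end/clg/r1/r2 rows (start/end cover the labelled
    run, or the whole chromosome when per-gene data are absent).
    """
    ref = reference_labels.set_index("chrom")
    sig = enrich[enrich["significant"]]
    rows = []
    have_genes = orth is not None and ann_query is not None and ann_ref is not None
    gene_partner = None
    if have_genes:
        ref_chrom = _chrom_map(ann_ref)
        gene_partner = pd.DataFrame({
            "gene": orth["gene_a"].to_numpy(),
            "partner": ref_chrom.reindex(orth["gene_b"]).to_numpy(),
        }).drop_duplicates("gene").set_index("gene")["partner"]

    for chrom_a, sub in enrich.groupby("chrom_a", sort=False):
        s = sub[sub["significant"]]
        if s.empty:
            rows.append((chrom_a, 0, _chrom_extent(ann_query, chrom_a),
                         "unassigned", "unassigned", "unassigned"))
            continue
        s = s.sort_values(["q", "shared"], ascending=[True, False])
        top = s.iloc[0]
        tie = s[(s["q"] == top["q"]) & (s["shared"] == top["shared"])]
        if len(tie) > 1:
            logger.warning("%s: conflicting equally-significant partners %s; unassigned",
                           chrom_a, list(tie["chrom_b"]))
            rows.append((chrom_a, 0, _chrom_extent(ann_query, chrom_a),
                         "unassigned", "unassigned", "unassigned"))
            continue
        sig_partners = set(s["chrom_b"])
        if have_genes:
            genes = (ann_query[ann_query["chrom"] == chrom_a]
                     .sort_values("start").reset_index(drop=True))
            partners = gene_partner.reindex(genes["gene_id"]).to_numpy(dtype=object)
            partners = np.array([p if p in sig_partners else None for p in partners],
                                dtype=object)
            rows.extend(_runs_to_segments(chrom_a, genes, partners, ref, min_run,
                                          fallback=top["chrom_b"]))
        else:
            rows.append((chrom_a, 0, 0) + _labels_of(ref, top["chrom_b"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "clg", "r1", "r2"])


def _chrom_extent(ann: pd.DataFrame | None, chrom: str) -> int:
    if ann is None:
        return 0
    sub = ann[ann["chrom"] == chrom]
    return int(sub["end"].max()) if len(sub) else 0


def _labels_of(ref: pd.DataFrame, chrom_b: str) -> tuple[str, str, str]:
    if chrom_b not in ref.index:
        return ("unassigned", "unassigned", "unassigned")
    row = ref.loc[chrom_b]
    return (str(row["clg"]), str(row.get("r1", "unassigned")),
            str(row.get("r2", "unassigned")))


def _runs_to_segments(chrom: str, genes: pd.DataFrame, partners: np.ndarray,
                      ref: pd.DataFrame, min_run: int, fallback: str) -> list:
    """Maximal runs of consecutive genes sharing a significant partner.

    Genes without an orthologue (no partner) are transparent: they neither
    break nor lengthen a run.
    """
    rows = []
    keep = np.flatnonzero(partners != None)  # noqa: E711 (object array)
    sub = genes.iloc[keep]
    pp = partners[keep]
    n = len(sub)
    i = 0
    while i < n:
        p = pp[i]
        j = i
        while j < n and pp[j] == p:
            j += 1
        if (j - i) >= min_run:
            start = int(sub.iloc[i]["start"])
            end = int(sub.iloc[j - 1]["end"])
            rows.append((chrom, start, end) + _labels_of(ref, p))
        i = j
    if not rows:  # no run long enough: whole chromosome from the top partner
        rows.append((chrom, int(genes["start"].min()), int(genes["end"].max()))
                    + _labels_of(ref, fallback))
    return rows


def retention_rates(orth: pd.DataFrame, segments: pd.DataFrame,
                    ancestor: AncestralGenome,
                    ann_query: pd.DataFrame) -> pd.DataFrame:
    """Per (CLG, 2R copy) fraction of ancestral genes with a surviving
    descendant on a segment of that label.

    ``orth`` maps ancestral genes (species A) to query genes (species B);
    ``segments`` are labelled query segments. Genes on unassigned segments
    are excluded (logged).
    """
    seg = segments[(segments["clg"] != "unassigned")
                   & (segments["r2"] != "unassigned")]
    loc = orth[["gene_a", "gene_b"]].merge(
        ann_query[["gene_id", "chrom", "start"]],
        left_on="gene_b", right_on="gene_id", how="inner")
    seg_clg = np.full(len(loc), None, dtype=object)
    seg_r1 = np.full(len(loc), None, dtype=object)
    seg_r2 = np.full(len(loc), None, dtype=object)
    for _, srow in seg.iterrows():
        hit = ((loc["chrom"] == srow["chrom"]) & (loc["start"] >= srow["start"])
               & (loc["start"] < srow["end"])).to_numpy()
        seg_clg[hit], seg_r1[hit], seg_r2[hit] = srow["clg"], srow["r1"], srow["r2"]
    n_excluded = int(pd.isna(seg_clg).sum())
    if n_excluded:
        logger.info("retention_rates: %d orthologues on unassigned segments excluded",
                    n_excluded)
    found = pd.DataFrame({"ancestor_gene": loc["gene_a"], "clg": seg_clg,
                          "r1": seg_r1, "r2": seg_r2}).dropna()
    anc = ancestor.genes[["gene_id", "clg"]]
    per_clg_total = anc.groupby("clg")["gene_id"].nunique()
    rows = []
    for clg, total in per_clg_total.items():
        # each (clg, 2R copy) class spans the two 1R segments: the retention
        # denominator is one slot per ancestral gene per 1R copy
        n_r1 = 2
        for r2 in ("a", "b"):
            got = found[(found["clg"] == clg) & (found["r2"] == r2)]
            retained = len(got.drop_duplicates(["ancestor_gene", "r1"]))
            slots = total * n_r1
            rows.append((clg, r2, int(retained), int(slots),
                         retained / slots if slots else np.nan))
    return pd.DataFrame(rows, columns=["clg", "r2_copy", "retained",
                                       "ancestral", "rate"])


def clg_fraction_track(ann: pd.DataFrame, clg_of_gene: pd.Series | dict,
                       window: int = 20) -> pd.DataFrame:
    """Per-chromosome CLG fractions in non-overlapping windows of ``window``
    consecutive genes (Fig-2a-style chromosome painting).

    The trailing partial window is kept and flagged. Fractions are over
    genes with a CLG assignment, so assigned fractions sum to 1 per window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    clg_of_gene = pd.Series(clg_of_gene)
    rows = []
    for chrom, sub in ann.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        if len(sub) < 1:
            continue
        for w0 in range(0, len(sub), window):
            chunk = sub.iloc[w0:w0 + window]
            labels = clg_of_gene.reindex(chunk["gene_id"]).dropna()
            counts = labels.value_counts()
            denom = counts.sum()
            for clg, c in counts.items():
                rows.append((chrom, w0 // window, int(chunk["start"].min()),
                             int(chunk["end"].max()), clg, c / denom,
                             len(chunk) < window))
    return pd.DataFrame(rows, columns=["chrom", "window_index", "start", "end",
                                       "clg", "fraction", "partial"])
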