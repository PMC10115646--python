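"""Hi-C summary statistics.

Consumes binned contact matrices given as a text bin table plus
``bin1_id bin2_id count`` triplets (a plain-text stand-in for .hic/.mcool),
and computes:

* the interchromosomal observed/expected map, where the expectation for a
  chromosome pair is proportional to the product of the two chromosomes'
  total interchromosomal contact counts;
* Crane-style insulation scores (sliding square, default 500-kb window on a
  25-kb matrix), boundary calls by local-minimum depth with a configurable
  boundary-score cutoff (default 1), and the TAD intervals between
  consecutive boundaries;
* virtual 4C viewpoint profiles;
* chromosome size classes (macro > 40 Mb, meso 20-40 Mb closed, micro
  < 20 Mb) joined with GC content;
* TAD counts and size distributions per whole-genome-duplication segment
  class (1/2 x alpha/beta).

Matrices are assumed pre-balanced; a naive iterative-proportional-fitting
balancer is available for synthetic data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FormatError

__all__ = [
    "ContactMatrix",
    "InsulationTrack",
    "load_contact_matrix",
    "balance_matrix",
    "interchrom_obs_exp",
    "insulation_track",
    "call_boundaries_and_tads",
    "virtual_4c",
    "chromosome_classes",
    "segment_tad_stats",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix (sparse upper-triangle storage)."""

    bins: pd.DataFrame   # chrom start end bin_id (bins tile chromosomes)
    pairs: pd.DataFrame  # bin1_id bin2_id count, bin1_id <= bin2_id
    resolution: int
    balanced: bool = False

    @classmethod
    def from_pairs(cls, bins: pd.DataFrame, pairs: pd.DataFrame,
                   resolution: int, balanced: bool = False) -> "ContactMatrix":
        """Canonicalise: symmetrize to upper triangle, merge duplicates."""
        bins = bins.sort_values("bin_id").reset_index(drop=True)
        _validate_bins(bins, resolution)
        p = pairs.copy()
        lo = np.minimum(p["bin1_id"], p["bin2_id"])
        hi = np.maximum(p["bin1_id"], p["bin2_id"])
        p["bin1_id"], p["bin2_id"] = lo, hi
        p = p.groupby(["bin1_id", "bin2_id"], as_index=False)["count"].sum()
        return cls(bins=bins, pairs=p, resolution=resolution, balanced=balanced)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def dense(self, chrom: str) -> tuple[np.ndarray, pd.DataFrame]:
        """Dense symmetric cis matrix for one chromosome + its bin table."""
        b = self.bins[self.bins["chrom"] == chrom]
        if b.empty:
            raise KeyError(f"chromosome {chrom!r} not in bin table")
        ids = b["bin_id"].to_numpy()
        lo, hi = ids.min(), ids.max()
        sel = self.pairs[(self.pairs["bin1_id"] >= lo) & (self.pairs["bin1_id"] <= hi)
                         & (self.pairs["bin2_id"] >= lo) & (self.pairs["bin2_id"] <= hi)]
        n = hi - lo + 1
        m = np.zeros((n, n))
        i = sel["bin1_id"].to_numpy() - lo
        j = sel["bin2_id"].to_numpy() - lo
        m[i, j] = sel["count"].to_numpy()
        m[j, i] = sel["count"].to_numpy()
        return m, b.reset_index(drop=True)


def _validate_bins(bins: pd.DataFrame, resolution: int) -> None:
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["end"] - sub["start"] != resolution).any():
            raise FormatError(f"{chrom}: bin widths differ from resolution")
        starts = sub["start"].to_numpy()
        if len(starts) > 1 and not np.all(np.diff(starts) == resolution):
            raise FormatError(f"{chrom}: bins have gaps or overlaps")


def load_contact_matrix(bins_path, pairs_path, balance: bool = False) -> ContactMatrix:
    """Load a matrix from a bin table + triplet pairs file.

    Asymmetric input pairs are symmetrized. Balancing is off by default —
    inputs are assumed pre-normalised upstream.
    """
    bins = pd.read_csv(bins_path, sep="\t")
    pairs = pd.read_csv(pairs_path, sep="\t")
    res = int((bins["end"] - bins["start"]).iloc[0])
    m = ContactMatrix.from_pairs(bins, pairs, resolution=res)
    if balance:
        m = balance_matrix(m)
    return m


def balance_matrix(matrix: ContactMatrix, n_iter: int = 50) -> ContactMatrix:
    """Naive iterative proportional fitting to equalise bin marginals
    (synthetic-data convenience, not a KR implementation)."""
    n = len(matrix.bins)
    dense = np.zeros((n, n))
    i = matrix.pairs["bin1_id"].to_numpy()
    j = matrix.pairs["bin2_id"].to_numpy()
    dense[i, j] = matrix.pairs["count"].to_numpy()
    dense[j, i] = matrix.pairs["count"].to_numpy()
    for _ in range(n_iter):
        s = dense.sum(axis=1)
        s[s == 0] = 1.0
        d = np.sqrt(s / s[s > 0].mean())
        dense /= np.outer(d, d)
    ii, jj = np.nonzero(np.triu(dense))
    pairs = pd.DataFrame({"bin1_id": ii, "bin2_id": jj, "count": dense[ii, jj]})
    return ContactMatrix(matrix.bins, pairs, matrix.resolution, balanced=True)


# ---------------------------------------------------------------------------
# interchromosomal observed / expected


def interchrom_obs_exp(matrix: ContactMatrix) -> pd.DataFrame:
    """Chromosome-by-chromosome log2 observed/expected interchromosomal map.

    O(c,c') sums contacts between bins of c and c'. The expectation is
    proportional to T(c)*T(c') — the product of the chromosomes' total
    interchromosomal counts — rescaled so that the summed expectation
    matches the summed observation; the diagonal and any chromosome with no
    interchromosomal signal are masked (NaN).
    """
    chroms = matrix.chromosomes()
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes for an interchromosomal map")
    chrom_of = matrix.bins.set_index("bin_id")["chrom"]
    c1 = chrom_of.loc[matrix.pairs["bin1_id"]].to_numpy()
    c2 = chrom_of.loc[matrix.pairs["bin2_id"]].to_numpy()
    counts = matrix.pairs["count"].to_numpy()
    inter = c1 != c2
    obs = pd.DataFrame(0.0, index=chroms, columns=chroms)
    for a, b, n in zip(c1[inter], c2[inter], counts[inter]):
        obs.loc[a, b] += n
        obs.loc[b, a] += n
    T = obs.sum(axis=1)
    E = np.outer(T, T).astype(float)
    np.fill_diagonal(E, 0.0)
    total_obs = obs.to_numpy().sum()
    if E.sum() > 0:
        E *= total_obs / E.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(obs.to_numpy() / E)
    ratio[~np.isfinite(ratio)] = np.nan
    np.fill_diagonal(ratio, np.nan)
    dead = T.to_numpy() == 0
    ratio[dead, :] = np.nan
    ratio[:, dead] = np.nan
    return pd.DataFrame(ratio, index=chroms, columns=chroms)


# ---------------------------------------------------------------------------
# insulation and boundaries


@dataclass
class InsulationTrack:
    """Per-bin insulation scores (log2 relative to the chromosome mean)."""

    track: pd.DataFrame  # chrom start end bin_id score (NaN in masked margins)
    window: int
    resolution: int


def insulation_track(matrix: ContactMatrix, window: int = 500_000) -> InsulationTrack:
    """Sliding-square insulation: per bin, the mean contact count in the
    window x window square straddling it, log2-normalised to the chromosome
    mean of defined scores (so defined scores average zero per chromosome).
    """
    if window % matrix.resolution != 0:
        raise ValueError("window must be a multiple of the resolution")
    w = window // matrix.resolution
    frames = []
    for chrom in matrix.chromosomes():
        m, b = matrix.dense(chrom)
        n = len(b)
        scores = np.full(n, np.nan)
        if n < 2 * w:
            warnings.warn(f"{chrom}: shorter than twice the window; fully masked")
        else:
            raw = np.full(n, np.nan)
            for i in range(w, n - w):
                raw[i] = m[i - w:i, i + 1:i + w + 1].mean()
            with np.errstate(divide="ignore"):
                logr = np.log2(raw)
            defined = np.isfinite(logr)
            if defined.any():
                logr[defined] -= logr[defined].mean()
            scores = logr
        f = b.copy()
        f["score"] = scores
        frames.append(f)
    track = pd.concat(frames, ignore_index=True)
    return InsulationTrack(track=track[["chrom", "start", "end", "bin_id", "score"]],
                           window=window, resolution=matrix.resolution)


def call_boundaries_and_tads(track: InsulationTrack, cutoff: float = 1.0
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boundaries at local insulation minima, scored by the mean of the two
    flanking local maxima minus the minimum; minima scoring >= ``cutoff``
    pass. TADs are the intervals between consecutive passing boundaries; a
    chromosome with no passing boundary is one TAD.

    Returns ``(boundaries, tads)``: boundaries carry bin coordinates, the
    boundary score and a ``passes_cutoff`` flag (all local minima are
    reported); tads are plain chrom/start/end intervals.
    """
    b_rows, t_rows = [], []
    res = track.resolution
    for chrom, sub in track.track.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        s = sub["score"].to_numpy()
        defined = np.flatnonzero(np.isfinite(s))
        chrom_end = int(sub["end"].max())
        if len(defined) < 3:
            t_rows.append((chrom, 0, chrom_end))
            continue
        v = s[defined]
        minima = [k for k in range(1, len(v) - 1)
                  if v[k] < v[k - 1] and v[k] <= v[k + 1]]
        maxima = [k for k in range(1, len(v) - 1)
                  if v[k] > v[k - 1] and v[k] >= v[k + 1]]
        passing_pos = []
        for k in minima:
            left = [m for m in maxima if m < k]
            right = [m for m in maxima if m > k]
            lmax = v[left[-1]] if left else v[:k].max()
            rmax = v[right[0]] if right else v[k + 1:].max()
            score = (lmax + rmax) / 2.0 - v[k]
            i = defined[k]
            passes = bool(score >= cutoff)
            b_rows.append((chrom, int(sub.loc[i, "start"]), int(sub.loc[i, "end"]),
                           float(score), passes))
            if passes:
                passing_pos.append(int(sub.loc[i, "start"]) + res // 2)
        edges = [0] + sorted(passing_pos) + [chrom_end]
        if len(edges) == 2:
            t_rows.append((chrom, 0, chrom_end))
        else:
            for a, b in zip(edges[:-1], edges[1:]):
                t_rows.append((chrom, int(a), int(b)))
    boundaries = pd.DataFrame(
        b_rows, columns=["chrom", "start", "end", "boundary_score", "passes_cutoff"])
    boundaries = boundaries.astype({"start": int, "end": int,
                                    "boundary_score": float,
                                    "passes_cutoff": bool})
    tads = pd.DataFrame(t_rows, columns=["chrom", "start", "end"])
    return boundaries, tads


# ---------------------------------------------------------------------------
# virtual 4C


def virtual_4c(matrix: ContactMatrix, viewpoint: tuple[str, int, int]) -> pd.DataFrame:
    """Contact profile of a viewpoint against its chromosome, normalised to
    the total cis signal of the viewpoint rows (bedGraph-style frame)."""
    chrom, vstart, vend = viewpoint
    try:
        m, b = matrix.dense(chrom)
    except KeyError:
        raise ValueError(f"viewpoint chromosome {chrom!r} absent from matrix")
    sel = (b["end"] > vstart) & (b["start"] < vend)
    if not sel.any():
        raise ValueError("viewpoint overlaps no bin")
    profile = m[sel.to_numpy()].sum(axis=0)
    total = profile.sum()
    if total > 0:
        profile = profile / total
    out = b[["chrom", "start", "end"]].copy()
    out["value"] = profile
    return out


# ---------------------------------------------------------------------------
# chromosome classes and per-segment TAD statistics

MACRO_MIN = 40_000_000   # strictly greater -> macro
MICRO_MAX = 20_000_000   # strictly smaller -> micro; [20, 40] Mb closed -> meso


def chromosome_classes(lengths: pd.Series | dict,
                       gc: pd.Series | dict | None = None) -> pd.DataFrame:
    """Classify chromosomes as macro (> 40 Mb), meso (20–40 Mb, boundaries
    included) or micro (< 20 Mb), joined with GC for the size–GC scatter."""
    lengths = pd.Series(lengths)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    cls = pd.Series("meso", index=lengths.index)
    cls[lengths > MACRO_MIN] = "macro"
    cls[lengths < MICRO_MAX] = "micro"
    out = pd.DataFrame({"chrom": lengths.index, "length": lengths.to_numpy(),
                        "class": cls.to_numpy()})
    if gc is not None:
        out["gc"] = pd.Series(gc).reindex(lengths.index).to_numpy()
    return out


def segment_tad_stats(tads: pd.DataFrame, segments: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each TAD to the WGD segment containing its midpoint and
    summarise counts and sizes per (1R copy, 2R copy) class.

    Returns ``(summary, assigned)``; TADs whose midpoint falls in no
    labelled segment get class ``unassigned``.
    """
    assigned = tads.copy().reset_index(drop=True)
    assigned["mid"] = (assigned["start"] + assigned["end"]) // 2
    r1 = np.full(len(assigned), "unassigned", dtype=object)
    r2 = np.full(len(assigned), "unassigned", dtype=object)
    for chrom, seg in segments.groupby("chrom", sort=False):
        sel = assigned["chrom"] == chrom
        if not sel.any():
            continue
        mids = assigned.loc[sel, "mid"].to_numpy()
        for _, srow in seg.iterrows():
            inside = (mids >= srow["start"]) & (mids < srow["end"])
            idx = assigned.index[sel].to_numpy()[inside]
            r1[idx], r2[idx] = srow["r1"], srow["r2"]
    assigned["r1"], assigned["r2"] = r1, r2
    assigned["size"] = assigned["end"] - assigned["start"]
    summary = (assigned.groupby(["r1", "r2"])
               .agg(n_tads=("size", "size"), mean_size=("size", "mean"),
                    median_size=("size", "median"))
               .reset_index())
    return summary, assigned.drop(columns="mid")
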