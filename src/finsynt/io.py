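"""Plain-text genomic I/O: GFF3, BED, BEDPE, TSV and contact-matrix text.

Internal coordinates are 0-based half-open; GFF3 is written/read 1-based
closed per the standard.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

GFF3_EXTRA = ["clg", "r1", "r2", "ancestor_id"]


class FormatError(ValueError):
    """Malformed input file."""


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table as GFF3 ``gene`` features.

    Extra label columns (clg, r1, r2, ancestor_id) go into the attribute
    field so that a round trip preserves them.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = [f"ID={g['gene_id']}"]
            for key in GFF3_EXTRA:
                if key in genes.columns:
                    attrs.append(f"{key}={g[key]}")
            fh.write("\t".join([
                str(g["chrom"]), "finsynt", "gene",
                str(int(g["start"]) + 1), str(int(g["end"])),  # 1-based closed
                ".", str(g.get("strand", "+")), ".", ";".join(attrs),
            ]) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features back into the internal 0-based half-open table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"bad GFF3 line: {line!r}")
            if f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            row = {"gene_id": attrs.get("ID", "."), "chrom": f[0],
                   "start": int(f[3]) - 1, "end": int(f[4]), "strand": f[6]}
            for key in GFF3_EXTRA:
                if key in attrs:
                    row[key] = attrs[key]
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + [c for c in ("name", "score", "strand")
                                        if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, names=("chrom", "start", "end", "name", "score", "strand")
             ) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(names)[:3])
    df.columns = list(names)[: df.shape[1]]
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: BED intervals must satisfy start < end")
    return df


BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def write_bedpe(df: pd.DataFrame, path: str | Path) -> None:
    cols = BEDPE_COLS + [c for c in df.columns if c not in BEDPE_COLS]
    df[cols].to_csv(path, sep="\t", header=True, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BEDPE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: BEDPE missing columns {missing}")
    return df


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix, bins_path: str | Path, pairs_path: str | Path) -> None:
    """Bin table (BED-like + bin_id) and ``bin1_id bin2_id count`` triplets."""
    matrix.bins[["chrom", "start", "end", "bin_id"]].to_csv(
        bins_path, sep="\t", header=True, index=False)
    matrix.pairs.to_csv(pairs_path, sep="\t", header=True, index=False)


def read_blocks(path: str | Path) -> pd.DataFrame:
    """Synteny-block TSV: refChrom refStart refEnd targetChrom targetStart
    targetEnd level strand endFlag."""
    df = pd.read_csv(path, sep="\t")
    required = ["refChrom", "refStart", "refEnd", "targetChrom",
                "targetStart", "targetEnd", "level", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: block table missing columns {missing}")
    if "endFlag" not in df.columns:
        df["endFlag"] = False
    return df
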