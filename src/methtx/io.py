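"""Readers and writers for the pipeline's plain-text formats.

Coordinate contract: positions are 1-based inclusive in memory and in TSV
outputs; BED exports are 0-based half-open (start - 1).  Methylation input is
the Bismark coverage dialect: chrom, start, end, methylation %, count
methylated, count unmethylated, one file per sample.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd


def read_counts(path, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a genes x samples integer count TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene_ids in {path}: {dupes[:5]}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals.index[vals != np.floor(vals.fillna(-1))]
            if len(bad) or vals.isna().any():
                raise ValueError(
                    f"non-integer count in {path}, column {col!r}"
                    + (f", row {bad[0]!r}" if len(bad) else "")
                )
            df[col] = vals.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    if design is not None:
        missing = set(design["sample_id"]) - set(df.columns)
        if missing:
            raise ValueError(f"count matrix missing design samples: {sorted(missing)}")
    return df


def write_counts(counts: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        counts.to_csv(fh, sep="\t")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_methylation(paths: dict[str, "str | Path"]) -> pd.DataFrame:
    """Read per-sample Bismark-coverage-style TSVs into one long table.

    Returns columns chrom, pos, sample_id, X, N with X = count methylated and
    N = methylated + unmethylated; positions are taken 1-based from the start
    column.  The percent column is cross-checked (warn if off by > 0.5;
    counts win).
    """
    frames = []
    cols = ["chrom", "start", "end", "pct", "meth", "unmeth"]
    for sample_id, path in paths.items():
        try:
            df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=cols)
        if df.empty:
            warnings.warn(f"empty methylation file for sample {sample_id}", stacklevel=2)
            continue
        if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
            raise ValueError(f"negative counts in {path}")
        n = df["meth"] + df["unmeth"]
        with np.errstate(divide="ignore", invalid="ignore"):
            expect = 100.0 * df["meth"] / n.replace(0, np.nan)
        bad = (df["pct"] - expect).abs() > 0.5
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} rows in {path} have methylation %% inconsistent "
                "with counts; counts take precedence",
                stacklevel=2,
            )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "pos": df["start"].astype(int),
                    "sample_id": sample_id,
                    "X": df["meth"].astype(int),
                    "N": n.astype(int),
                }
            )
        )
    if not frames:
        warnings.warn("no methylation records read", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "pos", "sample_id", "X", "N"])
    return pd.concat(frames, ignore_index=True)


def write_methylation(table: pd.DataFrame, outdir, suffix: str = ".cov.tsv") -> list[Path]:
    """Write one Bismark-coverage-style file per sample; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample_id, g in table.groupby("sample_id", sort=True):
        path = outdir / f"{sample_id}{suffix}"
        pct = np.where(g["N"] > 0, 100.0 * g["X"] / g["N"].replace(0, np.nan), 0.0)
        out = pd.DataFrame(
            {
                "chrom": g["chrom"],
                "start": g["pos"],
                "end": g["pos"],
                "pct": np.round(pct, 6),
                "meth": g["X"],
                "unmeth": g["N"] - g["X"],
            }
        ).sort_values(["chrom", "start"], kind="stable")
        out.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def read_bed_positions(path) -> set[tuple[str, int]]:
    """Read single-base BED intervals into a set of 1-based (chrom, pos)."""
    out: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{line_no}: malformed interval {start}-{end}")
            for pos0 in range(start, end):
                out.add((fields[0], pos0 + 1))
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED6 from 1-based inclusive intervals (start - 1 conversion).

    ``intervals`` needs columns chrom, start, end, name, score, strand
    (strand optional, defaults '.').
    """
    df = intervals.copy()
    if (df["end"] < df["start"]).any():
        raise ValueError("interval with end < start")
    if "strand" not in df.columns:
        df["strand"] = "."
    if "score" not in df.columns:
        df["score"] = 0
    df = df.sort_values(["chrom", "start"], kind="stable")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
            "name": df["name"],
            "score": df["score"],
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    """Write the gene annotation as BED6 (name = gene_id)."""
    write_bed(
        genes.rename(columns={"gene_id": "name"})[
            ["chrom", "start", "end", "name", "strand"]
        ].assign(score=0),
        path,
    )


def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED6 gene annotation into 1-based gene records with TSS."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{line_no}: BED6 with strand required")
            start, end, strand = int(f[1]) + 1, int(f[2]), f[5]
            if strand not in "+-":
                raise ValueError(f"{path}:{line_no}: strand must be + or -")
            rows.append(
                {
                    "gene_id": f[3],
                    "chrom": f[0],
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "tss": start if strand == "+" else end,
                }
            )
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT-style annotation sets: label <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
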