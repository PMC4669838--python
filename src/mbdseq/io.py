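"""Plain-text I/O for the standard formats the pipeline touches.

Reads and peaks travel as BED (6 and 6+2 columns), gene models as
11-column refFlat, CpG islands as BED3, chromosome sizes as two-column
TSV, and Ct tables as TSV.  All coordinates are 0-based half-open.
Malformed lines are reported with their line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import GeneModel, GenomicInterval, Peak, peaks_to_frame

PEAK_BED_COLUMNS = (
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "fold_enrichment",
    "n_reads",
)


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    """Write aligned reads as BED6 (name = library fraction, score = 0)."""
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["end"],
            "name": reads["fraction"],
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 read file written by :func:`write_reads_bed`."""
    df = _read_tsv(
        path,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtypes={"start": int, "end": int},
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "strand": df["strand"],
            "fraction": df["name"],
        }
    )


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6+2 (score = -log10 p, strand = '.')."""
    peaks_to_frame(peaks).to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path) -> list[Peak]:
    df = _read_tsv(
        path,
        names=list(PEAK_BED_COLUMNS),
        dtypes={"start": int, "end": int, "score": float, "fold_enrichment": float, "n_reads": int},
    )
    return [
        Peak(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            score=float(row.score),
            fold_enrichment=float(row.fold_enrichment),
            n_reads=int(row.n_reads),
        )
        for row in df.itertuples()
    ]


def write_refflat(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models in 11-column refFlat format."""
    rows = []
    for g in genes:
        rows.append(
            (
                g.name,
                g.name,
                g.chrom,
                g.strand,
                g.tx_start,
                g.tx_end,
                g.cds_start,
                g.cds_end,
                g.n_exons,
                ",".join(str(s) for s in g.exon_starts) + ",",
                ",".join(str(e) for e in g.exon_ends) + ",",
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_refflat(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 11:
                raise ValueError(
                    f"{path}:{lineno}: expected 11 refFlat columns, found {len(parts)}"
                )
            try:
                genes.append(
                    GeneModel(
                        name=parts[1],
                        chrom=parts[2],
                        strand=parts[3],
                        tx_start=int(parts[4]),
                        tx_end=int(parts[5]),
                        cds_start=int(parts[6]),
                        cds_end=int(parts[7]),
                        exon_starts=tuple(
                            int(x) for x in parts[9].rstrip(",").split(",")
                        ),
                        exon_ends=tuple(
                            int(x) for x in parts[10].rstrip(",").split(",")
                        ),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_bed3(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in intervals]
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bed3(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(sizes.items())).to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = _read_tsv(path, names=["chrom", "size"], dtypes={"size": int})
    return dict(zip(df["chrom"], df["size"]))


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table[["sample", "group", "gene", "replicate", "ct"]].to_csv(
        path, sep="\t", index=False
    )


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "group", "gene", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    return df


def _read_tsv(path: str | Path, names: list[str], dtypes: Mapping[str, type]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    for col, typ in dtypes.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            lineno = int(bad.index[0]) + 1 if len(bad) else "?"
            raise ValueError(
                f"{path}: line {lineno}: column '{col}' is not {typ.__name__}"
            ) from exc
    return df
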