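"""Readers and writers for the plain-text formats the pipeline exchanges.

GTF attributes are limited to the `gene_id` / `transcript_id` / `gene_name` /
`gene_type` keys the pipeline consumes; BED files are 0-based half-open as
usual; all TSVs carry headers.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf_attributes(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_gtf(path: str) -> pd.DataFrame:
    """Read a GTF into a frame of transcript records.

    Returns one row per `transcript` feature with columns
    chrom/source/feature/start/end/strand/gene_id/gene_name/transcript_id/biotype.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            attrs = parse_gtf_attributes(f[8])
            rows.append(
                {
                    "chrom": f[0],
                    "source": f[1],
                    "feature": f[2],
                    "start": int(f[3]),  # 1-based inclusive, GTF convention
                    "end": int(f[4]),
                    "strand": f[6],
                    "gene_id": attrs.get("gene_id", ""),
                    "gene_name": attrs.get("gene_name", attrs.get("gene_id", "")),
                    "transcript_id": attrs.get("transcript_id", ""),
                    "biotype": attrs.get(
                        "gene_type", attrs.get("gene_biotype", "protein_coding")
                    ),
                }
            )
    cols = [
        "chrom",
        "source",
        "feature",
        "start",
        "end",
        "strand",
        "gene_id",
        "gene_name",
        "transcript_id",
        "biotype",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_gtf(transcripts: Iterable[Mapping], path: str) -> None:
    """Write gene+transcript GTF records from mapping rows with keys
    chrom/start/end/strand/gene_id/gene_name/transcript_id/biotype."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t["gene_id"]}"; transcript_id "{t["transcript_id"]}"; '
                f'gene_name "{t["gene_name"]}"; gene_type "{t["biotype"]}";'
            )
            for feature in ("gene", "transcript"):
                fh.write(
                    "\t".join(
                        [
                            str(t["chrom"]),
                            "synthetic",
                            feature,
                            str(t["start"]),
                            str(t["end"]),
                            ".",
                            str(t["strand"]),
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_bed(path: str, names: tuple[str, ...] = ("chrom", "start", "end")) -> pd.DataFrame:
    """Read a headerless BED-like file; extra columns get the extra names."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(names))
    df = df.iloc[:, : len(names)]
    df.columns = list(names)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
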