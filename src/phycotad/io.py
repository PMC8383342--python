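"""Plain-text table and GFF3 input/output.

Every table the pipeline exchanges is tab-separated text with ``#``-prefixed
header comments (the generator records its seed there).  GFF3 files use
1-based inclusive coordinates and carry gene annotations as ``CDS`` features
with ``ID``, ``gene`` and ``product`` attributes.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = True,
              comments: Iterable[str] = ()) -> None:
    """Write a DataFrame as TSV with optional ``#`` header comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, *, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_tsv_comments(path: str | Path) -> list[str]:
    """Return the leading ``#`` comment lines of a TSV (seed provenance)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            out.append(line[1:].strip())
    return out


def write_hits(df: pd.DataFrame, path: str | Path,
               comments: Iterable[str] = ()) -> None:
    """Write a 12-column tabular hit table (no header row, BLAST outfmt 6)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df[BLAST6_COLUMNS].to_csv(fh, sep="\t", index=False, header=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular hit table, validating row shape.

    Malformed rows raise ``ValueError`` naming the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"fields, got {len(parts)}")
            try:
                rows.append((
                    parts[0], parts[1], float(parts[2]), int(parts[3]),
                    int(parts[4]), int(parts[5]), int(parts[6]),
                    int(parts[7]), int(parts[8]), int(parts[9]),
                    float(parts[10]), float(parts[11]),
                ))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: unparsable field ({exc})"
                ) from None
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D")


def _unescape(value: str) -> str:
    return value.replace("%3B", ";").replace("%3D", "=")


def write_gff3(features: pd.DataFrame, path: str | Path,
               comments: Iterable[str] = ()) -> None:
    """Write CDS features to GFF3 (1-based inclusive coordinates).

    ``features`` needs columns contig_id, start, end, strand, gene_id,
    gene_symbol, product.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in comments:
            fh.write(f"# {line}\n")
        for row in features.itertuples(index=False):
            attrs = (f"ID={_escape(str(row.gene_id))};"
                     f"gene={_escape(str(row.gene_symbol))};"
                     f"product={_escape(str(row.product))}")
            fh.write("\t".join([
                str(row.contig_id), "phycotad", "CDS", str(int(row.start)),
                str(int(row.end)), ".", row.strand, "0", attrs,
            ]) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read CDS features back into the annotation-table column layout."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            fields = {k.strip(): _unescape(v)
                      for k, v in _ATTR_RE.findall(attrs)}
            rows.append((seqid, int(start), int(end), strand,
                         fields.get("ID", ""), fields.get("gene", ""),
                         fields.get("product", "")))
    return pd.DataFrame(rows, columns=[
        "contig_id", "start", "end", "strand", "gene_id", "gene_symbol",
        "product"])


def write_mapping(mapping: Mapping, path: str | Path, key: str, value: str,
                  comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame({key: list(mapping.keys()), value: list(mapping.values())})
    write_tsv(df, path, index=False, comments=comments)
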