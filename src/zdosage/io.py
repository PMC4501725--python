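"""Readers and writers for the plain-text formats the pipeline owns.

FASTA via Biopython (line wrapping normalized to 60 columns on write,
CRLF tolerated on read); tabular data as UTF-8 TSV with a header row and
no quoting. Validation errors name the offending line.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .simulate import ReferenceGeneModel, ReferenceSet

FLOAT_FORMAT = "%.6g"

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_tsv",
    "write_tsv",
    "read_gene_table",
    "write_reference",
    "read_reference",
    "read_alignment_fasta",
    "write_manifest",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; duplicate ids are an error."""
    records = []
    seen = set()
    with open(path, newline=None) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append((rec.id, str(rec.seq)))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Count matrix: first column contig_id, remaining columns integer
    counts per sample. Ragged rows, duplicate ids, non-numeric or
    negative entries raise :class:`ParseError` with the line number."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"empty counts file {path}", line=1) from None
        if len(header) < 2:
            raise ParseError("counts header needs contig_id + >=1 sample",
                             line=1)
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise ParseError("duplicate sample ids in counts header", line=1)
        ids, rows = [], []
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(row)}",
                    line=lineno)
            cid = row[0]
            if cid in seen:
                raise ParseError(f"duplicate contig id {cid!r}", line=lineno)
            seen.add(cid)
            values = []
            for field in row[1:]:
                try:
                    v = int(field)
                except ValueError:
                    raise ParseError(f"non-integer count {field!r}",
                                     line=lineno) from None
                if v < 0:
                    raise ParseError(f"negative count {v}", line=lineno)
                values.append(v)
            ids.append(cid)
            rows.append(values)
    return pd.DataFrame(rows, index=ids, columns=samples, dtype=np.int64)


def write_counts_tsv(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="contig_id")


def read_tsv(path: str | Path, required: list[str] | None = None
             ) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ParseError(
                f"{path}: missing column(s) {sorted(missing)}", line=1)
    return df


def write_tsv(path: str | Path, df: pd.DataFrame,
              index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, required=["gene_id", "chromosome"])


def write_reference(ref: ReferenceSet, outdir: str | Path) -> dict[str, str]:
    """Write a simulated reference set; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": str(outdir / "reference_proteins.fasta"),
        "cds": str(outdir / "reference_cds.fasta"),
        "gene_table": str(outdir / "gene_table.tsv"),
        "contigs": str(outdir / "contigs.fasta"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
    }
    write_fasta(paths["proteins"],
                [(g.gene_id, g.protein) for g in ref.genes])
    write_fasta(paths["cds"], [(g.gene_id, g.cds) for g in ref.genes])
    write_tsv(paths["gene_table"], pd.DataFrame(
        [{"gene_id": g.gene_id, "chromosome": g.chromosome,
          "is_masc_like": int(g.is_masc_like)} for g in ref.genes]))
    write_fasta(paths["contigs"], ref.contigs)
    write_tsv(paths["ground_truth"], pd.DataFrame(
        [{"contig_id": cid, "gene_id": gid}
         for cid, gid in ref.contig_to_gene.items()]))
    return paths


def read_reference(protein_fasta: str | Path, gene_table: str | Path
                   ) -> list[ReferenceGeneModel]:
    proteins = dict(read_fasta(protein_fasta))
    table = read_gene_table(gene_table)
    genes = []
    for _, row in table.iterrows():
        gid = row["gene_id"]
        if gid not in proteins:
            raise ParseError(f"gene {gid!r} absent from protein FASTA")
        genes.append(ReferenceGeneModel(
            gene_id=gid,
            chromosome=str(row["chromosome"]),
            protein=proteins[gid],
            is_masc_like=bool(row.get("is_masc_like", 0)),
        ))
    return genes


def read_alignment_fasta(path: str | Path):
    """Aligned FASTA to an :class:`~zdosage.phylo.MsaBlock`."""
    from .phylo import MsaBlock

    records = read_fasta(path)
    return MsaBlock([r[0] for r in records], [r[1] for r in records])


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
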