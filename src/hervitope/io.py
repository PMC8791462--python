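"""Readers and writers for the pipeline's on-disk formats.

Tabular artifacts are plain TSV.  Files written by the pipeline carry a
provenance header: ``#`` comment lines recording the stage name, the run
seed and a hash of the configuration, so every output can be traced back
to the run that produced it.  All readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import ExpressionMatrix


def config_hash(config: Mapping) -> str:
    """Deterministic short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(stage: str, seed: int | None = None, cfg_hash: str | None = None) -> list[str]:
    lines = [f"# stage: {stage}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    return lines


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    *,
    stage: str | None = None,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index: bool = False,
    index_label: str | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stage is not None:
            fh.write("\n".join(provenance_lines(stage, seed, cfg_hash)) + "\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, lineterminator="\n")
    return path


def read_tsv(path: str | Path, *, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# -- expression matrices -------------------------------------------------

def write_counts(matrix: ExpressionMatrix, path: str | Path, **prov) -> Path:
    df = matrix.to_dataframe()
    return write_tsv(df, path, index=True, index_label="herv_id", **prov)


def read_counts(path: str | Path, layer: str = "raw_counts") -> ExpressionMatrix:
    df = read_tsv(path, index_col=0)
    return ExpressionMatrix.from_dataframe(df, layer=layer)


# -- sequences -----------------------------------------------------------

def write_fasta(records: Mapping[str, str] | Sequence[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, Mapping):
        items = records.items()
    else:
        items = records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seq_records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- BED loci ------------------------------------------------------------

def write_bed(loci: pd.DataFrame, path: str | Path) -> Path:
    """Write HERV loci; expects columns chrom, start, end, name."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    loci[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False, lineterminator="\n"
    )
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    return df


# -- GMT gene sets -------------------------------------------------------

def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    gene_sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            gene_sets[fields[0]] = [g for g in fields[2:] if g]
    return gene_sets
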