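"""Readers and writers for the plain-text formats used throughout the toolkit.

All tabular files are TSV with a header row and a fixed column order; protein
sequences are FASTA wrapped at 60 columns (via Biopython). Counts are genes x
samples with the gene identifier in the first column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix; index = gene_id, integer columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise InputError(f"duplicate gene ids in {path}")
    if df.columns.has_duplicates:
        raise InputError(f"duplicate sample ids in {path}")
    if (df.values < 0).any():
        raise InputError(f"negative counts in {path}")
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Sample metadata: sample_id, genotype, replicate, bnf_class, ploidy, fresh_mass, ethylene."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "bnf_class" in df.columns and df["bnf_class"].isna().any():
        raise InputError(f"missing bnf_class values in {path}")
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    with open(path) as fh:
        return list(SeqIO.parse(fh, "fasta"))


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> None:
    recs = []
    for rec in records:
        if isinstance(rec, tuple):
            rec = SeqRecord(Seq(rec[1]), id=rec[0], description="")
        recs.append(rec)
    SeqIO.write(recs, str(path), "fasta")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """qPCR cycle-threshold table with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample", "gene", "ct"}
    if not needed.issubset(df.columns):
        raise InputError(f"ct table {path} must have columns {sorted(needed)}")
    return df


def read_duplication_catalog(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df["gene_id"].duplicated().any():
        raise InputError(f"duplicate gene ids in catalog {path}")
    return df.set_index("gene_id")["mode"]


def read_duplicate_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """gene -> term annotation table (columns gene_id, term_id)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise InputError(f"annotation table {path} must have gene_id and term_id columns")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
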