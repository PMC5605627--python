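"""Readers and writers for the pipeline's plain-text formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import Pwm
from .matrix import read_matrix_tsv, write_matrix_tsv  # re-exported

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_annotation_tsv",
    "read_footprints_tsv",
    "read_ratio_tsv",
    "read_census",
    "read_fasta",
    "read_pwm_tsv",
]


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Gene annotation: gene_id, biotype, tx_length, cds_length, strand."""
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    required = {"biotype", "tx_length", "cds_length"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation lacks column(s): {sorted(missing)}")
    return ann


def read_footprints_tsv(path: str | Path) -> pd.DataFrame:
    """Footprint records: gene_id, five_prime_offset, length, strand
    (+ optional compartment, replicate)."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "five_prime_offset", "length"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"footprint table lacks column(s): {sorted(missing)}")
    return table


def read_ratio_tsv(path: str | Path) -> pd.Series:
    """SILAC ratio table: protein_id, ratio."""
    table = pd.read_csv(path, sep="\t", index_col="protein_id")
    if "ratio" not in table.columns:
        raise ValueError("ratio table needs a 'ratio' column")
    return table["ratio"].astype(float)


def read_census(path: str | Path) -> set[str]:
    """One identifier per line (e.g. an RBP census)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_pwm_tsv(path: str | Path, threshold: float) -> Pwm:
    """PWM as a TSV with columns A, C, G, U of per-position log2-odds."""
    table = pd.read_csv(path, sep="\t")
    cols = ["A", "C", "G", "U"]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"PWM table lacks column(s): {sorted(missing)}")
    return Pwm(weights=table[cols].to_numpy(dtype=float), threshold=threshold)
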