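"""Compartment-by-replicate abundance matrices.

Every omics layer in this package (RNA counts, RPKM, CDS-mapped footprint
counts, protein log2 intensities, junction counts) is held in the same
container: a :class:`pandas.DataFrame` indexed by feature id whose columns
are named ``<compartment>_<replicate>``, e.g. ``soma_1 .. soma_3,
neurite_1 .. neurite_3``.  Compartments are the neuronal cell body
("soma") and its outgrowths ("neurite"), the two fractions recovered from
either face of a microporous membrane.

On disk the matrix is a TSV with a ``feature_id`` first column and the
sample labels as the remaining header fields.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

SOMA = "soma"
NEURITE = "neurite"
COMPARTMENTS = (SOMA, NEURITE)

_LABEL_RE = re.compile(r"^(soma|neurite)_([0-9]+)$")


def make_columns(n_replicates: int) -> list[str]:
    """Canonical column order: all soma replicates, then all neurite ones."""
    return [f"{c}_{r}" for c in COMPARTMENTS for r in range(1, n_replicates + 1)]


def parse_label(label: str) -> tuple[str, int]:
    m = _LABEL_RE.match(str(label))
    if m is None:
        raise ValueError(f"not a '<compartment>_<replicate>' sample label: {label!r}")
    return m.group(1), int(m.group(2))


def sample_labels(matrix: pd.DataFrame) -> list[tuple[str, int]]:
    return [parse_label(c) for c in matrix.columns]


def compartment_frame(matrix: pd.DataFrame, compartment: str) -> pd.DataFrame:
    """The replicate columns of one compartment, in replicate order."""
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    cols = [c for c in matrix.columns if parse_label(c)[0] == compartment]
    return matrix[cols]


def validate_matrix(matrix: pd.DataFrame, kind: str = "abundance") -> None:
    """Check the container invariants.

    Parameters
    ----------
    kind
        ``"counts"`` additionally requires integer, non-negative values;
        ``"abundance"`` requires non-negative values (NaN allowed, used for
        protein intensities with missing cells).
    """
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups[:5]}")
    seen = {c: 0 for c in COMPARTMENTS}
    for label in matrix.columns:
        comp, _ = parse_label(label)
        seen[comp] += 1
    missing = [c for c, n in seen.items() if n == 0]
    if missing:
        raise ValueError(f"no samples for compartment(s): {missing}")
    if kind == "counts":
        values = matrix.to_numpy()
        if np.isnan(values).any():
            raise ValueError("count matrix contains NaN")
        if (values < 0).any() or not np.allclose(values, np.round(values)):
            raise ValueError("counts must be non-negative integers")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    for c in df.columns:
        parse_label(c)
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")
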