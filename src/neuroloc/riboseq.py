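"""Ribosome-profiling QC and CDS-level translation quantification.

Footprints arrive as transcript-relative records (gene, raw 5' offset
from the CDS start, length, strand, compartment, replicate).  QC applies
the gel-size-selection window (27-30 nt) and measures reading-frame
periodicity: the P-site of each footprint is its 5' end plus a fixed
offset (12 nt, the standard for ~29-mers), and genuine translation shows
a strong excess of P-sites in frame 0 of the CDS.  Quantification counts
in-CDS P-sites per gene and converts them to RPKM over CDS length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import diffloc, quant

FOOTPRINT_COLUMNS = [
    "gene_id",
    "five_prime_offset",
    "length",
    "strand",
    "compartment",
    "replicate",
]


@dataclass(frozen=True)
class PsiteConfig:
    """P-site offset and retained footprint-length window."""

    offset_nt: int = 12
    min_len: int = 27
    max_len: int = 30

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.offset_nt < 0:
            raise ValueError("offset_nt must be >= 0")


def filter_footprints(
    table: pd.DataFrame, cfg: PsiteConfig | None = None
) -> pd.DataFrame:
    """Keep records with min_len <= length <= max_len (default 27-30 nt)."""
    cfg = cfg or PsiteConfig()
    if table.empty:
        return table.copy()
    keep = (table["length"] >= cfg.min_len) & (table["length"] <= cfg.max_len)
    return table[keep].reset_index(drop=True)


@dataclass(frozen=True)
class FrameProfile:
    """Reading-frame composition of a footprint table.

    ``per_length`` has one row per footprint length with the three frame
    counts, the frame-0 fraction, and a chi-square goodness-of-fit p-value
    against the uniform frame distribution; pooled statistics aggregate
    over lengths.
    """

    per_length: pd.DataFrame
    pooled_counts: np.ndarray
    frame0_fraction: float
    chi2_p: float
    n_skipped: int = 0


def frame_profile(table: pd.DataFrame, cfg: PsiteConfig | None = None) -> FrameProfile:
    """P-site frame counts, frame-0 fraction, and periodicity test.

    P-site position = five_prime_offset + offset_nt; frame = P-site mod 3
    (frame 0 is the frame of the CDS start codon).
    """
    cfg = cfg or PsiteConfig()
    cols = ["length", "frame_0", "frame_1", "frame_2", "frame0_fraction", "chi2_p"]
    if table.empty:
        return FrameProfile(
            per_length=pd.DataFrame(columns=cols).set_index("length"),
            pooled_counts=np.zeros(3, dtype=np.int64),
            frame0_fraction=float("nan"),
            chi2_p=float("nan"),
        )
    psite = table["five_prime_offset"].to_numpy() + cfg.offset_nt
    frame = np.mod(psite, 3)
    lengths = table["length"].to_numpy()

    rows = []
    for L in np.unique(lengths):
        f = frame[lengths == L]
        counts = np.bincount(f, minlength=3)[:3]
        total = counts.sum()
        chi2_p = float(stats.chisquare(counts).pvalue) if total else float("nan")
        rows.append(
            {
                "length": int(L),
                "frame_0": int(counts[0]),
                "frame_1": int(counts[1]),
                "frame_2": int(counts[2]),
                "frame0_fraction": counts[0] / total,
                "chi2_p": chi2_p,
            }
        )
    per_length = pd.DataFrame(rows).set_index("length")
    pooled = np.bincount(frame, minlength=3)[:3].astype(np.int64)
    return FrameProfile(
        per_length=per_length,
        pooled_counts=pooled,
        frame0_fraction=float(pooled[0] / pooled.sum()),
        chi2_p=float(stats.chisquare(pooled).pvalue),
    )


def cds_quantify(
    table: pd.DataFrame,
    cds_lengths: pd.Series,
    cfg: PsiteConfig | None = None,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Per-gene CDS RPKM from in-CDS P-site counts.

    A footprint is counted for its gene iff its P-site falls in the
    half-open interval ``[0, cds_length)``; counts are then RPKM-scaled
    with the CDS length as the feature length.  Genes with no counted
    footprint appear with zeros.  ``n_replicates`` fixes the column
    layout when the table does not cover every (compartment, replicate).
    """
    cfg = cfg or PsiteConfig()
    cds_lengths = pd.Series(cds_lengths, dtype=float)
    if (cds_lengths <= 0).any():
        bad = cds_lengths.index[cds_lengths <= 0].tolist()
        raise ValueError(f"non-positive CDS length for gene(s): {bad[:10]}")
    if table.empty:
        raise ValueError("footprint table is empty")
    missing = set(table["gene_id"]) - set(cds_lengths.index)
    if missing:
        raise ValueError(f"no CDS length for gene(s): {sorted(missing)[:10]}")

    psite = table["five_prime_offset"].to_numpy() + cfg.offset_nt
    gene_cds = cds_lengths.reindex(table["gene_id"]).to_numpy()
    in_cds = (psite >= 0) & (psite < gene_cds)
    hits = table[in_cds]

    if n_replicates is None:
        n_replicates = int(table["replicate"].max())
    counts = (
        hits.assign(sample=lambda d: d["compartment"] + "_" + d["replicate"].astype(str))
        .groupby(["gene_id", "sample"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    from .matrix import make_columns

    counts = counts.reindex(
        index=cds_lengths.index, columns=make_columns(n_replicates), fill_value=0
    ).astype(np.int64)
    counts.index.name = "feature_id"
    return quant.compute_rpkm(counts, cds_lengths)


def translation_enrichment(
    cds_rpkm: pd.DataFrame,
    pseudocount: float = 0.5,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Neurite/soma translation enrichment with a ``locally_translated``
    flag (log2FC > 1 and p < 0.05: at least twofold more ribosome
    footprints in neurites)."""
    records = diffloc.classify_localized(
        diffloc.compartment_enrichment(cds_rpkm, pseudocount=pseudocount),
        fc_thresh=fc_thresh,
        p_thresh=p_thresh,
    )
    records["locally_translated"] = records["call"] == "neurite"
    return records
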