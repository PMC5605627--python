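"""Localization of non-coding RNAs: lncRNAs and circular transcripts.

lncRNAs use the same enrichment machinery as everything else but a
higher detection threshold (10 RPKM).  Circular RNAs are compared to the
linear transcript of the same gene within each compartment: a gene is
*neurite-preferential circular* when the circular form dominates in
neurites (log2 circ/linear > 1) while the linear form dominates in soma
(log2 circ/linear < 0).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import COMPARTMENTS, compartment_frame
from . import quant


def lncrna_localization(
    rpkm: pd.DataFrame,
    records: pd.DataFrame,
    biotype: pd.Series | Mapping[str, str],
    thresholds: Mapping[str, float] | None = None,
) -> set[str]:
    """Neurite-enriched lncRNA set.

    A lncRNA qualifies iff it is detected in neurites above the lncRNA
    RPKM threshold (strict > 10 by default) and its enrichment record
    carries a ``neurite`` call (log2FC > 1, p < 0.05).
    """
    biotype = pd.Series(biotype, dtype=object)
    detected = quant.filter_expressed(rpkm, biotype, thresholds=thresholds)
    lnc = set(biotype.index[biotype == "lncRNA"])
    called = set(records.index[records["call"] == "neurite"])
    return lnc & detected["neurite"] & called


def circ_linear_ratio(
    circ_counts: pd.DataFrame,
    linear_counts: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-compartment log2 circular/linear abundance ratios.

    Counts are depth-normalized to counts per million *junction* reads,
    with the per-sample denominator taken over circular and linear
    junctions together (so within-sample circ/linear ratios are
    preserved), then averaged over replicates per compartment.  A gene
    present in only one table is treated as zero in the other and
    flagged in the ``partial`` column.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    all_genes = circ_counts.index.union(linear_counts.index)
    partial = ~(all_genes.isin(circ_counts.index) & all_genes.isin(linear_counts.index))
    shared_cols = [c for c in circ_counts.columns if c in linear_counts.columns]
    if not shared_cols:
        raise ValueError("circ and linear tables share no sample columns")
    circ = circ_counts.reindex(index=all_genes, columns=shared_cols).fillna(0.0)
    linear = linear_counts.reindex(index=all_genes, columns=shared_cols).fillna(0.0)

    depth = circ.sum(axis=0) + linear.sum(axis=0)
    scale = 1e6 / depth.replace(0, np.nan)
    circ_cpm = circ * scale
    lin_cpm = linear * scale

    out = {"partial": partial}
    for comp in COMPARTMENTS:
        c_mean = compartment_frame(circ_cpm, comp).mean(axis=1)
        l_mean = compartment_frame(lin_cpm, comp).mean(axis=1)
        out[f"circ_{comp}"] = c_mean
        out[f"linear_{comp}"] = l_mean
        out[f"log2_cl_{comp}"] = np.log2((c_mean + pseudocount) / (l_mean + pseudocount))
    records = pd.DataFrame(out, index=all_genes)
    records.index.name = "gene_id"
    records["circ_class"] = "none"
    return records


def classify_circ(records: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene a circular-RNA localization class.

    ``neurite_preferential_circ``: log2 circ/linear > 1 in neurites and
    < 0 in soma.  ``circ_enriched_elsewhere``: circ-dominant in neurites
    (log2 > 1) without the soma reversal.  Else ``none``.  The first
    class is a subset of the circ-dominant-in-neurites genes by
    construction.
    """
    out = records.copy()
    neurite_dom = out["log2_cl_neurite"] > 1
    soma_rev = out["log2_cl_soma"] < 0
    out["circ_class"] = "none"
    out.loc[neurite_dom & ~soma_rev, "circ_class"] = "circ_enriched_elsewhere"
    out.loc[neurite_dom & soma_rev, "circ_class"] = "neurite_preferential_circ"
    return out
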