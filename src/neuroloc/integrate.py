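"""Mechanism attribution: why is a protein enriched in neurites?

For every neurite-localized protein (protein log2FC > 1, p < 0.05) the
classifier combines the RNA-seq and Ribo-seq enrichment of the encoding
gene into one of five mechanisms:

* ``mrna_localization`` -- the mRNA itself is neurite-enriched
  (RNA log2FC > 1, p < 0.05): protein is made where the mRNA went.
* ``intermediate``      -- the mRNA is moderately neurite-enriched
  (0 < RNA log2FC < 1): mixed mRNA- and protein-level contributions.
* for proteins whose mRNA is *not* neurite-enriched (RNA log2FC < 0),
  the translation layer arbitrates: ``protein_transport`` (ribo
  log2FC < 0, the protein is moved after synthesis in the soma),
  ``local_translation`` (ribo log2FC > 1, translational preference alone
  suffices), or ``combination`` (0 < ribo log2FC < 1).

Strict inequalities leave measure-zero boundaries; exact 0/1 values fall
to the adjacent lower-priority class (RNA boundary -> intermediate, ribo
boundary -> combination).  Genes missing a required layer are reported
as ``unquantified`` rather than silently dropped, so the five localized
categories plus ``unquantified`` always partition the neurite-localized
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffloc

LOCALIZED_CATEGORIES = (
    "mrna_localization",
    "intermediate",
    "protein_transport",
    "local_translation",
    "combination",
    "unquantified",
)
ALL_CATEGORIES = LOCALIZED_CATEGORIES + ("not_neurite_localized",)

CALL_COLUMNS = [
    "protein_log2fc",
    "protein_p",
    "rna_log2fc",
    "rna_p",
    "ribo_log2fc",
    "category",
]


def _categorize(
    protein_neurite: bool,
    rna_log2fc: float,
    rna_p: float,
    ribo_log2fc: float,
    fc_thresh: float,
    p_thresh: float,
) -> str:
    if not protein_neurite:
        return "not_neurite_localized"
    if np.isnan(rna_log2fc):
        return "unquantified"
    if rna_log2fc > fc_thresh and rna_p < p_thresh:
        return "mrna_localization"
    if rna_log2fc >= 0:
        # covers 0 < fc < 1, the fc > 1 / p >= 0.05 case, and both boundaries
        return "intermediate"
    if np.isnan(ribo_log2fc):
        return "unquantified"
    if ribo_log2fc < 0:
        return "protein_transport"
    if ribo_log2fc > fc_thresh:
        return "local_translation"
    return "combination"


def call_mechanism(
    protein_rec: pd.Series,
    rna_rec: pd.Series | None,
    ribo_rec: pd.Series | None,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
) -> pd.Series:
    """Mechanism call for a single gene from its three layer records.

    ``protein_rec`` is required (raises if absent); missing RNA or ribo
    records yield ``unquantified`` when the decision needs them.
    """
    if protein_rec is None:
        raise ValueError("protein record is required")
    protein_neurite = bool(
        protein_rec["log2fc"] > fc_thresh and protein_rec["pvalue"] < p_thresh
    )
    rna_fc = float(rna_rec["log2fc"]) if rna_rec is not None else float("nan")
    rna_p = float(rna_rec["pvalue"]) if rna_rec is not None else float("nan")
    ribo_fc = float(ribo_rec["log2fc"]) if ribo_rec is not None else float("nan")
    category = _categorize(protein_neurite, rna_fc, rna_p, ribo_fc, fc_thresh, p_thresh)
    return pd.Series(
        {
            "protein_log2fc": protein_rec["log2fc"],
            "protein_p": protein_rec["pvalue"],
            "rna_log2fc": rna_fc,
            "rna_p": rna_p,
            "ribo_log2fc": ribo_fc,
            "category": category,
        }
    )


def mechanism_calls(
    protein_records: pd.DataFrame,
    rna_records: pd.DataFrame,
    ribo_records: pd.DataFrame,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Vectorized mechanism attribution over all quantified proteins.

    Rows are the proteins of ``protein_records``; RNA and ribo layers are
    joined on the feature index and may be incomplete.
    """
    idx = protein_records.index
    rna_fc = rna_records["log2fc"].reindex(idx)
    rna_p = rna_records["pvalue"].reindex(idx)
    ribo_fc = ribo_records["log2fc"].reindex(idx)
    prot_neurite = (protein_records["log2fc"] > fc_thresh) & (
        protein_records["pvalue"] < p_thresh
    )

    category = pd.Series("not_neurite_localized", index=idx, dtype=object)
    loc = prot_neurite.to_numpy()
    rfc = rna_fc.to_numpy()
    rp = rna_p.to_numpy()
    bfc = ribo_fc.to_numpy()

    category[loc & np.isnan(rfc)] = "unquantified"
    known = loc & ~np.isnan(rfc)
    category[known & (rfc > fc_thresh) & (rp < p_thresh)] = "mrna_localization"
    rest = known & ~((rfc > fc_thresh) & (rp < p_thresh))
    category[rest & (rfc >= 0)] = "intermediate"
    neg = rest & (rfc < 0)
    category[neg & np.isnan(bfc)] = "unquantified"
    neg_known = neg & ~np.isnan(bfc)
    category[neg_known & (bfc < 0)] = "protein_transport"
    category[neg_known & (bfc > fc_thresh)] = "local_translation"
    category[neg_known & (bfc >= 0) & (bfc <= fc_thresh)] = "combination"

    return pd.DataFrame(
        {
            "protein_log2fc": protein_records["log2fc"],
            "protein_p": protein_records["pvalue"],
            "rna_log2fc": rna_fc,
            "rna_p": rna_p,
            "ribo_log2fc": ribo_fc,
            "category": category,
        },
        index=idx,
    )


@dataclass(frozen=True)
class SummaryReport:
    """Counts and fractions per mechanism category plus cross-layer stats."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n_localized_total: int
    fraction_mrna: float
    rna_protein_pearson: float | None
    mean_ribo_log2fc: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "fractions": self.fractions,
            "n_localized_total": self.n_localized_total,
            "fraction_mrna": self.fraction_mrna,
            "rna_protein_pearson": self.rna_protein_pearson,
            "mean_ribo_log2fc": self.mean_ribo_log2fc,
        }


def summarize(calls: pd.DataFrame) -> SummaryReport:
    """Aggregate mechanism calls into the headline partition.

    ``n_localized_total`` counts every neurite-localized protein (every
    category except ``not_neurite_localized``); fractions are taken over
    that denominator and sum to 1 when it is positive.  With no localized
    proteins the fractions are NaN and a warning is emitted.
    """
    import warnings

    localized = calls[calls["category"] != "not_neurite_localized"]
    n_total = int(len(localized))
    counts = {
        cat: int((localized["category"] == cat).sum()) for cat in LOCALIZED_CATEGORIES
    }
    if n_total == 0:
        warnings.warn("no neurite-localized proteins: fractions undefined", stacklevel=2)
        fractions = {cat: float("nan") for cat in LOCALIZED_CATEGORIES}
        fraction_mrna = float("nan")
    else:
        fractions = {cat: counts[cat] / n_total for cat in LOCALIZED_CATEGORIES}
        fraction_mrna = counts["mrna_localization"] / n_total

    try:
        r, _, _ = diffloc.cross_layer_correlation(
            calls["rna_log2fc"], calls["protein_log2fc"]
        )
    except ValueError:
        r = None

    mean_ribo = {
        cat: float(localized.loc[localized["category"] == cat, "ribo_log2fc"].mean())
        for cat in LOCALIZED_CATEGORIES
        if counts[cat]
    }
    return SummaryReport(
        counts=counts,
        fractions=fractions,
        n_localized_total=n_total,
        fraction_mrna=fraction_mrna,
        rna_protein_pearson=r,
        mean_ribo_log2fc=mean_ribo,
    )


def rbp_overlay(protein_records: pd.DataFrame, census: set[str]) -> pd.DataFrame:
    """Neurite-localized proteins that appear in an RNA-binding-protein
    census, with their enrichment statistics attached."""
    if not census:
        raise ValueError("RBP census is empty")
    neurite = protein_records[protein_records["call"] == "neurite"]
    return neurite[neurite.index.isin(census)]
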