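"""Label-swap SILAC ratio aggregation.

A pulsed-labeling experiment measures each protein twice with swapped
isotope channels: the forward ratio is H/M (heavy on neurites), the
reverse ratio M/H (heavy on soma), so labeling bias cancels between the
two.  Both ratios estimate the same neurite/soma quantity and are
averaged in log space -- the geometric mean -- which makes the swap
identities exact: the aggregate does not depend on which experiment is
labeled forward, and inverting every ratio negates it.  Proteins
quantified in only one experiment are kept with ``n_experiments = 1``
rather than dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffloc


def _as_ratio_series(table: pd.Series | pd.DataFrame, name: str) -> pd.Series:
    if isinstance(table, pd.DataFrame):
        if "ratio" not in table.columns:
            raise ValueError(f"{name} table needs a 'ratio' column")
        table = table["ratio"]
    return table.astype(float)


def labelswap_aggregate(
    fw: pd.Series | pd.DataFrame, rev: pd.Series | pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outer-join forward (H/M) and reverse (M/H) ratio tables.

    Returns ``(ratios, rejected)``.  ``ratios`` is indexed by protein id
    with columns ``ratio_fw, ratio_rev, avg_log2, n_experiments``, where
    ``avg_log2`` is the mean of the available log2 ratios.  Records with
    a non-positive ratio are rejected and reported separately.
    """
    fw = _as_ratio_series(fw, "forward")
    rev = _as_ratio_series(rev, "reverse")
    joined = pd.concat(
        [fw.rename("ratio_fw"), rev.rename("ratio_rev")], axis=1, join="outer"
    )
    joined.index.name = "protein_id"

    bad = (joined["ratio_fw"] <= 0) | (joined["ratio_rev"] <= 0)
    rejected = joined[bad.fillna(False)]
    ratios = joined[~bad.fillna(False)].copy()

    log_fw = np.log2(ratios["ratio_fw"])
    log_rev = np.log2(ratios["ratio_rev"])
    ratios["avg_log2"] = pd.concat([log_fw, log_rev], axis=1).mean(axis=1)
    ratios["n_experiments"] = ratios[["ratio_fw", "ratio_rev"]].notna().sum(axis=1)
    ratios = ratios[ratios["n_experiments"] > 0]
    return ratios, rejected


def compare_to_riboseq(
    ratios: pd.DataFrame, ribo_records: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation of SILAC ``avg_log2`` against ribosome-footprint
    log2 fold changes over shared proteins; returns ``(r, pvalue, n)``."""
    return diffloc.cross_layer_correlation(ratios["avg_log2"], ribo_records)


def threshold_upregulated(ratios: pd.DataFrame, fold: float = 4.0) -> set[str]:
    """Proteins whose aggregated ratio strictly exceeds ``fold``
    (e.g. the > 4-fold criterion for differentiation-induced proteins)."""
    return set(ratios.index[2.0 ** ratios["avg_log2"] > fold])
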