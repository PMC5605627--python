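"""Normalization and completion of raw quantifications.

RPKM for count matrices, biotype-specific expression thresholds, and the
down-shifted-Gaussian imputation of missing protein intensities that is
standard for label-free MS data (missingness concentrates at low
intensity, so missing cells are drawn from the low tail of each sample's
observed distribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import COMPARTMENTS, compartment_frame, validate_matrix

#: detection thresholds in mean RPKM, strict inequality
DEFAULT_THRESHOLDS = {"coding": 1.0, "lncRNA": 10.0}


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series | Mapping[str, float]) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads.

    ``RPKM[f, s] = counts[f, s] / (lengths[f]/1000 * colsum[s]/1e6)``.
    The per-library denominator is the column total of the counted
    features themselves.  Doubling every count leaves RPKM unchanged, and
    each column satisfies ``sum_f RPKM[f,s] * lengths[f]/1000 == 1e6``.
    """
    validate_matrix(counts, kind="counts")
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise ValueError(f"no length for counted feature(s): {missing.tolist()[:10]}")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive length for feature(s): {bad[:10]}")
    colsums = counts.sum(axis=0)
    if (colsums <= 0).any():
        bad = colsums.index[colsums <= 0].tolist()
        raise ValueError(f"zero library size in column(s): {bad}")
    kb = lengths.to_numpy()[:, None] / 1e3
    per_million = colsums.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        counts.to_numpy() / (kb * per_million), index=counts.index, columns=counts.columns
    )


def filter_expressed(
    rpkm: pd.DataFrame,
    biotype: pd.Series | Mapping[str, str],
    thresholds: Mapping[str, float] | None = None,
) -> dict[str, set[str]]:
    """Per-compartment detected-feature sets.

    A feature counts as detected in a compartment iff its mean RPKM over
    that compartment's replicates strictly exceeds its biotype threshold
    (default: 1 RPKM for coding transcripts, 10 RPKM for lncRNAs).
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    biotype = pd.Series(biotype, dtype=object)
    if rpkm.empty:
        return {c: set() for c in COMPARTMENTS}
    unknown_feature = rpkm.index.difference(biotype.index)
    if len(unknown_feature) > 0:
        raise ValueError(f"no biotype for feature(s): {unknown_feature.tolist()[:10]}")
    biotype = biotype.reindex(rpkm.index)
    unknown_type = set(biotype.unique()) - set(thresholds)
    if unknown_type:
        raise ValueError(f"no threshold for biotype(s): {sorted(unknown_type)}")
    cutoff = biotype.map(thresholds).astype(float)
    detected: dict[str, set[str]] = {}
    for comp in COMPARTMENTS:
        mean = compartment_frame(rpkm, comp).mean(axis=1)
        detected[comp] = set(rpkm.index[mean > cutoff])
    return detected


@dataclass(frozen=True)
class ImputationParams:
    """Down-shifted Gaussian imputation, in units of each sample column's
    observed standard deviation (the Perseus-style defaults)."""

    shift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift <= 0 or self.width <= 0:
            raise ValueError("shift and width must be > 0")


def impute_missing(
    log_intensities: pd.DataFrame,
    params: ImputationParams | None = None,
    cells: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing log2 intensities column-by-column.

    Each missing cell in sample ``s`` is drawn from
    ``Normal(mu_s - shift * sd_s, width * sd_s)`` where ``mu_s``/``sd_s``
    are the mean/SD of the observed values in that column.  Observed cells
    are untouched (bitwise).  Returns the completed matrix and a boolean
    mask of imputed cells.

    ``cells`` optionally restricts imputation to a boolean subset of
    cells (e.g. only proteins undetected in a whole compartment); other
    missing cells stay NaN.
    """
    params = params or ImputationParams()
    validate_matrix(log_intensities)
    rng = np.random.default_rng(params.seed)
    out = log_intensities.copy()
    mask = log_intensities.isna()
    if cells is not None:
        mask &= cells.reindex_like(mask).fillna(False).astype(bool)
    for col in out.columns:
        observed = log_intensities[col].dropna()
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        holes = mask[col]
        n_missing = int(holes.sum())
        if n_missing == 0:
            continue
        mu, sd = observed.mean(), observed.std(ddof=1)
        out.loc[holes, col] = rng.normal(
            mu - params.shift * sd, params.width * sd, size=n_missing
        )
    return out, mask
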