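"""Neurite/soma enrichment statistics and localization calls.

The common currency of every omics layer is an *enrichment record*: a
log2 fold change of mean neurite over mean soma abundance, a two-sided
p-value from a two-sample t-test on per-replicate log2 values (pooled
Student by default -- exact size at 3-vs-3 replicates -- with Welch as
an option), a BH-adjusted p-value (reported alongside; calls use the raw
p), and a three-way localization call at strict thresholds (default
|log2FC| > 1, p < 0.05).
Also provides cross-layer Pearson correlation of fold changes and the
qPCR delta-delta-Ct computation used for validation of localized RNAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import NEURITE, SOMA, compartment_frame, validate_matrix

#: smallest strictly positive p-value we report; p = 0 is forbidden
MIN_P = np.finfo(float).tiny

RECORD_COLUMNS = [
    "log2fc",
    "pvalue",
    "padj",
    "mean_abundance",
    "n_soma",
    "n_neurite",
    "degenerate",
    "call",
]


def _ttest(
    a: np.ndarray, b: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test of a (neurite) vs b (soma), NaN-aware.

    ``method="student"`` pools the variance (df = n_a + n_b - 2; exact
    size at the pipeline's tiny equal replicate counts);
    ``method="welch"`` uses the Welch-Satterthwaite approximation.

    Returns (pvalue, n_a, n_b, degenerate).  Rows where both groups have
    zero variance get p = 1 when the means agree, else the smallest
    representable p with the degenerate flag set.  Rows with fewer than
    two observations in either group get p = NaN.
    """
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
        var_a = np.full(a.shape[0], np.nan)
        var_b = np.full(b.shape[0], np.nan)
        ok_a = n_a >= 2
        ok_b = n_b >= 2
        var_a[ok_a] = np.nanvar(a[ok_a], axis=1, ddof=1)
        var_b[ok_b] = np.nanvar(b[ok_b], axis=1, ddof=1)
        if method == "welch":
            se2 = var_a / n_a + var_b / n_b
            df = se2**2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
        else:
            pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
            se2 = pooled * (1.0 / n_a + 1.0 / n_b)
            df = (n_a + n_b - 2).astype(float)
        t = (mean_a - mean_b) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)

    usable = ok_a & ok_b
    degenerate = usable & (se2 == 0)
    equal_means = degenerate & (mean_a == mean_b)
    p = np.where(equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, MIN_P, p)
    p = np.where(usable, np.clip(p, MIN_P, 1.0), np.nan)
    return p, n_a, n_b, degenerate & ~equal_means


def compartment_enrichment(
    matrix: pd.DataFrame,
    pseudocount: float = 0.5,
    scale: str = "linear",
    test: str = "student",
) -> pd.DataFrame:
    """Per-feature neurite/soma enrichment.

    Parameters
    ----------
    matrix
        Compartment matrix; linear abundances (counts, RPKM) or, with
        ``scale="log2"``, already log2-transformed intensities.
    pseudocount
        Added before ratios/logs on linear data; must be > 0 there.
    scale
        ``"linear"``: log2fc = log2((mean_N + pc) / (mean_S + pc)) and the
        t-test runs on log2(value + pc).  ``"log2"``: values are used
        directly; log2fc is the difference of compartment means.
    test
        ``"student"`` (pooled variance; default -- exact size at 3-vs-3
        replicate counts, where the Welch approximation is markedly
        conservative) or ``"welch"``.

    Returns a DataFrame indexed by feature with columns ``log2fc, pvalue,
    padj, mean_abundance, n_soma, n_neurite, degenerate, call`` (call is
    initialized to ``"none"``; see :func:`classify_localized`).
    """
    validate_matrix(matrix)
    if scale not in ("linear", "log2"):
        raise ValueError(f"unknown scale {scale!r}")
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    soma = compartment_frame(matrix, SOMA)
    neurite = compartment_frame(matrix, NEURITE)
    if soma.shape[1] < 2 or neurite.shape[1] < 2:
        raise ValueError("need >= 2 replicates per compartment")

    if scale == "linear":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 for linear-scale data")
        vals = matrix.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("linear-scale abundances must be >= 0")
        log_s = np.log2(soma.to_numpy(dtype=float) + pseudocount)
        log_n = np.log2(neurite.to_numpy(dtype=float) + pseudocount)
        log2fc = np.log2(
            (np.nanmean(neurite.to_numpy(dtype=float), axis=1) + pseudocount)
            / (np.nanmean(soma.to_numpy(dtype=float), axis=1) + pseudocount)
        )
    else:
        log_s = soma.to_numpy(dtype=float)
        log_n = neurite.to_numpy(dtype=float)
        log2fc = np.nanmean(log_n, axis=1) - np.nanmean(log_s, axis=1)

    p, n_neurite, n_soma, degenerate = _ttest(log_n, log_s, test)

    padj = np.full_like(p, np.nan)
    finite = ~np.isnan(p)
    if finite.any():
        padj[finite] = multipletests(p[finite], method="fdr_bh")[1]

    records = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": p,
            "padj": padj,
            "mean_abundance": np.nanmean(matrix.to_numpy(dtype=float), axis=1),
            "n_soma": n_soma,
            "n_neurite": n_neurite,
            "degenerate": degenerate,
            "call": "none",
        },
        index=matrix.index.rename("feature_id"),
    )
    return records


def classify_localized(
    records: pd.DataFrame, fc_thresh: float = 1.0, p_thresh: float = 0.05
) -> pd.DataFrame:
    """Three-way localization call at strict thresholds.

    ``neurite`` iff log2fc > fc_thresh and p < p_thresh; ``soma`` iff
    log2fc < -fc_thresh and p < p_thresh; else ``none``.
    """
    out = records.copy()
    sig = out["pvalue"] < p_thresh
    out["call"] = "none"
    out.loc[(out["log2fc"] > fc_thresh) & sig, "call"] = "neurite"
    out.loc[(out["log2fc"] < -fc_thresh) & sig, "call"] = "soma"
    return out


def cross_layer_correlation(
    records_a: pd.DataFrame | pd.Series, records_b: pd.DataFrame | pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation of log2 fold changes over shared features.

    Accepts enrichment-record frames (their ``log2fc`` column is used) or
    plain Series of fold changes.  Returns ``(r, pvalue, n)``; the
    p-value is the usual t-transform of r.  Requires >= 3 shared features.
    """
    a = records_a["log2fc"] if isinstance(records_a, pd.DataFrame) else records_a
    b = records_b["log2fc"] if isinstance(records_b, pd.DataFrame) else records_b
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"need >= 3 shared features, got {len(joined)}")
    if joined["a"].nunique() == 1 or joined["b"].nunique() == 1:
        raise ValueError("correlation undefined for a constant fold-change vector")
    r, p = stats.pearsonr(joined["a"], joined["b"])
    return float(r), float(p), int(len(joined))


def delta_delta_ct(
    target_ct: tuple[float, float], reference_ct: tuple[float, float]
) -> float:
    """Relative neurite/soma expression by the delta-delta-Ct method.

    Arguments are ``(Ct_neurite, Ct_soma)`` for the target RNA and for the
    reference RNA (e.g. rRNA).  Returns ``2 ** -ddCt`` where
    ``ddCt = (Ct_t,N - Ct_r,N) - (Ct_t,S - Ct_r,S)``.
    """
    (t_n, t_s), (r_n, r_s) = target_ct, reference_ct
    for v in (t_n, t_s, r_n, r_s):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (t_n - r_n) - (t_s - r_s)
    return float(2.0 ** (-ddct))
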