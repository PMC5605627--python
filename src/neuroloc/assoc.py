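"""2x2 set-association statistics and a position-weight-matrix scanner.

Used for motif and modification-site enrichment: build a foreground set
(genes localized and translated in neurites) and reference sets
(soma-localized or equally distributed genes), tabulate motif hits into
a 2x2 contingency table, and test the association with Fisher's exact
test.  The two-sided p-value follows the probability-mass rule: the sum
of hypergeometric probabilities of all margin-preserving tables no more
likely than the observed one.  The odds ratio is the sample
cross-product ratio a*d / (b*c), with an infinity convention when
b*c = 0 and a*d > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts: rows in-set/out-of-set, columns hit/no-hit."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p-value.

    Returns ``(odds_ratio, p)``.  The odds ratio is ``a*d / (b*c)``
    (``inf`` when ``b*c == 0`` with ``a*d > 0``; NaN when both products
    vanish).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return odds, p


def define_gene_sets(
    rna_records: pd.DataFrame,
    protein_records: pd.DataFrame,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    band: float = 0.58,
) -> tuple[set[str], set[str], set[str]]:
    """Foreground and reference gene sets for motif association.

    * foreground: RNA and protein log2FC > ``fc_thresh`` with both
      p-values < ``p_thresh`` (localized to and translated in neurites);
    * reference_soma: both log2FC < -``fc_thresh``, both p < ``p_thresh``;
    * reference_unlocalized: both log2FC strictly inside (-``band``,
      ``band``) -- about 1.5-fold either way -- with no p condition.

    The three sets are pairwise disjoint by construction.
    """
    joined = pd.concat(
        [
            rna_records[["log2fc", "pvalue"]].add_prefix("rna_"),
            protein_records[["log2fc", "pvalue"]].add_prefix("prot_"),
        ],
        axis=1,
        join="inner",
    ).dropna()
    fg = joined[
        (joined["rna_log2fc"] > fc_thresh)
        & (joined["prot_log2fc"] > fc_thresh)
        & (joined["rna_pvalue"] < p_thresh)
        & (joined["prot_pvalue"] < p_thresh)
    ]
    soma = joined[
        (joined["rna_log2fc"] < -fc_thresh)
        & (joined["prot_log2fc"] < -fc_thresh)
        & (joined["rna_pvalue"] < p_thresh)
        & (joined["prot_pvalue"] < p_thresh)
    ]
    unloc = joined[
        joined["rna_log2fc"].abs().lt(band) & joined["prot_log2fc"].abs().lt(band)
    ]
    return set(fg.index), set(soma.index), set(unloc.index)


_ALPHABET = "ACGU"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


@dataclass(frozen=True)
class Pwm:
    """Log2-odds position weight matrix over {A, C, G, U} (T read as U).

    ``weights`` has shape (width, 4); ``threshold`` is the minimum
    best-window score that counts as a hit.
    """

    weights: np.ndarray
    threshold: float
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError("weights must have shape (width >= 1, 4)")
        bg = np.asarray(self.background, dtype=float)
        if abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
            raise ValueError("background must be a positive distribution over 4 bases")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_probabilities(
        cls,
        probs: np.ndarray,
        threshold: float,
        background: np.ndarray | None = None,
        pseudo: float = 1e-3,
    ) -> "Pwm":
        """Build log2-odds weights from per-position base probabilities."""
        probs = np.asarray(probs, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        weights = np.log2((probs + pseudo) / bg[None, :])
        return cls(weights=weights, threshold=threshold, background=bg)


def _encode(seq_id: str, sequence: str) -> np.ndarray:
    out = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence.upper()):
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            raise ValueError(
                f"invalid character {ch!r} at position {i} of sequence {seq_id!r}"
            )
        out[i] = idx
    return out


def scan_pwm(sequences: dict[str, str], pwm: Pwm) -> pd.DataFrame:
    """Best-window PWM score per sequence.

    Returns a DataFrame indexed by sequence id with ``max_score`` (NaN
    for sequences shorter than the motif), ``hit`` (max_score >=
    threshold) and ``too_short``.  Raises on sequence characters outside
    A/C/G/U/T, naming the sequence and position.
    """
    if not sequences:
        raise ValueError("no sequences to scan")
    w = pwm.width
    rows = []
    for seq_id, seq in sequences.items():
        enc = _encode(seq_id, seq)
        n = enc.size - w + 1
        if n < 1:
            rows.append((seq_id, float("nan"), False, True))
            continue
        scores = np.zeros(n)
        for j in range(w):
            scores += pwm.weights[j, enc[j : j + n]]
        best = float(scores.max())
        rows.append((seq_id, best, best >= pwm.threshold, False))
    return pd.DataFrame(
        rows, columns=["id", "max_score", "hit", "too_short"]
    ).set_index("id")


def set_association(
    hits: pd.Series | pd.DataFrame, set_a: set[str], set_b: set[str]
) -> tuple[ContingencyTable2x2, float, float]:
    """Fisher association between set membership and motif hits.

    ``hits`` maps ids to booleans (or is a :func:`scan_pwm` result, whose
    ``hit`` column is used).  The two sets must be disjoint and non-empty
    and every member must have a defined hit value.  Returns the 2x2
    table (rows set_a/set_b, columns hit/no-hit), odds ratio and
    two-sided p.
    """
    if isinstance(hits, pd.DataFrame):
        hits = hits["hit"]
    hits = hits.astype(bool)
    overlap = set_a & set_b
    if overlap:
        raise ValueError(f"sets overlap: {sorted(overlap)[:5]}")
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    undefined = (set_a | set_b) - set(hits.index)
    if undefined:
        raise ValueError(f"no hit value for: {sorted(undefined)[:5]}")
    a = int(hits[list(set_a)].sum())
    b = len(set_a) - a
    c = int(hits[list(set_b)].sum())
    d = len(set_b) - c
    table = ContingencyTable2x2(a, b, c, d)
    odds, p = fisher_exact(table)
    return table, odds, p
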