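"""Synthetic compartmentalized multi-omics data with known ground truth.

The generator emulates the statistical structure of a neurite/soma
fractionation experiment on stem-cell-derived neurons: negative-binomial
RNA-seq counts with compartment-specific means, ribosome footprints
(27-31 nt) with a tunable reading-frame bias, log-normal protein
intensities with intensity-dependent (MNAR) missingness, label-swap
SILAC-style ratio pairs, and circular/linear junction counts.  Each gene
carries a *mechanism* label that fixes the sign pattern of its true RNA,
translation (ribo) and protein neurite/soma log2 fold changes, so every
downstream analysis stage can be scored against ground truth.

Mechanism taxonomy (effects in log2 units, ``L`` = ``loc_effect_log2``,
``M`` = ``mid_effect_log2``):

====================  =========  =========  =========
mechanism             RNA fc     ribo fc    protein fc
====================  =========  =========  =========
mrna_localization      L          L          L
intermediate           M          M          L
protein_transport     -L/2       -L/2        L
local_translation     -L/2        L          L
combination           -L/2        M          L
soma_restricted       -L         -L         -L
unlocalized            0          0          0
====================  =========  =========  =========

All randomness comes from per-table :func:`numpy.random.default_rng`
streams seeded as ``seed + <fixed per-table offset>``, so adding one table
never perturbs another and identical configs give byte-identical bundles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import COMPARTMENTS, NEURITE, make_columns

MECHANISMS = (
    "mrna_localization",
    "intermediate",
    "protein_transport",
    "local_translation",
    "combination",
    "soma_restricted",
    "unlocalized",
)
#: mechanisms whose definition involves no protein layer; only these may be
#: assigned to lncRNA genes (interpreted at the RNA level).
RNA_LEVEL_MECHANISMS = ("mrna_localization", "soma_restricted", "unlocalized")

DEFAULT_MECHANISM_FRACTIONS: Mapping[str, float] = MappingProxyType(
    {
        "mrna_localization": 0.08,
        "intermediate": 0.05,
        "protein_transport": 0.02,
        "local_translation": 0.01,
        "combination": 0.02,
        "soma_restricted": 0.12,
        "unlocalized": 0.70,
    }
)

# per-table RNG stream offsets (added to SimConfig.seed)
_STREAM = {"genes": 0, "rna": 1, "footprints": 2, "protein": 3, "silac": 4, "circ": 5}

DEFAULT_FOOTPRINT_LENGTH_PROBS: Mapping[int, float] = MappingProxyType(
    {27: 0.20, 28: 0.30, 29: 0.30, 30: 0.15, 31: 0.05}
)


class ConfigurationError(ValueError):
    """Raised for an invalid :class:`SimConfig`."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one synthetic experiment.

    Defaults describe the study conditions the package's acceptance
    benchmarks run under: 2,000 genes, 2 compartments x 3 replicates,
    a 2.0 log2 localization effect, NB dispersion 0.05 and 0.5 log2
    protein noise.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    mechanism_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MECHANISM_FRACTIONS)
    )
    lncrna_fraction: float = 0.10
    rna_depth: float = 1_000_000.0
    footprint_depth: float = 200_000.0
    junction_depth: float = 200_000.0
    frame0_bias: float = 0.85
    loc_effect_log2: float = 2.0
    mid_effect_log2: float = 0.5
    protein_noise_sd: float = 0.4
    rna_dispersion: float = 0.05
    protein_rna_slope: float = 1.0
    protein_intercept: float = 18.0
    missing_steepness: float = 1.5
    missing_midpoint: float = 19.0
    silac_noise_sd: float = 0.3
    silac_coverage: float = 0.2
    circ_fraction: float = 0.05
    circ_background_ratio: float = 0.1
    footprint_length_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FOOTPRINT_LENGTH_PROBS)
    )
    base_expression_log2_mean: float = 5.0
    base_expression_log2_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        fr = self.mechanism_fractions
        unknown = set(fr) - set(MECHANISMS)
        if unknown:
            raise ConfigurationError(f"unknown mechanisms: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ConfigurationError("mechanism fractions must be >= 0")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ConfigurationError("mechanism fractions must sum to 1")
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates per compartment")
        if not (1.0 / 3.0 <= self.frame0_bias <= 1.0):
            raise ConfigurationError("frame0_bias must lie in [1/3, 1]")
        if not (0.0 <= self.lncrna_fraction < 1.0):
            raise ConfigurationError("lncrna_fraction must lie in [0, 1)")
        if abs(sum(self.footprint_length_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("footprint length probabilities must sum to 1")

    def stream(self, table: str) -> np.random.Generator:
        return np.random.default_rng(self.seed + _STREAM[table])


def _quota_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation: class counts are exact, not sampled."""
    order = [m for m in MECHANISMS if fractions.get(m, 0.0) > 0]
    raw = {m: fractions[m] * n for m in order}
    counts = {m: math.floor(raw[m]) for m in order}
    short = n - sum(counts.values())
    by_remainder = sorted(order, key=lambda m: (-(raw[m] - counts[m]), m))
    for m in by_remainder[:short]:
        counts[m] += 1
    return counts


def simulate_genes(config: SimConfig) -> pd.DataFrame:
    """Draw the gene annotation plus per-gene ground truth.

    Returns a DataFrame indexed by ``gene_id`` with columns ``biotype``
    (coding / lncRNA), ``tx_length``, ``cds_length``, ``strand``,
    ``mechanism``, ``base_expression`` and the three true log2 fold
    changes ``rna_loc_log2fc``, ``ribo_loc_log2fc``, ``prot_loc_log2fc``
    (the latter two NaN for lncRNAs, which have no protein product).
    """
    config.validate()
    rng = config.stream("genes")
    n = config.n_genes
    L = config.loc_effect_log2
    M = config.mid_effect_log2
    effects = {
        "mrna_localization": (L, L, L),
        "intermediate": (M, M, L),
        "protein_transport": (-L / 2, -L / 2, L),
        "local_translation": (-L / 2, L, L),
        "combination": (-L / 2, M, L),
        "soma_restricted": (-L, -L, -L),
        "unlocalized": (0.0, 0.0, 0.0),
    }

    counts = _quota_counts(config.mechanism_fractions, n)
    mech = np.concatenate([np.repeat(m, c) for m, c in counts.items()]) if n else np.array([], dtype=object)
    rng.shuffle(mech)

    # lncRNA flags only among genes whose mechanism needs no protein layer
    n_lnc = round(config.lncrna_fraction * n)
    eligible = np.flatnonzero(np.isin(mech, RNA_LEVEL_MECHANISMS))
    if n_lnc > eligible.size:
        raise ConfigurationError(
            f"lncrna_fraction requires {n_lnc} RNA-level genes but only "
            f"{eligible.size} have RNA-level mechanisms"
        )
    lnc_idx = rng.choice(eligible, size=n_lnc, replace=False) if n_lnc else np.array([], dtype=int)
    biotype = np.repeat("coding", n).astype(object)
    biotype[lnc_idx] = "lncRNA"

    coding = biotype == "coding"
    n_codons = rng.integers(100, 801, size=n)
    utr = rng.integers(200, 1501, size=n)
    cds_length = np.where(coding, 3 * n_codons, 0)
    tx_length = np.where(coding, cds_length + utr, rng.integers(500, 3001, size=n))

    base = 2.0 ** rng.normal(
        config.base_expression_log2_mean, config.base_expression_log2_sd, size=n
    )

    eff = np.array([effects[m] for m in mech]) if n else np.empty((0, 3))
    rna_fc = eff[:, 0] if n else np.array([])
    ribo_fc = np.where(coding, eff[:, 1], np.nan) if n else np.array([])
    prot_fc = np.where(coding, eff[:, 2], np.nan) if n else np.array([])

    width = max(4, len(str(max(n, 1))))
    genes = pd.DataFrame(
        {
            "biotype": biotype,
            "tx_length": tx_length.astype(int),
            "cds_length": cds_length.astype(int),
            "strand": "+",
            "mechanism": mech,
            "base_expression": base,
            "rna_loc_log2fc": rna_fc,
            "ribo_loc_log2fc": ribo_fc,
            "prot_loc_log2fc": prot_fc,
        },
        index=pd.Index([f"g{i:0{width}d}" for i in range(1, n + 1)], name="gene_id"),
    )
    return genes


def _column_means(genes: pd.DataFrame, fc_col: str, n_replicates: int) -> pd.DataFrame:
    """Expected abundance per gene x sample before library scaling."""
    base = genes["base_expression"].to_numpy()
    fc = np.nan_to_num(genes[fc_col].to_numpy())
    cols = make_columns(n_replicates)
    means = {}
    for c in cols:
        comp = c.split("_")[0]
        means[c] = base * (2.0 ** fc if comp == NEURITE else 1.0)
    return pd.DataFrame(means, index=genes.index)


def _scale_to_depth(means: pd.DataFrame, depth: float) -> pd.DataFrame:
    scaled = means.copy()
    for c in scaled.columns:
        tot = scaled[c].sum()
        scaled[c] = scaled[c] * (depth / tot) if tot > 0 else 0.0
    return scaled


def simulate_rna_counts(genes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Negative-binomial RNA-seq counts per gene x (compartment, replicate).

    The neurite mean is the soma mean times ``2**rna_loc_log2fc``; each
    library is then scaled so its expected total equals ``rna_depth``.
    """
    if genes.empty:
        raise ValueError("gene table is empty")
    rng = config.stream("rna")
    mu = _scale_to_depth(
        _column_means(genes, "rna_loc_log2fc", config.n_replicates), config.rna_depth
    )
    phi = config.rna_dispersion
    out = {}
    for c in mu.columns:
        m = mu[c].to_numpy()
        if phi <= 1e-12:
            out[c] = rng.poisson(m)
        else:
            size = 1.0 / phi
            p = size / (size + np.maximum(m, 1e-300))
            out[c] = np.where(m > 0, rng.negative_binomial(size, p), 0)
    return pd.DataFrame(out, index=genes.index, dtype=np.int64)


def simulate_footprints(genes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Ribosome footprint records for coding genes.

    Each record is ``(gene_id, five_prime_offset, length, strand,
    compartment, replicate)``.  The footprint's P-site is placed on a
    uniformly drawn CDS codon; its frame is 0 with probability
    ``frame0_bias``, else 1 or 2 equiprobably.  The emitted coordinate is
    the raw 5' end (P-site minus 12 nt), so downstream P-site offsetting
    is exercised.  Lengths 27-31 nt are drawn from
    ``footprint_length_probs``; 31-mers exist to exercise the 27-30 filter.
    """
    rng = config.stream("footprints")
    coding = genes[genes["cds_length"] > 0]
    columns = ["gene_id", "five_prime_offset", "length", "strand", "compartment", "replicate"]
    if coding.empty:
        warnings.warn("no coding genes: footprint table is empty", stacklevel=2)
        return pd.DataFrame(columns=columns)

    mu = _scale_to_depth(
        _column_means(coding, "ribo_loc_log2fc", config.n_replicates),
        config.footprint_depth,
    )
    lengths = np.array(sorted(config.footprint_length_probs), dtype=np.int64)
    lprobs = np.array([config.footprint_length_probs[k] for k in lengths])
    n_codons = (coding["cds_length"].to_numpy() // 3).astype(np.int64)
    gene_ids = coding.index.to_numpy()

    parts = []
    for col in mu.columns:
        comp, rep = col.split("_")
        counts = rng.poisson(mu[col].to_numpy())
        total = int(counts.sum())
        if total == 0:
            continue
        gidx = np.repeat(np.arange(len(coding)), counts)
        flen = rng.choice(lengths, size=total, p=lprobs)
        in_frame = rng.random(total) < config.frame0_bias
        frame = np.where(in_frame, 0, rng.integers(1, 3, size=total))
        codon = (rng.random(total) * n_codons[gidx]).astype(np.int64)
        psite = 3 * codon + frame
        parts.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids[gidx],
                    "five_prime_offset": psite - 12,
                    "length": flen,
                    "strand": "+",
                    "compartment": comp,
                    "replicate": int(rep),
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=columns)
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class ProteinSim:
    """Observed (MNAR-masked) and complete protein log2-intensity matrices."""

    observed: pd.DataFrame
    complete: pd.DataFrame


def simulate_protein_intensities(genes: pd.DataFrame, config: SimConfig) -> ProteinSim:
    """Log-normal protein intensities with intensity-dependent missingness.

    log2 intensity = intercept + slope * log2(base expression)
    + prot_loc_log2fc * [neurite] + Normal(0, protein_noise_sd); a cell is
    masked missing with probability
    ``logistic((missing_midpoint - intensity) / missing_steepness)``, i.e.
    dimmer proteins drop out more often (missing-not-at-random).
    """
    rng = config.stream("protein")
    coding = genes[genes["cds_length"] > 0]
    if coding.empty:
        raise ValueError("no coding genes: cannot simulate protein intensities")
    cols = make_columns(config.n_replicates)
    base_term = config.protein_intercept + config.protein_rna_slope * np.log2(
        coding["base_expression"].to_numpy()
    )
    fc = coding["prot_loc_log2fc"].to_numpy()
    complete = {}
    for c in cols:
        comp = c.split("_")[0]
        mean = base_term + (fc if comp == NEURITE else 0.0)
        complete[c] = mean + rng.normal(0.0, config.protein_noise_sd, size=len(coding))
    complete_df = pd.DataFrame(complete, index=coding.index)

    p_missing = expit((config.missing_midpoint - complete_df.to_numpy()) / config.missing_steepness)
    mask = rng.random(complete_df.shape) < p_missing
    observed = complete_df.mask(mask)
    return ProteinSim(observed=observed, complete=complete_df)


def simulate_silac(genes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Label-swap ratio pairs (forward H/M, reverse M/H) for a random
    subset of coding proteins, emulating the low coverage of a short
    pulsed-labeling experiment.

    Both ratios equal ``2**(ribo_loc_log2fc + eps)`` with independent
    Normal(0, silac_noise_sd) errors, so their log2 mean is an unbiased
    translation-rate proxy.
    """
    rng = config.stream("silac")
    coding = genes[genes["cds_length"] > 0]
    if coding.empty:
        raise ValueError("no coding genes: cannot simulate SILAC ratios")
    k = round(config.silac_coverage * len(coding))
    if k == 0:
        return pd.DataFrame(
            columns=["ratio_fw", "ratio_rev"], index=pd.Index([], name="protein_id")
        )
    idx = rng.choice(len(coding), size=k, replace=False)
    idx.sort()
    sub = coding.iloc[idx]
    fc = sub["ribo_loc_log2fc"].to_numpy()
    eps1 = rng.normal(0.0, config.silac_noise_sd, size=k)
    eps2 = rng.normal(0.0, config.silac_noise_sd, size=k)
    return pd.DataFrame(
        {"ratio_fw": 2.0 ** (fc + eps1), "ratio_rev": 2.0 ** (fc + eps2)},
        index=pd.Index(sub.index, name="protein_id"),
    )


@dataclass(frozen=True)
class CircSim:
    """Poisson circular/linear junction counts plus the flagged truth set."""

    circ_counts: pd.DataFrame
    linear_counts: pd.DataFrame
    neurite_preferential: frozenset[str]


def simulate_circ(genes: pd.DataFrame, config: SimConfig) -> CircSim:
    """Junction counts for circular and linear transcript forms.

    A ``circ_fraction`` subset of genes is flagged neurite-preferential:
    their expected circ:linear ratio is 10:1 in neurites and 1:7 in soma
    (the pattern of a receptor-kinase transcript whose circular form
    dominates neurites while the linear form dominates soma).  All other
    genes keep a constant background circ/linear ratio in both
    compartments.
    """
    if genes.empty:
        raise ValueError("gene table is empty")
    rng = config.stream("circ")
    n = len(genes)
    base = genes["base_expression"].to_numpy()
    rna_fc = np.nan_to_num(genes["rna_loc_log2fc"].to_numpy())
    n_flag = round(config.circ_fraction * n)
    flag_idx = rng.choice(n, size=n_flag, replace=False) if n_flag else np.array([], dtype=int)
    flagged = np.zeros(n, dtype=bool)
    flagged[flag_idx] = True

    cols = make_columns(config.n_replicates)
    lin_mu, circ_mu = {}, {}
    for c in cols:
        comp = c.split("_")[0]
        lin = base * (2.0 ** rna_fc if comp == NEURITE else 1.0)
        circ = config.circ_background_ratio * lin
        if comp == NEURITE:
            lin = np.where(flagged, base * 1.0, lin)
            circ = np.where(flagged, base * 10.0, circ)
        else:
            lin = np.where(flagged, base * 7.0, lin)
            circ = np.where(flagged, base * 1.0, circ)
        lin_mu[c], circ_mu[c] = lin, circ
    # one scale per library so circ+linear junction totals match junction_depth
    circ_counts, lin_counts = {}, {}
    for c in cols:
        tot = lin_mu[c].sum() + circ_mu[c].sum()
        scale = config.junction_depth / tot if tot > 0 else 0.0
        circ_counts[c] = rng.poisson(circ_mu[c] * scale)
        lin_counts[c] = rng.poisson(lin_mu[c] * scale)
    return CircSim(
        circ_counts=pd.DataFrame(circ_counts, index=genes.index, dtype=np.int64),
        linear_counts=pd.DataFrame(lin_counts, index=genes.index, dtype=np.int64),
        neurite_preferential=frozenset(genes.index[flagged]),
    )


@dataclass(frozen=True)
class SimBundle:
    """One complete synthetic experiment: observables plus ground truth."""

    config: SimConfig
    genes: pd.DataFrame
    rna_counts: pd.DataFrame
    footprints: pd.DataFrame
    protein: ProteinSim
    silac: pd.DataFrame
    circ: CircSim

    @property
    def annotation(self) -> pd.DataFrame:
        """Observable annotation (no ground-truth columns)."""
        return self.genes[["biotype", "tx_length", "cds_length", "strand"]]

    @property
    def truth(self) -> pd.DataFrame:
        return self.genes[
            ["mechanism", "rna_loc_log2fc", "ribo_loc_log2fc", "prot_loc_log2fc"]
        ]


def simulate_bundle(config: SimConfig | None = None, **overrides) -> SimBundle:
    """Generate every table of a synthetic experiment from one config."""
    config = replace(config or SimConfig(), **overrides)
    config.validate()
    genes = simulate_genes(config)
    return SimBundle(
        config=config,
        genes=genes,
        rna_counts=simulate_rna_counts(genes, config),
        footprints=simulate_footprints(genes, config),
        protein=simulate_protein_intensities(genes, config),
        silac=simulate_silac(genes, config),
        circ=simulate_circ(genes, config),
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Write the bundle as plain TSV files (ground truth kept separate)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index_label="gene_id")
    bundle.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index_label="gene_id")
    bundle.rna_counts.to_csv(outdir / "rna_counts.tsv", sep="\t", index_label="feature_id")
    bundle.footprints.to_csv(outdir / "footprints.tsv", sep="\t", index=False)
    bundle.protein.observed.to_csv(
        outdir / "protein_log_intensities.tsv", sep="\t", index_label="feature_id"
    )
    bundle.silac["ratio_fw"].rename("ratio").to_csv(
        outdir / "silac_fw.tsv", sep="\t", index_label="protein_id"
    )
    bundle.silac["ratio_rev"].rename("ratio").to_csv(
        outdir / "silac_rev.tsv", sep="\t", index_label="protein_id"
    )
    bundle.circ.circ_counts.to_csv(outdir / "circ_counts.tsv", sep="\t", index_label="feature_id")
    bundle.circ.linear_counts.to_csv(
        outdir / "linear_counts.tsv", sep="\t", index_label="feature_id"
    )
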