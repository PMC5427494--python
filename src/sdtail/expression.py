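"""Expression strata: the I_TE codon-adaptation index, HEG/LEG labels from
abundance or I_TE, and HTE/LTE labels from protein-on-mRNA regression.

I_TE (index of translation elongation) measures how well a gene's codon
usage matches that of a highly-expressed reference set, correcting for
background mutation bias: within each synonymous codon (sub)family the
relative adaptiveness of a codon is its observed frequency in the
reference divided by its expected frequency under the genomic nucleotide
composition at the family's variable (third) position, rescaled so the
best codon in each family has w = 1.  Sixfold-degenerate families (Leu,
Ser, Arg) are split into their fourfold and twofold subfamilies.  A gene's
I_TE is the geometric mean of w over its codons, skipping start and stop
codons and the single-codon families (Met, Trp).

HEGs/LEGs are the top/bottom 10% of genes by protein abundance or I_TE.
HTE/LTE genes are the 200 most extreme positive/negative residuals of
log10(protein) regressed on log10(mRNA): at equal mRNA level, genes
producing more protein are translated more efficiently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome_io import GenomeComposition

__all__ = [
    "ExpressionRecord",
    "CodonWeights",
    "STANDARD_FAMILIES",
    "compute_ite",
    "build_weights",
    "stratify_heg_leg",
    "stratify_hte_lte",
    "read_abundance_tsv",
]

logger = logging.getLogger(__name__)

# Synonymous codon families (RNA alphabet), sixfold families split into
# four- and twofold subfamilies.  Met (AUG) and Trp (UGG) are single-codon
# families and never contribute to I_TE; stop codons are excluded.
STANDARD_FAMILIES: dict[str, tuple[str, ...]] = {
    "Phe": ("UUU", "UUC"),
    "Leu2": ("UUA", "UUG"),
    "Leu4": ("CUU", "CUC", "CUA", "CUG"),
    "Ile": ("AUU", "AUC", "AUA"),
    "Val": ("GUU", "GUC", "GUA", "GUG"),
    "Ser4": ("UCU", "UCC", "UCA", "UCG"),
    "Ser2": ("AGU", "AGC"),
    "Pro": ("CCU", "CCC", "CCA", "CCG"),
    "Thr": ("ACU", "ACC", "ACA", "ACG"),
    "Ala": ("GCU", "GCC", "GCA", "GCG"),
    "Tyr": ("UAU", "UAC"),
    "His": ("CAU", "CAC"),
    "Gln": ("CAA", "CAG"),
    "Asn": ("AAU", "AAC"),
    "Lys": ("AAA", "AAG"),
    "Asp": ("GAU", "GAC"),
    "Glu": ("GAA", "GAG"),
    "Cys": ("UGU", "UGC"),
    "Arg4": ("CGU", "CGC", "CGA", "CGG"),
    "Arg2": ("AGA", "AGG"),
    "Gly": ("GGU", "GGC", "GGA", "GGG"),
}

_STOPS = {"UAA", "UAG", "UGA"}
_SINGLES = {"AUG", "UGG"}


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression measurements and stratum labels."""

    gene_id: str
    protein_abundance: float = float("nan")
    mrna_rpkm: float = float("nan")
    i_te: float = float("nan")
    strata: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class CodonWeights:
    """Per-codon relative adaptiveness w in (0, 1], organised by synonymous
    (sub)family; max w within each family is 1."""

    w: Mapping[str, float]
    families: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(STANDARD_FAMILIES)
    )

    def __post_init__(self) -> None:
        for fam, codons in self.families.items():
            ws = [self.w[c] for c in codons if c in self.w]
            if ws and abs(max(ws) - 1.0) > 1e-9:
                raise ValueError(f"family {fam}: max w is {max(ws)}, not 1")


def _codons(cds: str) -> list[str]:
    seq = cds.upper().replace("T", "U")
    if len(seq) % 3:
        warnings.warn(
            f"CDS length {len(seq)} not divisible by 3; trailing partial codon dropped",
            stacklevel=3,
        )
        seq = seq[: len(seq) - len(seq) % 3]
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def compute_ite(cds_sequence: str, weights: CodonWeights) -> float | None:
    """I_TE of one CDS: geometric mean of w over codons in multi-codon
    (sub)families, excluding the start codon, the stop codon, and the
    single-codon families.

    Returns None (record skipped) when fewer than two scorable codons
    remain.
    """
    codons = _codons(cds_sequence)
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    codons = codons[1:]  # drop the start codon
    logs = [
        np.log(weights.w[c])
        for c in codons
        if c in weights.w and c not in _SINGLES and c not in _STOPS
    ]
    if len(logs) < 2:
        return None
    return float(np.exp(np.mean(logs)))


def build_weights(
    reference_cds: Iterable[str],
    background: "GenomeComposition | Mapping[str, float]",
    families: Mapping[str, tuple[str, ...]] | None = None,
    pseudo_count: float = 0.5,
) -> CodonWeights:
    """Relative adaptiveness from a highly-expressed reference set.

    Within each (sub)family, ``w_c`` is proportional to the codon's observed
    frequency in the reference divided by its expected frequency under the
    background nucleotide proportions at the family's variable third
    position, normalised to max 1.  Zero-count codons are floored at
    ``pseudo_count`` observations.  A family entirely absent from the
    reference gets uniform weights with a warning.
    """
    families = dict(families or STANDARD_FAMILIES)
    freqs = background.freqs if isinstance(background, GenomeComposition) else background
    counts: dict[str, float] = {}
    for cds in reference_cds:
        for c in _codons(cds):
            counts[c] = counts.get(c, 0.0) + 1.0
    if not counts:
        raise ValueError("empty reference set")

    w: dict[str, float] = {}
    for fam, codons in families.items():
        obs = np.array([counts.get(c, 0.0) for c in codons])
        if obs.sum() == 0:
            warnings.warn(f"family {fam} absent from reference; uniform weights", stacklevel=2)
            w.update({c: 1.0 for c in codons})
            continue
        obs = np.maximum(obs, pseudo_count)
        expected = np.array([freqs[c[2]] for c in codons])
        ratio = (obs / obs.sum()) / (expected / expected.sum())
        ratio = ratio / ratio.max()
        w.update(dict(zip(codons, ratio.astype(float))))
    return CodonWeights(w=w, families=families)


def stratify_heg_leg(
    records: pd.DataFrame,
    metric: str = "protein_abundance",
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Label the top/bottom ``fraction`` of genes by ``metric`` as HEG/LEG.

    ``records`` needs columns ``gene_id`` and ``metric``.  Genes with a
    missing metric are excluded from ranking (logged); boundary ties are
    broken deterministically by gene_id.  Returns a copy with a
    ``stratum_expr`` column in {"HEG", "LEG", ""}.
    """
    df = records.copy()
    usable = df[metric].notna()
    n_missing = int((~usable).sum())
    if n_missing:
        logger.info("%d genes missing %s excluded from HEG/LEG ranking", n_missing, metric)
    ranked = df[usable].sort_values([metric, "gene_id"], ascending=[False, True])
    n = len(ranked)
    if n < 20:
        raise ValueError(f"need >= 20 genes with {metric}, got {n}")
    k = int(np.floor(fraction * n))
    # one ranking serves both ends, so boundary ties can never place a gene
    # in both strata
    df["stratum_expr"] = ""
    df.loc[ranked.index[:k], "stratum_expr"] = "HEG"
    df.loc[ranked.index[n - k :], "stratum_expr"] = "LEG"
    return df


def stratify_hte_lte(
    records: pd.DataFrame,
    n_each: int = 200,
    protein_col: str = "protein_abundance",
    mrna_col: str = "mrna_rpkm",
) -> tuple[pd.DataFrame, sm.regression.linear_model.RegressionResultsWrapper]:
    """Label translation-efficiency strata from the residuals of
    log10(protein) regressed on log10(mRNA).

    Genes with either abundance missing or nonpositive are excluded.  The
    ``n_each`` largest residuals become HTE, the ``n_each`` smallest LTE
    (ties broken by gene_id).  Returns the labelled copy (columns
    ``residual`` and ``stratum_te``) and the fitted OLS results.
    """
    df = records.copy()
    ok = (df[protein_col] > 0) & (df[mrna_col] > 0)
    usable = df[ok].copy()
    if len(usable) < 2 * n_each:
        raise ValueError(f"need >= {2 * n_each} usable genes, got {len(usable)}")
    y = np.log10(usable[protein_col].to_numpy(dtype=float))
    x = np.log10(usable[mrna_col].to_numpy(dtype=float))
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    usable["residual"] = fit.resid
    if float(np.std(fit.resid)) < 1e-12:
        warnings.warn("all residuals ~0; HTE/LTE labels degenerate to gene_id order", stacklevel=2)
    df["residual"] = np.nan
    df.loc[usable.index, "residual"] = usable["residual"]
    df["stratum_te"] = ""
    top = usable.sort_values(["residual", "gene_id"], ascending=[False, True])
    bottom = usable.sort_values(["residual", "gene_id"], ascending=[True, True])
    df.loc[top.index[:n_each], "stratum_te"] = "HTE"
    df.loc[bottom.index[:n_each], "stratum_te"] = "LTE"
    return df, fit


def read_abundance_tsv(
    path,
    id_map_path=None,
    value_col: str = "value",
) -> pd.DataFrame:
    """Read a two-column (gene_id, value) abundance TSV, optionally passing
    foreign IDs through a two-column (foreign_id, gene_id) mapping file.

    Unmappable IDs are dropped with a log message.
    """
    df = pd.read_csv(path, sep="\t", header=0, names=["gene_id", value_col], dtype={0: str})
    if id_map_path is not None:
        mapping = pd.read_csv(
            id_map_path, sep="\t", header=0, names=["foreign_id", "gene_id"], dtype=str
        )
        merged = df.rename(columns={"gene_id": "foreign_id"}).merge(mapping, on="foreign_id")
        dropped = len(df) - len(merged)
        if dropped:
            logger.info("%d abundance rows had unmappable IDs and were dropped", dropped)
        df = merged[["gene_id", value_col]]
    return df
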