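"""Chi-square null models for species-specific SD counts, and the
Cochran-Armitage trend test.

Three nested nulls for comparing a motif-class hit count between two
species (df = 1 in each case, no continuity correction):

* equal frequencies — expected counts split 50:50;
* CDS-weighted — expected counts proportional to each species' number of
  included (non-pseudogene) CDSs;
* composition-weighted — expected counts proportional to
  ``N_CDS,s * sum_m prod_{base in m} P_base,s``, i.e. CDS counts times the
  total probability of the motif set under each species' genomic base
  frequencies (a motif like AGAA contributes P_A^3 * P_G).

The Cochran-Armitage test scores a 2 x k table of strata (e.g. high- vs
low-translation-efficiency genes) by ordered SD-length bins for a linear
trend in proportions; scores default to the bin's SD length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2

from .genome_io import GenomeComposition

__all__ = [
    "TwoCellCounts",
    "TrendTable",
    "ChiSquareResult",
    "chisq_equal",
    "chisq_cds_weighted",
    "chisq_composition_weighted",
    "cochran_armitage",
    "motif_probability",
]


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float
    expected: tuple[float, ...]


@dataclass(frozen=True)
class TwoCellCounts:
    """Hit counts for one motif class in two species, with the per-species
    context (included CDS counts, genomic composition) the weighted nulls
    need."""

    n_a: int
    n_b: int
    cds_a: int = 0
    cds_b: int = 0
    comp_a: "GenomeComposition | Mapping[str, float] | None" = None
    comp_b: "GenomeComposition | Mapping[str, float] | None" = None

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("hit counts must be nonnegative")


def _pearson(observed: Sequence[float], expected: Sequence[float]) -> ChiSquareResult:
    stat = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    return ChiSquareResult(stat, 1, float(_chi2.sf(stat, 1)), tuple(float(e) for e in expected))


def chisq_equal(counts: TwoCellCounts) -> ChiSquareResult:
    """Pearson chi-square of (n_a, n_b) against a 50:50 split."""
    total = counts.n_a + counts.n_b
    if total == 0:
        raise ValueError("zero total hit count")
    return _pearson((counts.n_a, counts.n_b), (total / 2, total / 2))


def chisq_cds_weighted(counts: TwoCellCounts) -> ChiSquareResult:
    """Pearson chi-square with expectations proportional to the two species'
    included CDS counts."""
    total = counts.n_a + counts.n_b
    if total == 0:
        raise ValueError("zero total hit count")
    if counts.cds_a <= 0 or counts.cds_b <= 0:
        raise ValueError("CDS counts must be positive")
    denom = counts.cds_a + counts.cds_b
    return _pearson(
        (counts.n_a, counts.n_b),
        (total * counts.cds_a / denom, total * counts.cds_b / denom),
    )


def _freqs(comp: "GenomeComposition | Mapping[str, float]") -> Mapping[str, float]:
    return comp.freqs if isinstance(comp, GenomeComposition) else comp


def motif_probability(motif: str, comp: "GenomeComposition | Mapping[str, float]") -> float:
    """Probability of ``motif`` under i.i.d. draws from genomic base
    frequencies: the product of per-base frequencies."""
    p = _freqs(comp)
    m = motif.upper().replace("T", "U")
    if set(m) - set("ACGU"):
        raise ValueError(f"motif {motif!r} contains non-ACGU characters")
    return math.prod(p[c] for c in m)


def chisq_composition_weighted(counts: TwoCellCounts, motifs: Iterable[str]) -> ChiSquareResult:
    """Pearson chi-square with expectations proportional to
    ``N_CDS,s * sum_m P(m | composition_s)`` for each species ``s``."""
    motifs = list(motifs)
    if not motifs:
        raise ValueError("empty motif set")
    total = counts.n_a + counts.n_b
    if total == 0:
        raise ValueError("zero total hit count")
    if counts.cds_a <= 0 or counts.cds_b <= 0:
        raise ValueError("CDS counts must be positive")
    if counts.comp_a is None or counts.comp_b is None:
        raise ValueError("both genome compositions are required")
    w_a = counts.cds_a * sum(motif_probability(m, counts.comp_a) for m in motifs)
    w_b = counts.cds_b * sum(motif_probability(m, counts.comp_b) for m in motifs)
    return _pearson(
        (counts.n_a, counts.n_b),
        (total * w_a / (w_a + w_b), total * w_b / (w_a + w_b)),
    )


@dataclass(frozen=True)
class TrendTable:
    """A 2 x k contingency table of two strata over ordered bins, with
    numeric scores per bin (default: the bin labels, e.g. SD lengths)."""

    counts: tuple[tuple[int, ...], tuple[int, ...]]
    scores: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        a, b = self.counts
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("need a 2 x k table with k >= 2")
        if any(c < 0 for c in a + b):
            raise ValueError("all cells must be nonnegative")
        if not self.scores:
            object.__setattr__(self, "scores", tuple(float(i) for i in range(1, len(a) + 1)))
        elif len(self.scores) != len(a):
            raise ValueError("scores length must match number of bins")


def cochran_armitage(table: TrendTable) -> ChiSquareResult:
    """Cochran-Armitage chi-square (df=1) for a linear trend in the row-1
    proportion across ordered bins.

    Classic asymptotic form (as in R's ``prop.trend.test``), no continuity
    correction: with row-1 counts a_j, column totals n_j, scores s_j,
    N = sum n_j and p = R1/N,

        X^2 = [sum s_j (a_j - n_j p)]^2
              / [p (1-p) (sum n_j s_j^2 - (sum n_j s_j)^2 / N)].
    """
    a = np.asarray(table.counts[0], dtype=float)
    b = np.asarray(table.counts[1], dtype=float)
    s = np.asarray(table.scores, dtype=float)
    n = a + b
    N = n.sum()
    R1 = a.sum()
    if R1 == 0 or b.sum() == 0:
        raise ValueError("degenerate table: a row margin is zero")
    if np.count_nonzero(n) < 2:
        raise ValueError("degenerate table: fewer than two occupied bins")
    p = R1 / N
    var = p * (1 - p) * ((n * s**2).sum() - (n * s).sum() ** 2 / N)
    if var <= 0:
        raise ValueError("degenerate scores: zero trend variance")
    num = (s * (a - n * p)).sum()
    stat = float(num**2 / var)
    return ChiSquareResult(stat, 1, float(_chi2.sf(stat, 1)), ())
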