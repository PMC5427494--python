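"""Small-subunit rRNA 3' tails and the SD motifs they can pair with.

The free 3' end of the 16S rRNA (the "3'TAIL") base-pairs with the
Shine-Dalgarno (SD) sequence upstream of bacterial start codons.  A tail is
written here 3'->5', exactly the orientation in which it pairs with an mRNA
read 5'->3': position ``i`` of the tail, counted 1-based from the 3'
terminus, pairs position ``i`` of the tail's perfect Watson-Crick complement
read 5'->3'.  Every SD motif a tail can bind perfectly is therefore a
substring of that complement string.

Because *E. coli* (...CUCCUUA-3') and *B. subtilis* (...CUCCUUUCU-3' or
...CUCCUUUCUA-3') differ at the very 3' end, some motifs pair perfectly with
one species' tail but not the other's; those are the species-specific SD
sets (SD_Ec, SD_Bs) this module enumerates and classifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "RRNATail",
    "MotifInventory",
    "complement_string",
    "enumerate_motifs",
    "species_specific",
    "classify_motif",
    "canonical_inventory",
    "ECOLI_TAIL",
    "BSUB_UCU_TAIL",
    "BSUB_AUCU_TAIL",
    "MIN_SD_LEN",
    "CANONICAL_SERIES_CAPS",
]

_RNA = set("ACGU")
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Minimum number of consecutive paired bases for a match to count as an SD.
MIN_SD_LEN = 4


def _check_rna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - _RNA
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)} in {what}: {seq!r}")
    if not seq:
        raise ValueError(f"empty {what}")
    return seq


@dataclass(frozen=True)
class RRNATail:
    """A 3' ssu-rRNA tail.

    Parameters
    ----------
    name
        Identifier, e.g. ``"Ec-13"``.
    tail_3to5
        The tail written 3'->5' (first character = 3'-terminal base).
    """

    name: str
    tail_3to5: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "tail_3to5", _check_rna(self.tail_3to5, "tail"))

    @property
    def length(self) -> int:
        """Tail length T in nucleotides."""
        return len(self.tail_3to5)

    @property
    def complement_5to3(self) -> str:
        """Perfect Watson-Crick complement, read 5'->3'.

        Position ``i`` (1-based) pairs tail position ``i`` counted from the
        3' terminus; the full string is the longest SD the tail can bind.
        """
        return complement_string(self.tail_3to5)


def complement_string(tail: "RRNATail | str") -> str:
    """Watson-Crick complement of a 3'->5' tail, read 5'->3'.

    No G.U wobble: A<->U and G<->C only.  Because the tail is stored 3'->5'
    and its complement is read 5'->3', the complement is simply the
    base-wise complement in the same character order.
    """
    seq = tail.tail_3to5 if isinstance(tail, RRNATail) else _check_rna(str(tail), "tail")
    return "".join(_WC[c] for c in seq)


# The three tails of the study organisms.  E. coli's 13-nt tail ends with A;
# B. subtilis' ends with UCU (15 nt) or AUCU (16 nt) depending on how far
# 3'->5' exonucleolytic maturation has proceeded.
ECOLI_TAIL = RRNATail("Ec-13", "AUUCCUCCACUAG")
BSUB_UCU_TAIL = RRNATail("Bs-UCU-15", "UCUUUCCUCCACUAG")
BSUB_AUCU_TAIL = RRNATail("Bs-AUCU-16", "AUCUUUCCUCCACUAG")


def enumerate_motifs(
    tail: RRNATail,
    min_len: int = MIN_SD_LEN,
    max_len: int | None = None,
    allow_short: bool = False,
) -> frozenset[str]:
    """All distinct substrings of the tail's complement with length in
    ``[min_len, max_len]`` — i.e. every SD motif the tail can pair perfectly.

    ``min_len < 4`` is rejected unless ``allow_short=True``: three or fewer
    consecutive pairs are not counted as an SD.
    """
    comp = tail.complement_5to3
    if max_len is None:
        max_len = len(comp)
    if min_len < MIN_SD_LEN and not allow_short:
        raise ValueError(f"min_len={min_len} below the SD minimum of {MIN_SD_LEN}")
    if not (1 <= min_len <= max_len <= len(comp)):
        raise ValueError(f"need 1 <= min_len <= max_len <= {len(comp)}")
    return frozenset(
        comp[i : i + L]
        for L in range(min_len, max_len + 1)
        for i in range(len(comp) - L + 1)
    )


@dataclass(frozen=True)
class MotifInventory:
    """SD motifs partitioned by which of two tails can bind them.

    ``specific_to_a`` pair perfectly with tail *a* but not *b*;
    ``specific_to_b`` symmetrically; ``shared`` pair with both.  The three
    sets are pairwise disjoint.
    """

    tail_a: str
    tail_b: str
    specific_to_a: frozenset[str] = field(default_factory=frozenset)
    specific_to_b: frozenset[str] = field(default_factory=frozenset)
    shared: frozenset[str] = field(default_factory=frozenset)

    @property
    def all_motifs(self) -> frozenset[str]:
        return self.specific_to_a | self.specific_to_b | self.shared


def _apply_series_caps(motifs: Iterable[str], caps: Mapping[str, int]) -> frozenset[str]:
    # Keep a motif iff its leading 4-mer names a configured series and the
    # motif does not exceed that series' length cap.
    return frozenset(m for m in motifs if len(m) <= caps.get(m[:MIN_SD_LEN], -1))


def species_specific(
    tail_a: RRNATail,
    tail_b: RRNATail,
    min_len: int = MIN_SD_LEN,
    max_len_a: int | None = None,
    max_len_b: int | None = None,
    caps_a: Mapping[str, int] | None = None,
    caps_b: Mapping[str, int] | None = None,
) -> MotifInventory:
    """Partition the SD motifs of two tails into specific / shared sets.

    A motif enumerated from tail *a* is specific to *a* when it is not a
    substring of *b*'s complement string (it cannot pair perfectly with *b*),
    and shared otherwise.  ``caps_a``/``caps_b`` optionally restrict each
    specific set by per-series maximum lengths (keyed by the motif's leading
    4-mer), which is how the shipped canonical inventories are configured.
    """
    comp_a = tail_a.complement_5to3
    comp_b = tail_b.complement_5to3
    mot_a = enumerate_motifs(tail_a, min_len, max_len_a)
    mot_b = enumerate_motifs(tail_b, min_len, max_len_b)
    spec_a = frozenset(m for m in mot_a if m not in _substr_set(comp_b, len(m)))
    spec_b = frozenset(m for m in mot_b if m not in _substr_set(comp_a, len(m)))
    shared = frozenset((mot_a - spec_a) | (mot_b - spec_b))
    if caps_a is not None:
        spec_a = _apply_series_caps(spec_a, caps_a)
    if caps_b is not None:
        spec_b = _apply_series_caps(spec_b, caps_b)
    return MotifInventory(tail_a.name, tail_b.name, spec_a, spec_b, shared)


def _substr_set(s: str, L: int) -> set[str]:
    return {s[i : i + L] for i in range(len(s) - L + 1)}


def classify_motif(motif: str, inventory: MotifInventory) -> str:
    """Class of ``motif`` under an inventory.

    Returns one of ``"specific_to_a"``, ``"specific_to_b"``, ``"shared"``,
    ``"none"`` (pairs with neither tail / outside the configured sets).
    """
    m = _check_rna(motif, "motif")
    if m in inventory.specific_to_a:
        return "specific_to_a"
    if m in inventory.specific_to_b:
        return "specific_to_b"
    if m in inventory.shared:
        return "shared"
    return "none"


# Per-series length caps that realise the canonical published inventories:
# 7 SD_Ec motifs (one UAAG-led series, lengths 4-10) and 25 SD_Bs motifs
# (AGAA series 4-11, GAAA series 4-12, AAAG series 4-11 for the UCU tail;
# the AUCU tail adds the UAGA series, lengths 4-12).
CANONICAL_SERIES_CAPS: dict[str, dict[str, int]] = {
    "Ec-13": {"UAAG": 10},
    "Bs-UCU-15": {"AGAA": 11, "GAAA": 12, "AAAG": 11},
    "Bs-AUCU-16": {"UAGA": 12, "AGAA": 11, "GAAA": 12, "AAAG": 11},
}


def canonical_inventory(bs_tail: str = "UCU") -> MotifInventory:
    """The shipped SD_Ec / SD_Bs inventory for the *E. coli* tail versus the
    chosen *B. subtilis* tail (``"UCU"`` or ``"AUCU"``)."""
    if bs_tail == "UCU":
        tb = BSUB_UCU_TAIL
    elif bs_tail == "AUCU":
        tb = BSUB_AUCU_TAIL
    else:
        raise ValueError(f"bs_tail must be 'UCU' or 'AUCU', got {bs_tail!r}")
    return species_specific(
        ECOLI_TAIL,
        tb,
        caps_a=CANONICAL_SERIES_CAPS[ECOLI_TAIL.name],
        caps_b=CANONICAL_SERIES_CAPS[tb.name],
    )
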