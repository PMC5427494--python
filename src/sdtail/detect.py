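"""SD match detection and the D_toStart positioning statistic.

A putative SD is a run of at least four consecutive Watson-Crick pairs
between the 30-nt window upstream of a start codon and an rRNA 3' tail.
Its position is scored by D_toStart: the distance from the first base of
the start codon to the mRNA position opposite the tail's 3' terminus when
the full tail is projected rigidly along the duplex.  With the SD spanning
tail positions ``s .. s+L-1`` (counted 1-based from the 3' terminus) and
``g`` bases between the SD's 3' end and the start codon,

    D_toStart = g + L + s.

Unlike the raw SD-to-start distance ``g``, D_toStart measures where the
ribosome's decoding centre lands and is tightly constrained in real genes
(10-22 nt for the *E. coli* tail; 12-23 / 13-24 nt for the 15/16-nt
*B. subtilis* tails — the one-base tail extension shifts every D_toStart
by exactly +1, so those windows are equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .tails import MIN_SD_LEN, RRNATail, _check_rna

__all__ = [
    "SDMatch",
    "WindowSpec",
    "DEFAULT_WINDOWS",
    "d_to_start",
    "find_sd_matches",
    "filter_by_window",
    "best_sd",
]


@dataclass(frozen=True)
class SDMatch:
    """One SD/aSD pairing.

    ``mrna_start``/``mrna_end`` are positions of the SD within the mRNA as
    negative offsets relative to the first base of the start codon at +1
    (the base immediately 5' of the start codon is -1, so
    ``mrna_end <= -1``).  ``tail_pos`` is the 1-based tail position, counted
    from the 3' terminus, paired with the SD's 5'-most base.
    """

    gene_id: str
    motif: str
    mrna_start: int
    mrna_end: int
    tail_pos: int
    d_to_start: int
    in_window: bool = False

    @property
    def length(self) -> int:
        return self.mrna_end - self.mrna_start + 1

    @property
    def gap(self) -> int:
        """Bases strictly between the SD 3' end and the start codon."""
        return -1 - self.mrna_end


@dataclass(frozen=True)
class WindowSpec:
    """Admissible D_toStart range for one tail."""

    tail_name: str
    d_min: int
    d_max: int

    def __post_init__(self) -> None:
        if self.d_min > self.d_max:
            raise ValueError(f"d_min {self.d_min} > d_max {self.d_max}")

    def contains(self, d: int) -> bool:
        return self.d_min <= d <= self.d_max


#: Default optimal-positioning windows per tail.
DEFAULT_WINDOWS: dict[str, WindowSpec] = {
    "Ec-13": WindowSpec("Ec-13", 10, 22),
    "Bs-UCU-15": WindowSpec("Bs-UCU-15", 12, 23),
    "Bs-AUCU-16": WindowSpec("Bs-AUCU-16", 13, 24),
}


def d_to_start(g: int, L: int, s: int) -> int:
    """D_toStart = g + L + s for a match of length ``L`` at tail position
    ``s`` with ``g`` bases between its 3' end and the start codon.

    ``g`` must be >= 0: an SD overlapping the start codon is not modelled.
    """
    if g < 0:
        raise ValueError(f"negative gap g={g}: SD may not overlap the start codon")
    if L < MIN_SD_LEN:
        raise ValueError(f"SD length {L} below minimum {MIN_SD_LEN}")
    if s < 1:
        raise ValueError(f"tail position s={s} must be >= 1")
    return g + L + s


def find_sd_matches(
    upstream: str,
    tail: RRNATail,
    min_len: int = MIN_SD_LEN,
    gene_id: str = "",
) -> list[SDMatch]:
    """All maximal SD/aSD pairings between an upstream window and a tail.

    Every maximal common-substring occurrence of length >= ``min_len``
    between the window (5'->3', ending immediately before the start codon)
    and the tail's complement string yields one match per (window position,
    tail position) pair.  Maximal means the run of consecutive pairs cannot
    be extended on either side — shorter runs embedded in a longer one are
    not reported separately for the same diagonal.
    """
    if not upstream:
        return []
    u = _check_rna(upstream, "upstream window")
    comp = tail.complement_5to3
    W, C = len(u), len(comp)
    out: list[SDMatch] = []
    # Walk each diagonal (fixed i - j) and emit maximal equal runs.
    for i in range(W):
        for j in range(C):
            if u[i] != comp[j]:
                continue
            if i > 0 and j > 0 and u[i - 1] == comp[j - 1]:
                continue  # not the start of a maximal run
            L = 1
            while i + L < W and j + L < C and u[i + L] == comp[j + L]:
                L += 1
            if L < min_len:
                continue
            s = j + 1
            mrna_start = i - W  # window index 0 is offset -W from the start codon
            mrna_end = i + L - 1 - W
            g = -1 - mrna_end
            out.append(
                SDMatch(
                    gene_id=gene_id,
                    motif=u[i : i + L],
                    mrna_start=mrna_start,
                    mrna_end=mrna_end,
                    tail_pos=s,
                    d_to_start=d_to_start(g, L, s),
                )
            )
    return out


def filter_by_window(matches: Iterable[SDMatch], spec: WindowSpec) -> list[SDMatch]:
    """Return the matches with ``in_window`` set per ``spec``."""
    return [replace(m, in_window=spec.contains(m.d_to_start)) for m in matches]


def _rank_key(m: SDMatch) -> tuple[int, int, int]:
    # Longest first; ties by smaller D_toStart, then by 3'-most mRNA position.
    return (-m.length, m.d_to_start, -m.mrna_end)


def best_sd(matches: Sequence[SDMatch], report_secondary: bool = False) -> list[SDMatch]:
    """Per-gene SD call: the best in-window match, optionally plus one
    non-overlapping secondary match.

    The best match is the longest; ties are broken by smaller D_toStart,
    then by the more 3' (start-codon-proximal) placement.  In secondary
    mode, the best match among those not overlapping the primary on the
    mRNA is also reported (genes can carry two distinct well-positioned
    SDs, e.g. one species-specific and one shared).
    """
    valid = sorted((m for m in matches if m.in_window), key=_rank_key)
    if not valid:
        return []
    primary = valid[0]
    picked = [primary]
    if report_secondary:
        for m in valid[1:]:
            if m.mrna_end < primary.mrna_start or m.mrna_start > primary.mrna_end:
                picked.append(m)
                break
    return picked
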