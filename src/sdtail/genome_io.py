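"""GenBank genome input: per-CDS upstream windows and genome composition.

For every annotated CDS we extract the 30 nt immediately 5' of the start
codon, in gene orientation (minus-strand windows are reverse-complemented),
transcribed to the RNA alphabet.  Coordinates follow the GenBank convention:
1-based, inclusive; the upstream window excludes the start codon itself.
Circular topology (declared on the LOCUS line) is honoured by wrapping the
window across the origin; on linear contigs the window is truncated at the
edge.  Pseudogenes are parsed and flagged but excluded from all downstream
counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "GenomeComposition",
    "read_genome",
    "composition",
    "records_to_tsv",
    "UPSTREAM_LEN",
]

logger = logging.getLogger(__name__)

#: Length of the extracted upstream window.
UPSTREAM_LEN = 30


@dataclass(frozen=True)
class GeneRecord:
    """One CDS: identity, orientation, start-codon coordinate and the
    upstream window used for SD detection.

    ``start_pos`` is the 1-based genome coordinate of the first base of the
    start codon.  ``upstream30`` reads 5'->3' toward the start codon and is
    30 nt unless truncated by a linear-contig boundary.
    """

    gene_id: str
    locus_tag: str
    strand: str  # "+" or "-"
    start_pos: int
    upstream30: str
    is_pseudo: bool = False
    product: str = ""


@dataclass(frozen=True)
class GenomeComposition:
    """Whole-genome base proportions (T counted under U) and the number of
    non-pseudogene CDSs included in the analysis."""

    freqs: Mapping[str, float]
    n_cds_included: int = 0

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base proportions sum to {total!r}, not 1")
        if self.n_cds_included < 0:
            raise ValueError("n_cds_included must be >= 0")


def composition(source: "str | Sequence[str]", n_cds_included: int = 0) -> GenomeComposition:
    """Base proportions over a raw sequence (or sequences).

    Ambiguity codes are excluded from numerator and denominator; T and U are
    counted jointly and reported under the RNA key ``U``.
    """
    seqs = [source] if isinstance(source, str) else list(source)
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    for seq in seqs:
        for ch in seq.upper():
            if ch in ("T", "U"):
                counts["U"] += 1
            elif ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty sequence: composition undefined")
    return GenomeComposition(
        freqs={b: c / total for b, c in counts.items()},
        n_cds_included=n_cds_included,
    )


def _transcribe(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _upstream_window(genome: str, start0: int, strand: int, circular: bool) -> str:
    """Window of UPSTREAM_LEN bases 5' of a start codon at 0-based ``start0``
    (coordinate of the start codon's first base in genome orientation)."""
    n = len(genome)
    if strand >= 0:
        lo = start0 - UPSTREAM_LEN
        if lo >= 0:
            window = genome[lo:start0]
        elif circular:
            window = genome[lo % n :] + genome[:start0] if start0 else genome[lo % n :]
        else:
            window = genome[0:start0]
        return _transcribe(window)
    # minus strand: upstream lies 3' of the feature end in genome orientation
    hi = start0 + 1 + UPSTREAM_LEN
    if hi <= n:
        window = genome[start0 + 1 : hi]
    elif circular:
        window = genome[start0 + 1 :] + genome[: hi - n]
    else:
        window = genome[start0 + 1 :]
    return _transcribe(str(Seq(window).reverse_complement()))


def _cds_start(feature) -> tuple[int, int] | None:
    """(0-based start-codon coordinate, strand) of a CDS feature; the
    5'-most segment's start in gene orientation for compound locations."""
    loc = feature.location
    if loc is None:
        return None
    strand = loc.strand if loc.strand is not None else 1
    parts = loc.parts
    if strand >= 0:
        part = min(parts, key=lambda p: int(p.start))
        return int(part.start), 1
    part = max(parts, key=lambda p: int(p.end))
    return int(part.end) - 1, -1


def read_genome(path: "str | Path") -> tuple[list[GeneRecord], GenomeComposition]:
    """Parse a GenBank flat file into GeneRecords plus genome composition.

    One record per CDS feature; pseudogenes flagged via the ``pseudo`` /
    ``pseudogene`` qualifiers; composition computed over the full genomic
    sequence of all records.  CDSs without a resolvable start coordinate
    are skipped with a logged warning.  Multiple records (e.g. chromosome
    plus plasmids) are simply concatenated.
    """
    path = Path(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
    if not seq_records:
        raise ValueError(f"no GenBank records found in {path}")

    genes: list[GeneRecord] = []
    sequences: list[str] = []
    for rec in seq_records:
        genome = str(rec.seq)
        sequences.append(genome)
        circular = str(rec.annotations.get("topology", "linear")).lower() == "circular"
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            locus = quals.get("locus_tag", [""])[0]
            gene_id = quals.get("gene", [locus])[0] or locus
            pseudo = "pseudo" in quals or "pseudogene" in quals
            pos = _cds_start(feat)
            if pos is None:
                logger.warning("CDS %s lacks a resolvable start coordinate; skipped", gene_id)
                continue
            start0, strand = pos
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    locus_tag=locus,
                    strand="+" if strand >= 0 else "-",
                    start_pos=start0 + 1,
                    upstream30=_upstream_window(genome, start0, strand, circular),
                    is_pseudo=pseudo,
                    product=quals.get("product", [""])[0],
                )
            )

    n_included = sum(1 for g in genes if not g.is_pseudo)
    n_pseudo = len(genes) - n_included
    if n_pseudo:
        logger.info("%d pseudogene CDSs flagged for exclusion", n_pseudo)
    return genes, composition(sequences, n_cds_included=n_included)


def records_to_tsv(records: Iterable[GeneRecord], path: "str | Path") -> None:
    """Write per-gene records as TSV (gene_id, locus_tag, strand, start_pos,
    upstream30, is_pseudo)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tlocus_tag\tstrand\tstart_pos\tupstream30\tis_pseudo\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.locus_tag}\t{r.strand}\t{r.start_pos}\t"
                f"{r.upstream30}\t{int(r.is_pseudo)}\n"
            )
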