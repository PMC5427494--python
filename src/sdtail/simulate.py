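"""Synthetic genomes and expression tables with known ground truth.

The generator emulates the study's two kinds of input:

* an annotated genome — CDSs on both strands, each preceded by a 30-nt
  upstream window drawn i.i.d. from a configurable base composition, with
  SD motifs optionally planted at a controlled gap ``g`` from the start
  codon (so the expected D_toStart is known exactly), written as a GenBank
  flat file plus a TSV truth table;
* paired protein/mRNA abundance tables — log10 mRNA is normal, a per-gene
  translation-efficiency multiplier is either i.i.d. or tied to SD length,
  and protein = mRNA * efficiency * multiplicative lognormal noise.

Everything is driven by a single integer seed through one numpy
``default_rng`` stream, so identical configurations produce byte-identical
files.  Chance SD hits in the random background are deliberately not
suppressed; the truth table flags planted genes where a chance hit
outranks the planted SD under the default per-gene call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from . import detect
from .tails import ECOLI_TAIL, RRNATail

__all__ = ["SimConfig", "generate_genome", "generate_expression", "sample_cds"]

# E. coli-like background composition (A, C, G, U).
_DEFAULT_COMPOSITION = {"A": 0.2462, "C": 0.2542, "G": 0.2537, "U": 0.2459}

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in ("UAA", "UAG", "UGA")
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the synthetic genome / expression generators.

    ``planted`` lists (motif, g, fraction-of-genes) triples; fractions must
    sum to <= 1.  The expression block: ``mu_mrna``/``sigma_mrna`` are on
    the log10 RPKM scale; ``efficiency_model`` is ``"iid"`` (log10
    efficiency ~ Normal(0, sigma_eff)) or ``"sd_length"`` (log10 efficiency
    = beta_eff * (SD length - mean SD length)); ``noise_cv`` is the
    coefficient of variation of the multiplicative measurement noise.
    """

    seed: int = 0
    n_genes: int = 1000
    composition: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_COMPOSITION))
    planted: tuple[tuple[str, int, float], ...] = ()
    topology: str = "linear"
    tail: RRNATail = ECOLI_TAIL
    upstream_len: int = 30
    spacer_len: int = 20
    body_codons: int = 30
    # expression block
    mu_mrna: float = 1.5
    sigma_mrna: float = 0.6
    efficiency_model: str = "iid"
    sigma_eff: float = 1.0
    beta_eff: float = 0.1
    noise_cv: float = 0.10
    slope: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition proportions sum to {total}, not 1")
        if sum(f for _, _, f in self.planted) > 1 + 1e-9:
            raise ValueError("planted fractions sum to more than 1")
        for motif, g, _ in self.planted:
            if g < 0:
                raise ValueError(f"negative gap g={g} for planted motif {motif}")
            if g + len(motif) > self.upstream_len:
                raise ValueError(
                    f"planted motif {motif} at g={g} does not fit in a "
                    f"{self.upstream_len}-nt window"
                )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        if self.sigma_mrna < 0 or self.sigma_eff < 0 or self.noise_cv < 0:
            raise ValueError("variance parameters must be nonnegative")


def _expected_d(motif: str, g: int, tail: RRNATail) -> int:
    comp = tail.complement_5to3
    s = comp.find(motif) + 1  # 5'-most pairing position (smallest s)
    if s == 0:
        raise ValueError(f"planted motif {motif} cannot pair with tail {tail.name}")
    return detect.d_to_start(g, len(motif), s)


def sample_cds(rng: np.random.Generator, n_codons: int, skew: dict[str, float] | None = None) -> str:
    """A random CDS body (RNA): ``n_codons`` sense codons, uniform by
    default or biased by per-codon ``skew`` weights.  No start/stop
    included."""
    codons = np.array(_SENSE_CODONS)
    if skew:
        w = np.array([skew.get(c, 1.0) for c in _SENSE_CODONS], dtype=float)
        p = w / w.sum()
    else:
        p = None
    return "".join(rng.choice(codons, size=n_codons, p=p))


def generate_genome(cfg: SimConfig, out_path: "str | Path") -> pd.DataFrame:
    """Write a synthetic annotated genome and return its truth table.

    Each gene cassette is: spacer | 30-nt upstream window | ATG | body |
    TAA, embedded in the chromosome on a random strand (minus-strand
    cassettes are reverse-complemented in place, so planted coordinates
    never collide with neighbouring CDSs).  The truth table lists, per
    gene: strand, start position, planted motif (if any) with its gap and
    expected D_toStart, and whether a chance background hit outranks the
    planted SD under the default best-SD call.
    """
    rng = np.random.default_rng(cfg.seed)
    bases = np.array(["A", "C", "G", "U"])
    probs = np.array([cfg.composition[b] for b in "ACGU"])

    # Assign planted motifs to a random subset of genes.
    assignment: list[tuple[str, int] | None] = [None] * cfg.n_genes
    order = rng.permutation(cfg.n_genes)
    pos = 0
    for motif, g, frac in cfg.planted:
        k = int(round(frac * cfg.n_genes))
        for idx in order[pos : pos + k]:
            assignment[idx] = (motif.upper().replace("T", "U"), g)
        pos += k

    window_spec = detect.DEFAULT_WINDOWS[cfg.tail.name]
    chunks: list[str] = []
    features: list[SeqFeature] = []
    truth_rows: list[dict] = []
    offset = 0  # 0-based running coordinate
    for i in range(cfg.n_genes):
        gene_id = f"sg{i + 1:05d}"
        window = "".join(rng.choice(bases, size=cfg.upstream_len, p=probs))
        planted = assignment[i]
        if planted is not None:
            motif, g = planted
            lo = cfg.upstream_len - g - len(motif)
            window = window[:lo] + motif + window[lo + len(motif) :]
        body = sample_cds(rng, cfg.body_codons)
        cassette_rna = window + "AUG" + body + "UAA"
        cassette = cassette_rna.replace("U", "T")
        spacer = "".join(rng.choice(bases, size=cfg.spacer_len, p=probs)).replace("U", "T")
        strand = 1 if rng.random() < 0.5 else -1

        cds_len = 3 * cfg.body_codons + 6
        if strand == 1:
            block = spacer + cassette
            cds_start0 = offset + cfg.spacer_len + cfg.upstream_len
            loc = FeatureLocation(cds_start0, cds_start0 + cds_len, strand=1)
            start_pos = cds_start0 + 1
        else:
            block = str(Seq(spacer + cassette).reverse_complement())
            # after revcomp, the cassette occupies the start of the block
            cds_start0 = offset  # 5'-most genomic coord of the (reversed) CDS
            loc = FeatureLocation(cds_start0, cds_start0 + cds_len, strand=-1)
            start_pos = cds_start0 + cds_len  # first base of start codon, 1-based
        chunks.append(block)
        offset += len(block)
        features.append(
            SeqFeature(
                loc,
                type="CDS",
                qualifiers={
                    "gene": [gene_id],
                    "locus_tag": [gene_id],
                    "product": ["synthetic protein"],
                },
            )
        )

        # Flag plantings outranked by chance background hits.
        flagged = False
        expected_d = None
        if planted is not None:
            motif, g = planted
            expected_d = _expected_d(motif, g, cfg.tail)
            matches = detect.filter_by_window(
                detect.find_sd_matches(window, cfg.tail, gene_id=gene_id), window_spec
            )
            best = detect.best_sd(matches)
            flagged = not (
                best and best[0].motif == motif and best[0].d_to_start == expected_d
            )
        truth_rows.append(
            {
                "gene_id": gene_id,
                "strand": "+" if strand == 1 else "-",
                "start_pos": start_pos,
                "planted_motif": planted[0] if planted else "",
                "planted_g": planted[1] if planted else -1,
                "expected_d_to_start": expected_d if expected_d is not None else -1,
                "chance_hit_outranks": flagged,
            }
        )

    record = SeqRecord(
        Seq("".join(chunks)),
        id="SYNTH01",
        name="SYNTH01",
        description=f"synthetic genome, seed={cfg.seed}",
        annotations={"molecule_type": "DNA", "topology": cfg.topology, "date": "01-JAN-2000"},
        features=features,
    )
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        SeqIO.write([record], fh, "genbank")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_path.with_suffix(".truth.tsv"), sep="\t", index=False)
    return truth


def generate_expression(
    cfg: SimConfig,
    gene_ids: Sequence[str],
    sd_lengths: "Sequence[int] | None" = None,
    out_dir: "str | Path | None" = None,
) -> pd.DataFrame:
    """Paired protein/mRNA abundance tables with a known per-gene
    translation-efficiency multiplier.

    ``sd_lengths`` is required for the ``"sd_length"`` efficiency model
    (genes without an SD may be coded 0).  Returns a truth frame with
    columns gene_id, mrna_rpkm, efficiency, protein_abundance (and
    sd_length when given); when ``out_dir`` is set, also writes
    ``protein.tsv``, ``mrna.tsv`` and ``expression.truth.tsv``.
    """
    if len(gene_ids) == 0:
        raise ValueError("gene_ids must be nonempty")
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the genome stream
    n = len(gene_ids)
    log_mrna = rng.normal(cfg.mu_mrna, cfg.sigma_mrna, n)
    if cfg.efficiency_model == "iid":
        log_eff = rng.normal(0.0, cfg.sigma_eff, n)
    elif cfg.efficiency_model == "sd_length":
        if sd_lengths is None:
            raise ValueError("sd_lengths required for the sd_length efficiency model")
        sd = np.asarray(sd_lengths, dtype=float)
        log_eff = cfg.beta_eff * (sd - sd.mean())
    else:
        raise ValueError(f"unknown efficiency model {cfg.efficiency_model!r}")
    if cfg.noise_cv > 0:
        sigma_ln = np.sqrt(np.log1p(cfg.noise_cv**2))
        noise = rng.lognormal(-(sigma_ln**2) / 2, sigma_ln, n)  # mean-1
    else:
        noise = np.ones(n)
    mrna = 10.0**log_mrna
    eff = 10.0**log_eff
    protein = mrna**cfg.slope * eff * noise

    truth = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "mrna_rpkm": mrna,
            "efficiency": eff,
            "protein_abundance": protein,
        }
    )
    if sd_lengths is not None:
        truth["sd_length"] = np.asarray(sd_lengths, dtype=int)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        truth[["gene_id", "protein_abundance"]].to_csv(
            out_dir / "protein.tsv", sep="\t", index=False
        )
        truth[["gene_id", "mrna_rpkm"]].to_csv(out_dir / "mrna.tsv", sep="\t", index=False)
        truth.to_csv(out_dir / "expression.truth.tsv", sep="\t", index=False)
    return truth
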