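"""Orchestration: genome-wide SD scans, motif count tables, stratified
tables, the chi-square battery, and the phage host-compatibility report.

Counting convention: each gene contributes at most one count, via its best
in-window SD call against the tail being considered, so a motif's N equals
the number of distinct genes whose best SD is that motif and proportions
are N divided by the number of included genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import stats as sdstats
from .detect import DEFAULT_WINDOWS, WindowSpec, best_sd, filter_by_window, find_sd_matches
from .genome_io import GeneRecord, GenomeComposition
from .tails import MotifInventory, RRNATail, classify_motif

__all__ = [
    "SpeciesInput",
    "scan_genome",
    "motif_count_table",
    "sd_length_trend_table",
    "run_species_analysis",
    "run_phage_report",
]

logger = logging.getLogger(__name__)

#: Product-annotation keywords that mark a gene as hypothetical (excluded
#: from phage reports by default).
HYPOTHETICAL_KEYWORDS = ("hypothetical", "uncharacterized", "unknown")


@dataclass(frozen=True)
class SpeciesInput:
    """One species' inputs to the cross-species analysis."""

    name: str
    records: Sequence[GeneRecord]
    comp: GenomeComposition
    tail: RRNATail
    window: WindowSpec


def scan_genome(
    records: Iterable[GeneRecord],
    tail: RRNATail,
    window: "WindowSpec | None" = None,
    min_len: int = 4,
    report_secondary: bool = False,
    inventory: "MotifInventory | None" = None,
) -> pd.DataFrame:
    """Best SD call per non-pseudogene CDS against one tail.

    Returns one row per reported SD with columns gene_id, motif, L, g, s,
    d_to_start, in_window, rank (1 = primary, 2 = secondary) and, when an
    inventory is given, the motif class.
    """
    window = window or DEFAULT_WINDOWS[tail.name]
    rows = []
    for rec in records:
        if rec.is_pseudo:
            continue
        matches = filter_by_window(
            find_sd_matches(rec.upstream30, tail, min_len=min_len, gene_id=rec.gene_id),
            window,
        )
        for rank, m in enumerate(best_sd(matches, report_secondary=report_secondary), start=1):
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "motif": m.motif,
                    "L": m.length,
                    "g": m.gap,
                    "s": m.tail_pos,
                    "d_to_start": m.d_to_start,
                    "in_window": m.in_window,
                    "rank": rank,
                }
            )
    df = pd.DataFrame(
        rows, columns=["gene_id", "motif", "L", "g", "s", "d_to_start", "in_window", "rank"]
    )
    if inventory is not None:
        df["class"] = [classify_motif(m, inventory) for m in df["motif"]] if len(df) else []
    return df


def _sorted_motifs(motifs: Iterable[str]) -> list[str]:
    # Stable presentation order: by leading 4-mer series, then by length.
    return sorted(motifs, key=lambda m: (m[:4], len(m), m))


def motif_count_table(
    scan_df: pd.DataFrame,
    motifs: Iterable[str],
    n_genes: int,
    gene_subset: "set[str] | None" = None,
) -> pd.DataFrame:
    """N and Prop per motif from primary best-SD calls, plus a Total row.

    ``n_genes`` is the number of included genes (the denominator of Prop,
    reported to 4 decimal places).  ``gene_subset`` restricts counting to a
    stratum.
    """
    motifs = _sorted_motifs(motifs)
    primary = scan_df[scan_df["rank"] == 1] if len(scan_df) else scan_df
    if gene_subset is not None and len(primary):
        primary = primary[primary["gene_id"].isin(gene_subset)]
    counts = primary["motif"].value_counts() if len(primary) else {}
    rows = []
    for m in motifs:
        n = int(counts.get(m, 0))
        rows.append({"motif": m, "N": n, "Prop": round(n / n_genes, 4) if n_genes else 0.0})
    total = sum(r["N"] for r in rows)
    rows.append(
        {"motif": "Total", "N": total, "Prop": round(total / n_genes, 4) if n_genes else 0.0}
    )
    return pd.DataFrame(rows)


def sd_length_trend_table(
    scan_df: pd.DataFrame,
    strata: Mapping[str, str],
    stratum_pair: tuple[str, str] = ("HTE", "LTE"),
) -> sdstats.TrendTable:
    """2 x k table of the two strata over SD-length bins, scored by length.

    ``strata`` maps gene_id -> stratum label; genes without a primary SD
    call are not binned.
    """
    primary = scan_df[scan_df["rank"] == 1]
    lengths: dict[str, list[int]] = {s: [] for s in stratum_pair}
    for _, row in primary.iterrows():
        s = strata.get(row["gene_id"], "")
        if s in lengths:
            lengths[s].append(int(row["L"]))
    all_lens = sorted(set(lengths[stratum_pair[0]]) | set(lengths[stratum_pair[1]]))
    if len(all_lens) < 2:
        raise ValueError("fewer than two SD-length bins; trend test undefined")
    counts = tuple(
        tuple(sum(1 for v in lengths[s] if v == L) for L in all_lens) for s in stratum_pair
    )
    return sdstats.TrendTable(counts=counts, scores=tuple(float(L) for L in all_lens))


def _stats_block(
    name: str, n_a: int, n_b: int, sp_a: SpeciesInput, sp_b: SpeciesInput, motifs: Iterable[str]
) -> pd.DataFrame:
    counts = sdstats.TwoCellCounts(
        n_a=n_a,
        n_b=n_b,
        cds_a=sp_a.comp.n_cds_included,
        cds_b=sp_b.comp.n_cds_included,
        comp_a=sp_a.comp,
        comp_b=sp_b.comp,
    )
    rows = []
    for test_name, res in [
        ("equal", sdstats.chisq_equal(counts)),
        ("cds_weighted", sdstats.chisq_cds_weighted(counts)),
        ("composition_weighted", sdstats.chisq_composition_weighted(counts, motifs)),
    ]:
        rows.append(
            {
                "motif_class": name,
                "test": test_name,
                "statistic": res.statistic,
                "df": res.df,
                "pvalue": res.pvalue,
                "expected_a": res.expected[0],
                "expected_b": res.expected[1],
                "observed_a": n_a,
                "observed_b": n_b,
            }
        )
        logger.info(
            "%s %s: chi2=%.4f df=%d p=%.3g expected=(%.2f, %.2f)",
            name, test_name, res.statistic, res.df, res.pvalue, *res.expected,
        )
    return pd.DataFrame(rows)


def run_species_analysis(
    species_a: SpeciesInput,
    species_b: SpeciesInput,
    inventory: MotifInventory,
    strata: "Mapping[str, Mapping[str, str]] | None" = None,
    stratum_pairs: tuple[tuple[str, str], ...] = (("HEG", "LEG"), ("HTE", "LTE")),
    out_dir: "str | Path | None" = None,
) -> dict:
    """The full cross-species SD analysis.

    For each species-specific motif set, both genomes are scanned against
    the owning tail (a motif specific to tail *a* can only be detected as
    pairing with tail *a*) and genes are counted by their best SD.  The
    three chi-square nulls are run on the species totals; when per-species
    strata are supplied (gene_id -> label), per-stratum count tables and
    Cochran-Armitage SD-length trend tests are added.  TSV files are
    written under ``out_dir`` when given.
    """
    result: dict = {"tables": {}, "stats": None, "scans": {}, "trend": {}}
    if not inventory.all_motifs:
        logger.warning("empty motif inventory: tables are empty, stats skipped")

    sides = {
        "specific_to_a": (inventory.specific_to_a, species_a.tail.name),
        "specific_to_b": (inventory.specific_to_b, species_b.tail.name),
    }
    tail_specs: dict[str, tuple[RRNATail, WindowSpec]] = {}
    for sp in (species_a, species_b):
        tail_specs.setdefault(sp.tail.name, (sp.tail, sp.window))
    scans: dict[tuple[str, str], pd.DataFrame] = {}
    for sp in (species_a, species_b):
        for tail, window in tail_specs.values():
            scans[(sp.name, tail.name)] = scan_genome(
                sp.records, tail, window, inventory=inventory
            )
    result["scans"] = scans

    totals: dict[str, dict[str, int]] = {}
    for side, (motifs, tail_name) in sides.items():
        for sp in (species_a, species_b):
            tab = motif_count_table(
                scans[(sp.name, tail_name)], motifs, sp.comp.n_cds_included
            )
            result["tables"][f"{side}_{sp.name}"] = tab
            totals.setdefault(side, {})[sp.name] = int(tab.iloc[-1]["N"])
            if strata and sp.name in strata:
                labels = strata[sp.name]
                for pair in stratum_pairs:
                    for label in pair:
                        members = {g for g, s in labels.items() if s == label}
                        if members:
                            result["tables"][f"{side}_{sp.name}_{label}"] = motif_count_table(
                                scans[(sp.name, tail_name)],
                                motifs,
                                sp.comp.n_cds_included,
                                gene_subset=members,
                            )

    if inventory.all_motifs:
        blocks = [
            _stats_block(
                "specific_to_a",
                totals["specific_to_a"][species_a.name],
                totals["specific_to_a"][species_b.name],
                species_a,
                species_b,
                inventory.specific_to_a,
            ),
            _stats_block(
                "specific_to_b",
                totals["specific_to_b"][species_a.name],
                totals["specific_to_b"][species_b.name],
                species_a,
                species_b,
                inventory.specific_to_b,
            ),
        ]
        result["stats"] = pd.concat(blocks, ignore_index=True)

    if strata:
        for sp in (species_a, species_b):
            if sp.name not in strata:
                continue
            for pair in stratum_pairs:
                try:
                    table = sd_length_trend_table(
                        scans[(sp.name, sp.tail.name)], strata[sp.name], pair
                    )
                    res = sdstats.cochran_armitage(table)
                except ValueError as exc:
                    logger.warning("trend test skipped for %s %s: %s", sp.name, pair, exc)
                    continue
                result["trend"][(sp.name, pair)] = {"table": table, "result": res}
                logger.info(
                    "trend %s %s vs %s: chi2=%.4f df=1 p=%.4g",
                    sp.name, pair[0], pair[1], res.statistic, res.pvalue,
                )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, tab in result["tables"].items():
            tab.to_csv(out_dir / f"motif_counts_{key}.tsv", sep="\t", index=False)
        if result["stats"] is not None:
            result["stats"].to_csv(out_dir / "chisq_tests.tsv", sep="\t", index=False)
    return result


def run_phage_report(
    records: Iterable[GeneRecord],
    hosts: Sequence[tuple[str, RRNATail, WindowSpec]],
    include_hypothetical: bool = False,
    hypothetical_keywords: Sequence[str] = HYPOTHETICAL_KEYWORDS,
    report_secondary: bool = True,
) -> pd.DataFrame:
    """Per-gene SD compatibility of a phage genome with each host's
    translation machinery.

    For each host (name, tail, window) the gene's best (and optionally
    secondary) in-window SD is reported; a gene with no valid SD for a
    host is flagged ``{host}_incompatible`` — its message cannot form a
    well-positioned SD/aSD duplex on that host's ribosome.  Genes whose
    product annotation matches a hypothetical keyword are excluded unless
    ``include_hypothetical``.
    """
    rows = []
    for rec in records:
        if rec.is_pseudo:
            continue
        if not include_hypothetical:
            prod = rec.product.lower()
            if any(k in prod for k in hypothetical_keywords):
                continue
        row: dict = {"gene_id": rec.gene_id, "product": rec.product}
        for host_name, tail, window in hosts:
            matches = filter_by_window(
                find_sd_matches(rec.upstream30, tail, gene_id=rec.gene_id), window
            )
            calls = best_sd(matches, report_secondary=report_secondary)
            row[f"{host_name}_d_to_start"] = ",".join(str(m.d_to_start) for m in calls)
            row[f"{host_name}_sd"] = ",".join(m.motif for m in calls)
            row[f"{host_name}_incompatible"] = not calls
        rows.append(row)
    columns = ["gene_id", "product"]
    for host_name, _, _ in hosts:
        columns += [f"{host_name}_d_to_start", f"{host_name}_sd", f"{host_name}_incompatible"]
    return pd.DataFrame(rows, columns=columns)
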