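"""Orchestration: count tables, cross-species analysis, phage report."""

import logging

import pandas as pd
import pytest

from sdtail.detect import DEFAULT_WINDOWS, WindowSpec
from sdtail.genome_io import GeneRecord, GenomeComposition, read_genome
from sdtail.report import (
    SpeciesInput,
    motif_count_table,
    run_phage_report,
    run_species_analysis,
    scan_genome,
    sd_length_trend_table,
)
from sdtail.simulate import SimConfig, generate_genome
from sdtail.tails import BSUB_AUCU_TAIL, ECOLI_TAIL, MotifInventory


def _gene(gene_id, window, product="protein X", pseudo=False):
    return GeneRecord(
        gene_id=gene_id, locus_tag=gene_id, strand="+", start_pos=1000,
        upstream30=window, is_pseudo=pseudo, product=product,
    )


def _pad(core, g):
    return "C" * (30 - g - len(core)) + core + "C" * g


def test_scan_counts_each_gene_once(inventory_ucu):
    # one gene with two valid SDs must contribute a single primary call
    genes = [
        _gene("a", _pad("UAAGGAG", 8)),
        _gene("b", _pad("AAGGAGG", 7)),
        _gene("c", "C" * 30),
        _gene("p", _pad("UAAGGAG", 8), pseudo=True),
    ]
    df = scan_genome(genes, ECOLI_TAIL, inventory=inventory_ucu)
    assert set(df[df["rank"] == 1].gene_id) == {"a", "b"}
    assert len(df) == len(df.gene_id.unique())
    tab = motif_count_table(df, inventory_ucu.specific_to_a, n_genes=3)
    assert int(tab[tab.motif == "UAAGGAG"].N.iloc[0]) == 1
    assert int(tab[tab.motif == "Total"].N.iloc[0]) == 1  # AAGGAGG is shared, not counted
    assert tab[tab.motif == "Total"].Prop.iloc[0] == pytest.approx(round(1 / 3, 4))


def test_motif_count_table_totals_are_row_sums(inventory_ucu):
    genes = [_gene(f"g{i}", _pad("UAAG", 10)) for i in range(5)]
    df = scan_genome(genes, ECOLI_TAIL, inventory=inventory_ucu)
    tab = motif_count_table(df, inventory_ucu.specific_to_a, n_genes=5)
    body = tab[tab.motif != "Total"]
    assert int(tab[tab.motif == "Total"].N.iloc[0]) == int(body.N.sum())


def test_planted_counts_recovered_through_full_analysis(tmp_path, inventory_ucu):
    cfg = SimConfig(seed=13, n_genes=200,
                    planted=(("UAAGGAG", 8, 0.25), ("AAGGAGG", 7, 0.25)))
    truth = generate_genome(cfg, tmp_path / "g.gb")
    genes, comp = read_genome(tmp_path / "g.gb")
    df = scan_genome(genes, ECOLI_TAIL, inventory=inventory_ucu)
    tab = motif_count_table(df, inventory_ucu.specific_to_a, comp.n_cds_included)
    clean = truth[(truth.planted_motif == "UAAGGAG") & ~truth.chance_hit_outranks]
    # every clean planting of the species-specific motif is counted
    n = int(tab[tab.motif == "UAAGGAG"].N.iloc[0])
    assert n >= len(clean)
    primary = df[df["rank"] == 1]
    assert n == (primary.motif == "UAAGGAG").sum()


def test_species_analysis_stats_and_tables(tmp_path, inventory_ucu):
    from sdtail.tails import BSUB_UCU_TAIL

    cfg_a = SimConfig(seed=41, n_genes=120, planted=(("UAAGG", 8, 0.3),))
    cfg_b = SimConfig(seed=42, n_genes=120, tail=BSUB_UCU_TAIL,
                      planted=(("AGAAAG", 8, 0.3),))
    generate_genome(cfg_a, tmp_path / "a.gb")
    generate_genome(cfg_b, tmp_path / "b.gb")
    genes_a, comp_a = read_genome(tmp_path / "a.gb")
    genes_b, comp_b = read_genome(tmp_path / "b.gb")
    sp_a = SpeciesInput("A", genes_a, comp_a, ECOLI_TAIL, DEFAULT_WINDOWS["Ec-13"])
    sp_b = SpeciesInput("B", genes_b, comp_b, BSUB_UCU_TAIL, DEFAULT_WINDOWS["Bs-UCU-15"])
    res = run_species_analysis(sp_a, sp_b, inventory_ucu, out_dir=tmp_path / "out")
    # species-specific motifs planted in A dominate the A column
    ta = res["tables"]["specific_to_a_A"]
    tb = res["tables"]["specific_to_a_B"]
    assert int(ta[ta.motif == "Total"].N.iloc[0]) > int(tb[tb.motif == "Total"].N.iloc[0])
    stats = res["stats"]
    assert set(stats.test) == {"equal", "cds_weighted", "composition_weighted"}
    assert (stats.statistic >= 0).all()
    assert (tmp_path / "out" / "chisq_tests.tsv").exists()
    assert (tmp_path / "out" / "motif_counts_specific_to_a_A.tsv").exists()


def test_empty_inventory_warns_and_skips_stats(caplog):
    genes = [_gene("a", _pad("UAAGGAG", 8))]
    comp = GenomeComposition({"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}, 1)
    empty = MotifInventory("Ec-13", "Bs-UCU-15")
    sp = SpeciesInput("A", genes, comp, ECOLI_TAIL, DEFAULT_WINDOWS["Ec-13"])
    from sdtail.tails import BSUB_UCU_TAIL

    sp_b = SpeciesInput("B", genes, comp, BSUB_UCU_TAIL, DEFAULT_WINDOWS["Bs-UCU-15"])
    with caplog.at_level(logging.WARNING):
        res = run_species_analysis(sp, sp_b, empty)
    assert res["stats"] is None
    assert "empty motif inventory" in caplog.text


def test_trend_table_from_strata(inventory_ucu):
    genes = (
        [_gene(f"h{i}", _pad("UAAGGAGG", 7)) for i in range(6)]
        + [_gene(f"l{i}", _pad("UAAG", 10)) for i in range(6)]
        + [_gene(f"m{i}", _pad("UAAGG", 9)) for i in range(4)]
    )
    df = scan_genome(genes, ECOLI_TAIL)
    strata = {f"h{i}": "HTE" for i in range(6)} | {f"l{i}": "LTE" for i in range(6)}
    strata |= {f"m{i}": ("HTE" if i % 2 else "LTE") for i in range(4)}
    t = sd_length_trend_table(df, strata)
    assert t.scores == (4.0, 5.0, 8.0)
    assert sum(t.counts[0]) == 8 and sum(t.counts[1]) == 8


def test_phage_report_host_specific_gene():
    ec_win = DEFAULT_WINDOWS["Ec-13"]
    bs_win = DEFAULT_WINDOWS["Bs-AUCU-16"]
    hosts = [("Ec", ECOLI_TAIL, ec_win), ("Bs", BSUB_AUCU_TAIL, bs_win)]
    genes = [
        # UAGAAAG pairs only the B. subtilis AUCU tail
        _gene("gp6", _pad("UAGAAAG", 9), product="DNA polymerase"),
        # GAGGUG is a substring of both complement strings
        _gene("gpX", _pad("GAGGUG", 8), product="major capsid protein"),
        _gene("hyp", _pad("GAGGUG", 8), product="hypothetical protein"),
    ]
    rep = run_phage_report(genes, hosts)
    assert list(rep.gene_id) == ["gp6", "gpX"]  # hypothetical excluded
    row6 = rep[rep.gene_id == "gp6"].iloc[0]
    assert row6.Ec_incompatible and not row6.Bs_incompatible
    assert row6.Bs_sd.startswith("UAGAAAG")
    rowx = rep[rep.gene_id == "gpX"].iloc[0]
    assert not rowx.Ec_incompatible and not rowx.Bs_incompatible
    # D_toStart under the 16-nt tail runs one beyond the 13-nt tail
    assert int(rowx.Bs_d_to_start.split(",")[0]) == int(rowx.Ec_d_to_start.split(",")[0]) + 3


def test_phage_report_two_sds_and_empty_input():
    bs_win = DEFAULT_WINDOWS["Bs-AUCU-16"]
    hosts = [("Bs", BSUB_AUCU_TAIL, bs_win)]
    window = "C" * 9 + "UAGAAAG" + "CC" + "AGGAGG" + "C" * 6
    genes = [_gene("gp7", window, product="tail knob")]
    rep = run_phage_report(genes, hosts)
    assert rep.iloc[0].Bs_sd == "UAGAAAG,AGGAGG"
    assert "," in rep.iloc[0].Bs_d_to_start
    assert run_phage_report([], hosts).empty


def test_report_deterministic(tmp_path, inventory_ucu):
    genes = [_gene(f"g{i}", _pad("UAAGG", 9)) for i in range(10)]
    a = scan_genome(genes, ECOLI_TAIL, inventory=inventory_ucu)
    b = scan_genome(genes, ECOLI_TAIL, inventory=inventory_ucu)
    pd.testing.assert_frame_equal(a, b)
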