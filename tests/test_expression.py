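"""I_TE weights and scores, HEG/LEG and HTE/LTE stratification."""

import numpy as np
import pandas as pd
import pytest

from sdtail.expression import (
    STANDARD_FAMILIES,
    CodonWeights,
    build_weights,
    compute_ite,
    read_abundance_tsv,
    stratify_heg_leg,
    stratify_hte_lte,
)
from sdtail.simulate import SimConfig, generate_expression


def uniform_weights():
    return CodonWeights(w={c: 1.0 for fam in STANDARD_FAMILIES.values() for c in fam})


def test_ite_all_optimal_codons_is_one():
    cds = "AUG" + "UUC" * 10 + "UAA"
    assert compute_ite(cds, uniform_weights()) == pytest.approx(1.0)


def test_ite_geometric_mean_two_codons():
    w = {c: 1.0 for fam in STANDARD_FAMILIES.values() for c in fam}
    w["UUU"] = 0.25
    cds = "AUG" + "UUC" + "UUU" + "UAA"  # w = 1 and 0.25
    assert compute_ite(cds, CodonWeights(w=w)) == pytest.approx(0.5)


def test_ite_matches_log_domain_oracle():
    rng = np.random.default_rng(5)
    w = {c: float(x) for fam in STANDARD_FAMILIES.values() for c in fam
         for x in [0.05 + 0.95 * rng.random()]}
    # renormalise each family to max 1
    for fam in STANDARD_FAMILIES.values():
        top = max(w[c] for c in fam)
        for c in fam:
            w[c] /= top
    weights = CodonWeights(w=w)
    codons = ["GCU", "GCG", "AAA", "AAG", "CGU", "UUU", "GGA", "ACC", "CAU", "GAA"]
    cds = "AUG" + "".join(codons) + "UAA"
    # independent oracle: plain product then n-th root
    prod = 1.0
    for c in codons:
        prod *= w[c]
    assert compute_ite(cds, weights) == pytest.approx(prod ** (1 / len(codons)))


def test_ite_invariant_under_codon_permutation():
    rng = np.random.default_rng(11)
    w = uniform_weights().w.copy()
    w["GCC"] = 0.3
    w["AAA"] = 0.6
    weights = CodonWeights(w=w)
    codons = ["GCC", "AAA", "UUC", "GGU", "ACA", "GCC"]
    cds = lambda cs: "AUG" + "".join(cs) + "UAA"
    base = compute_ite(cds(codons), weights)
    for _ in range(5):
        perm = list(rng.permutation(codons))
        assert compute_ite(cds(perm), weights) == pytest.approx(base)


def test_ite_skips_start_stop_and_singles():
    w = uniform_weights().w.copy()
    w["UUU"] = 0.5
    weights = CodonWeights(w=w)
    # AUG and UGG inside the gene must not contribute
    a = compute_ite("AUG" + "UUU" + "GCA" + "UAA", weights)
    b = compute_ite("AUG" + "UUU" + "AUG" + "UGG" + "GCA" + "UAA", weights)
    assert a == pytest.approx(b)


def test_ite_too_short_returns_none():
    assert compute_ite("AUGUAA", uniform_weights()) is None
    assert compute_ite("AUGUUCUAA", uniform_weights()) is None  # one scorable codon


def test_ite_trailing_partial_codon_warns():
    with pytest.warns(UserWarning):
        compute_ite("AUG" + "UUC" * 3 + "UAA" + "GC", uniform_weights())


def test_build_weights_uniform_reference_uniform_background():
    ref = ["".join(fam) for fam in STANDARD_FAMILIES.values()]  # each codon once
    bg = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}
    cw = build_weights(ref, bg)
    assert all(v == pytest.approx(1.0) for v in cw.w.values())


def test_build_weights_twofold_ratio():
    # twofold family observed 90:10 against a 50:50 background expectation
    ref = ["AAA" * 90 + "AAG" * 10]
    bg = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}
    cw = build_weights(ref, bg, families={"Lys": ("AAA", "AAG")})
    assert cw.w["AAA"] == pytest.approx(1.0)
    assert cw.w["AAG"] == pytest.approx((10 / 90) / (0.25 / 0.25))


def test_build_weights_fourfold_skewed_background_spreadsheet_oracle():
    # observed GCU:GCC:GCA:GCG = 40:30:20:10; background U,C,A,G = .1,.2,.3,.4
    ref = ["GCU" * 40 + "GCC" * 30 + "GCA" * 20 + "GCG" * 10]
    bg = {"A": 0.3, "C": 0.2, "G": 0.4, "U": 0.1}
    cw = build_weights(ref, bg, families={"Ala": ("GCU", "GCC", "GCA", "GCG")})
    obs = np.array([0.4, 0.3, 0.2, 0.1])
    exp = np.array([0.1, 0.2, 0.3, 0.4])
    ratio = obs / exp
    expected = ratio / ratio.max()
    for c, e in zip(("GCU", "GCC", "GCA", "GCG"), expected):
        assert cw.w[c] == pytest.approx(e)


def test_build_weights_zero_count_floor_and_absent_family():
    ref = ["AAA" * 10]  # AAG never observed
    bg = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}
    with pytest.warns(UserWarning):
        cw = build_weights(
            ref, bg, families={"Lys": ("AAA", "AAG"), "Phe": ("UUU", "UUC")}
        )
    assert cw.w["AAG"] == pytest.approx(0.05)  # 0.5 / 10
    assert cw.w["UUU"] == cw.w["UUC"] == 1.0  # absent family -> uniform


def _records(n, rng, metric="protein_abundance"):
    return pd.DataFrame(
        {"gene_id": [f"g{i:04d}" for i in range(n)],
         metric: 10 ** rng.normal(2, 1, n)}
    )


def test_heg_leg_ten_percent_each(rng):
    df = stratify_heg_leg(_records(100, rng))
    assert (df["stratum_expr"] == "HEG").sum() == 10
    assert (df["stratum_expr"] == "LEG").sum() == 10
    assert not set(df[df.stratum_expr == "HEG"].gene_id) & set(df[df.stratum_expr == "LEG"].gene_id)


def test_heg_leg_all_equal_metric_resolved_by_gene_id(rng):
    df = pd.DataFrame({"gene_id": [f"g{i:02d}" for i in range(30)],
                       "protein_abundance": 1.0})
    out = stratify_heg_leg(df)
    assert (out.stratum_expr == "HEG").sum() == 3
    assert (out.stratum_expr == "LEG").sum() == 3
    assert list(out[out.stratum_expr == "HEG"].gene_id) == ["g00", "g01", "g02"]
    assert list(out[out.stratum_expr == "LEG"].gene_id) == ["g27", "g28", "g29"]


def test_heg_leg_agrees_with_sort_oracle(rng):
    df = _records(250, rng)
    out = stratify_heg_leg(df)
    order = df.sort_values(["protein_abundance", "gene_id"], ascending=[False, True])
    assert set(out[out.stratum_expr == "HEG"].gene_id) == set(order.gene_id.iloc[:25])
    assert set(out[out.stratum_expr == "LEG"].gene_id) == set(order.gene_id.iloc[-25:])


def test_hte_lte_noiseless_recovers_exact_top(rng):
    cfg = SimConfig(seed=3, noise_cv=0.0, sigma_eff=1.0)
    truth = generate_expression(cfg, [f"g{i:04d}" for i in range(1000)])
    out, fit = stratify_hte_lte(truth, n_each=100)
    top_true = set(truth.sort_values(["efficiency", "gene_id"], ascending=[False, True])
                   .gene_id.iloc[:100])
    hte = set(out[out.stratum_te == "HTE"].gene_id)
    # residuals order by efficiency up to the O(1/(sigma sqrt(n))) error of
    # the fitted slope, which can swap genes right at the rank boundary
    assert len(hte & top_true) >= 99
    assert (out.stratum_te == "HTE").sum() == 100
    assert (out.stratum_te == "LTE").sum() == 100


def test_hte_lte_degenerate_warns(rng):
    n = 500
    df = pd.DataFrame({"gene_id": [f"g{i:03d}" for i in range(n)],
                       "mrna_rpkm": 10 ** rng.normal(1, 0.5, n)})
    df["protein_abundance"] = 3.0 * df["mrna_rpkm"]
    with pytest.warns(UserWarning):
        out, _ = stratify_hte_lte(df, n_each=100)
    assert (out.stratum_te == "HTE").sum() == 100


def test_hte_lte_requires_enough_genes(rng):
    df = _records(100, rng)
    df["mrna_rpkm"] = 1.0
    with pytest.raises(ValueError):
        stratify_hte_lte(df, n_each=200)


def test_regression_slope_recovery():
    cfg = SimConfig(seed=9, n_genes=4000, noise_cv=0.10, slope=1.0)
    truth = generate_expression(cfg, [f"g{i:05d}" for i in range(4000)])
    _, fit = stratify_hte_lte(truth, n_each=200)
    assert fit.params[1] == pytest.approx(cfg.slope, abs=0.05)


def test_read_abundance_with_mapping(tmp_path):
    (tmp_path / "ab.tsv").write_text("id\tvalue\nP1\t10\nP2\t20\nP3\t5\n")
    (tmp_path / "map.tsv").write_text("foreign_id\tgene_id\nP1\tgeneA\nP2\tgeneB\n")
    df = read_abundance_tsv(tmp_path / "ab.tsv", tmp_path / "map.tsv")
    assert list(df.gene_id) == ["geneA", "geneB"]
    assert list(df.value) == [10, 20]
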