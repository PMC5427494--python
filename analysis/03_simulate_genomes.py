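"""Simulate two annotated genomes with planted, species-biased SD usage.

Emulates the study design with full ground truth: an "ecoli-like" genome
(E. coli base composition, E. coli-specific and shared SD motifs planted
upstream of a fraction of genes) and a "bsub-like" genome (B. subtilis
composition, B. subtilis-specific and shared motifs).  GenBank files and
per-gene truth tables go to scratch/ (regenerated on demand); a small
summary of what was planted goes to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sdtail.simulate import SimConfig, generate_genome
from sdtail.tails import BSUB_UCU_TAIL

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

EC_COMP = {"A": 0.2462, "C": 0.2542, "G": 0.2537, "U": 0.2459}
BS_COMP = {"A": 0.2818, "C": 0.2181, "G": 0.2171, "U": 0.2830}

N_GENES = 1500


def configs(seed: int) -> dict[str, SimConfig]:
    return {
        # E. coli-like: species-specific UAAG-series plus shared core motifs
        "ecoli_like": SimConfig(
            seed=seed, n_genes=N_GENES, composition=EC_COMP,
            planted=(("UAAG", 10, 0.02), ("UAAGG", 9, 0.02), ("UAAGGA", 9, 0.03),
                     ("UAAGGAG", 8, 0.03), ("AGGAGG", 7, 0.12), ("GGAG", 8, 0.10)),
        ),
        # B. subtilis-like: AGAA/GAAA/AAAG series plus shared core motifs
        "bsub_like": SimConfig(
            seed=seed + 1, n_genes=N_GENES, composition=BS_COMP, tail=BSUB_UCU_TAIL,
            planted=(("AGAAA", 9, 0.02), ("GAAAGG", 9, 0.02), ("AAAGG", 9, 0.04),
                     ("AAAGGAG", 8, 0.04), ("AGGAGG", 7, 0.10), ("GGAG", 8, 0.08)),
        ),
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    summaries = []
    for name, cfg in configs(args.seed).items():
        truth = generate_genome(cfg, SCRATCH / f"{name}.gb")
        planted = truth[truth.planted_motif != ""]
        per_motif = (
            planted.groupby("planted_motif")
            .agg(n_planted=("gene_id", "size"),
                 n_outranked=("chance_hit_outranks", "sum"))
            .reset_index()
        )
        per_motif.insert(0, "genome", name)
        summaries.append(per_motif)
        print(f"{name}: {cfg.n_genes} genes, {len(planted)} with planted SDs "
              f"({int(planted.chance_hit_outranks.sum())} outranked by chance hits)")
    out = RESULTS / "sim_planting_summary.tsv"
    pd.concat(summaries, ignore_index=True).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}; genomes under {SCRATCH}/")


if __name__ == "__main__":
    main()
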