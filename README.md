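# sdtail

Shine-Dalgarno (SD) / anti-SD analysis for bacterial genomes: which SD
motifs can a species' ribosome bind, how are they positioned, and does
their usage track gene expression?

Bacterial translation initiation relies on base pairing between an SD
sequence upstream of the start codon and the free 3' end of the 16S
rRNA (the 3'TAIL).  *E. coli* (tail `3'-AUUCCUCCACUAG-5'`) and
*B. subtilis* (`3'-UCUUUCCUCCACUAG-5'` or `3'-AUCUUUCCUCCACUAG-5'`)
differ only at the very 3' end, so each species can bind SD motifs the
other cannot.  `sdtail` enumerates those species-specific motif
inventories, detects SD matches in the 30 nt upstream of every annotated
CDS, scores their positioning with

    D_toStart = g + L + s

(`g` = gap to the start codon, `L` = match length, `s` = tail position
of the SD's 5' base counted from the 3' terminus — the distance from the
start codon to the spot opposite the rRNA's 3' terminus), filters calls
to each species' optimal window (10-22 nt for *E. coli*, 12-23 / 13-24
for the two *B. subtilis* tails), stratifies genes by expression
(HEG/LEG) and translation efficiency (HTE/LTE, residuals of
log-protein on log-mRNA), and runs the associated statistics:
three nested chi-square nulls (equal, CDS-weighted,
composition-weighted) and the Cochran-Armitage SD-length trend test.
A synthetic-data module generates annotated genomes with planted SDs
and paired abundance tables with known ground truth, so the whole
pipeline is testable offline.

## Layout

* `src/sdtail/` — the library: `genome_io` (GenBank -> per-gene upstream
  windows + composition), `tails` (3'TAILs, motif enumeration,
  species-specific inventories), `detect` (SD matching, D_toStart,
  windows, best-SD calls), `expression` (I_TE, HEG/LEG, HTE/LTE),
  `stats` (chi-square nulls, Cochran-Armitage), `simulate` (synthetic
  genomes/expression), `report` (cross-species tables, phage report).
* `analysis/` — numbered narrative drivers; tables land in `results/`,
  bulky intermediates (synthetic GenBank files) in `scratch/`.
* `docs/methods.md` — model, conventions, calibrations, limitations.

## Worked example

```bash
python analysis/01_tail_inventories.py
python analysis/02_published_stats.py
python analysis/03_simulate_genomes.py --seed 1
python analysis/04_scan_species.py
python analysis/05_expression_strata.py --seed 1
python analysis/06_phage_report.py --seed 1
```

Step 01 derives the motif inventories from the tail sequences alone:

```
Ec-13 vs Bs-UCU: 7 SD_Ec, 25 SD_Bs, 45 shared motifs
Ec-13 vs Bs-AUCU: 7 SD_Ec, 34 SD_Bs, 45 shared motifs
```

— the 7 *E. coli*-specific motifs are the UAAG-led series
(`UAAG ... UAAGGAGGUG`); the 25 *B. subtilis*-specific motifs fall in
the AGAA, GAAA and AAAG series, and the 16-nt AUCU tail adds the 9-motif
UAGA series.

Step 02 tests the published genome-wide totals (455 SD_Ec hits in
*E. coli* vs 267 in *B. subtilis*; 576 vs 1203 SD_Bs) against the three
nulls:

```
SD_Ec  equal                  chi2 =   48.9529  p = 2.62e-12
SD_Ec  cds_weighted           chi2 =   50.3648  p = 1.28e-12
SD_Ec  composition_weighted   chi2 =  102.9595  p = 3.42e-24
```

Each species overuses its own specific motifs far beyond what genome
size or base composition predicts.

Steps 03-05 rebuild the same tables on synthetic genomes with known
planted truth, then tie a planted translation-efficiency signal to SD
length and recover it:

```
Cochran-Armitage (HTE vs LTE x SD length): chi2=70.7593 df=1 p=4.04e-17
I_TE: biased genes mean 0.703, unbiased genes mean 0.509
```

Step 06 is the phage host-compatibility report: a gene whose only
well-positioned SD is the *B. subtilis*-specific `UAGAAAG` is flagged
incompatible with the *E. coli* machinery:

```
2 gene(s) compatible with B. subtilis only: sg00007, sg00010
```

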