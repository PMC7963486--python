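# gdikit

Genome-scale species delineation when you only have two or three genomes.

Taxonomic decisions for elusive or rare mammals often rest on a handful of
specimens. `gdikit` implements a comparative approach for exactly that
regime: an F<sub>ST</sub>-like **genetic differentiation index (GDI)**
computed from the heterozygosity of just 2–3 diploid individuals mapped to
one reference assembly, estimated over resampled genomic windows, and
interpreted by comparison with the same index computed for well-defined
species pairs. A mitochondrial **barcoding-gap** analysis on patristic
distances complements the nuclear index, and a two-population coalescent
simulator with closed-form expectations makes every stage testable without
any external data.

## The statistic

At a biallelic SNP, the genotypes of two diploid individuals fall into four
polymorphic categories — fixed difference (AA/TT), shared heterozygote
(AT/AT), and heterozygotes private to either individual (AT/AA, AA/AT) —
or the site is monomorphic. Writing π₁ and π₂ for the per-bp
heterozygosity of each individual and π<sub>tot</sub> for the unbiased
pairwise nucleotide diversity of the four alleles the pair carries
(fixed difference and shared heterozygote each contribute 2/3 per site,
a private heterozygote 1/2),

```
GDI = 1 − (π₁ + π₂) / (2 · π_tot)
```

Under panmixia, Hardy–Weinberg genotype frequencies make E[GDI] = 0;
population structure depresses within-individual heterozygosity relative
to the pooled diversity and drives GDI towards 1. Under a clean isolation
model (split T generations ago, constant diploid size N, no migration)
the expectation for one individual per population is **T / (T + 3N)**.

Estimation follows a windowed design: per replicate, 100 random
non-overlapping 100-kb windows are drawn from contigs longer than 100 kb
(contaminant- and X-linked contigs excluded by list), sites with caller
quality ≤ 10 are discarded, all sites of a replicate are pooled into one
GDI, and 10 replicates give the mean ± sd. A focal pair's GDI is then
read against reference pairs: above the smallest interspecific reference
value → species-level differentiation; below the largest intraspecific
value → undifferentiated; in between → the gray zone of the speciation
continuum.

## Worked example

Simulate a 10-Mb, three-individual dataset (two diploids from population
A, one from B) that split T = 3N generations ago, then run the pipeline:

```sh
gdikit simulate --out-dir demo --n-a 5000 --n-b 5000 --n-anc 5000 \
    --t-split 15000 --l-bp 250000 --n-contigs 40 --seed 42
gdikit gdi --vcf demo/sim.vcf --fai demo/sim.fai \
    --roster "A1:A,A2:A,B1:B" --out-dir demo/run \
    --n-regions 40 --n-replicates 10 --seed 7
```

`demo/run/summary.tsv` then holds, per pair, the across-replicate mean
and sd of the GDI and the per-individual heterozygosities. Running the
equivalent analysis scripts (`analysis/01…` to `analysis/03…`, which
write `results/gdi_recovery.tsv`) printed:

```
# dataset     expected_inter_gdi  intra_gdi  inter_gdi_mean  inter_gdi_sd
t_over_n_0    0.000               -0.021     0.016           0.029
t_over_n_1    0.250               -0.010     0.243           0.021
t_over_n_3    0.500               -0.025     0.573           0.020
t_over_n_9    0.750               0.078      0.774           0.013
```

The within-population (intra) GDI stays near 0 at every split age — the
two A individuals remain panmictic — while the between-population (inter)
GDI tracks the analytical expectation T/(T+3N). Classifying these focal
values against the published carnivoran reference extrema (intraspecific
GDIs up to 0.137 for lion; interspecific from 0.437 for wolf/golden
jackal) yields `undifferentiated`, `gray_zone`, `species_level`,
`species_level` respectively (`analysis/03_delineation.py`, writing
`results/verdicts.tsv`).

For the mitochondrial side:

```sh
gdikit barcode tree.nwk species_map.tsv --out-dir barcode_out
```

computes all tip-to-tip patristic distances, splits them into
intraspecific (polymorphism) and interspecific (divergence) sets, and
reports the threshold separating the two with the fewest
misclassifications, plus the gap interval (`analysis/04_barcoding_gap.py`
demonstrates this on a synthetic phylogram: threshold 0.031
substitutions/site, 0 misclassified).

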