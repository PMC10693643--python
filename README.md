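# splitabc

Demographic inference for two recently separated populations under a
clean-split coalescent model, by Approximate Bayesian Computation — with
the haplotype statistics (IBD segments, runs of homozygosity, f2-allele
sharing) that make recent demography identifiable.

The package is written for population geneticists studying recent
divergence — its motivating case is the separation of two Bantu-speaker
populations (Angola/Cabinda and Mozambique cohorts) during the Bantu
expansion — but every component is generic: any two-population diploid SNP
dataset with a genetic map can be analysed, and a synthetic-data generator
reproduces the statistical structure of the restricted-access cohorts so
the whole pipeline is testable without any data download.

## The model and the method

Backwards in time, populations P_CAB and P_MOZ start at diploid sizes
N_CAB, N_MOZ and change exponentially at rates

    alpha_n = log(N_n / N'_n) / T_split

reaching sizes N'_CAB, N'_MOZ at the split generation T_split, where they
merge into one ancestral population (which changes instantaneously to
12,000 diploids at generation 7,586). Five free parameters: the four sizes
and T_split; no migration — a clean split, read as a lower bound on the
separation time.

Inference is likelihood-free. A reference table of simulations drawn from
the priors (msprime coalescent, biallelic SNPs, genotype error 0.001) is
summarised by a fixed vector of 46 statistics — per-population diversity
(S, singletons, doubletons, pi, Tajima's D, heterozygosity), IBD segment
counts/lengths in 2–4, 4–8 and >8 cM bins within and between populations,
ROH counts/lengths below and above 1 Mb, Hudson FST, Dxy, and the
shared/private/fixed site partition. Rejection keeps the closest 10% of
simulations in standardised-statistic space; a single-hidden-layer neural
network (4 units, logit-transformed parameters, 10 averaged restarts)
regression-adjusts the accepted draws toward the observed statistics.
Posterior medians and [2.5, 97.5] percentile intervals are reported per
parameter; the split time additionally in years BP (27 years/generation).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Generate a pseudo-observed dataset at known parameters, build a small
reference table, and estimate the posterior (a desk-scale demonstration;
real analyses use larger references and genomes):

```bash
splitabc synth --config examples/desk.yaml --seed 3 \
    --truth 20000,5000,8000,3000,118 --out obs.vcf
splitabc stats --config examples/desk.yaml --seed 3 \
    --vcf obs.vcf --out obs.tsv
splitabc make-reference --config examples/desk.yaml --seed 2 \
    --n-sim 500 --out ref.tsv
splitabc abc --config examples/desk.yaml --seed 1 \
    --reference ref.tsv --observed obs.tsv \
    --tolerance 0.1 --method neuralnet --out posterior.tsv
```

The final command prints

```
split time: 219 generations (~5926 years BP, 95% interval 1014-12314)
wrote posterior.tsv
```

The truth here is a 118-generation split (3,186 years BP at 27
years/generation). The 95% interval contains it comfortably; the median
sits within a factor of two, and the interval is wide — the honest answer
for 500 simulations of a 1 Mb segment, where the IBD bins are empty and
only the diversity statistics inform the fit. `posterior.tsv` holds the
median and percentile bounds for all five parameters on their natural
scales. The package's own calibration study (see below) runs at 2.5 Mb
with 3,000 simulations, where the haplotype statistics start contributing.

The same machinery is available as library calls
(`splitabc.generate_reference`, `splitabc.estimate_posterior`,
`splitabc.holdout_validate`, ...), and the cohort statistics have their own
subcommands (`splitabc f2`, `splitabc ibd-test`).

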