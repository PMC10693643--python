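# Methods

## The demographic model

`splitabc` infers the joint size and separation history of two populations
under a *clean-split* coalescent model. Backwards in time, populations
P_CAB and P_MOZ start at diploid effective sizes N_CAB and N_MOZ
(generation 0) and change exponentially at per-generation rates

    alpha_n = log(N_n / N'_n) / T_split ,

so that each branch reaches its split-generation size N'_n exactly at the
split generation T_split, where the two branches merge into a single
ancestral population. The model has five free parameters: the four branch
sizes and T_split. Two quantities are fixed: the merged ancestral
population changes instantaneously to 12,000 diploids at generation 7,586
(a standard composite model of deep human history), which caps the
timescale over which the free parameters act. Mutation is fixed at
1.25e-8 per bp per generation; generations convert to years BP by a factor
of 27 at reporting time only — all internal computation is in generations.

The clean split (no migration after the split) is deliberately the
simplest separation model; its split-time estimate is best read as a lower
bound, since post-split gene flow would push the apparent split later.

**Ancestral size at the merge.** The size of the merged population between
T_split and generation 7,586 is not itself a model parameter; we set it to
N'_CAB + N'_MOZ, the natural choice when two demes fuse, constant until
the fixed ancestral change. This is a modelling decision of this package;
alternatives (e.g. carrying one branch's size forward) would alter the
deep-coalescence signal only mildly because the 12,000-diploid cap takes
over at generation 7,586.

**Priors.** Defaults are weakly informative: log-uniform on all four sizes
over [1e2, 1e5] diploids and uniform on T_split over [10, 7000]
generations (kept below the fixed ancestral event). All priors are
config-overridable; the log-uniform choice makes the size posteriors
scale-free a priori.

## Simulation

Coalescent simulation goes through msprime (`sim_ancestry` with the
three-epoch demography, `sim_mutations` with a binary 0/1 mutation model).
Recombination is either a uniform rate or a variable genetic map read from
the standard 3/4-column text dialect; a bundled 10 Mb variable-rate map
(0.3-3.2 cM/Mb) stands in for a chromosome-1 map segment. Tree sequences
are reduced to phased 0/1 haplotype matrices restricted to
biallelic-segregating sites. Coordinates are 0-based half-open internally
and 1-based at VCF boundaries.

Genotype error is injected at the genotype level after simulation, before
any statistic: with probability 0.001 per genotype, a homozygote becomes a
heterozygote and a heterozygote becomes a random homozygote. Perturbed
genotypes are written unphased. Sites rendered monomorphic by error are
retained (they were segregating pre-error, as in the observed-data
filtering order). Missing genotypes are never perturbed.

## Summary statistics (the 46-entry registry)

The ABC distance operates on a fixed, ordered vector of 46 statistics:

* per population (x2): segregating sites S, singletons, doubletons
  (folded, minor-allele counts), nucleotide diversity pi (summed unbiased
  per-site heterozygosity, equal to the mean pairwise haplotype
  difference), Tajima's D, and mean observed heterozygosity (12 values);
* within-population IBD segment count and total cM in three length bins
  [2,4), [4,8), [8,inf) cM (12 values);
* per-population ROH count and total kb in two classes, <1 Mb and >=1 Mb
  (8 values);
* cross-population Hudson FST (1 − Hw/Hb as a ratio of sums), Dxy, and
  the shared / private-A / private-B / fixed-difference partition of
  segregating sites (6 values);
* between-population IBD count and total cM in the same three bins (6
  values);
* overall S and overall Tajima's D (2 values).

The registry is data-driven (`StatRegistry`) so the list can be replaced
without touching the pipeline. Non-finite entries (e.g. FST of two
monomorphic panels) are replaced by 0 with a logged warning, keeping the
distance computable.

**IBD detection** is a likelihood-ratio scan on unphased genotypes: per
site and pair, the log10 ratio of P(genotype pair | one shared haplotype
IBD) to P(genotype pair | independent HWE draws), both computed from
sample allele frequencies after a MAF > 0.01 filter. A small error weight
(1e-3) is mixed into the IBD emission so opposite homozygotes score about
−3 LOD rather than −infinity. All maximal positive-scoring runs
(Ruzzo–Tompa extraction, linear time via skip links) with total LOD >= 3
and genetic length >= 2 cM become segments. Adjacent same-pair segments
are then merged when the gap between them is < 0.6 cM and contains at most
one opposite-homozygote site, iterated to a fixpoint, and segments with
fewer than 50 SNPs per cM are dropped. The detector follows the model
class of genotype-based IBD callers rather than phased-haplotype matching
because the pipeline applies it to unphased post-error genotypes.

**ROH scanning** follows the standard sliding-window procedure: 50-SNP
windows are homozygous if they contain <= 1 heterozygote and <= 5 missing
calls; a SNP is in ROH state when >= 5% of its overlapping windows are
homozygous; maximal runs of ROH-state SNPs are reported if they have
>= 50 SNPs, span >= 300 kb (bp -> kb by floor division), have density
<= 50 kb/SNP, and contain no inter-SNP gap > 1000 kb. The window
tolerances (1 het, 5 missing) are the scanning engine's conventional
defaults.

## ABC inference

A reference table holds one row per simulation: 5 parameters + 46
statistics. Estimation proceeds as:

1. **Standardisation** — each statistic is scaled by (x − median)/MAD of
   the reference. Robust scaling is the primary choice because the IBD/ROH
   counts are heavy-tailed; but those same columns are zero-inflated at
   desk scale (a zero median *and* zero MAD while still carrying signal),
   so zero-MAD columns fall back to standard-deviation scaling and only
   zero-variance columns are dropped (with a warning).
2. **Rejection** — Euclidean distance in standardised statistic space; the
   ceil(tolerance x n) closest rows are kept (default tolerance 0.10),
   ties broken by row order.
3. **Regression adjustment** — parameters are mapped to an unbounded scale
   by a logit over their prior bounds (log-uniform parameters first go to
   log10 scale, so the logit acts where their prior is flat; boundary
   values are nudged inward by 1e-9 of the range). A single-hidden-layer
   feed-forward network (4 logistic units, L2 weight decay 1e-3, LBFGS)
   regresses transformed parameters on standardised statistics over the
   accepted rows; predictions are averaged over 10 seeded restarts because
   single fits at 4 hidden units are initialisation-sensitive. Each
   accepted draw is corrected as theta* = m(s_obs) + (theta − m(s)) and
   back-transformed, which forces posterior support inside the prior
   bounds. `loclinear` (weighted least squares) and plain `rejection` are
   drop-in alternatives; a failed regression falls back to rejection with
   a warning. The network fit itself is unweighted; Epanechnikov distance
   weights w = 1 − (d/d_max)^2 enter the posterior summaries (weighted
   medians and percentiles). Rejection-method posteriors are summarised
   unweighted.
4. **Summaries** — per-parameter weighted median and [2.5, 97.5]
   percentiles; the split time is additionally reported in years BP
   (x 27).

## Validation

`holdout_validate` re-estimates the posterior for pseudo-observed rows of
the reference (each row excluded from the reference while it is being
evaluated, avoiding the distance-zero self-match), and reports
per-parameter MAE/MSE/RMSE of posterior medians against truth plus the
frequency with which the [2.5, 97.5] interval covers truth. Medians (not
means) are the point estimates throughout. `compare_tolerances` replays
the tolerance/method selection grid on a common holdout set; its
`mean_prediction_error` column averages per-parameter MAE scaled by the
prior interquartile range so parameters of different magnitude contribute
comparably.

A strong structural oracle: with tolerance 1.0 and no adjustment the
posterior is the prior, so 95% intervals must cover prior draws at 95%.
This baseline is exercised in the tests and the acceptance script.

## Cohort statistics

**f2 sharing.** An f2 site has dataset-wide minor allele count exactly 2
(sites inside excluded-region BED masks are ignored). If its two copies
sit in two distinct carriers, the symmetric group-pair cell of the sharing
matrix is incremented; a homozygous doubleton in a single individual is
tallied separately, so matrix + within-individual counts conserve the
total number of f2 sites. Sharing is tallied per group pair; the
per-individual breakdown is recoverable from the same machinery if needed.

**Permutation test.** Differences in mean pairwise IBD (per pair total cM
within a length bin, zero for pairs with no segment) are tested one-tailed
by permuting individual group labels (pairs are not exchangeable units, so
pair-level resampling is not used): p = (1 + #{permuted >= observed}) /
(1 + n_perm). The statistic is either within-X minus within-Y, or — with a
reference group R — mean(R, X) minus mean(R, Y).

## Desk-scale study conditions

The study this package emulates ran 135,000 simulations of a ~249 Mb
chromosome with 40+40 diploids. That campaign is cluster work; the
package's own calibration study runs 3,000 simulations of a 2.5 Mb segment
with 20+20 diploids (uniform 1 cM/Mb recombination, genotype error 0.001,
default priors), which one CPU completes in about ten minutes. The full
configuration remains a matter of config values (sequence length, samples
per population, n_sim), not code. Reference generation derives per-row
seeds as SeedSequence((master_seed, row)), so chunked and monolithic runs
produce identical tables and interrupted campaigns can resume at any row.

At 2.5 Mb the summary statistics carry far less information than at
chromosome scale: posteriors are wide, and the IBD/ROH bins are
zero-inflated (many simulations yield no qualifying segment). Interval
*calibration* — the property the tests check — is meaningful at this
scale; the sharpness of the full-scale study is not reproduced, and point
estimates of individual runs should be read accordingly.

## What the synthetic data does and does not emulate

The generator reproduces: two labelled populations, biallelic segregating
SNPs with physical and genetic coordinates, phased GT fields, genotype
error at 0.001, and the clean-split parameter dependence of all 46
statistics. It does not emulate: SNP ascertainment of real genotyping
pipelines beyond segregating-site/MAF filters, sequencing depth or
allele-balance error structure, phasing switch errors, or real genetic-map
fine structure (the bundled map is a plausible stand-in, flagged
synthetic). Passing tests therefore demonstrate correctness and
calibration of the machinery under the model's own assumptions, not
robustness to real-data artefacts.

## Numerical choices and degenerate inputs

* Tie-break in rejection: stable argsort by row order (documented,
  deterministic).
* Epanechnikov weights degenerate to uniform when all accepted distances
  are equal (or zero).
* Weighted quantiles interpolate the weighted empirical CDF at
  (cumw − w/2)/sum(w); with uniform weights this is the Hazen quantile.
* Monomorphic or empty panels: diversity statistics return zeros; FST is
  NaN and subject to the registry's NaN->0 policy.
* detect_roh and detect_ibd reject unsorted positions and mismatched
  coordinate arrays outright.
* msprime seeds are derived from user seeds via SeedSequence and kept in
  [1, 2^31), the engine's valid range.

## Known limitations

* The 46-statistic registry reconstructs the statistic *families* of the
  original design; the original's exact list and order are not public, so
  numerical identity with that table is not claimed (the registry is
  replaceable data, not code).
* The IBD detector is a deliberately compact likelihood-ratio scan, not a
  reimplementation of any external caller's windowed-LD machinery; its
  thresholds (LOD >= 3, >= 2 cM) are conventional defaults.
* The neural-network adjustment averages restarts for stability but, like
  all regression-adjusted ABC, can undercover when the accepted set is
  locally uninformative; the holdout coverage test guards the default
  configuration.
* Single-chromosome analyses only; multi-chromosome runs are outer loops
  over this machinery.
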