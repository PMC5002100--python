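# Methods

`sweepscan` detects genomic signatures of recent artificial selection in
several reproductively isolated breeding lines genotyped on one SNP array.
It follows a two-statistic, two-stage design: every ordered pair of lines is
scanned with a haplotype statistic (XP-EHH) and an allele-frequency
statistic (an XP-CLR-style composite likelihood); within each line the two
methods must agree, and across lines a region must recur in at least two
lines before it is called a high-confidence selection region.  A
pooled-heterozygosity (ZHp) window scan is provided alongside as an
independent, older-signature view and is deliberately kept out of the
consensus.

## Quality control

SNPs are filtered in a fixed order so that every removed SNP is attributed
to exactly one category: (1) excluded or unplaced chromosomes, (2)
Mendelian inconsistency above a threshold (default 0.001), (3) fully
ungenotyped SNPs, (4) SNPs monomorphic jointly across *all* lines pooled (a
SNP fixed in four lines but segregating in one is kept), (5) call rate
below 90 % computed over all samples pooled.  The accounting invariant
`retained + sum(removed) = input` holds by construction.

The Mendelian rate counts one *check* per (child, SNP) with the child and
at least one parent genotyped; a violation is a child genotype impossible
given the genotyped parent(s) (trio-level compatibility when both parents
are present, homozygous-parent exclusion for duos).  The denominator is
checks, not trios.  Without a pedigree the filter is skipped with a loud
warning rather than passing silently.

`naive_impute` fills missing alleles by Bernoulli draws from the within-line
allele frequency (pooled frequency as fallback).  It is a deliberately
simple stand-in for statistical imputation and phasing: the pipeline's scan
stages require externally phased input, and imputation output is only
flagged phased when the input already was.

## Genetic map

Marker cM positions are linearly interpolated between anchor markers of
known genetic position — recombination is assumed uniform within each
anchor interval.  Beyond the terminal anchors the terminal interval's local
cM/bp rate is extrapolated, floored at 0 cM.  Equal-cM anchor plateaus
(recombination deserts) are allowed and interpolate to a constant.

## XP-EHH

For a core SNP, EHH at marker x is the probability that two haplotypes
drawn without replacement are identical-by-state over every marker from the
core to x: with haplotypes partitioned into groups identical over
[core..x], `EHH = sum_g C(n_g,2) / C(n,2)`.  Site EHH over all haplotypes
(not allele-partitioned) is used, as the cross-population statistic
requires.  iHH integrates the decay curve by the trapezoid rule over
genetic distance, left plus right of the core.

Both populations are truncated at the *same* boundary per direction: the
curve is cut at the last marker where the EHH of the combined
two-population sample is still at or above `ehh_floor` (default 0.05); the
segment crossing below the floor is not counted.  A shared boundary keeps
iHH_A and iHH_B comparable; the floor follows common practice for this
statistic.

The statistic is `ln(iHH_A / iHH_B)`, standardized by the genome-wide mean
and population standard deviation (denominator n) within each ordered
comparison; SNPs with a zero iHH on either side are excluded from
standardization and flagged.  One-sided upper-tail normal P-values are the
default (positive scores mean extended haplotypes in the focal line);
two-sided is available.  Significant SNPs (P < 0.05) closer than 200 kb are
clustered into candidate regions spanning [min bp, max bp] of the cluster.

The production scan runs a numba kernel that refines the haplotype
partition marker-by-marker with a stable counting split (O(n) per marker);
the plain-Python `ehh_site`/`ihh` functions are the reference path and the
test suite checks the kernel against them and against exhaustive
pair-counting enumeration.

## XP-CLR-style composite likelihood

The original cross-population CLR's likelihood internals are not
re-implemented; this module is a self-contained drift-vs-sweep mixture that
keeps the published scan geometry (2 kb grid, 0.5 cM windows, |r| >= 0.9 LD
down-weighting, top 0.5 % threshold, 1 cM clustering) and is labelled
"XP-CLR-style" in all output headers.

Per window SNP with focal frequency p_A and reference frequency p_B:

* null density `f0(p_A | p_B)`: normal, mean p_B, variance
  `omega * p_B q_B + p_B q_B / n_A`, truncated and renormalized on [0, 1].
  `omega` is a genome-wide drift variance scale estimated by
  method-of-moments: `omega = max(0, mean[(p_A-p_B)^2 / (p_B q_B)] -
  mean[1/n_A])` over SNPs with p_B strictly inside (0, 1).
* sweep density: with escape probability `c_i = 1 - exp(-d_i/s)` for
  genetic distance d_i to the grid point and sweep scale s,
  `f1 = c_i f0 + (1-c_i) [p_B g1(p_A) + (1-p_B) g0(p_A)]`, where g1/g0 are
  the same truncated-normal family centered at 1 and 0 with sd
  `eps = 0.02`.
* `CLR = 2 max_s sum_i w_i (ln f1 - ln f0)`, maximized over 12 log-spaced
  scales from 0.01 to 5 cM plus the no-sweep model, so CLR >= 0.

LD weights are `w_i = 1/k_i` with k_i the number of window SNPs (including
i) whose allele correlation with i in the *reference* line reaches |r| >=
0.9; the reference line is used so the weighting is not driven by
sweep-distorted focal LD.  SNPs monomorphic in the reference have undefined
r and weight 1.  SNPs with p_B in {0, 1} have a degenerate null variance
and are excluded from the likelihood sum (a window with no usable SNP
scores NaN and is ignored by thresholding).

Numerical choices: the genome scan evaluates the scale loop in single
precision with densities floored at 1e-30 (the reference per-window
`clr_score` stays in double precision and the suite checks the two paths
against each other); the empirical (1 - 0.005) quantile uses midpoint
interpolation with ties at the cutoff all kept.

Known artifact: at near-fixed reference frequencies (roughly
min(p_B, q_B) < ~0.05 with the default eps) the boundary mixture density
can exceed the null density *at the observed point* even when p_A = p_B, so
identical populations can retain a small positive residue score (observed
< 0.1 versus sweep scores in the hundreds).  The "CLR = 0 when focal equals
reference" property is exact for mid-range reference frequencies.

## ZHp

Per line, sliding windows of 5 SNPs (step 1) are summarized by
`Hp = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))^2` — the
standard pooled-heterozygosity definition — using called alleles only, and
Z-transformed genome-wide within the line.  Hp lies in [0, 0.5] with both
bounds attained (all-fixed windows, all-50/50 windows).  Sex chromosomes
are excluded; no significance threshold is imposed by default, and ZHp
regions do not feed the consensus stage.

## Region consensus

Intervals are 1-based inclusive internally; BED exports are 0-based
half-open.  Per line and method, regions from the comparisons against every
other line are unioned (gap <= 1 bp coalesces) — a region flagged against
any reference line is evidence for selection in the focal line.  A line's
*candidates* are the XP-CLR-style regions that overlap (>= 1 bp) at least
one XP-EHH region; the narrower XP-CLR span defines the candidate span and
one wide XP-EHH region may support several candidates.  Cross-line
consensus sweeps interval breakpoints and emits every maximal genomic
segment covered by the same set of >= 2 lines, merging adjacent segments
with identical supporting sets; the emitted interval is the trimmed common
overlap, with untrimmed per-line spans kept as provenance.

## Synthetic data

The generator emulates the study design: K lines derived from one base
population, then reproductively isolated.

* **Markers**: a fixed panel (no new mutations), as on a genotyping array;
  default 3,000 SNPs over 3 chromosomes of 20 Mb at 1 cM/Mb.  Allele
  frequencies are drawn from a density proportional to 1/p with a
  minor-allele-frequency floor of 0.05, mimicking array ascertainment; the
  floor is also enforced on the realized generation-0 panel.
* **Base population**: 60 founder haplotypes drawn per SNP independently;
  500 base haplotypes are recombinant mosaics of the founders (Poisson
  crossovers, 10 per Morgan), which induces LD through shared founder
  segments.  The founder count and mosaic depth are realism choices for a
  commercial line derived from a narrow breed pool; measured r^2 in evolved
  lines is ~0.08 at 0.05 cM decaying to ~0.05 at 1 cM.
* **Line evolution**: each line evolves independently for 40 generations of
  Wright-Fisher reproduction at N_e = 250 (matching a breeding program
  selecting ~50-80 males and ~500-800 females); each gamete recombines with
  Poisson crossovers per Morgan.  Under a sweep, parents are sampled with
  weight (1+s) per favored-allele copy.
* **Hard sweeps**: the favored allele is seeded at the configured start
  frequency (default 0.05) on a *single ancestral background*: carriers are
  copies of one origin haplotype over a +/-1.5 cM core around the locus,
  modeling selection on standing variation whose carriers share one
  predominant ancestral segment.  Seeding the allele on scattered
  backgrounds instead produces a soft sweep with essentially no haplotype
  or heterozygosity signature — not the hard-sweep condition the tests
  target.  Losses by drift are recorded in the truth table;
  `condition_on_establishment` re-evolves a line losing the allele.
* **Export**: per line 24-60 diploids (defaults 24/60/38/48/36) as a
  phased, complete dataset plus an "unphased" copy with genotype-wise
  missingness, optional trios, and Mendelian errors injected only at sites
  where a parent is homozygous, so every injected error is a detectable
  violation and the recovered rate is comparable to the injected count.

What the generator does *not* emulate: new mutations, sex chromosomes,
overlapping generations, crossbreeding/backcross events in a line's
history, genotyping-intensity error modes, and genome-scale marker density
(3,000 SNPs over 60 Mb versus ~50K over ~1 Gb).  Passing recovery tests
therefore shows the pipeline detects hard sweeps against drift at this
scale, not that its false-discovery behavior on a full genome matches the
published analysis.

## Recovery testing and problem sizes

Seeded recovery tests implant one hard sweep (s = 0.5, start 0.05) in two
of the five lines and require a cross-line consensus region at the sweep in
at least 80 % of 20 replicates; 10 no-sweep replicates bound the null
(per-line candidate coverage and consensus coverage).  The replicate counts
and the default synthetic scale were chosen to keep the full suite in the
minutes range on one CPU.

A sweep "hit" means a consensus region within 0.25 cM of the selected SNP
— the same locus-coverage tolerance used for the top-window recovery
property.  The tolerance matters because after fixation the *entire* shared
ancestral core is equally extreme in frequency: the top-0.5 % windows are a
subset of the core whose span need not be centered on the selected SNP, and
the trimmed cross-line intersection can end tens of kilobases from it while
still flagging the swept segment.

At this desk scale the null is hard in one specific way: with a 60 cM
genome, 40 generations of drift at N_e = 250 fixes haplotype blocks a few
cM wide that genuinely mimic sweeps, and the top-0.5 % windows of a
comparison concentrate in a handful of such blocks.  Per-line candidate
coverage under the null is therefore a heavy-tailed quantity (median ~3 %
of the genome, occasional replicates above 5 %) even though consensus
coverage is far smaller than per-line coverage on average — which is
exactly the motivation for the cross-line consensus stage.  Two caveats at
this scale: consensus intervals from different line pairs union, so no
single line's coverage strictly bounds the consensus union; and lines
drifting from the same structured base population occasionally share a
drift block, so a null replicate can show a percent-scale consensus
region.

## Limitations

* The composite likelihood is a documented simplification, not the
  published XP-CLR model; scores are comparable within a run, not across
  tools.
* One-sided XP-EHH P-values assume the standardized scores are
  approximately normal; LD makes neighboring scores dependent, so the
  nominal 5 % significant fraction under the null is only approximate.
* `estimate_omega` treats the reference frequency as the ancestral one and
  ignores reference-side sampling noise beyond the spec of the moment; with
  drifted references the estimate absorbs both lines' drift.
* The Mendelian filter detects only genotype combinations that are
  impossible, so the recovered error rate is a lower bound on an underlying
  genotyping error rate.
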