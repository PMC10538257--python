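# Methods

`poolscan` implements a Pool-seq genome scan for a locus controlling
reproductive-mode variation (cyclical vs. obligate parthenogenesis, CP
vs. OP) and three estimators of the divergence time between the locus's
two allelic classes. This note records the models, the parameter
choices, and the compromises behind each stage.

## Study design being modeled

Six populations — three per reproductive mode — are sequenced as DNA
pools (CP pools of 20–21 clonal lineages, OP pools of 14), each pool
split into two replicate Illumina libraries at roughly 15–20x. Allele
counts arrive as a PoPoolation2 `sync` file. Because the replicate
libraries of a population come from a single DNA pool, their counts are
summed and treated as one library throughout. The trait maps to the X
chromosome, so the candidate region is X-linked, strongly differentiated
between modes (F_ST ≈ 0.35 against a genomic background of ≈ 0.025) and
depleted of diversity in OP pools.

## SNP calling and filtering

A site becomes a SNP when at least two nucleotides are observed in the
population-summed counts and the global minor allele carries ≥ 4 reads
(MAC ≥ 4). Triallelic sites are kept only when the third allele carries
exactly one read, in which case that read is ignored and the site is
treated as biallelic; two or more extra reads drop the site. This
"nonfiltered" set feeds Tajima's D, Fay & Wu's H and the dating
estimators. The "filtered" set — used for F_ST and H_E — additionally
requires every population's depth in [20, 60] (both bounds inclusive;
the depth ceiling guards against collapsed duplications) and global
minor-allele frequency ≥ 5%. Depth always counts A/C/G/T reads only;
N and deletion columns are carried through I/O but never enter allele
counts. The MAC and MAF thresholds are applied to counts summed over
all populations; whether the original analysis applied them jointly or
per library is not documented, and the joint reading is the natural one
for pooled counts.

## F_ST

Two per-SNP estimators are available:

* `nei` — the variance-partition form (H_T − H_S)/H_T with
  H_S = mean of 2p_i(1−p_i) and H_T = 2p̄(1−p̄) at equal group weights.
  It is simple and oracle-checkable but biased upward by read sampling
  (roughly by the 1/depth and 1/pool-size identity terms).
* `pool_corrected` (default) — the same decomposition with unbiased
  within-pool heterozygosities. Two distinct reads from a pool of n
  chromosomes are identical with probability 1/n + (1 − 1/n)Q, Q being
  the identity of two distinct chromosomes; inverting this and the
  with-replacement read draw debiases H_S, while the between-group term
  p̂₁(1−p̂₂) + p̂₂(1−p̂₁) is already unbiased because the pools are
  independent. In the limit of deep sequencing and large pools the two
  estimators coincide.

Multilocus and windowed values are always ratio-of-sums (Σ numerators /
Σ denominators), never means of per-SNP ratios. Genome-wide absolute
values depend on the data and the estimator; they are reported but are
not calibration targets. Windows are 20 kb sliding by 5 kb for the scan
and 100 kb contiguous for diversity statistics; a window must lie fully
inside its chromosome.

## Pooled Tajima's D and Fay & Wu's H

Both statistics are computed after subsampling every site to a uniform
depth of 30 reads (sites below 30 or above 360 are excluded;
subsampling is hypergeometric, i.e. without replacement). This
"subsample-then-classical" route is a deliberate simplification of the
pooled estimators in the tools it emulates: reads are treated as
haploid samples of size 30, which ignores the residual probability that
two reads descend from the same pool chromosome (small here: pools hold
84–120 chromosomes per mode).

For D, alleles whose folded count falls below `min_count` (default 2)
are treated as unobserved. Simply dropping those classes from the
classical statistic pushes D strongly positive under neutrality
(singletons carry ~25% of Watterson's theta at n = 30), so both theta
estimators are renormalized by the neutral weight of the omitted
classes — θ_W uses a₁ minus the omitted harmonic terms, θ_π is rescaled
by the omitted fraction of its expectation — and the classical variance
is evaluated at the implied total segregating-site count. The
standardization is therefore approximate; under the neutral generator
the window mean settles near +0.2, reflecting the residual
MAC-ascertainment of the SNP calling step.

H = θ_π − θ_H is reported unnormalized, with θ_H = Σ 2k²/(n(n−1)) over
derived counts k polarized against an outgroup genome (sites where the
outgroup matches neither allele, or is N, are skipped). The
`nolowfreq` guard (default 3) removes sites whose folded count is ≤ 3
entirely — both from θ_π and θ_H — as a sequencing-error guard; the
truncation is symmetric in k ↔ n−k, so it does not bias H under
neutrality. Base-quality filtering is a no-op on sync input, where
qualities were applied upstream.

## Candidate-region delimitation

The original call was made by eye; the codified surrogate is: take all
20-kb windows with mean F_ST ≥ 0.25, merge overlapping windows into
maximal runs, optionally require each run to contain at least one SNP
whose externally computed association score (e.g. BayPass C2) exceeds
60, and trim the run to the outermost SNPs with per-SNP F_ST > 0.5.
The region mean F_ST is recomputed from the member SNPs after trimming.
All thresholds are exposed in the run configuration. The rule is a
reproducible surrogate, not a claim to reproduce any particular
published coordinates.

## Depth-ratio structure scan

Per-position OP and CP mode depths are each normalized by that mode's
mean depth over the scanned interval, and the ratio OP/(OP+CP) is
averaged over 2-kb nonoverlapping windows. Equal copy number gives an
expected ratio of 0.5; an OP-specific deletion at half copy number
drives it toward 1/3 (0.5x/(0.5x + x)); an OP-absent segment gives 0.

## Divergence dating

Annual substitution rates combine a measured per-parthenogenetic-
generation rate μ_parth = 2.7 × 10⁻¹⁰ (95% CI 1.9–3.5 × 10⁻¹⁰) with an
insect per-sexual-generation average μ_sex = 2.96 × 10⁻⁹ (95% CI
1.52–4.99 × 10⁻⁹) at N_gen = 15 generations per year:
μ_op = N_gen·μ_parth, μ_cp = (N_gen−1)·μ_parth + μ_sex, and dating uses
their mean (5.39 × 10⁻⁹; CI bounds composed by pushing the input bounds
through the same formulas: 3.52–7.57 × 10⁻⁹).

1. **Net divergence**: T = D_a/(2μ) with
   D_a = D_xy − (π_op + π_cp)/2, where D_xy is the mean over callable
   sites of p₁(1−p₂) + p₂(1−p₁) and π the mean of 2p(1−p), computed
   from pooled frequencies without pool-size correction (the cited
   original computation is not printed; this is the plain
   frequency-based form).
2. **Substitution counts**: one haploid consensus per mode is drawn by
   a Bernoulli trial per polymorphic site with success probability
   equal to the mode's allele frequency; substitutions are counted on
   the callable mask (depth ≥ 20 in every population) and
   T = N_mutated/(2·N_sites·μ). The draw is repeated 100 times; the
   point estimate uses the replicate mean of N and the 95% CI pairs the
   2.5/97.5 replicate percentiles of N with the opposite μ bounds
   (low N with high μ, and vice versa — deliberately conservative; the
   N-only and μ-only intervals are reported alongside).
3. **Synonymous divergence**: per replicate, CDS pairs are extracted
   from the consensus sequences for every gene wholly inside the
   region, dS is computed by Nei–Gojobori (1986) pathway counting with
   the Jukes–Cantor correction, and the median across genes taken;
   T = (dS/0.2268) × 22 My by proportionality against the calibrated
   interspecies synonymous divergence. Genes with broken frames or a
   premature stop in either consensus are skipped with a warning. In
   the NG86 counts, mutations creating stop codons are nonsynonymous
   for site counting, and substitution pathways through a stop codon
   are excluded unless every pathway is blocked. Only NG86 is
   implemented; alternative counting schemes change dS by far less
   than the calibration uncertainty this estimator inherits.

## Variant-effect classification

Variants with between-mode F_ST strictly above 0.5 and depth ≥ 20 in
every population are classified against the longest transcript of each
gene (transcripts ranked by summed CDS length; genes whose CDS chain is
not a codon multiple after phase adjustment are flagged and their
variants left as `modifier`). Coding SNPs are translated on the correct
strand and frame with the standard genetic code into synonymous /
missense / nonsense / stop-lost calls; indels are frameshift unless the
net length change is a multiple of 3 (then in-frame). The two intronic
bases flanking each CDS edge are flagged `splice_adjacent` but not
subdivided further. Impact mapping: frameshift and premature stops high,
missense and in-frame indels moderate, synonymous low, non-coding
modifier. Per-gene summaries count effects per category and report the
percentage of the gene span where *every* population of a mode reaches
depth 20, per mode — the per-population reading of an ambiguous
depth-coverage criterion, matching the variant filter's logic.

## Synthetic data

The generator emulates the design above so every stage is testable
without sequencing data. Defaults: 4 chromosomes (X first) × 2 Mb; a
200-kb candidate interval on X; 3 populations per mode with 20 (CP) /
14 (OP) lineages; 2 replicate libraries per population at Poisson
depth, mean 18 per library; SNP density 0.01/bp (about half the real
density, keeping desk-scale runtimes while leaving hundreds of SNPs
per 100-kb window); outgroup divergence 1%; ~30 genes in the candidate
region. Within-mode differentiation defaults to 0 (the emulated study
found none between same-mode populations) and is exposed as a
parameter.

Background sites share an ancestral frequency drawn from a neutral
1/i spectrum on a 40-point grid; each mode's frequency is a Beta
perturbation with dispersion F\* = 2f/(1+f), the value for which the
expected multilocus Nei F_ST between two groups equals f (the naive
choice F\* = f would yield F_ST ≈ f/2). Candidate sites place the OP
frequency at a distance ε from fixation chosen so OP heterozygosity
equals its target (2ε(1−ε) = 0.14 by default), and the CP frequency at
the root of the per-site Nei F_ST equation for the target 0.35
(plus small jitter). Orientation (which allele OP fixes) is random per
site. Derived alleles falling in coding sequence are redrawn to avoid
creating premature stop codons — the purifying-selection constraint
that lets consensus CDS pairs stay translatable.

Sampling is two-stage: a pool frequency is drawn once per population
per site as Binomial(2 × lineages, p)/(2 × lineages) — shared by the
replicate libraries, which are technical replicates of one pool — and
then per-library counts are Binomial(Poisson depth, pool frequency).
This makes the pool-size corrections in the estimators testable rather
than vacuous.

What the generator does **not** model: read-level errors and mapping
artifacts, linkage disequilibrium beyond the block-level sharing of
frequencies, indels (indel variants enter the annotation stage through
an optional TSV), within-window coverage gaps (windows are treated as
fully covered when computing covered fractions), and selection beyond
the stop-avoidance constraint. Passing tests therefore demonstrate the
correctness of the estimators and the internal consistency of the
pipeline under the stated sampling model, not robustness to artifacts
of real short-read data.

## Numerical and design choices

* Internal coordinates are 0-based half-open; sync and GFF3 I/O use the
  formats' native 1-based inclusive conventions.
* Depth bounds "higher than 20 and lower than 60" are read as the
  inclusive interval [20, 60] (the accompanying tables use "≥ 20");
  MAF 5% and the region-trimming F_ST > 0.5 follow the same reading as
  their sources (inclusive and strict respectively).
* Mann–Whitney comparisons use the exact null for samples ≤ 20 without
  ties and the normal approximation otherwise; the paired OP-vs-CP
  window comparison is a two-sided Wilcoxon signed-rank test.
* All randomness flows from a single integer seed through named
  `SeedSequence` streams (truth, sampling, outgroup, stats, dating), so
  a rerun with the same seed is byte-identical, and stages can be rerun
  in isolation from their input files.
* Desk-scale problem sizes used by the test-suite properties: F_ST
  recovery at ~10⁴ SNPs per stratum (3 bootstrap-SE tolerance);
  consensus-substitution expectation over 200 seeds × 10⁴ sites (3 SE);
  divergence-time recovery on 2 × 10⁵ simulated sites for T·μ ≤ 0.01
  (2 SE); candidate-block localization in ≥ 95 of 100 seeded replicates
  of a 2 × 400-kb genome.

## Known limitations

* The pooled Tajima's D is approximately standardized only (see above);
  its absolute values are comparable within a run, not across tools.
* Fay & Wu's H is an unnormalized sum over usable sites, so its scale
  grows with SNP density; comparisons are again within-run.
* The dS route inherits its calibration's fossil uncertainty entirely;
  CIs reflect consensus-draw variation only.
* `fst_snp` on single SNPs can be noisy and slightly negative under the
  corrected estimator; only ratio-of-sums aggregates are interpreted.
* Consensus sequences are haploid caricatures of the allelic classes;
  heterozygous lineages are not represented.
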