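# Methods

## Problem setting

A single diploid genome sequenced at modest coverage yields uneven
per-site read depth: confident genotypes where the coverage happens to
be deep, ambiguous ones where it is shallow. Because nearby variants
are co-inherited on haplotypes, a phased reference panel lets evidence
flow along the chromosome: well-covered sites constrain which panel
haplotypes the individual is copying, and that mosaic in turn predicts
the genotype at poorly covered sites. `lowcov` implements this
refinement and the population-genetic companions that typically
accompany a single-genome study: a sliding-window Tajima's D scan with
gene/paralog stratification, and LD-based prioritization of novel
variants near known disease markers.

## Genotype likelihoods and sequence-only calling

At each site the diploid genotype space is the 10 unordered base pairs.
A read with Phred quality Q has error probability e = 10^(−Q/10)
(capped at 0.75); a genotype xy emits each of its alleles with
probability 1/2 before the error channel, so

    P(b | xy) = ( P(b|x) + P(b|y) ) / 2,   P(b|x) = 1−e if b=x else e/3.

Likelihoods are reported as ratios to the best genotype (best = 1) and
renormalized to sum to one ("conditionals") when fed to the Bayesian
combiner. Sequence-only calling weights the likelihoods by a prior
with heterozygosity theta = 0.001: mass theta split over the three
heterozygotes containing the reference allele, theta/2 over the three
non-reference homozygotes, remainder on the reference homozygote. This
prior is deliberately conservative: it suppresses false positives at
the cost of under-calling heterozygotes with skewed read splits, which
is why the heterozygote-discordance rate dominates at low depth.
Depth filters default to [4, 100] for diploid calling and [2, 100]
with a 0.5 normalized-likelihood rule for haploid (sex-chromosome)
calling. The direction of the Phred-scaled consensus-quality cutoff is
ambiguous in the tooling this emulates, so it ships permissive
(disabled) and configurable. Exact posterior ties are broken uniformly
at random under a dedicated seed.

## The haplotype-copying prior

The target's two haplotypes are a hidden mosaic of the K panel
haplotypes. We model the *pair* of copied rows jointly: the hidden
state is (j, k) ∈ K×K, each coordinate switching independently between
adjacent sites with probability 1 − exp(−rho·d) (d = distance in bp,
rho = `switch_rate`, default 1e-6/bp) to a uniformly chosen row, and a
copied allele is flipped with probability `mutation_rate` (default
1e-3). Evidence at surrounding sites is soft: the read conditionals
(or hard array genotypes) define a distribution over dosage 0/1/2, and
the emission weight of state (j, k) is that distribution evaluated
under the dosage law of the two (independently mutated) copied
alleles. Forward-backward over up to `neighborhood` (default 20)
informative sites on each side — with *no emission at the target* —
gives the prior genotype distribution there; posteriors follow by
elementwise multiplication with the target's own conditional and
renormalization.

Joint pair modelling is the decisive design choice. A factorized
model (each haplotype filtered independently against marginal
per-haplotype allele evidence) was implemented first and measured: an
unphased heterozygous neighbor then contributes identical, uninformative
evidence to both haplotypes, the prior mass on a true heterozygote is
capped near 0.5, and the refinement gains over a plain
genotype-frequency prior nearly vanish (92.2% vs 91.6% concordance at
2.4X on the standard design). The joint model restores the constraint
that the two copied rows must jointly explain each observed dosage and
reaches ~99% on the same design. It is also the formulation used by
the imputation tools this package re-implements in spirit. The cost is
K² states, which is why the forward-backward works on windowed
neighborhoods rather than whole chromosomes.

Uninformative sites can be skipped exactly: their emission is constant
across states, so dropping them changes nothing but the transition
distance, which is computed from physical positions anyway.

The recursion is verified against exhaustive enumeration over all
pairs of copy paths on panels small enough to enumerate (4–6
haplotypes, 4–5 sites), to 1e-8. Distance enters transitions through
physical bp with a single intensity; no recombination map is modelled.

Array-based imputation of untyped sites runs the same engine with
one-hot evidence at typed sites and emits an untyped genotype only
when its posterior strictly exceeds `report_threshold` (default 0.9).

## Synthetic data

The generators define the study conditions and are first-class, tested
code.

* **Panel.** Sequential copying: haplotype k+1 copies a uniformly
  chosen existing haplotype with Poisson(`recombination_intensity`)
  switch points and per-site copy error `theta_site`/k. The 1/k
  scaling is the Hoppe-urn approximation to neutral sampling, so the
  site-frequency spectrum of retained (polymorphic) sites is
  approximately neutral — this is what the selection-scan calibration
  leans on — while shared copying segments give LD that decays with
  distance. Candidate sites are laid uniformly over the region and
  thinned evenly to the requested count. Defaults: `theta_site` 0.05,
  `recombination_intensity` 3 switches per region.
* **Target.** Two independent mosaics of panel rows with
  Poisson-distributed switch counts; every switch moves to a different
  row, so recorded breakpoints match the Poisson draw exactly.
* **Pileups.** Poisson depth; each read copies one haplotype uniformly
  and mis-reports its base with probability `base_error` (uniform over
  the other three bases); qualities are the matching Phred score, so
  the caller's error model is correctly specified. Default base error
  1% (Q20), the regime of the depth-titration experiments.
* **Array truth.** Bernoulli site inclusion, small genotype error rate
  (default 0.5%) toward a uniformly chosen different genotype.
* **Annotations.** Non-overlapping fixed-length genes; paralog pairs
  with duplication-age classes (species-specific → primate → eutherian
  → vertebrate) and a proximity flag below 250 kb; disease markers at
  panel sites; known-variant, consequence and deleterious labels drawn
  at random with realistic proportions.

What this emulates — and does not. Mosaic copying reproduces LD decay,
an approximately neutral SFS, and targets that are genuinely imputable
from the panel. It does not model coalescent genealogy variance,
recombination hotspots, indels, structural variation, mapping
artifacts, GC-dependent coverage, or population divergence between
target and panel. Passing tests therefore demonstrate correctness of
the machinery and the direction/magnitude of the method's gains under
idealized LD, not performance on real reads; in particular the
2.4X concordance figure should be read as an in-model ceiling.

## Depth evaluation

Downsampling removes each read independently with probability
1 − target/current (binomial thinning, composable). Concordance is
computed over unfiltered calls at shared sites; filtered sites are
reported as no-calls, not errors, mirroring comparisons restricted to
successfully genotyped positions. The positive predictive value is the
fraction of called variants that are true variants, and the
heterozygote-undercall rate the fraction of true heterozygotes called
homozygous. The depth-titration experiments use `min_depth=1` (sites
covered by at least one read) so the low-coverage regime is actually
exercised; the [4, 100] default remains for discovery-style calling.

## Selection scan

Tajima's D per window uses the standard 1989 constants
(a1, a2, b1, b2, c1, c2, e1, e2) with D = (π − S/a1) / √(e1·S +
e2·S(S−1)); windows with S = 0 are flagged undefined and excluded
rather than set to zero. The scan consumes either haplotype matrices
or per-site alternate-allele counts — π and S depend only on per-site
counts, so unphased genotype input is handled identically. Windows are
10 kb with a 5-kb step, 1-based inclusive, starts at 1, 5001, …, so a
boundary site belongs to exactly the windows whose closed interval
contains it. Outlier windows (D < −2 or D > +2) that overlap or abut
are concatenated into maximal regions. Gene-level D is the unweighted
mean over overlapping windows. The paralog-age comparison drops pairs
whose gene starts lie within 250 kb (their windows are shared),
summarizes per class, runs Kruskal-Wallis across classes plus the
non-paralog background, and separately compares each pair's greater-D
member against the background (Welch t-test). The default sample size
of 21 chromosomes reflects the ten-genome-plus-reference design such
scans typically pool.

## LD prioritization and enrichment

r² between panel sites is the squared correlation of phased allele
indicators; it is undefined (an error) at monomorphic sites. "Flanked
by a high-LD pair" is interpreted as a single spanning pair: one
member at or left of both positions, one at or right of both, with
r² ≥ the threshold (default 0.8 — "high LD" is conventionally
unquantified). Prioritized candidates must be novel, within 250 kb of
a disease marker heterozygous in the individual, and carry spanning-
pair evidence; output is sorted by consequence severity. Enrichment
runs Fisher's exact test (the one-sided version is the hypergeometric
upper tail) or Pearson's chi-square without continuity correction; the
odds ratio uses Haldane-Anscombe 0.5 correction only when a cell is
zero, and the genome-wide reference group includes the subset, matching
how such totals are usually printed (an exclusive background is a
caller-side choice of counts).

## Numerical and scale choices

Forward/backward vectors are renormalized each step; degenerate
combinations (disjoint prior/conditional supports) raise rather than
return NaN. Read conditionals that place zero mass on both panel
alleles (all reads off-panel) fall back to uniform over the panel
genotypes. The acceptance experiment uses a 100-haplotype ×
2,000-site panel over 2 Mb, 1% base error, and 10 replicate seeds;
test-suite calibration runs use 60-haplotype × 400-site panels (20
paired replicates) and 550 neutral 21-haplotype windows. These sizes
were chosen so each statistical check has enough resolution for its
stated bound while the whole suite stays desk-scale.

## Known limitations

* The copying prior assumes the target is drawn from the panel's
  population; panel-target divergence degrades gains and is not
  simulated.
* K² state cost limits panels to a few hundred haplotypes at these
  site counts; larger panels would need state-space reduction.
* Indel handling covers only candidate filtering, not likelihoods.
* The scan's ±2 cutoffs are conventional, not calibrated p-values;
  under the neutral generator about the right tail fraction falls
  beyond them, but real-genome window D distributions are wider.
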