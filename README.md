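# lowcov

Haplotype-informed genotype calling at low sequencing depth, with the
population-genetic companions of a single-genome resequencing study:
a depth-vs-accuracy evaluation harness, a sliding-window Tajima's D
selection scan with paralog-age stratification, and LD-proximity
prioritization of novel variants near disease markers. Everything is
exercisable on synthetic data with known ground truth.

## Who this is for

Anyone analysing (or simulating) a single diploid genome sequenced at
modest coverage who wants to squeeze reliable genotypes out of shallow
sites by borrowing strength from a phased reference panel — and to run
the standard downstream scans without stitching together one-off
scripts.

## The method

At a site with reads R and genotype g over the site's two panel
alleles, calls combine three ingredients by Bayes' rule:

    P(g | R, panel) ∝ P(R | g) · P(g | neighboring sites, panel)

* **Likelihood** P(R | g): product over reads of
  ½·P(b|x) + ½·P(b|y) for g = xy, with Phred-scaled base error
  (e = 10^(−Q/10)). Reported as likelihood ratios (best genotype = 1)
  and renormalized to "conditionals" that sum to one.
* **Prior** P(g | …): a haplotype-copying hidden Markov model. The
  hidden state is the *pair* of panel haplotypes the target is
  copying; each coordinate switches with probability 1 − exp(−ρ·d)
  per d bp and copies with per-site error μ. Soft genotype evidence at
  flanking sites (their read conditionals) drives forward-backward;
  the target's own reads are excluded from its prior. Alternatives:
  a Hardy-Weinberg prior {p², 2pq, q²} from the panel frequency
  (`freq_prior`), or no prior beyond the θ = 0.001 heterozygosity
  convention (`sequence_only`).
* **Posterior**: elementwise product, renormalized; maximum a
  posteriori with seeded random tie-breaking; depth filters
  (default 4–100, haploid 2–100) applied throughout.

The selection scan computes Tajima's D = (π − S/a₁) / √(e₁S + e₂S(S−1))
in 10-kb windows stepped by 5 kb (n = 21 chromosomes by default),
merges windows beyond ±2 into regions, and averages D per gene.

## Worked example

```python
import lowcov as lc

panel = lc.simulate_panel(n_haplotypes=100, n_sites=2000,
                          region_length=2_000_000,
                          recombination_intensity=3.0, seed=0)
target = lc.sample_diploid(panel, recombination_intensity=3.0, seed=500)
reads = lc.simulate_pileups(target, mean_depth=2.4, base_error=0.01,
                            seed=1000)

config = lc.CallerConfig(min_depth=1)   # keep shallow sites in play
for mode in ("sequence_only", "freq_prior", "haplotype_prior"):
    calls = lc.call_with_prior(reads, panel, mode, config)
    report = lc.genotype_concordance(calls, target.genotype_table())
    print(f"{mode:>16}: {100 * report.concordance:.1f}% of "
          f"{report.n_compared} genotypes correct, "
          f"het undercall {100 * report.het_undercall_rate:.1f}%")
```

Output:

```
   sequence_only: 79.4% of 1822 genotypes correct, het undercall 75.0%
      freq_prior: 91.3% of 1822 genotypes correct, het undercall 25.2%
 haplotype_prior: 98.8% of 1822 genotypes correct, het undercall 2.5%
```

At a mean depth of 2.4X, reads alone genotype 79% of covered sites
correctly — three quarters of true heterozygotes are miscalled
homozygous, the classic low-coverage failure. The panel's allele
frequencies lift concordance to 91%, and the haplotype-copying prior —
which identifies the panel mosaic the individual carries — reaches
98.8%, comparable to what reads alone achieve at more than triple the
depth. The `examples/` directory
walks through each capability: simulation, calling, the
accuracy-vs-depth curve, array-based imputation, the selection scan,
and LD prioritization with enrichment testing.

## Layout

```
src/lowcov/
  panel.py        phased reference panels, hap/legend text, r²
  simulate.py     synthetic panels, diploid targets, pileups, annotations
  likelihood.py   genotype likelihoods, conditionals, sequence-only calls
  imputation.py   haplotype-copying priors, array-based imputation
  calling.py      Bayesian combination, calling modes, indel filters
  evaluation.py   downsampling, concordance metrics, depth curves
  selection.py    Tajima's D scan, region merging, paralog stratification
  prioritize.py   LD-proximity rules, flanking evidence, enrichment tests
  fileio.py       pileup/call/genotype TSV and BED interchange
```

See `docs/methods.md` for the model details, parameter defaults, and
what the synthetic generators do and do not emulate.
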