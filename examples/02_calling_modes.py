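"""Call genotypes at 2.4X under the three prior modes and compare.

Shows the central claim of the package: at low depth, a haplotype-
copying prior recovers most of the genotypes that reads alone miss.
"""

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
# Heterozygotes covered by one or two concordant reads are the dominant
# sequence-only failure; the copying prior identifies the panel mosaic
# and rescues most of them.
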