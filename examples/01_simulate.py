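"""Simulate a phased reference panel, a diploid target, and reads.

Builds the core synthetic objects and prints their shape, the LD decay
of the panel, and the realized read depth — the quantities that tell
you the simulation matches its knobs.
"""

import numpy as np

import lowcov as lc

panel = lc.simulate_panel(n_haplotypes=100, n_sites=1000,
                          region_length=1_000_000,
                          recombination_intensity=3.0, seed=1)
adjacent = np.mean([lc.ld_r2(panel, i, i + 1)
                    for i in range(0, panel.n_sites - 1, 11)])
distant = np.mean([lc.ld_r2(panel, i, i + 400)
                   for i in range(0, panel.n_sites - 401, 11)])

target = lc.sample_diploid(panel, recombination_intensity=3.0, seed=2)
reads = lc.simulate_pileups(target, mean_depth=2.4, base_error=0.01, seed=3)
array = lc.simulate_array_truth(target, site_fraction=0.25,
                                array_error=0.005, seed=4)

print(f"panel: {panel.n_haplotypes} haplotypes x {panel.n_sites} sites "
      f"over {panel.positions[-1] - panel.positions[0] + 1:,} bp")
print(f"mean r2, adjacent site pairs : {adjacent:.3f}")
print(f"mean r2, pairs 400 sites apart: {distant:.3f}")
print(f"target mosaic breakpoints: {len(target.mosaic_breakpoints[0])} + "
      f"{len(target.mosaic_breakpoints[1])}")
print(f"heterozygous fraction of target: "
      f"{np.mean(target.dosage() == 1):.2f}")
print(f"realized mean depth: {np.mean([p.depth for p in reads]):.2f} "
      f"(target 2.4)")
print(f"array-like truth subset: {len(array)} sites")
# Adjacent sites share copying history, so their r2 should dwarf the
# distant-pair value; the realized depth should sit near the Poisson mean.
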