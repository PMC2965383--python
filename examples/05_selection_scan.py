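"""Sliding-window Tajima's D scan with paralog-age stratification.

Simulates 21-chromosome variant data, scans 10-kb windows stepped by
5 kb, merges outlier regions, averages D per gene, and compares
duplication-age classes.
"""

import numpy as np

import lowcov as lc

panel = lc.simulate_panel(n_haplotypes=21, n_sites=3000,
                          region_length=1_500_000,
                          recombination_intensity=4.0, seed=30)
windows = lc.sliding_window_scan(
    {"chr1": (panel.positions, panel.matrix)},
    window_length=10_000, step=5_000, n_chromosomes=21)

defined = [w for w in windows if w.D is not None]
ds = np.array([w.D for w in defined])
print(f"windows: {len(windows)} total, {len(defined)} with defined D")
print(f"mean D {ds.mean():+.2f}, range [{ds.min():+.2f}, {ds.max():+.2f}]")

sweeps = lc.merge_outlier_regions(windows, cutoff=-2.0)
balancing = lc.merge_outlier_regions(windows, cutoff=+2.0)
print(f"putative sweep regions (D < -2): {len(sweeps)}")
print(f"putative balancing regions (D > +2): {len(balancing)}")

ann = lc.simulate_annotations(panel, n_genes=30, n_markers=5, seed=31)
gene_stats = lc.gene_average_d(ann.genes, windows)
res = lc.paralog_age_comparison(gene_stats, ann)
print(res["summary"].to_string(index=False))
print(f"Kruskal-Wallis p across age classes: {res['kruskal_p']:.3f}")
# Under this neutral simulation mean D sits near zero, few windows
# cross +/-2, and the age classes should NOT separate (p well above
# any threshold) — the scan only fires when a class truly differs.
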