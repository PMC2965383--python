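"""Sliding-window Tajima's D scan and paralog-age stratification.

Tajima's D contrasts two estimators of the population-genetics
parameter theta: mean pairwise diversity (pi) and the number of
segregating sites scaled by a1 = sum_{i<n} 1/i. Under neutrality the
two agree; an excess of rare variants (selective sweep, expansion)
drives D negative, an excess of intermediate-frequency variants
(balancing selection) drives it positive.

The scan tiles each chromosome with fixed-length windows on a fixed
step (1-based inclusive bounds: [1, L], [1+s, L+s], ...), flags windows
beyond +/-2, concatenates overlapping or abutting outlier windows into
regions, averages D per gene, and compares gene-level D across paralog
duplication-age classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import AnnotationSet

__all__ = [
    "WindowStat",
    "GeneStat",
    "tajimas_d",
    "sliding_window_scan",
    "merge_outlier_regions",
    "gene_average_d",
    "paralog_age_comparison",
]


@dataclass
class WindowStat:
    """Per-window segregating sites, diversity and Tajima's D."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    n_chromosomes: int
    S: int
    pi: float
    D: float | None  # None when undefined (S == 0)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneStat:
    """Average D over the windows a gene overlaps."""

    gene_id: str
    start: int
    end: int
    mean_D: float | None
    age_class: str | None = None
    pair_id: str | None = None


def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1 * a1 + a2)


def tajimas_d(
    n_chromosomes: int, window_haplotypes: np.ndarray
) -> tuple[int, float, float | None]:
    """(S, pi, D) for an n x sites binary allele matrix.

    ``pi`` is the mean pairwise Hamming distance over all chromosome
    pairs; ``D`` is None (undefined) when no site segregates or the
    variance term vanishes.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    m = np.asarray(window_haplotypes)
    if m.size == 0:
        return 0, 0.0, None
    if m.shape[0] != n_chromosomes:
        raise ValueError("matrix row count must equal n_chromosomes")
    counts = m.sum(axis=0).astype(float)
    return _tajima_from_counts(n_chromosomes, counts)


def _tajima_from_counts(
    n: int, alt_counts: np.ndarray
) -> tuple[int, float, float | None]:
    """Tajima summaries from per-site alternate-allele counts.

    pi and S depend only on per-site allele counts, so this path also
    serves unphased genotype input.
    """
    c = np.asarray(alt_counts, dtype=float)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    if S == 0:
        return 0, 0.0, None
    cs = c[seg]
    pairs = n * (n - 1) / 2.0
    pi = float((cs * (n - cs)).sum() / pairs)
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return S, pi, None
    return S, pi, float((pi - S / a1) / np.sqrt(var))


def sliding_window_scan(
    variants: dict[str, tuple[np.ndarray, np.ndarray]],
    window_length: int = 10_000,
    step: int = 5_000,
    n_chromosomes: int = 21,
) -> list[WindowStat]:
    """Tile each chromosome with overlapping windows and compute D.

    ``variants`` maps chromosome label -> (positions, allele matrix)
    with 1-based sorted positions and an ``n_chromosomes x n_sites``
    binary matrix (or a 1-D array of per-site alternate counts).
    Windows are 1-based inclusive ``[start, start + window_length - 1]``
    with starts 1, 1+step, ..., covering the last variant position; a
    site at a window's end coordinate belongs to that window.
    """
    if window_length <= 0 or step <= 0:
        raise ValueError("window_length and step must be positive")
    out: list[WindowStat] = []
    for chrom, (positions, matrix) in variants.items():
        positions = np.asarray(positions)
        if len(positions) and np.any(np.diff(positions) < 0):
            raise ValueError(f"positions on {chrom} must be sorted")
        matrix = np.asarray(matrix)
        counts = (matrix if matrix.ndim == 1
                  else matrix.sum(axis=0)).astype(float)
        last = int(positions[-1]) if len(positions) else window_length
        start = 1
        while start <= last:
            end = start + window_length - 1
            lo = np.searchsorted(positions, start, side="left")
            hi = np.searchsorted(positions, end, side="right")
            S, pi, D = _tajima_from_counts(n_chromosomes, counts[lo:hi])
            out.append(WindowStat(chrom, start, end, n_chromosomes, S, pi, D))
            start += step
    return out


def merge_outlier_regions(
    windows: list[WindowStat], cutoff: float = -2.0
) -> list[tuple[str, int, int]]:
    """Concatenate overlapping/abutting windows beyond the cutoff.

    A negative cutoff selects windows with D < cutoff (putative positive
    selection); a positive cutoff selects D > cutoff (putative balancing
    selection). Windows with undefined D never qualify. Returns merged
    (chromosome, start, end) regions, 1-based inclusive.
    """
    if cutoff < 0:
        qualifying = [w for w in windows if w.D is not None and w.D < cutoff]
    else:
        qualifying = [w for w in windows if w.D is not None and w.D > cutoff]
    qualifying.sort(key=lambda w: (w.chromosome, w.start))
    regions: list[tuple[str, int, int]] = []
    for w in qualifying:
        if regions and regions[-1][0] == w.chromosome and w.start <= regions[-1][2] + 1:
            chrom, start, end = regions[-1]
            regions[-1] = (chrom, start, max(end, w.end))
        else:
            regions.append((w.chromosome, w.start, w.end))
    return regions


def gene_average_d(
    genes: list[tuple[str, int, int]],
    windows: list[WindowStat],
    chromosome: str | None = None,
) -> list[GeneStat]:
    """Unweighted mean D over all windows each gene overlaps.

    Windows with undefined D are ignored; a gene overlapping no such
    window gets ``mean_D=None``. Gene intervals are 1-based inclusive.
    """
    pool = [w for w in windows
            if w.D is not None and (chromosome is None or w.chromosome == chromosome)]
    starts = np.array([w.start for w in pool])
    ends = np.array([w.end for w in pool])
    ds = np.array([w.D for w in pool])
    out = []
    for gid, gstart, gend in genes:
        if len(pool):
            mask = (starts <= gend) & (ends >= gstart)
            mean_d = float(ds[mask].mean()) if mask.any() else None
        else:
            mean_d = None
        out.append(GeneStat(gid, gstart, gend, mean_d))
    return out


def paralog_age_comparison(
    gene_stats: list[GeneStat],
    annotations: AnnotationSet,
    proximity_threshold: int = 250_000,
) -> dict:
    """Stratify gene-level D by paralog duplication age.

    Paralog pairs whose gene starts lie closer than
    ``proximity_threshold`` are ignored (their windows overlap, so their
    D values are not independent). Produces per-age-class mean/median D,
    a Kruskal-Wallis omnibus test across the age classes plus the
    non-paralog background, and a secondary comparison (Welch t-test) of
    each pair's greater-D member against the background.
    """
    d_by_gene = {g.gene_id: g.mean_D for g in gene_stats if g.mean_D is not None}
    pair_genes: set[str] = set()
    eligible_pairs = []
    for g1, g2, age, _ in annotations.paralog_pairs:
        s1 = annotations.gene_interval(g1)[0]
        s2 = annotations.gene_interval(g2)[0]
        pair_genes.update((g1, g2))
        if abs(s1 - s2) < proximity_threshold:
            continue
        if g1 in d_by_gene and g2 in d_by_gene:
            eligible_pairs.append((g1, g2, age))

    class_values: dict[str, list[float]] = {c: [] for c in annotations.age_classes}
    greater_members: list[float] = []
    for g1, g2, age in eligible_pairs:
        d1, d2 = d_by_gene[g1], d_by_gene[g2]
        class_values[age].extend((d1, d2))
        greater_members.append(max(d1, d2))

    background = [d for gid, d in d_by_gene.items() if gid not in pair_genes]

    summary = pd.DataFrame([
        {"age_class": c, "n_genes": len(v),
         "mean_D": np.mean(v) if v else np.nan,
         "median_D": np.median(v) if v else np.nan}
        for c, v in class_values.items()
    ] + [{"age_class": "background", "n_genes": len(background),
          "mean_D": np.mean(background) if background else np.nan,
          "median_D": np.median(background) if background else np.nan}])

    groups = []
    for c, v in class_values.items():
        if len(v) >= 2:
            groups.append(v)
        elif v:
            warnings.warn(f"age class {c!r} has fewer than 2 genes; "
                          "excluded from the omnibus test")
    if len(background) >= 2:
        groups.append(background)

    kw_stat = kw_p = None
    if len(groups) >= 2:
        kw_stat, kw_p = stats.kruskal(*groups)

    greater_stat = greater_p = None
    if len(greater_members) >= 2 and len(background) >= 2:
        greater_stat, greater_p = stats.ttest_ind(
            greater_members, background, equal_var=False)

    return {
        "summary": summary,
        "kruskal_statistic": None if kw_stat is None else float(kw_stat),
        "kruskal_p": None if kw_p is None else float(kw_p),
        "greater_member_t": None if greater_stat is None else float(greater_stat),
        "greater_member_p": None if greater_p is None else float(greater_p),
        "n_pairs": len(eligible_pairs),
    }
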