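"""LD-proximity prioritization of novel variants near disease markers.

A novel variant is prioritized when (i) it is absent from the
known-variant catalog, (ii) it lies within 250 kb of a disease-
associated marker, (iii) that marker is heterozygous in the individual,
and (iv) at least one pair of panel markers in high LD flanks both
positions — putative evidence the novel variant rides the same
haplotype as the risk marker. A 2x2 enrichment test (Fisher exact or
Pearson chi-square) asks whether prioritized variants are enriched for
deleterious labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calling import VariantCall
from .panel import HaplotypePanel, ld_r2
from .simulate import AnnotationSet

__all__ = [
    "CandidateVariant",
    "ContingencyTable",
    "SEVERITY_ORDER",
    "has_flanking_high_ld_pair",
    "prioritize_novel_variants",
    "enrichment_test",
]

#: Consequence classes ordered most to least severe.
SEVERITY_ORDER = ("stop_gained", "essential_splice", "splice",
                  "non_synonymous", "other")


@dataclass
class CandidateVariant:
    """A prioritized novel variant with its supporting evidence."""

    position: int
    genotype: str
    novel: bool
    consequence: str
    nearest_marker: int
    marker_distance: int
    flanking_pairs: list[tuple[int, int, float]]  # (pos1, pos2, r2)
    deleterious: bool | None = None

    def __post_init__(self) -> None:
        if self.marker_distance < 0:
            raise ValueError("marker distance must be non-negative")


@dataclass
class ContingencyTable:
    """2x2 counts with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("outcome", "no_outcome")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=0) == 0) or np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("table has a zero margin")


def has_flanking_high_ld_pair(
    novel_pos: int,
    marker_pos: int,
    panel: HaplotypePanel,
    r2_threshold: float = 0.8,
    search_flank: int = 250_000,
) -> tuple[bool, list[tuple[int, int, float]]]:
    """Is there a panel marker pair in high LD spanning both positions?

    Qualifying pairs (m1, m2) satisfy m1 <= min(novel, marker),
    m2 >= max(novel, marker) and r²(m1, m2) >= r2_threshold. The search
    considers flanking markers up to ``search_flank`` bp beyond the
    spanned interval (LD at larger distances would not qualify anyway).
    Returns the flag and every qualifying pair as (pos1, pos2, r2).
    """
    lo, hi = sorted((novel_pos, marker_pos))
    pos = panel.positions
    left = np.flatnonzero((pos <= lo) & (pos >= lo - search_flank))
    right = np.flatnonzero((pos >= hi) & (pos <= hi + search_flank))
    if not len(left) or not len(right):
        return False, []
    # r2 for all left x right pairs via one centered cross-product
    m = panel.matrix.astype(float)
    xl = m[:, left] - m[:, left].mean(axis=0)
    xr = m[:, right] - m[:, right].mean(axis=0)
    n = panel.n_haplotypes
    cov = xl.T @ xr / n
    var_l = (xl**2).mean(axis=0)
    var_r = (xr**2).mean(axis=0)
    r2 = cov**2 / np.outer(var_l, var_r)
    ii, jj = np.nonzero(r2 >= r2_threshold)
    keep = left[ii] != right[jj]
    evidence = [
        (int(pos[left[i]]), int(pos[right[j]]), float(r2[i, j]))
        for i, j in zip(ii[keep], jj[keep])
    ]
    return bool(evidence), evidence


def prioritize_novel_variants(
    calls: list[VariantCall],
    annotations: AnnotationSet,
    panel: HaplotypePanel,
    max_distance: int = 250_000,
    r2_threshold: float = 0.8,
) -> list[CandidateVariant]:
    """Apply the four prioritization rules and sort by severity.

    ``calls`` must contain the individual's genotypes both at candidate
    positions and at the disease-marker positions (the marker must be
    heterozygous for its neighborhood to contribute). Consequence and
    deleterious labels come from ``annotations``.
    """
    genotype_at = {c.position: c.genotype for c in calls
                   if c.filter_status == "PASS" and c.genotype is not None}
    het_markers = [
        (pos, label) for pos, label, _known in annotations.disease_markers
        if pos in genotype_at and genotype_at[pos][0] != genotype_at[pos][1]
    ]

    out: list[CandidateVariant] = []
    for call in calls:
        if call.filter_status != "PASS" or call.genotype is None:
            continue
        if call.position in annotations.known_variants:
            continue
        try:
            ref = panel.alleles[panel.site_index(call.position)][0]
        except KeyError:
            continue
        if call.genotype == ref * 2:
            continue  # not a variant in this individual
        near = [(abs(call.position - mpos), mpos) for mpos, _ in het_markers]
        near = [x for x in near if x[0] < max_distance]
        if not near:
            continue
        dist, marker = min(near)
        ok, evidence = has_flanking_high_ld_pair(call.position, marker, panel,
                                                 r2_threshold)
        if not ok:
            continue
        consequence = annotations.consequences.get(call.position, "other")
        out.append(CandidateVariant(
            call.position, call.genotype, True, consequence, marker, dist,
            evidence, call.position in annotations.deleterious))
    out.sort(key=lambda c: (SEVERITY_ORDER.index(c.consequence), c.position))
    return out


def enrichment_test(
    table: ContingencyTable, method: str = "fisher_one_sided"
) -> dict[str, float]:
    """Fisher exact or Pearson chi-square on a 2x2 table.

    ``fisher_one_sided`` tests enrichment of the top-left cell (upper
    hypergeometric tail); the chi-square uses no continuity correction
    (df = 1). The odds ratio comes from cross-products, with 0.5 added
    to every cell (Haldane-Anscombe, flagged) when any cell is zero.
    """
    c = table.counts
    if method == "fisher_one_sided":
        statistic, p = stats.fisher_exact(c, alternative="greater")
    elif method == "fisher_two_sided":
        statistic, p = stats.fisher_exact(c, alternative="two-sided")
    elif method == "chi_square":
        statistic, p, _, _ = stats.chi2_contingency(c, correction=False)
    else:
        raise ValueError(f"unknown method {method!r}")

    corrected = bool((c == 0).any())
    cc = c + 0.5 if corrected else c
    odds_ratio = float(cc[0, 0] * cc[1, 1] / (cc[0, 1] * cc[1, 0]))
    return {"statistic": float(statistic), "p_value": float(p),
            "odds_ratio": odds_ratio, "zero_cell_corrected": corrected}
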