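"""Synthetic data with known truth.

Everything downstream — likelihood calling, haplotype-copying priors,
depth titration, the selection scan and LD prioritization — is exercised
against data from this module, so each generator states exactly what it
emulates:

* :func:`simulate_panel` — a phased reference panel with mosaic LD. New
  haplotypes copy a uniformly chosen existing one with Poisson switch
  points (recombination) and per-site copy errors whose rate scales as
  ``theta_site / k`` when ``k`` haplotypes exist. That urn-style scaling
  makes the site-frequency spectrum approximately neutral, which the
  selection-scan calibration relies on.
* :func:`sample_diploid` — a diploid whose haplotypes are mosaics of
  panel rows, i.e. a target the copying model can actually impute.
* :func:`simulate_pileups` — per-site read stacks with Poisson depth and
  a uniform base-error model at a fixed Phred quality.
* :func:`simulate_array_truth` — a bead-array-like genotype subset with
  a small error rate.
* :func:`simulate_annotations` — gene models, paralog pairs with
  duplication-age classes, disease markers and known-variant flags.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import SitePileup
from .panel import HaplotypePanel

__all__ = [
    "DiploidTruth",
    "AnnotationSet",
    "simulate_panel",
    "sample_diploid",
    "simulate_pileups",
    "simulate_array_truth",
    "simulate_annotations",
]

_BASES = np.array(list("ACGT"))

#: Duplication-age labels ordered young -> old, mirroring the lineage
#: depths used for human paralog ages.
DEFAULT_AGE_CLASSES = (
    "species_specific",
    "primate",
    "eutherian",
    "vertebrate",
)


@dataclass
class DiploidTruth:
    """Ground-truth diploid sampled as a mosaic of panel haplotypes."""

    haplotype_a: np.ndarray
    haplotype_b: np.ndarray
    genotypes: list[str]  # unordered allele pairs, e.g. "AG"
    mosaic_breakpoints: tuple[np.ndarray, np.ndarray]
    panel: HaplotypePanel

    def dosage(self) -> np.ndarray:
        """Per-site count of alternate alleles (0, 1 or 2)."""
        return (self.haplotype_a + self.haplotype_b).astype(np.int8)

    def genotype_table(self) -> dict[int, str]:
        """Mapping position -> unordered genotype string."""
        return {int(p): g for p, g in zip(self.panel.positions, self.genotypes)}


@dataclass
class AnnotationSet:
    """Gene models, paralog pairs, disease markers, known variants.

    ``paralog_pairs`` entries are ``(gene_id_1, gene_id_2, age_class,
    proximal)`` where ``proximal`` is True when the gene starts lie
    closer than 250 kb (such pairs are excluded from age comparisons).
    ``consequences`` and ``deleterious`` carry simulated functional
    labels so prioritization and enrichment are testable without a
    predictor.
    """

    genes: list[tuple[str, int, int]]
    paralog_pairs: list[tuple[str, str, str, bool]]
    disease_markers: list[tuple[int, str, bool]]
    known_variants: set[int]
    age_classes: tuple[str, ...] = DEFAULT_AGE_CLASSES
    consequences: dict[int, str] = field(default_factory=dict)
    deleterious: set[int] = field(default_factory=set)

    def gene_interval(self, gene_id: str) -> tuple[int, int]:
        for gid, start, end in self.genes:
            if gid == gene_id:
                return start, end
        raise KeyError(gene_id)


def _dosage_to_genotype(dosage: int, ref: str, alt: str) -> str:
    g = {0: ref + ref, 1: ref + alt, 2: alt + alt}[int(dosage)]
    return "".join(sorted(g))


def _mosaic_row(matrix: np.ndarray, n_rows_available: int, n_switches: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Copy a mosaic of the first ``n_rows_available`` rows of ``matrix``.

    Returns the new row and the site indices where the copied row switches.
    Each switch moves to a different source row.
    """
    n_sites = matrix.shape[1]
    n_switches = min(n_switches, n_sites - 1)
    if n_switches:
        breakpoints = np.sort(rng.choice(np.arange(1, n_sites),
                                         size=n_switches, replace=False))
    else:
        breakpoints = np.array([], dtype=np.int64)
    bounds = np.concatenate(([0], breakpoints, [n_sites]))
    row = np.empty(n_sites, dtype=np.int8)
    src = int(rng.integers(n_rows_available))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        row[lo:hi] = matrix[src, lo:hi]
        if n_rows_available > 1:
            step = int(rng.integers(n_rows_available - 1))
            src = step if step < src else step + 1
    return row, breakpoints


def simulate_panel(
    n_haplotypes: int,
    n_sites: int,
    region_length: int = 2_000_000,
    recombination_intensity: float = 3.0,
    seed: int = 0,
    theta_site: float = 0.05,
    chromosome_label: str = "chr1",
) -> HaplotypePanel:
    """Simulate a phased panel with mosaic LD structure.

    ``recombination_intensity`` is the expected number of copy switches
    per new haplotype across the region; lower values give longer shared
    segments and stronger LD. ``theta_site`` is the scaled per-site
    mutation intensity; the realised per-copy error rate is
    ``theta_site / k`` for the (k+1)-th haplotype, which yields an
    approximately neutral frequency spectrum among the sites kept.

    Candidate sites are laid down uniformly over ``region_length`` and
    only sites polymorphic among the simulated haplotypes are retained
    (evenly thinned to exactly ``n_sites``).
    """
    if n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if region_length < n_sites:
        raise ValueError("region_length must be at least n_sites")
    if not 0 < theta_site < 1:
        raise ValueError("theta_site must be in (0, 1)")

    a1 = sum(1.0 / i for i in range(1, n_haplotypes))
    p_poly = min(0.9, theta_site * a1)  # crude yield estimate
    rng = np.random.default_rng(seed)
    for attempt in range(6):
        factor = 1.6 * 2**attempt
        n_cand = min(region_length, int(np.ceil(n_sites / p_poly * factor)))
        batch_rng = np.random.default_rng(rng.integers(2**31))
        positions = np.sort(batch_rng.choice(
            np.arange(1, region_length + 1), size=n_cand, replace=False))
        matrix = np.zeros((n_haplotypes, n_cand), dtype=np.int8)
        for k in range(1, n_haplotypes):
            row, _ = _mosaic_row(matrix, k, int(batch_rng.poisson(
                recombination_intensity)), batch_rng)
            mu = theta_site / k
            row = row ^ (batch_rng.random(n_cand) < mu)
            matrix[k] = row.astype(np.int8)
        counts = matrix.sum(axis=0)
        poly = np.flatnonzero((counts > 0) & (counts < n_haplotypes))
        if len(poly) >= n_sites:
            keep = poly[np.linspace(0, len(poly) - 1, n_sites).round().astype(int)]
            ref_idx = batch_rng.integers(0, 4, size=n_sites)
            alt_off = batch_rng.integers(1, 4, size=n_sites)
            alleles = [(_BASES[r], _BASES[(r + o) % 4])
                       for r, o in zip(ref_idx, alt_off)]
            return HaplotypePanel(chromosome_label, positions[keep],
                                  alleles, matrix[:, keep])
    raise RuntimeError(
        "could not generate enough polymorphic sites; raise theta_site "
        "or region_length")


def sample_diploid(
    panel: HaplotypePanel,
    recombination_intensity: float = 3.0,
    seed: int = 0,
) -> DiploidTruth:
    """Sample a diploid target as two independent mosaics of panel rows.

    Each haplotype carries Poisson(``recombination_intensity``) switch
    points; every switch moves to a different panel row, so the recorded
    breakpoint count is exactly the Poisson draw.
    """
    if panel.n_sites == 0 or panel.n_haplotypes == 0:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(seed)
    haps, bps = [], []
    for _ in range(2):
        row, bp = _mosaic_row(panel.matrix, panel.n_haplotypes,
                              int(rng.poisson(recombination_intensity)), rng)
        haps.append(row)
        bps.append(bp)
    genotypes = [
        _dosage_to_genotype(haps[0][j] + haps[1][j], *panel.alleles[j])
        for j in range(panel.n_sites)
    ]
    return DiploidTruth(haps[0], haps[1], genotypes, (bps[0], bps[1]), panel)


def simulate_pileups(
    truth: DiploidTruth,
    mean_depth: float,
    base_error: float = 0.01,
    base_quality: int | None = None,
    seed: int = 0,
) -> list[SitePileup]:
    """Simulate per-site read pileups over the truth's panel sites.

    Depth is Poisson(``mean_depth``); each read copies one of the two
    haplotypes uniformly and reports the true base with probability
    ``1 − base_error``, otherwise a uniformly chosen different base.
    ``base_quality`` defaults to the Phred score matching ``base_error``.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    if not 0 <= base_error <= 0.75:
        raise ValueError("base_error must be in [0, 0.75]")
    if base_quality is None:
        base_quality = 93 if base_error == 0 else int(round(-10 * np.log10(base_error)))
    rng = np.random.default_rng(seed)
    panel = truth.panel
    pileups = []
    depths = rng.poisson(mean_depth, size=panel.n_sites)
    for j, depth in enumerate(depths):
        ref, alt = panel.alleles[j]
        hap_alleles = np.array([ref, alt])
        which = rng.integers(0, 2, size=depth)
        dos = np.where(which == 0, truth.haplotype_a[j], truth.haplotype_b[j])
        bases = hap_alleles[dos]
        if base_error > 0 and depth:
            err = rng.random(depth) < base_error
            if err.any():
                bases = bases.copy()
                for i in np.flatnonzero(err):
                    others = [b for b in "ACGT" if b != bases[i]]
                    bases[i] = others[rng.integers(3)]
        pileups.append(SitePileup(
            position=int(panel.positions[j]),
            reference_base=ref,
            read_bases=list(bases),
            qualities=[base_quality] * int(depth),
        ))
    return pileups


def simulate_array_truth(
    truth: DiploidTruth,
    site_fraction: float = 0.25,
    array_error: float = 0.005,
    seed: int = 0,
) -> dict[int, str]:
    """Bead-array-like genotype subset: position -> genotype string.

    Each site enters independently with probability ``site_fraction``;
    an entered genotype is replaced by a uniformly chosen different
    genotype (from the site's three) with probability ``array_error``.
    """
    if not 0 <= site_fraction <= 1:
        raise ValueError("site_fraction must be in [0, 1]")
    if not 0 <= array_error < 0.5:
        raise ValueError("array_error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    panel = truth.panel
    table: dict[int, str] = {}
    chosen = rng.random(panel.n_sites) < site_fraction
    flip = rng.random(panel.n_sites) < array_error
    for j in np.flatnonzero(chosen):
        g = truth.genotypes[j]
        if flip[j]:
            space = [s for s in panel.genotype_space(j) if s != g]
            g = space[rng.integers(len(space))]
        table[int(panel.positions[j])] = g
    return table


def simulate_annotations(
    panel: HaplotypePanel,
    n_genes: int = 20,
    n_markers: int = 5,
    paralog_age_classes: tuple[str, ...] = DEFAULT_AGE_CLASSES,
    seed: int = 0,
    gene_length: int = 20_000,
    paralog_fraction: float = 0.5,
    known_fraction: float = 0.6,
    deleterious_fraction: float = 0.1,
    proximity_threshold: int = 250_000,
) -> AnnotationSet:
    """Generate gene models, paralog pairs, disease markers and labels.

    Genes are non-overlapping fixed-length intervals; a fraction of them
    are paired as paralogs with an age class drawn from
    ``paralog_age_classes`` and flagged proximal when their starts are
    closer than ``proximity_threshold``. Disease markers sit at panel
    sites. A ``known_fraction`` of panel sites is marked as previously
    catalogued; the rest are novel. Consequence classes and deleterious
    labels are assigned at random so that enrichment machinery has
    something to chew on.
    """
    rng = np.random.default_rng(seed)
    region_length = int(panel.positions[-1])
    if n_genes * (gene_length + 1) > region_length:
        raise ValueError("cannot pack that many genes into the region")
    if n_markers > panel.n_sites:
        raise ValueError("more markers requested than panel sites")

    # non-overlapping placement: distribute leftover space as random gaps
    free = region_length - n_genes * gene_length
    gaps = rng.multinomial(free - n_genes, [1 / (n_genes + 1)] * (n_genes + 1))
    genes: list[tuple[str, int, int]] = []
    cursor = 1
    for i in range(n_genes):
        cursor += int(gaps[i]) + (1 if i else 0)
        start = cursor
        end = start + gene_length - 1
        genes.append((f"G{i:04d}", start, end))
        cursor = end

    n_pairs = int(n_genes * paralog_fraction) // 2
    paired = rng.choice(n_genes, size=2 * n_pairs, replace=False)
    paralog_pairs = []
    for p in range(n_pairs):
        g1, g2 = genes[paired[2 * p]], genes[paired[2 * p + 1]]
        age = paralog_age_classes[rng.integers(len(paralog_age_classes))]
        proximal = abs(g1[1] - g2[1]) < proximity_threshold
        paralog_pairs.append((g1[0], g2[0], age, proximal))

    marker_sites = rng.choice(panel.n_sites, size=n_markers, replace=False)
    disease_markers = [
        (int(panel.positions[j]), f"phenotype_{i}", True)
        for i, j in enumerate(sorted(marker_sites))
    ]
    known = set(int(p) for p in panel.positions[
        rng.random(panel.n_sites) < known_fraction])
    known.update(pos for pos, _, _ in disease_markers)

    classes = ["non_synonymous", "splice", "essential_splice", "stop_gained",
               "other"]
    weights = np.array([0.1, 0.04, 0.01, 0.005, 0.845])
    draw = rng.choice(len(classes), size=panel.n_sites, p=weights / weights.sum())
    consequences = {int(p): classes[d] for p, d in zip(panel.positions, draw)}
    deleterious = set(int(p) for p in panel.positions[
        rng.random(panel.n_sites) < deleterious_fraction])

    return AnnotationSet(genes, paralog_pairs, disease_markers, known,
                         tuple(paralog_age_classes), consequences, deleterious)
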