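"""Bayesian genotype calling: priors x read conditionals -> posteriors.

Three modes mirror the comparison at the heart of the method:

* ``sequence_only`` — reads alone under a theta-weighted prior;
* ``freq_prior`` — Hardy-Weinberg prior from the panel allele frequency;
* ``haplotype_prior`` — copying-model prior from surrounding sites'
  read conditionals and the phased panel.

Also hosts the short-indel candidate filters (spacing, mapping quality,
depth) used alongside SNP calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imputation import ImputationParams, genotype_frequency_prior, impute_genotype_prior
from .likelihood import (
    CallerConfig,
    GenotypeDistribution,
    SitePileup,
    call_sequence_only,
    likelihoods_to_conditionals,
    site_genotype_likelihoods,
    _map_call,
)
from .panel import HaplotypePanel

__all__ = [
    "VariantCall",
    "IndelCandidate",
    "MODES",
    "combine_posterior",
    "call_with_prior",
    "filter_indel_candidates",
]

MODES = ("sequence_only", "freq_prior", "haplotype_prior")


@dataclass
class VariantCall:
    """A per-site genotype call with its posterior and provenance."""

    position: int
    genotype: str | None
    posterior: float | None
    mode: str
    filter_status: str  # "PASS" or a reason code
    depth: int = 0

    def __post_init__(self) -> None:
        if self.posterior is not None and not 0 <= self.posterior <= 1:
            raise ValueError("posterior must lie in [0, 1]")
        if self.filter_status != "PASS" and not self.filter_status:
            raise ValueError("filtered calls need a reason code")


@dataclass
class IndelCandidate:
    """A raw short-indel candidate prior to filtering.

    ``length`` is signed: negative for deletions, positive insertions.
    """

    position: int
    length: int
    quality: float
    mapping_quality: float
    depth: int


def combine_posterior(
    prior: GenotypeDistribution, conditional: GenotypeDistribution
) -> GenotypeDistribution:
    """Bayes combination: element-wise product, renormalized to sum 1."""
    if prior.space != conditional.space:
        raise ValueError("prior and conditional must share a genotype space")
    if prior.site != conditional.site:
        raise ValueError("prior and conditional must describe the same site")
    if prior.kind != "probability" or conditional.kind != "probability":
        raise ValueError("both inputs must be probability distributions")
    product = prior.values * conditional.values
    total = product.sum()
    if total <= 0:
        raise ValueError("degenerate site: prior and conditional supports are disjoint")
    return GenotypeDistribution(prior.site, prior.space, product / total,
                                "probability")


def _panel_conditionals(
    pileups: list[SitePileup], panel: HaplotypePanel
) -> dict[int, GenotypeDistribution]:
    """Read conditionals restricted to each site's panel genotype space.

    Sites with no reads are omitted (their conditional is uniform and
    carries no information for the copying prior).
    """
    conditionals: dict[int, GenotypeDistribution] = {}
    for pu in pileups:
        if pu.depth == 0:
            continue
        j = panel.site_index(pu.position)
        cond10 = likelihoods_to_conditionals(site_genotype_likelihoods(pu))
        conditionals[j] = cond10.restrict(panel.genotype_space(j))
    return conditionals


def call_with_prior(
    pileups: list[SitePileup],
    panel: HaplotypePanel,
    mode: str = "haplotype_prior",
    caller_config: CallerConfig | None = None,
    imputation_params: ImputationParams | None = None,
) -> list[VariantCall]:
    """Posterior genotype calls at panel sites under the chosen prior.

    ``sequence_only`` reproduces :func:`call_sequence_only` exactly.
    The prior modes combine each site's read conditional (restricted to
    the panel's two alleles) with either the Hardy-Weinberg prior or the
    copying-model prior built from the *other* sites' conditionals, then
    take the MAP genotype with seeded random tie-breaking. Depth filters
    from ``caller_config`` apply in all modes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    caller_config = caller_config or CallerConfig()
    imputation_params = imputation_params or ImputationParams()

    if mode == "sequence_only":
        return [
            VariantCall(c.position, c.genotype, c.posterior, mode,
                        c.filter_status, c.depth)
            for c in call_sequence_only(pileups, caller_config)
        ]

    conditionals = _panel_conditionals(pileups, panel)
    rng = np.random.default_rng(caller_config.tie_break_seed)
    calls: list[VariantCall] = []
    for pu in pileups:
        if pu.depth < caller_config.min_depth:
            calls.append(VariantCall(pu.position, None, None, mode,
                                     "LOW_DEPTH", pu.depth))
            continue
        if pu.depth > caller_config.max_depth:
            calls.append(VariantCall(pu.position, None, None, mode,
                                     "HIGH_DEPTH", pu.depth))
            continue
        j = panel.site_index(pu.position)
        if mode == "freq_prior":
            prior = genotype_frequency_prior(j, panel)
        else:
            neighbors = {k: d for k, d in conditionals.items() if k != j}
            prior = impute_genotype_prior(j, neighbors, panel,
                                          imputation_params)
        cond = conditionals.get(j)
        if cond is None:
            posterior = prior
        else:
            posterior = combine_posterior(prior, cond)
        genotype, post = _map_call(posterior.values, posterior.space, rng)
        calls.append(VariantCall(pu.position, genotype, post, mode, "PASS",
                                 pu.depth))
    return calls


def filter_indel_candidates(
    candidates: list[IndelCandidate], ploidy: str = "diploid"
) -> list[IndelCandidate]:
    """Apply the short-indel spacing and quality filters.

    Candidates closer than 20 bp are resolved left-to-right greedily,
    keeping the higher-quality member of any clash. Survivors must have
    mapping quality > 20 and depth strictly between the lower bound
    (4 diploid, 2 haploid) and 100.
    """
    if ploidy not in ("diploid", "haploid"):
        raise ValueError(f"unknown ploidy {ploidy!r}")
    min_depth = 4 if ploidy == "diploid" else 2

    spaced: list[IndelCandidate] = []
    for cand in sorted(candidates, key=lambda c: c.position):
        if spaced and cand.position - spaced[-1].position < 20:
            if cand.quality > spaced[-1].quality:
                spaced[-1] = cand
            continue
        spaced.append(cand)
    return [c for c in spaced
            if c.mapping_quality > 20 and min_depth < c.depth < 100]
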