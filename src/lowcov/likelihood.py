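"""Per-site genotype likelihoods from read pileups.

The diploid genotype space is the 10 unordered base pairs (AA, AC, ...,
TT); heterozygotes emit each allele with probability 1/2 before the
Phred-scaled error channel is applied. Likelihoods are reported as
ratios to the most likely genotype (so the best genotype scores 1) and
can be renormalized into "conditionals" that sum to one — the currency
passed to the Bayesian combiner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

__all__ = [
    "SitePileup",
    "GenotypeDistribution",
    "CallerConfig",
    "DIPLOID_GENOTYPES",
    "phred_to_error",
    "site_genotype_likelihoods",
    "likelihoods_to_conditionals",
    "call_sequence_only",
]

BASES = "ACGT"

#: The 10 unordered diploid genotypes over {A,C,G,T}.
DIPLOID_GENOTYPES: tuple[str, ...] = tuple(
    a + b for a, b in combinations_with_replacement(BASES, 2)
)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def phred_to_error(quality: float | np.ndarray) -> np.ndarray:
    """Phred score -> base error probability, capped at 0.75."""
    return np.minimum(10.0 ** (-np.asarray(quality, dtype=float) / 10.0), 0.75)


@dataclass
class SitePileup:
    """Observed read bases and Phred qualities at one position."""

    position: int
    reference_base: str
    read_bases: list[str]
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.read_bases) != len(self.qualities):
            raise ValueError("read_bases and qualities must be the same length")

    @property
    def depth(self) -> int:
        return len(self.read_bases)


@dataclass
class GenotypeDistribution:
    """Values over an ordered genotype space at one site.

    ``kind`` is ``"likelihood_ratio"`` (max value 1) or ``"probability"``
    (values sum to 1 within 1e-9).
    """

    site: int
    space: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.space) != len(self.values):
            raise ValueError("space and values must be the same length")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        if self.kind == "probability":
            if abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")
        elif self.kind == "likelihood_ratio":
            if self.values.size and abs(self.values.max() - 1.0) > 1e-9:
                raise ValueError("likelihood ratios must have max 1")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    def __getitem__(self, genotype: str) -> float:
        return float(self.values[self.space.index(genotype)])

    def argmax(self) -> str:
        return self.space[int(np.argmax(self.values))]

    def restrict(self, space: tuple[str, ...]) -> "GenotypeDistribution":
        """Project onto a genotype sub-space and renormalize.

        Used to collapse a 10-genotype read conditional onto the three
        genotypes a biallelic panel admits. A zero-mass restriction
        (all reads support off-panel bases) returns the uniform
        distribution: the reads then carry no information about the
        admissible genotypes.
        """
        idx = [self.space.index(g) for g in space]
        vals = self.values[idx]
        total = vals.sum()
        if total == 0:
            vals = np.full(len(space), 1.0 / len(space))
        else:
            vals = vals / total
        return GenotypeDistribution(self.site, tuple(space), vals, "probability")


@dataclass
class CallerConfig:
    """Filters and priors for sequence-only calling.

    ``theta`` is the prior heterozygosity; autosomal sites outside
    [``min_depth``, ``max_depth``] are excluded; the haploid rule calls a
    non-reference allele whose normalized likelihood exceeds
    ``haploid_likelihood_threshold`` at depths in
    [``haploid_min_depth``, ``max_depth``]. ``consensus_quality_cutoff``
    is a Phred-scaled posterior-quality cutoff, permissive by default
    (None disables it).
    """

    theta: float = 0.001
    min_depth: int = 4
    max_depth: int = 100
    haploid_min_depth: int = 2
    haploid_likelihood_threshold: float = 0.5
    consensus_quality_cutoff: float | None = None
    tie_break_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")

    def genotype_prior(self, reference_base: str) -> np.ndarray:
        """Theta-weighted prior over the 10 unordered genotypes.

        Mass ``theta`` is split over the three heterozygotes containing
        the reference allele, ``theta/2`` over the three non-reference
        homozygotes, and the remainder sits on the reference homozygote.
        """
        prior = np.zeros(len(DIPLOID_GENOTYPES))
        for i, g in enumerate(DIPLOID_GENOTYPES):
            a, b = g[0], g[1]
            if a == b:
                prior[i] = (1.0 - 1.5 * self.theta if a == reference_base
                            else self.theta / 6.0)
            elif reference_base in g:
                prior[i] = self.theta / 3.0
        return prior


def site_genotype_likelihoods(pileup: SitePileup) -> GenotypeDistribution:
    """Likelihood ratios over the 10 unordered diploid genotypes.

    Per genotype g = xy, L(g) = prod over reads of
    ``0.5 P(base|x) + 0.5 P(base|y)`` with ``P(base|x) = 1−e`` when the
    base matches x and ``e/3`` otherwise. The output is scaled so the
    most likely genotype has ratio 1; an empty pileup yields all ratios
    equal to 1 (no information).
    """
    if pileup.depth == 0:
        return GenotypeDistribution(
            pileup.position, DIPLOID_GENOTYPES,
            np.ones(len(DIPLOID_GENOTYPES)), "likelihood_ratio")
    errors = phred_to_error(np.array(pileup.qualities, dtype=float))
    base_idx = np.array([_BASE_INDEX[b] for b in pileup.read_bases])
    # per-read emission matrix: reads x 4 alleles
    emit = np.tile((errors / 3.0)[:, None], (1, 4))
    emit[np.arange(pileup.depth), base_idx] = 1.0 - errors
    loglik = np.empty(len(DIPLOID_GENOTYPES))
    for i, g in enumerate(DIPLOID_GENOTYPES):
        per_read = 0.5 * emit[:, _BASE_INDEX[g[0]]] + 0.5 * emit[:, _BASE_INDEX[g[1]]]
        loglik[i] = np.log(per_read).sum()
    ratios = np.exp(loglik - loglik.max())
    return GenotypeDistribution(pileup.position, DIPLOID_GENOTYPES, ratios,
                                "likelihood_ratio")


def likelihoods_to_conditionals(dist: GenotypeDistribution) -> GenotypeDistribution:
    """Normalize likelihood ratios by their sum so they sum to one."""
    total = dist.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero distribution")
    return GenotypeDistribution(dist.site, dist.space, dist.values / total,
                                "probability")


@dataclass
class SiteCall:
    """One row of a call table."""

    position: int
    reference_base: str
    genotype: str | None
    posterior: float | None
    depth: int
    filter_status: str  # "PASS" | "LOW_DEPTH" | "HIGH_DEPTH" | "LOW_QUAL"


def _map_call(values: np.ndarray, space: tuple[str, ...],
              rng: np.random.Generator) -> tuple[str, float]:
    """Maximum-a-posteriori genotype with seeded random tie-breaking."""
    total = values.sum()
    probs = values / total
    best = probs.max()
    ties = np.flatnonzero(probs >= best * (1.0 - 1e-12))
    pick = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
    return space[pick], float(probs[pick])


def call_sequence_only(
    pileups: list[SitePileup],
    config: CallerConfig | None = None,
    ploidy: str = "diploid",
) -> list[SiteCall]:
    """Genotype calls from reads alone under the depth/quality filters.

    Diploid: sites with depth outside [min_depth, max_depth] are marked
    filtered; the rest get the MAP genotype under the theta-weighted
    prior, with exact posterior ties broken at random (seeded). Haploid:
    a single-allele call is emitted when its normalized likelihood
    exceeds the threshold at depths in [haploid_min_depth, max_depth].
    """
    config = config or CallerConfig()
    if ploidy not in ("diploid", "haploid"):
        raise ValueError(f"unknown ploidy {ploidy!r}")
    rng = np.random.default_rng(config.tie_break_seed)
    calls: list[SiteCall] = []
    for pu in pileups:
        lo = config.min_depth if ploidy == "diploid" else config.haploid_min_depth
        if pu.depth < lo:
            calls.append(SiteCall(pu.position, pu.reference_base, None, None,
                                  pu.depth, "LOW_DEPTH"))
            continue
        if pu.depth > config.max_depth:
            calls.append(SiteCall(pu.position, pu.reference_base, None, None,
                                  pu.depth, "HIGH_DEPTH"))
            continue
        if ploidy == "haploid":
            calls.append(_call_haploid(pu, config))
            continue
        lik = site_genotype_likelihoods(pu)
        weighted = lik.values * config.genotype_prior(pu.reference_base)
        if weighted.sum() == 0:
            weighted = lik.values
        genotype, post = _map_call(weighted, DIPLOID_GENOTYPES, rng)
        status = "PASS"
        if config.consensus_quality_cutoff is not None:
            qual = -10.0 * np.log10(max(1.0 - post, 1e-30))
            if qual < config.consensus_quality_cutoff:
                status = "LOW_QUAL"
        calls.append(SiteCall(pu.position, pu.reference_base, genotype, post,
                              pu.depth, status))
    return calls


def _call_haploid(pileup: SitePileup, config: CallerConfig) -> SiteCall:
    errors = phred_to_error(np.array(pileup.qualities, dtype=float))
    base_idx = np.array([_BASE_INDEX[b] for b in pileup.read_bases])
    emit = np.tile((errors / 3.0)[:, None], (1, 4))
    emit[np.arange(pileup.depth), base_idx] = 1.0 - errors
    loglik = np.log(emit).sum(axis=0)
    lik = np.exp(loglik - loglik.max())
    lik /= lik.sum()
    best = int(np.argmax(lik))
    allele = BASES[best]
    if allele != pileup.reference_base and lik[best] > config.haploid_likelihood_threshold:
        return SiteCall(pileup.position, pileup.reference_base,
                        allele + allele, float(lik[best]), pileup.depth, "PASS")
    return SiteCall(pileup.position, pileup.reference_base,
                    pileup.reference_base * 2, float(lik[_BASE_INDEX[pileup.reference_base]]),
                    pileup.depth, "PASS")
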