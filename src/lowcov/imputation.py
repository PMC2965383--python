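"""Haplotype-copying genotype priors and imputation.

The prior engine models the unphased diploid target as a hidden mosaic
of the reference-panel haplotypes: the hidden state is the *pair* of
panel rows the two target haplotypes are currently copying, so the
state space has K x K entries for a K-haplotype panel. Each haplotype
switches rows independently between adjacent sites with probability
``1 − exp(−rho·d)`` (``d`` the physical distance in bp, ``rho`` the
per-bp switch intensity), moving to a uniformly chosen row; emissions
allow a per-site copy error (``mutation_rate``).

Evidence at surrounding sites is *soft*: a genotype probability
distribution per site (read conditionals, or hard array genotypes).
Given a state pair (j, k) the emitted genotype dosage is the sum of two
independently mutated copied alleles, and the emission weight is the
evidence distribution evaluated under that dosage law. The target
site's own evidence is excluded, making the output a genuine prior for
Bayesian combination with the target's reads.

Modelling the pair jointly (rather than factorizing the two haplotypes)
is what lets heterozygous neighbors constrain the mosaic: an unordered
dosage-1 observation ties the two copied rows together even though
neither haplotype is individually resolved. The forward-backward
recursion is checked elsewhere against exhaustive enumeration over all
pairs of copy paths on small panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import GenotypeDistribution
from .panel import HaplotypePanel

__all__ = [
    "ImputationParams",
    "impute_genotype_prior",
    "genotype_frequency_prior",
    "impute_untyped_sites",
]


@dataclass
class ImputationParams:
    """Free parameters of the copying prior.

    switch_rate:
        Expected copy switches per base pair per haplotype (scales the
        transition probability with distance). Default 1e-6: about one
        switch per megabase, a long-LD regime.
    mutation_rate:
        Per-site copy-error probability. Default 1e-3.
    neighborhood:
        Number of flanking informative sites used on each side of the
        target. Default 20.
    report_threshold:
        Posterior cutoff for emitting an imputed genotype; strict
        inequality (> 0.9 by default).
    """

    switch_rate: float = 1e-6
    mutation_rate: float = 1e-3
    neighborhood: int = 20
    report_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.switch_rate < 1:
            raise ValueError("switch_rate must be in (0, 1)")
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in (0, 1)")
        if self.neighborhood < 1:
            raise ValueError("neighborhood must be >= 1")
        if not 0 <= self.report_threshold <= 1:
            raise ValueError("report_threshold must be in [0, 1]")


def _pair_transition(V: np.ndarray, rho: float) -> np.ndarray:
    """One step of the pair kernel (T x T) V.

    Per haplotype T = (1−rho) I + rho/K J; the two axes of the K x K
    state mass transition independently.
    """
    K = V.shape[0]
    V = (1.0 - rho) * V + rho * V.sum(axis=0, keepdims=True) / K
    V = (1.0 - rho) * V + rho * V.sum(axis=1, keepdims=True) / K
    return V


def _dosage_probs(alt_prob: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outer-product dosage laws P(dosage g | state pair) for g = 0,1,2."""
    a = alt_prob
    P0 = np.outer(1.0 - a, 1.0 - a)
    P2 = np.outer(a, a)
    P1 = 1.0 - P0 - P2
    return P0, P1, P2


def _pair_emission(col: np.ndarray, evidence: np.ndarray, mu: float) -> np.ndarray:
    """P(soft genotype evidence | state pair) for every pair of rows."""
    a = mu + (1.0 - 2.0 * mu) * col
    P0, P1, P2 = _dosage_probs(a)
    return evidence[0] * P0 + evidence[1] * P1 + evidence[2] * P2


def _pair_genotype_posterior(
    panel: HaplotypePanel,
    target_index: int,
    evidence: dict[int, np.ndarray],
    params: ImputationParams,
) -> np.ndarray:
    """Copying-model genotype distribution (dosage 0/1/2) at a site.

    ``evidence`` maps panel site indices to 3-vectors of genotype
    probabilities; the target's own entry is ignored. Runs forward-
    backward over the pair state across up to ``neighborhood``
    informative flanking sites each side, with no emission at the
    target site itself.
    """
    K = panel.n_haplotypes
    pos = panel.positions
    mu = params.mutation_rate
    informative = sorted(j for j in evidence if j != target_index)
    left = [j for j in informative if j < target_index][-params.neighborhood:]
    right = [j for j in informative if j > target_index][:params.neighborhood]

    cols = panel.matrix.astype(float)

    alpha = np.full((K, K), 1.0 / (K * K))
    prev = None
    for j in left:
        if prev is not None:
            rho = 1.0 - np.exp(-params.switch_rate * (pos[j] - pos[prev]))
            alpha = _pair_transition(alpha, rho)
        alpha = alpha * _pair_emission(cols[:, j], evidence[j], mu)
        alpha /= alpha.sum()
        prev = j
    if prev is not None:
        rho = 1.0 - np.exp(-params.switch_rate * (pos[target_index] - pos[prev]))
        alpha = _pair_transition(alpha, rho)

    beta = np.ones((K, K))
    nxt = None
    for j in reversed(right):
        if nxt is not None:
            rho = 1.0 - np.exp(-params.switch_rate * (pos[nxt] - pos[j]))
            beta = _pair_transition(beta, rho)
        beta = beta * _pair_emission(cols[:, j], evidence[j], mu)
        beta /= beta.sum()
        nxt = j
    if nxt is not None:
        rho = 1.0 - np.exp(-params.switch_rate * (pos[nxt] - pos[target_index]))
        beta = _pair_transition(beta, rho)

    gamma = alpha * beta
    gamma /= gamma.sum()
    P0, P1, P2 = _dosage_probs(mu + (1.0 - 2.0 * mu) * cols[:, target_index])
    values = np.array([(gamma * P0).sum(), (gamma * P1).sum(),
                       (gamma * P2).sum()])
    values = np.clip(values, 0.0, None)
    return values / values.sum()


def _evidence_vector(dist: GenotypeDistribution) -> np.ndarray:
    if len(dist.space) != 3:
        raise ValueError("expected a 3-genotype panel-space distribution")
    return np.asarray(dist.values, dtype=float)


def _to_distribution(panel: HaplotypePanel, target_index: int,
                     values: np.ndarray) -> GenotypeDistribution:
    return GenotypeDistribution(int(panel.positions[target_index]),
                                panel.genotype_space(target_index),
                                values, "probability")


def impute_genotype_prior(
    target_index: int,
    neighbor_distributions: dict[int, GenotypeDistribution],
    panel: HaplotypePanel,
    params: ImputationParams | None = None,
) -> GenotypeDistribution:
    """Copying-model genotype prior at a panel site from soft neighbors.

    ``neighbor_distributions`` maps panel site indices to probability-
    kind distributions over that site's three panel genotypes. The
    target's own entry, if present, is ignored. With all neighbors
    uninformative the prior reduces to the panel Hardy-Weinberg
    distribution (up to the copy-error rate).
    """
    params = params or ImputationParams()
    if not 0 <= target_index < panel.n_sites:
        raise ValueError("target site is not a panel site")
    evidence = {j: _evidence_vector(d)
                for j, d in neighbor_distributions.items()}
    values = _pair_genotype_posterior(panel, target_index, evidence, params)
    return _to_distribution(panel, target_index, values)


def genotype_frequency_prior(
    target_index: int, panel: HaplotypePanel
) -> GenotypeDistribution:
    """Hardy-Weinberg genotype prior from the panel allele frequency."""
    if not 0 <= target_index < panel.n_sites:
        raise ValueError("target site is not a panel site")
    q = panel.alt_frequency(target_index)
    values = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    values /= values.sum()
    return _to_distribution(panel, target_index, values)


def _genotype_to_evidence(genotype: str, space: tuple[str, str, str]) -> np.ndarray:
    """Hard genotype -> one-hot dosage evidence vector."""
    key = "".join(sorted(genotype))
    try:
        idx = space.index(key)
    except ValueError:
        raise ValueError(f"genotype {genotype!r} not in site space {space}")
    v = np.zeros(3)
    v[idx] = 1.0
    return v


def impute_untyped_sites(
    typed_genotypes: dict[int, str],
    panel: HaplotypePanel,
    params: ImputationParams | None = None,
) -> pd.DataFrame:
    """Impute genotypes at panel sites missing from a typed table.

    ``typed_genotypes`` maps 1-based positions (a subset of panel sites)
    to unordered genotype strings. Typed sites pass through unchanged
    with posterior 1.0 and ``typed=True``; untyped sites are emitted only
    when the copying-model posterior exceeds ``report_threshold``
    (strictly).
    """
    params = params or ImputationParams()
    if not typed_genotypes:
        raise ValueError("typed set must be non-empty")
    evidence: dict[int, np.ndarray] = {}
    for pos, g in typed_genotypes.items():
        j = panel.site_index(pos)
        evidence[j] = _genotype_to_evidence(g, panel.genotype_space(j))
    typed_idx = set(evidence)

    rows = []
    for j in range(panel.n_sites):
        pos = int(panel.positions[j])
        if j in typed_idx:
            rows.append((pos, typed_genotypes[pos], 1.0, True))
            continue
        values = _pair_genotype_posterior(panel, j, evidence, params)
        best = int(np.argmax(values))
        post = float(values[best])
        if post > params.report_threshold:
            rows.append((pos, panel.genotype_space(j)[best], post, False))
    return pd.DataFrame(rows, columns=["position", "genotype", "posterior",
                                       "typed"])
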