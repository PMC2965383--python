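import numpy as np
import pytest

from lowcov import HaplotypePanel, sample_diploid, simulate_panel


@pytest.fixture(scope="session")
def small_panel() -> HaplotypePanel:
    """20 haplotypes x 60 sites, moderate LD."""
    return simulate_panel(20, 60, region_length=300_000,
                          recombination_intensity=2.0, seed=11)


@pytest.fixture(scope="session")
def medium_panel() -> HaplotypePanel:
    """60 haplotypes x 400 sites over 800 kb; used for calling tests."""
    return simulate_panel(60, 400, region_length=800_000,
                          recombination_intensity=2.0, seed=7)


@pytest.fixture(scope="session")
def medium_truth(medium_panel):
    return sample_diploid(medium_panel, recombination_intensity=2.0, seed=13)


@pytest.fixture()
def tiny_panel() -> HaplotypePanel:
    """Hand-written 4-haplotype, 5-site panel for enumeration oracles."""
    matrix = np.array([
        [0, 0, 1, 0, 1],
        [1, 0, 1, 1, 0],
        [0, 1, 0, 1, 1],
        [1, 1, 0, 0, 0],
    ], dtype=np.int8)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C")]
    return HaplotypePanel("chrT", np.array([100, 1100, 2600, 4100, 6100]),
                          alleles, matrix)


def enumerate_pair_prior(panel, target_index, evidence, switch_rate,
                         mutation_rate):
    """Exhaustive copy-path-pair oracle for the copying-model prior.

    Enumerates every pair of hidden copy paths over the informative
    sites plus the target, accumulating transition weights and soft-
    evidence emissions, and returns the genotype (dosage) distribution
    at the target with no emission there. Independent of the forward-
    backward implementation under test.
    """
    from itertools import product

    K = panel.n_haplotypes
    pos = panel.positions
    sites = sorted(set(j for j in evidence if j != target_index) | {target_index})
    n = len(sites)
    t_local = sites.index(target_index)
    mu = mutation_rate

    # transition matrices between consecutive local sites
    trans = []
    for a, b in zip(sites[:-1], sites[1:]):
        rho = 1.0 - np.exp(-switch_rate * (pos[b] - pos[a]))
        T = np.full((K, K), rho / K) + (1.0 - rho) * np.eye(K)
        trans.append(T)

    paths = np.array(list(product(range(K), repeat=n)))  # K^n x n
    w = np.full(len(paths), 1.0 / K)
    for step, T in enumerate(trans):
        w *= T[paths[:, step], paths[:, step + 1]]

    # per-path per-site probability the copied (mutated) allele is ALT
    alt = mu + (1.0 - 2.0 * mu) * panel.matrix[paths, np.arange(n)[None, :]]

    total = np.outer(w, w)
    for s, j in enumerate(sites):
        if j == target_index:
            continue
        a = alt[:, s]
        d = evidence[j]
        P0 = np.outer(1 - a, 1 - a)
        P2 = np.outer(a, a)
        total *= d[0] * P0 + d[1] * (1 - P0 - P2) + d[2] * P2

    a = alt[:, t_local]
    P0 = np.outer(1 - a, 1 - a)
    P2 = np.outer(a, a)
    values = np.array([(total * P0).sum(), (total * (1 - P0 - P2)).sum(),
                       (total * P2).sum()])
    return values / values.sum()


def tajima_oracle(matrix):
    """Straight-line Tajima's D with explicit pairwise difference loops."""
    m = np.asarray(matrix)
    n = m.shape[0]
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int((m[i] != m[j]).sum()))
    pi = float(np.mean(diffs))
    counts = m.sum(axis=0)
    S = int(((counts > 0) & (counts < n)).sum())
    if S == 0:
        return S, pi, None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return S, pi, (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def fisher_upper_tail_oracle(table):
    """One-sided Fisher p by margin-fixed enumeration (exact arithmetic)."""
    from math import comb

    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    num = sum(comb(c1, k) * comb(n - c1, r1 - k) for k in range(a, hi + 1))
    den = sum(comb(c1, k) * comb(n - c1, r1 - k) for k in range(lo, hi + 1))
    return num / den
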