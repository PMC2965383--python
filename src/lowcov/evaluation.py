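"""Depth titration and genotype-accuracy evaluation.

Reproduces the accuracy-vs-depth experiment: thin pileups by random
read removal, call genotypes under each prior mode, and compare against
truth (or an array-like table) via concordance, positive predictive
value and the heterozygote-undercall rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import MODES, VariantCall, call_with_prior
from .imputation import ImputationParams
from .likelihood import CallerConfig, SitePileup
from .panel import HaplotypePanel

__all__ = [
    "ConcordanceReport",
    "downsample_pileups",
    "genotype_concordance",
    "accuracy_vs_depth_curve",
]


@dataclass
class ConcordanceReport:
    """Agreement between unfiltered calls and reference genotypes.

    ``positive_predictive_value`` is the fraction of called variants
    (non-reference-homozygote genotypes) that are true variants;
    ``het_undercall_rate`` the fraction of true heterozygotes called
    homozygous. ``n_no_call`` counts shared sites excluded by filters.
    """

    n_compared: int
    n_match: int
    n_no_call: int
    positive_predictive_value: float | None
    het_undercall_rate: float | None
    stratification: pd.DataFrame | None = None

    @property
    def concordance(self) -> float:
        return self.n_match / self.n_compared


def downsample_pileups(
    pileups: list[SitePileup], target_mean_depth: float, seed: int = 0
) -> list[SitePileup]:
    """Randomly remove reads to reach a target mean depth.

    Each read is kept independently with probability
    ``target / current`` (binomial thinning), so thinning to d1 then d2
    is distributionally identical to thinning straight to d2.
    """
    depths = np.array([p.depth for p in pileups], dtype=float)
    current = depths.mean() if len(depths) else 0.0
    if target_mean_depth > current:
        raise ValueError(
            f"target depth {target_mean_depth} exceeds current mean {current:.3f}")
    keep_p = 0.0 if current == 0 else target_mean_depth / current
    rng = np.random.default_rng(seed)
    out = []
    for pu in pileups:
        keep = rng.random(pu.depth) < keep_p
        out.append(SitePileup(
            pu.position, pu.reference_base,
            [b for b, k in zip(pu.read_bases, keep) if k],
            [q for q, k in zip(pu.qualities, keep) if k],
        ))
    return out


def _is_variant(genotype: str, reference_base: str) -> bool:
    return genotype != reference_base * 2


def _is_het(genotype: str) -> bool:
    return genotype[0] != genotype[1]


def genotype_concordance(
    calls: list[VariantCall],
    reference_genotypes: dict[int, str],
    reference_bases: dict[int, str] | None = None,
    depth_bins: list[float] | None = None,
) -> ConcordanceReport:
    """Compare unfiltered calls to a position->genotype reference table.

    Only unfiltered (PASS) calls at shared positions enter the
    denominator; filtered or missing calls at shared positions are
    counted as no-calls. PPV requires ``reference_bases`` (position ->
    reference allele) to define what a "variant" call is.
    """
    shared = [c for c in calls if c.position in reference_genotypes]
    if not shared:
        raise ValueError("no overlap between calls and reference genotypes")
    compared = [c for c in shared if c.filter_status == "PASS"]
    n_no_call = len(shared) - len(compared)
    if not compared:
        raise ValueError("all shared sites were filtered")

    matches = np.array([
        "".join(sorted(c.genotype)) == "".join(sorted(reference_genotypes[c.position]))
        for c in compared
    ])

    ppv = None
    if reference_bases is not None:
        called_var = [c for c in compared
                      if _is_variant(c.genotype, reference_bases[c.position])]
        if called_var:
            true_var = sum(
                _is_variant(reference_genotypes[c.position],
                            reference_bases[c.position])
                for c in called_var)
            ppv = true_var / len(called_var)

    true_hets = [c for c in compared if _is_het(reference_genotypes[c.position])]
    het_undercall = None
    if true_hets:
        het_undercall = sum(not _is_het(c.genotype) for c in true_hets) / len(true_hets)

    strat = None
    if depth_bins is not None:
        depths = np.array([c.depth for c in compared])
        labels = np.digitize(depths, depth_bins)
        strat = pd.DataFrame({
            "depth_bin": labels, "match": matches}).groupby("depth_bin").agg(
                n_compared=("match", "size"), n_match=("match", "sum"))
        strat["concordance"] = strat.n_match / strat.n_compared

    return ConcordanceReport(len(compared), int(matches.sum()), n_no_call,
                             ppv, het_undercall, strat)


def accuracy_vs_depth_curve(
    pileups: list[SitePileup],
    panel: HaplotypePanel,
    truth_genotypes: dict[int, str],
    modes: list[str] | None = None,
    depths: list[float] | None = None,
    replicates: int = 5,
    seed: int = 0,
    caller_config: CallerConfig | None = None,
    imputation_params: ImputationParams | None = None,
) -> pd.DataFrame:
    """Concordance for every (mode, depth, replicate) cell.

    Each replicate thins the source pileups to the target depth with a
    fresh seed, calls under each mode, and scores concordance with the
    truth over unfiltered sites. Returns a tidy DataFrame with columns
    mode, depth, replicate, realized_depth, concordance, n_compared.
    """
    modes = list(modes) if modes is not None else list(MODES)
    depths = list(depths) if depths is not None else [1, 2, 2.4, 4, 6, 8]
    if not modes or not depths:
        raise ValueError("modes and depths must be non-empty")
    unknown = set(modes) - set(MODES)
    if unknown:
        raise ValueError(f"unknown modes: {sorted(unknown)}")
    source_mean = np.mean([p.depth for p in pileups])
    if max(depths) > source_mean:
        raise ValueError("requested depth exceeds the source mean depth")

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        for depth in depths:
            thin_seed = int(rng.integers(2**31))
            thinned = downsample_pileups(pileups, depth, seed=thin_seed)
            realized = float(np.mean([p.depth for p in thinned]))
            for mode in modes:
                calls = call_with_prior(thinned, panel, mode,
                                        caller_config, imputation_params)
                report = genotype_concordance(calls, truth_genotypes)
                rows.append((mode, depth, rep, realized, report.concordance,
                             report.n_compared))
    return pd.DataFrame(rows, columns=[
        "mode", "depth", "replicate", "realized_depth", "concordance",
        "n_compared"])


def summarize_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of concordance per (mode, depth)."""
    return (curve.groupby(["mode", "depth"])["concordance"]
            .agg(["mean", "std"]).reset_index())


def plot_curve(curve: pd.DataFrame, path: str) -> None:
    """Render the accuracy-vs-depth figure (one series per mode)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize_curve(curve)
    fig, ax = plt.subplots(figsize=(6, 4))
    for mode, grp in summary.groupby("mode"):
        ax.errorbar(grp.depth, 100 * grp["mean"], yerr=100 * grp["std"].fillna(0),
                    marker="o", label=mode)
    ax.set_xlabel("mean read depth (X)")
    ax.set_ylabel("% genotypes matching truth")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
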