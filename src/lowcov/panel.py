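"""Phased haplotype reference panels.

A :class:`HaplotypePanel` is the LD backbone of the package: a binary
allele matrix over ordered biallelic sites, together with 1-based
physical positions and per-site (reference, alternate) allele symbols.
It backs simulation, haplotype-copying priors, Hardy-Weinberg priors
and pairwise r².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["HaplotypePanel", "ld_r2"]


@dataclass
class HaplotypePanel:
    """Phased binary allele matrix over ordered biallelic sites.

    Parameters
    ----------
    chromosome_label:
        Name of the chromosome the panel spans.
    positions:
        1-based physical coordinates, strictly increasing.
    alleles:
        Per-site ``(reference, alternate)`` allele symbols.
    matrix:
        ``n_haplotypes x n_sites`` array with entries in {0, 1}; 0 codes
        the reference allele, 1 the alternate.
    """

    chromosome_label: str
    positions: np.ndarray
    alleles: list[tuple[str, str]]
    matrix: np.ndarray
    _freq_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("matrix column count must match number of positions")
        if len(self.alleles) != len(self.positions):
            raise ValueError("alleles must match number of positions")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        counts = self.matrix.sum(axis=0)
        if np.any(counts == 0) or np.any(counts == self.n_haplotypes):
            raise ValueError("every site must be polymorphic in the panel")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def alt_frequency(self, site_index: int) -> float:
        """Alternate-allele frequency at a site."""
        return float(self.matrix[:, site_index].mean())

    def alt_frequencies(self) -> np.ndarray:
        if self._freq_cache is None:
            self._freq_cache = self.matrix.mean(axis=0)
        return self._freq_cache

    def site_index(self, position: int) -> int:
        """Index of the site at a 1-based position; KeyError if absent."""
        i = int(np.searchsorted(self.positions, position))
        if i >= self.n_sites or self.positions[i] != position:
            raise KeyError(f"position {position} is not a panel site")
        return i

    def genotype_space(self, site_index: int) -> tuple[str, str, str]:
        """Unordered genotypes (ref/ref, ref/alt, alt/alt) at a site."""
        ref, alt = self.alleles[site_index]
        return ("".join(sorted(ref + ref)), "".join(sorted(ref + alt)),
                "".join(sorted(alt + alt)))

    # -- hap/legend text interchange ------------------------------------

    def write(self, hap_path: str | Path, legend_path: str | Path) -> None:
        """Write hap/legend text: one allele column per haplotype, legend
        with id, position, allele0, allele1."""
        with open(hap_path, "w") as fh:
            for j in range(self.n_sites):
                fh.write(" ".join(str(int(v)) for v in self.matrix[:, j]) + "\n")
        with open(legend_path, "w") as fh:
            fh.write("id position allele0 allele1\n")
            for j, pos in enumerate(self.positions):
                ref, alt = self.alleles[j]
                fh.write(f"{self.chromosome_label}:{pos} {pos} {ref} {alt}\n")

    @classmethod
    def read(cls, hap_path: str | Path, legend_path: str | Path,
             chromosome_label: str | None = None) -> "HaplotypePanel":
        positions: list[int] = []
        alleles: list[tuple[str, str]] = []
        label = chromosome_label
        with open(legend_path) as fh:
            next(fh)  # header
            for line in fh:
                ident, pos, a0, a1 = line.split()
                positions.append(int(pos))
                alleles.append((a0, a1))
                if label is None and ":" in ident:
                    label = ident.split(":")[0]
        rows = []
        with open(hap_path) as fh:
            for line in fh:
                rows.append([int(v) for v in line.split()])
        matrix = np.array(rows, dtype=np.int8).T  # rows are sites on disk
        return cls(label or "chr1", np.array(positions), alleles, matrix)


def ld_r2(panel: HaplotypePanel, site_a: int, site_b: int) -> float:
    """Squared haplotype-count correlation r² between two panel sites.

    r² = (p_ab − p_a p_b)² / (p_a(1−p_a) p_b(1−p_b)) from phased counts.
    Raises ``ValueError`` for a monomorphic site (undefined LD); the panel
    invariant normally precludes this, but sliced matrices may violate it.
    """
    a = panel.matrix[:, site_a].astype(float)
    b = panel.matrix[:, site_b].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("LD is undefined at a monomorphic site")
    pab = (a * b).mean()
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))
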