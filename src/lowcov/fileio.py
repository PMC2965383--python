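"""Plain-text interchange: pileup TSV, call tables, genotype tables, BED.

All coordinates are 1-based inclusive in memory; BED output converts to
0-based half-open on write.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .calling import VariantCall
from .likelihood import SitePileup

__all__ = [
    "write_pileups", "read_pileups",
    "write_calls", "read_calls",
    "write_genotype_table", "read_genotype_table",
    "write_bed", "read_bed",
]


def write_pileups(pileups: list[SitePileup], path: str | Path) -> None:
    """position, ref, bases (string), qualities (comma-separated)."""
    with open(path, "w") as fh:
        fh.write("position\tref\tbases\tqualities\n")
        for p in pileups:
            fh.write(f"{p.position}\t{p.reference_base}\t"
                     f"{''.join(p.read_bases)}\t"
                     f"{','.join(map(str, p.qualities))}\n")


def read_pileups(path: str | Path) -> list[SitePileup]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            pos, ref, bases, quals = (line.rstrip("\n").split("\t") + [""])[:4]
            out.append(SitePileup(
                int(pos), ref, list(bases),
                [int(q) for q in quals.split(",") if q]))
    return out


def write_calls(calls: list[VariantCall], path: str | Path,
                reference_bases: dict[int, str] | None = None) -> None:
    """Minimal VCF-like TSV: position, ref, genotype, posterior, mode, filter."""
    with open(path, "w") as fh:
        fh.write("position\tref\tgenotype\tposterior\tmode\tfilter\n")
        for c in calls:
            ref = (reference_bases or {}).get(c.position, ".")
            post = "." if c.posterior is None else f"{c.posterior:.6g}"
            geno = c.genotype or "."
            fh.write(f"{c.position}\t{ref}\t{geno}\t{post}\t{c.mode}\t"
                     f"{c.filter_status}\n")


def read_calls(path: str | Path) -> list[VariantCall]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            pos, _ref, geno, post, mode, filt = line.rstrip("\n").split("\t")
            out.append(VariantCall(
                int(pos), None if geno == "." else geno,
                None if post == "." else float(post), mode, filt))
    return out


def write_genotype_table(table: dict[int, str], path: str | Path) -> None:
    """Tab-separated position, genotype."""
    with open(path, "w") as fh:
        fh.write("position\tgenotype\n")
        for pos in sorted(table):
            fh.write(f"{pos}\t{table[pos]}\n")


def read_genotype_table(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.position.astype(int), df.genotype))


def write_bed(regions: list[tuple[str, int, int]], path: str | Path) -> None:
    """1-based inclusive regions -> 0-based half-open BED lines."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED lines -> 1-based inclusive (chromosome, start, end)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out
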