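"""Sliding haplotype windows over a multi-parent SNP matrix.

A window is a contiguous run of polymorphic sites on one chromosome; it
partitions the haploid parents into local haplotypes by exact equality of
their allele-code vectors over the span. The scan enumerates, for each SNP
start, the shortest window of at least ``min_snps`` sites whose partition
has an admissible number of haplotypes and at least two haplotypes carried
by ``min_carriers`` or more parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ioformats import VariantTable


@dataclass
class WindowConfig:
    """Admissibility bounds for haplotype windows.

    Defaults follow the scan design this package implements: 3-10 SNPs,
    2-9 haplotypes per window, and haplotypes analyzable only when carried
    by at least 3 parents. ``max_haplotypes`` is a soft bound (set it to a
    large value to lift it).
    """

    min_snps: int = 3
    max_snps: int = 10
    min_haplotypes: int = 2
    max_haplotypes: int = 9
    min_carriers: int = 3

    def __post_init__(self):
        if not (2 <= self.min_snps <= self.max_snps):
            raise ValueError("need 2 <= min_snps <= max_snps")
        if self.min_haplotypes < 2:
            raise ValueError("need min_haplotypes >= 2")
        if self.min_carriers < 1:
            raise ValueError("need min_carriers >= 1")


@dataclass
class HaplotypeWindow:
    """A called window: span, per-parent labels, and carrier counts.

    Labels are dense integers ordered by descending carrier count (label 0 =
    most frequent haplotype; ties broken by first occurrence across the
    parent order).
    """

    chrom: str
    start_idx: int  # global site index, inclusive
    end_idx: int    # global site index, inclusive
    start_pos: int
    end_pos: int
    parents: tuple
    labels: np.ndarray      # (n_parents,) int
    carriers: np.ndarray    # (n_haplotypes,) int

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def n_haplotypes(self) -> int:
        return len(self.carriers)

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start_pos}-{self.end_pos}"

    def label_of(self, parent: str) -> int:
        return int(self.labels[self.parents.index(parent)])


def call_haplotypes(vt: VariantTable, start_idx: int, end_idx: int):
    """Partition parents by identical allele vectors over an inclusive span.

    Returns ``(labels, carriers)``; two parents share a label iff their
    allele-code vectors over the span are identical. Raises if the span
    crosses a chromosome boundary.
    """
    if not (0 <= start_idx <= end_idx < vt.n_sites):
        raise ValueError("window span outside the table")
    if vt.chrom[start_idx] != vt.chrom[end_idx]:
        raise ValueError("window span crosses chromosomes")
    sub = vt.alleles[start_idx:end_idx + 1]
    first_seen: dict = {}
    raw = np.empty(vt.n_parents, dtype=np.int64)
    for j in range(vt.n_parents):
        key = sub[:, j].tobytes()
        raw[j] = first_seen.setdefault(key, len(first_seen))
    counts = np.bincount(raw, minlength=len(first_seen))
    order = sorted(range(len(counts)), key=lambda h: (-counts[h], h))
    rank = np.empty(len(counts), dtype=np.int64)
    rank[order] = np.arange(len(counts))
    return rank[raw], counts[order]


def window_at(vt: VariantTable, start_idx: int, end_idx: int) -> HaplotypeWindow:
    labels, carriers = call_haplotypes(vt, start_idx, end_idx)
    return HaplotypeWindow(
        chrom=vt.chrom[start_idx],
        start_idx=start_idx,
        end_idx=end_idx,
        start_pos=int(vt.pos[start_idx]),
        end_pos=int(vt.pos[end_idx]),
        parents=vt.parents,
        labels=labels,
        carriers=carriers,
    )


def _admissible(carriers: np.ndarray, cfg: WindowConfig) -> bool:
    k = len(carriers)
    if not (cfg.min_haplotypes <= k <= cfg.max_haplotypes):
        return False
    return int((carriers >= cfg.min_carriers).sum()) >= 2


def enumerate_windows(vt: VariantTable, cfg: WindowConfig | None = None) -> list:
    """Shortest admissible window per SNP start, sliding one SNP at a time.

    For each start index the window grows from ``min_snps`` up to
    ``max_snps`` sites and the first admissible span is emitted; starts with
    no admissible window are skipped. Windows may overlap; exact duplicate
    spans are emitted once.
    """
    cfg = cfg or WindowConfig()
    out, seen = [], set()
    for chrom in vt.chroms:
        lo, hi = vt.chrom_bounds(chrom)
        for start in range(lo, hi):
            for length in range(cfg.min_snps, cfg.max_snps + 1):
                end = start + length - 1
                if end >= hi:
                    break
                labels, carriers = call_haplotypes(vt, start, end)
                if _admissible(carriers, cfg):
                    key = (chrom, start, end)
                    if key not in seen:
                        seen.add(key)
                        out.append(HaplotypeWindow(
                            chrom=chrom, start_idx=start, end_idx=end,
                            start_pos=int(vt.pos[start]), end_pos=int(vt.pos[end]),
                            parents=vt.parents, labels=labels, carriers=carriers,
                        ))
                    break
    return out


def summarize_windows(windows: list) -> pd.DataFrame:
    """min/median/mean/max of n_snps, n_haplotypes and bp span."""
    if not windows:
        raise ValueError("no windows to summarize")
    metrics = {
        "n_snps": np.array([w.n_snps for w in windows], dtype=float),
        "n_haplotypes": np.array([w.n_haplotypes for w in windows], dtype=float),
        "span_bp": np.array([w.span_bp for w in windows], dtype=float),
    }
    rows = {
        name: {"min": v.min(), "median": float(np.median(v)), "mean": v.mean(), "max": v.max()}
        for name, v in metrics.items()
    }
    return pd.DataFrame(rows).T[["min", "median", "mean", "max"]]


def write_windows_bed(windows: list, path) -> None:
    """BED-style TSV (0-based half-open) for genome-browser use."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\twindow_id\tn_snps\tn_haplotypes\n")
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start_pos - 1}\t{w.end_pos}\t{w.window_id}"
                f"\t{w.n_snps}\t{w.n_haplotypes}\n"
            )
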