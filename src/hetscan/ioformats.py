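"""Genotype / phenotype / result table formats and phenotype normalization.

The central containers are deliberately thin:

* :class:`VariantTable` — per-site allele codes of N haploid parents with
  ordered 1-based genomic positions (TSV or haploid-GT VCF on disk).
* phenotype tables — plain :class:`pandas.DataFrame` objects with columns
  ``strain, parent1, parent2, condition, plate, replicate, dt[, log2dt]``,
  one row per replicate measurement of doubling time (DT, hours).
* cross designs — DataFrames with columns ``diploid_id, parent1, parent2``.

Doubling times are normalized for plate effects against a reference strain
measured on every plate (multiplicative ratio-to-global-mean model) and
log2-transformed for between-strain statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["strain", "parent1", "parent2", "condition", "plate", "replicate", "dt"]
DESIGN_COLUMNS = ["diploid_id", "parent1", "parent2"]

SCAN_RESULT_COLUMNS = [
    "window_id", "chrom", "start_pos", "end_pos", "n_snps", "n_haplotypes",
    "hap1", "hap2", "n_hom1", "n_het", "n_hom2",
    "mean_hom1", "mean_het", "mean_hom2",
    "p_het_hom1", "p_het_hom2", "p_summary", "q_value", "classification",
]


class FormatError(ValueError):
    """Raised for malformed input tables."""


@dataclass
class VariantTable:
    """Allele codes of haploid parents at ordered polymorphic sites.

    Parameters
    ----------
    chrom : array of str, one per site
    pos : array of int, 1-based coordinates, strictly increasing per chromosome
    alleles : int array of shape (n_sites, n_parents), codes >= 0, no missing
    parents : ordered parent identifiers
    n_dropped : count of sites dropped while loading (missing genotypes)
    """

    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray
    parents: tuple
    n_dropped: int = 0
    _chrom_bounds: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int16)
        self.parents = tuple(str(p) for p in self.parents)
        if self.alleles.ndim != 2 or self.alleles.shape != (self.pos.size, len(self.parents)):
            raise FormatError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{self.pos.size} sites x {len(self.parents)} parents"
            )
        if len(self.parents) < 2:
            raise FormatError("a VariantTable needs at least 2 parents")
        if len(set(self.parents)) != len(self.parents):
            raise FormatError("duplicate parent identifiers")
        if self.alleles.size and self.alleles.min() < 0:
            raise FormatError("negative allele codes (missing data must be dropped on load)")
        self._chrom_bounds = {}
        start = 0
        for i in range(1, self.n_sites + 1):
            if i == self.n_sites or self.chrom[i] != self.chrom[start]:
                c = self.chrom[start]
                if c in self._chrom_bounds:
                    raise FormatError(f"chromosome {c} appears in non-contiguous blocks")
                p = self.pos[start:i]
                if np.any(np.diff(p) <= 0):
                    raise FormatError(f"positions not strictly increasing on {c}")
                self._chrom_bounds[c] = (start, i)
                start = i

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def chroms(self) -> list:
        return list(self._chrom_bounds)

    def chrom_bounds(self, chrom) -> tuple:
        """Half-open global site-index range ``(lo, hi)`` of one chromosome."""
        return self._chrom_bounds[chrom]

    def site_index(self, chrom, pos) -> int:
        lo, hi = self._chrom_bounds[chrom]
        i = lo + np.searchsorted(self.pos[lo:hi], pos)
        if i >= hi or self.pos[i] != pos:
            raise KeyError(f"no site at {chrom}:{pos}")
        return int(i)

    def parent_column(self, parent) -> np.ndarray:
        return self.alleles[:, self.parents.index(parent)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for j, p in enumerate(self.parents):
            df[p] = self.alleles[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_dropped: int = 0) -> "VariantTable":
        if list(df.columns[:2]) != ["chrom", "pos"]:
            raise FormatError("first two columns must be 'chrom' and 'pos'")
        parents = tuple(df.columns[2:])
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            alleles=df[list(parents)].to_numpy(dtype=np.int16),
            parents=parents,
            n_dropped=n_dropped,
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.parents == other.parents
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.alleles, other.alleles)
        )


# ---------------------------------------------------------------------------
# variant readers / writers
# ---------------------------------------------------------------------------

def read_variants(path, format: str = "tsv") -> VariantTable:
    """Load a :class:`VariantTable` from TSV or haploid-GT VCF.

    Sites with any missing genotype are dropped and counted in
    ``VariantTable.n_dropped``. Diploid genotypes in a VCF are an error:
    the parents of the design are haploid (or fully homozygous) strains.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        n_dropped = int(df.iloc[:, 2:].isna().any(axis=1).sum())
        if n_dropped:
            df = df.dropna(subset=df.columns[2:])
            logger.info("read_variants: dropped %d sites with missing codes", n_dropped)
        return VariantTable.from_frame(df, n_dropped=n_dropped)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown variant format {format!r}")


def _read_vcf(path) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    parents = tuple(vcf.samples)
    chroms, poss, rows = [], [], []
    n_dropped = 0
    for var in vcf:
        gts = var.genotypes  # [allele, (allele,) phased] per sample
        codes = []
        for g in gts:
            if len(g) > 2:  # two allele fields -> diploid call
                raise FormatError(
                    f"diploid genotype at {var.CHROM}:{var.POS}; haploid parents expected"
                )
            codes.append(g[0])
        if any(c < 0 for c in codes):
            n_dropped += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(codes)
    vcf.close()
    if n_dropped:
        logger.info("read_variants: dropped %d VCF sites with missing GTs", n_dropped)
    return VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        alleles=np.array(rows, dtype=np.int16).reshape(len(rows), len(parents)),
        parents=parents,
        n_dropped=n_dropped,
    )


def write_variants(vt: VariantTable, path, format: str = "tsv") -> None:
    """Write a VariantTable as TSV, or as a minimal haploid-GT VCF."""
    if format == "tsv":
        vt.to_frame().to_csv(path, sep="\t", index=False)
        return
    if format == "vcf":
        _write_vcf(vt, path)
        return
    raise ValueError(f"unknown variant format {format!r}")


def _allele_base(code: int) -> str:
    # synthetic nucleotide for an allele code; codes are abstract labels
    bases = ["A", "C", "G", "T"]
    return bases[code] if code < 4 else "A" + "C" * (code - 3)


def _write_vcf(vt: VariantTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in vt.chroms:
            lo, hi = vt.chrom_bounds(c)
            fh.write(f"##contig=<ID={c},length={int(vt.pos[hi - 1]) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vt.parents) + "\n")
        for i in range(vt.n_sites):
            codes = vt.alleles[i]
            n_all = int(codes.max()) + 1
            alt = ",".join(_allele_base(k) for k in range(1, n_all)) or "."
            gts = "\t".join(str(int(c)) for c in codes)
            fh.write(
                f"{vt.chrom[i]}\t{int(vt.pos[i])}\t.\t{_allele_base(0)}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def validate_phenotypes(ph: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in ph.columns]
    if missing:
        raise FormatError(f"phenotype table missing columns {missing}")
    if (ph["dt"] <= 0).any():
        raise FormatError("non-positive DT values")
    key = ph[["strain", "condition", "plate", "replicate"]]
    if key.duplicated().any():
        raise FormatError("duplicate (strain, condition, plate, replicate) rows")
    return ph


def read_phenotypes(path) -> pd.DataFrame:
    ph = pd.read_csv(path, comment="#", keep_default_na=False, na_values=[])
    ph["dt"] = ph["dt"].astype(float)
    if "log2dt" in ph.columns:
        ph["log2dt"] = ph["log2dt"].astype(float)
    return validate_phenotypes(ph)


def write_phenotypes(ph: pd.DataFrame, path, header_comment: str | None = None) -> None:
    validate_phenotypes(ph)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        ph.to_csv(fh, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cross design missing columns {missing}")
    return df


def write_design(design: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        design.to_csv(fh, index=False)


def normalize_plates(ph: pd.DataFrame, reference_strain) -> pd.DataFrame:
    """Remove multiplicative plate effects using a shared reference strain.

    Within each condition, every DT on plate *p* is multiplied by
    ``mean(reference DT over all plates) / mean(reference DT on plate p)``,
    so the reference strain's per-plate means become equal. Idempotent, and
    preserves within-plate DT ratios between strains exactly.
    """
    validate_phenotypes(ph)
    out = ph.copy()
    for cond, sub in ph.groupby("condition", sort=False):
        ref = sub[sub["strain"] == reference_strain]
        plates = sub["plate"].unique()
        ref_plates = set(ref["plate"])
        missing = [p for p in plates if p not in ref_plates]
        if missing:
            raise FormatError(
                f"reference strain {reference_strain!r} absent from plate(s) "
                f"{missing} in condition {cond!r}"
            )
        global_mean = ref["dt"].mean()
        plate_means = ref.groupby("plate")["dt"].mean()
        factors = global_mean / plate_means
        idx = sub.index
        out.loc[idx, "dt"] = sub["dt"].to_numpy() * factors[sub["plate"]].to_numpy()
    if "log2dt" in out.columns:
        out["log2dt"] = np.log2(out["dt"])
    return out


def log2_transform(ph: pd.DataFrame) -> pd.DataFrame:
    """Populate a ``log2dt`` column (DT preserved). Errors on DT <= 0."""
    validate_phenotypes(ph)
    out = ph.copy()
    out["log2dt"] = np.log2(out["dt"].to_numpy())
    return out


def strain_means(ph: pd.DataFrame, condition=None) -> pd.Series:
    """Replicate-mean DT per strain (optionally within one condition)."""
    sub = ph if condition is None else ph[ph["condition"] == condition]
    if sub.empty:
        raise FormatError(f"no phenotype rows for condition {condition!r}")
    return sub.groupby("strain")["dt"].mean()


# ---------------------------------------------------------------------------
# scan results
# ---------------------------------------------------------------------------

def write_scan_results(results, path, header_comment: str | None = None) -> None:
    """Write window test results (objects or a DataFrame) as a 1-based TSV."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        if not len(results):
            raise ValueError("empty result list")
        df = pd.DataFrame([r.as_record() for r in results])
    df = df[[c for c in SCAN_RESULT_COLUMNS if c in df.columns]
            + [c for c in df.columns if c not in SCAN_RESULT_COLUMNS]]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_scan_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
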