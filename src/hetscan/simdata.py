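"""Synthetic multi-parent genomes, crosses, and doubling-time phenotypes.

Emulates the study designs of a yeast diallel heterosis experiment with a
known, planted genetic architecture:

* haploid parents built as mosaics of a small number of founder haplotypes
  (geometric block lengths), so that short genomic windows carry several
  distinct local haplotypes;
* the complete diallel of unordered parental pairs (16 parents -> 120 hybrids);
* tetrad meiosis with exact 2:2 segregation and Poisson crossovers,
  producing F1 haploid spores, BC1 and F2 diploids;
* log2 doubling-time (log2DT) phenotypes with per-genotype locus effects,
  optional het-x-het synergistic interaction terms, multiplicative plate
  effects and Gaussian noise. Smaller DT always means faster growth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ioformats import PHENOTYPE_COLUMNS, VariantTable


class SimulationError(ValueError):
    """Raised for invalid simulation parameters or designs."""


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass
class HaploidGenome:
    """One haploid strain: allele codes aligned with a VariantTable."""

    name: str
    alleles: np.ndarray
    vt: VariantTable

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int16)
        if self.alleles.shape != (self.vt.n_sites,):
            raise SimulationError("haploid genome does not match its VariantTable")

    def genotype_at(self, i: int) -> tuple:
        a = int(self.alleles[i])
        return (a, a)


@dataclass
class Diploid:
    """A diploid strain: the union of two haploid genomes."""

    id: str
    hap1: HaploidGenome
    hap2: HaploidGenome
    parent1: str = ""
    parent2: str = ""

    def __post_init__(self):
        if self.hap1.vt is not self.hap2.vt and not self.hap1.vt.equals(self.hap2.vt):
            raise SimulationError("diploid haplotypes defined on different VariantTables")

    @property
    def vt(self) -> VariantTable:
        return self.hap1.vt

    def genotype_at(self, i: int) -> tuple:
        return (int(self.hap1.alleles[i]), int(self.hap2.alleles[i]))


@dataclass
class SegregantPopulation:
    """F1/BC1/F2 individuals genotyped against two founder parents."""

    pop_type: str  # F1_haploid | BC1 | F2
    individuals: list
    founders: tuple = None  # (HaploidGenome, HaploidGenome) of the original cross

    def genotype_tokens(self, chrom, pos) -> np.ndarray:
        """Per-individual HOM1/HET/HOM2 tokens at one locus.

        HOM1 means homozygous (or hemizygous, for haploids) for the allele of
        the first founder parent. The locus must distinguish the founders.
        """
        if self.founders is None:
            raise SimulationError("population has no founder genomes")
        vt = self.founders[0].vt
        i = vt.site_index(chrom, pos)
        a1 = int(self.founders[0].alleles[i])
        a2 = int(self.founders[1].alleles[i])
        if a1 == a2:
            raise SimulationError(f"locus {chrom}:{pos} does not segregate between founders")
        toks = []
        for ind in self.individuals:
            g = ind.genotype_at(i)
            n1 = (g[0] == a1) + (g[1] == a1)
            n2 = (g[0] == a2) + (g[1] == a2)
            if n1 == 2:
                toks.append("HOM1")
            elif n2 == 2:
                toks.append("HOM2")
            elif n1 == 1 and n2 == 1:
                toks.append("HET")
            else:
                raise SimulationError(f"non-parental allele at {chrom}:{pos}")
        return np.array(toks, dtype=object)


# ---------------------------------------------------------------------------
# trait architecture
# ---------------------------------------------------------------------------

@dataclass
class TraitLocus:
    """Genotype-specific effects (log2DT units) of one biallelic locus.

    ``allele_a`` is the reference allele code; genotypes with two, one or
    zero copies of it receive ``effect_aa``, ``effect_ab``, ``effect_bb``.
    An over-dominant locus (faster heterozygote) has
    ``effect_ab < min(effect_aa, effect_bb)``.
    """

    chrom: str
    pos: int
    effect_aa: float
    effect_ab: float
    effect_bb: float
    allele_a: int = 0

    def effect(self, genotype: tuple) -> float:
        n_a = (genotype[0] == self.allele_a) + (genotype[1] == self.allele_a)
        if n_a == 2:
            return self.effect_aa
        if n_a == 1:
            return self.effect_ab
        return self.effect_bb

    def is_het(self, genotype: tuple) -> bool:
        return ((genotype[0] == self.allele_a) + (genotype[1] == self.allele_a)) == 1


@dataclass
class TraitArchitecture:
    """Planted genetic architecture of the log2DT trait.

    log2DT = baseline + sum of locus effects + sum of het-x-het interaction
    terms gamma + N(0, noise_sd^2); DT = 2**log2DT x plate factor.
    Negative effects and negative gamma mean faster growth.
    """

    baseline_log2dt: float = 1.5
    loci: list = field(default_factory=list)
    epistatic_pairs: list = field(default_factory=list)  # (i, j, gamma) indices into loci
    noise_sd: float = 0.05
    plate_effects: dict = field(default_factory=dict)  # plate id -> factor > 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        for k, f in self.plate_effects.items():
            if f <= 0:
                raise SimulationError(f"plate factor for {k!r} must be > 0")
        for i, j, _ in self.epistatic_pairs:
            if not (0 <= i < len(self.loci) and 0 <= j < len(self.loci) and i != j):
                raise SimulationError("epistatic pair indexes invalid loci")


@dataclass
class RecombinationConfig:
    """Meiosis model: Poisson crossovers per chromosome, no interference."""

    crossovers_per_chrom_mean: float = 1.0
    interference: None = None  # reserved
    seed: int = 0

    def __post_init__(self):
        if self.crossovers_per_chrom_mean < 0:
            raise SimulationError("crossover mean must be >= 0")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_parents(
    n_parents: int,
    n_chrom: int,
    snps_per_chrom: int,
    block_len_mean: int = 5,
    n_founder_haplotypes: int = 4,
    seed: int = 0,
) -> VariantTable:
    """Simulate divergent haploid parents as founder-haplotype mosaics.

    Each site is biallelic and polymorphic among the founders; each parent
    is a mosaic of founder haplotypes with geometric block lengths (mean
    ``block_len_mean`` SNPs), so short windows carry between 2 and
    ``n_founder_haplotypes`` distinct local haplotypes. Positions are
    strictly increasing with random inter-SNP gaps.
    """
    if n_parents < 4:
        raise SimulationError("need n_parents >= 4")
    if n_founder_haplotypes < 1:
        raise SimulationError("need n_founder_haplotypes >= 1")
    if snps_per_chrom < 3:
        raise SimulationError("need snps_per_chrom >= 3")
    if n_chrom < 1 or block_len_mean < 1:
        raise SimulationError("n_chrom and block_len_mean must be >= 1")
    rng = np.random.default_rng(seed)
    n_sites = n_chrom * snps_per_chrom

    founders = rng.integers(0, 2, size=(n_founder_haplotypes, n_sites), dtype=np.int16)
    if n_founder_haplotypes >= 2:
        # force every site to be polymorphic among founders
        mono = np.ptp(founders, axis=0) == 0
        flip = rng.integers(0, n_founder_haplotypes, size=int(mono.sum()))
        founders[flip, np.flatnonzero(mono)] ^= 1

    alleles = np.empty((n_sites, n_parents), dtype=np.int16)
    for j in range(n_parents):
        for c in range(n_chrom):
            lo = c * snps_per_chrom
            i = lo
            while i < lo + snps_per_chrom:
                f = int(rng.integers(n_founder_haplotypes))
                blk = int(rng.geometric(1.0 / block_len_mean))
                hi = min(i + blk, lo + snps_per_chrom)
                alleles[i:hi, j] = founders[f, i:hi]
                i = hi

    chrom = np.repeat([f"chr{c + 1}" for c in range(n_chrom)], snps_per_chrom).astype(object)
    gaps = rng.integers(20, 200, size=n_sites)
    pos = np.concatenate(
        [np.cumsum(gaps[c * snps_per_chrom:(c + 1) * snps_per_chrom]) for c in range(n_chrom)]
    )
    parents = tuple(f"P{j + 1:02d}" for j in range(n_parents))
    return VariantTable(chrom=chrom, pos=pos, alleles=alleles, parents=parents)


def pick_balanced_site(vt: VariantTable, chrom: str, min_minor: int = 5) -> int:
    """Global index of a site whose minor allele is carried by >= min_minor parents.

    Picks the qualifying site closest to the chromosome midpoint. A planted
    locus is only mappable by local-heterozygosity grouping when both
    alleles are carried by enough parents to form homozygous hybrid groups;
    loci on skewed splits are blind spots of the scan design itself.
    """
    lo, hi = vt.chrom_bounds(chrom)
    mid = (lo + hi) // 2
    best = None
    for i in range(lo, hi):
        counts = np.bincount(vt.alleles[i], minlength=2)
        counts = counts[counts > 0]
        if counts.size < 2 or sorted(counts)[-2] < min_minor:
            continue
        if best is None or abs(i - mid) < abs(best - mid):
            best = i
    if best is None:
        raise SimulationError(
            f"no site on {chrom} with minor-allele carriers >= {min_minor}")
    return best


def pick_cross_parents(vt: VariantTable, sites) -> tuple:
    """First parent pair whose alleles differ at every given global site index.

    Used to choose the founders of a biparental (BC1/F2) cross in which all
    candidate loci segregate.
    """
    for a in range(vt.n_parents):
        for b in range(a + 1, vt.n_parents):
            if all(vt.alleles[i, a] != vt.alleles[i, b] for i in sites):
                return vt.parents[a], vt.parents[b]
    raise SimulationError("no parent pair differs at all requested sites")


def parent_genomes(vt: VariantTable) -> dict:
    """The haploid genome of every parent column of a VariantTable."""
    return {p: HaploidGenome(p, vt.parent_column(p).copy(), vt) for p in vt.parents}


def gen_diallel(parent_ids) -> pd.DataFrame:
    """All unordered pairs of distinct parents: n(n-1)/2 hybrids."""
    ids = list(parent_ids)
    if len(ids) != len(set(ids)):
        raise SimulationError("duplicate parent ids in diallel")
    if len(ids) < 2:
        raise SimulationError("a diallel needs >= 2 parents")
    rows = [
        {"diploid_id": f"{a}x{b}", "parent1": a, "parent2": b}
        for a, b in itertools.combinations(ids, 2)
    ]
    return pd.DataFrame(rows, columns=["diploid_id", "parent1", "parent2"])


def make_hybrids(vt: VariantTable, design: pd.DataFrame) -> list:
    """Diploid hybrid genomes for every row of a cross design."""
    haps = parent_genomes(vt)
    return [
        Diploid(r.diploid_id, haps[r.parent1], haps[r.parent2], r.parent1, r.parent2)
        for r in design.itertuples()
    ]


def meiose(
    diploid: tuple,
    rc: RecombinationConfig,
    n_tetrads: int,
    seed: int | None = None,
) -> list:
    """Simulate tetrad meiosis of a diploid; 4 spores per tetrad.

    Each tetrad consists of two independent complementary chromatid pairs;
    within a pair, one spore takes parent-1 alleles wherever the other takes
    parent-2 alleles, so 2:2 segregation holds exactly at every site.
    Crossover counts per chromosome are Poisson(``crossovers_per_chrom_mean``)
    with breakpoints uniform over inter-SNP intervals (two crossovers in the
    same interval cancel).
    """
    hap1, hap2 = diploid
    if hap1.vt is not hap2.vt and not hap1.vt.equals(hap2.vt):
        raise SimulationError("cannot meiose haploids from different VariantTables")
    vt = hap1.vt
    rng = np.random.default_rng(rc.seed if seed is None else seed)
    spores = []
    for t in range(n_tetrads):
        for pair in range(2):
            mask = np.empty(vt.n_sites, dtype=bool)
            for c in vt.chroms:
                lo, hi = vt.chrom_bounds(c)
                n = hi - lo
                phase = bool(rng.integers(2))
                m = np.full(n, phase)
                n_co = rng.poisson(rc.crossovers_per_chrom_mean)
                if n_co and n > 1:
                    # a crossover in interval k flips parentage from site k+1 on
                    cuts = rng.integers(0, n - 1, size=n_co)
                    flips = np.zeros(n, dtype=int)
                    np.add.at(flips, cuts + 1, 1)
                    m ^= (np.cumsum(flips) % 2).astype(bool)
                mask[lo:hi] = m
            a = np.where(mask, hap1.alleles, hap2.alleles)
            b = np.where(mask, hap2.alleles, hap1.alleles)
            base = f"{hap1.name}x{hap2.name}_t{t + 1}"
            spores.append(HaploidGenome(f"{base}{'ab'[pair]}1", a, vt))
            spores.append(HaploidGenome(f"{base}{'ab'[pair]}2", b, vt))
    return spores


def gen_population(
    f1_haploids: list,
    mode: str,
    backcross_parent: HaploidGenome | None = None,
    design: tuple | None = None,
    seed: int = 0,
    founders: tuple = None,
) -> SegregantPopulation:
    """Build a BC1 or F2 diploid population from F1 haploid spores.

    BC1: every F1 spore is crossed to ``backcross_parent``.
    F2: ``design`` gives two disjoint index subsets of ``f1_haploids``
    (emulating the two mating types); all between-subset pairs are mated.
    """
    if mode == "BC1":
        if backcross_parent is None:
            raise SimulationError("BC1 requires a backcross parent")
        inds = [
            Diploid(f"bc1_{k + 1:04d}", sp, backcross_parent, sp.name, backcross_parent.name)
            for k, sp in enumerate(f1_haploids)
        ]
        return SegregantPopulation("BC1", inds, founders=founders)
    if mode == "F2":
        if design is None:
            raise SimulationError("F2 requires a pairing design (two index subsets)")
        sub_a, sub_b = design
        if set(sub_a) & set(sub_b):
            raise SimulationError("F2 pairing subsets overlap")
        inds = []
        for k, (ia, ib) in enumerate(itertools.product(sub_a, sub_b)):
            a, b = f1_haploids[ia], f1_haploids[ib]
            inds.append(Diploid(f"f2_{k + 1:04d}", a, b, a.name, b.name))
        return SegregantPopulation("F2", inds, founders=founders)
    raise SimulationError(f"unknown population mode {mode!r}")


def phenotype(
    individuals: list,
    arch: TraitArchitecture,
    replicates: int = 3,
    seed: int = 0,
    condition: str = "YEPD37",
    reference_strain: str | None = None,
) -> pd.DataFrame:
    """Simulate replicate DT measurements for genotyped strains.

    Strains are distributed round-robin over the plates of
    ``arch.plate_effects`` (a single unit plate if none are given); a
    reference strain growing at the architecture baseline can be added to
    every plate to support plate normalization downstream.
    """
    rng = np.random.default_rng(seed)
    vt = individuals[0].vt if individuals else None
    idx = {}
    for l in arch.loci:
        try:
            idx[(l.chrom, l.pos)] = vt.site_index(l.chrom, l.pos)
        except (KeyError, AttributeError):
            raise SimulationError(f"architecture locus {l.chrom}:{l.pos} not in VariantTable")

    plates = sorted(arch.plate_effects) or ["P1"]
    factors = {p: arch.plate_effects.get(p, 1.0) for p in plates}

    rows = []

    def emit(strain, p1, p2, gvalue, plate):
        for r in range(1, replicates + 1):
            log2dt = gvalue + rng.normal(0.0, arch.noise_sd)
            rows.append((strain, p1, p2, condition, plate, r, 2.0 ** log2dt * factors[plate]))

    for k, ind in enumerate(individuals):
        gv = arch.baseline_log2dt
        genos = {key: ind.genotype_at(i) for key, i in idx.items()}
        for l in arch.loci:
            gv += l.effect(genos[(l.chrom, l.pos)])
        for i, j, gamma in arch.epistatic_pairs:
            li, lj = arch.loci[i], arch.loci[j]
            if li.is_het(genos[(li.chrom, li.pos)]) and lj.is_het(genos[(lj.chrom, lj.pos)]):
                gv += gamma
        name = ind.id if isinstance(ind, Diploid) else ind.name
        p1 = ind.parent1 if isinstance(ind, Diploid) else ""
        p2 = ind.parent2 if isinstance(ind, Diploid) else ""
        emit(name, p1, p2, gv, plates[k % len(plates)])

    if reference_strain is not None:
        for plate in plates:
            emit(reference_strain, "", "", arch.baseline_log2dt, plate)

    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)


# ---------------------------------------------------------------------------
# composite study designs
# ---------------------------------------------------------------------------

def simulate_f2_cross(
    vt: VariantTable,
    parent1: str,
    parent2: str,
    rc: RecombinationConfig,
    n_a: int = 16,
    n_b: int = 24,
    seed: int = 0,
) -> SegregantPopulation:
    """F1 spores of one hybrid mated in all between-subset pairs (F2 design).

    Mirrors the published design scale: 16 x 24 spore subsets give up to 384
    diploids (the study recovered 350 of these after failed crosses, which
    are not modeled).
    """
    haps = parent_genomes(vt)
    p1, p2 = haps[parent1], haps[parent2]
    n_tet = -(-(n_a + n_b) // 4)
    spores = meiose((p1, p2), rc, n_tetrads=n_tet, seed=seed)
    return gen_population(
        spores[: n_a + n_b],
        "F2",
        design=(list(range(n_a)), list(range(n_a, n_a + n_b))),
        founders=(p1, p2),
    )


def simulate_bc1_cross(
    vt: VariantTable,
    parent1: str,
    parent2: str,
    backcross_to: str,
    rc: RecombinationConfig,
    n_tetrads: int = 44,
    seed: int = 0,
) -> SegregantPopulation:
    """BC1 population: every F1 spore of parent1 x parent2 backcrossed once."""
    haps = parent_genomes(vt)
    p1, p2 = haps[parent1], haps[parent2]
    spores = meiose((p1, p2), rc, n_tetrads=n_tetrads, seed=seed)
    return gen_population(spores, "BC1", backcross_parent=haps[backcross_to], founders=(p1, p2))
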