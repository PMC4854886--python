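"""Shared fixtures: small simulated genomes and F2 study helpers."""

import numpy as np
import pytest

from hetscan import simdata
from hetscan.ioformats import VariantTable


@pytest.fixture(scope="session")
def vt16():
    """16 divergent parents, one chromosome, 40 SNPs."""
    return simdata.gen_parents(
        n_parents=16, n_chrom=1, snps_per_chrom=40,
        block_len_mean=5, n_founder_haplotypes=4, seed=11,
    )


@pytest.fixture(scope="session")
def biparental_vt():
    """Four parents over two chromosomes; P1/P2 maximally divergent.

    Two chromosomes so that the candidate loci used in F2/epistasis tests
    (site indices 4 and 8) segregate independently.
    """
    n = 12
    alleles = np.zeros((n, 4), dtype=np.int16)
    alleles[:, 1] = 1                      # P2 opposite of P1 everywhere
    alleles[::2, 2] = 1                    # P3, P4: arbitrary mosaics
    alleles[1::3, 3] = 1
    return VariantTable(
        chrom=np.array(["chr1"] * 6 + ["chr2"] * 6, dtype=object),
        pos=np.tile(np.arange(100, 100 + 50 * 6, 50), 2),
        alleles=alleles,
        parents=("P1", "P2", "P3", "P4"),
    )


def make_f2_frame(vt, effects, noise_sd, n_a, n_b, seed, gamma=None, locus2_index=8):
    """Simulate an F2 study and return its tidy analysis frame.

    ``effects`` is (effect_aa, effect_ab, effect_bb) of the focal locus at
    site index 4; an optional het-x-het interaction ``gamma`` couples it to
    a second, main-effect-free locus at ``locus2_index``.
    """
    from hetscan import popvalidate

    i1, i2 = 4, locus2_index
    loci = [simdata.TraitLocus(vt.chrom[i1], int(vt.pos[i1]), *effects)]
    pairs = []
    if gamma is not None:
        loci.append(simdata.TraitLocus(vt.chrom[i2], int(vt.pos[i2]), 0.0, 0.0, 0.0))
        pairs = [(0, 1, gamma)]
    arch = simdata.TraitArchitecture(loci=loci, epistatic_pairs=pairs, noise_sd=noise_sd)
    rc = simdata.RecombinationConfig(crossovers_per_chrom_mean=1.0)
    pop = simdata.simulate_f2_cross(vt, "P1", "P2", rc, n_a=n_a, n_b=n_b, seed=seed)
    ph = simdata.phenotype(pop.individuals, arch, replicates=3, seed=seed + 1)
    names = {"L1": (vt.chrom[i1], int(vt.pos[i1]))}
    if gamma is not None:
        names["L2"] = (vt.chrom[i2], int(vt.pos[i2]))
    return popvalidate.population_frame(pop, ph, names)
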