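"""BC1/F2 locus tests, mode-of-inheritance calls, epistasis, factorial ANOVA."""

import numpy as np
import pandas as pd
import pytest

from hetscan import popvalidate, simdata
from hetscan.popvalidate import PopulationError
from hetscan.simdata import RecombinationConfig, TraitArchitecture, TraitLocus

from conftest import make_f2_frame


def frame_from_tokens(tokens, dts):
    df = pd.DataFrame({"individual": range(len(tokens)), "L": tokens, "dt": dts})
    df["log2dt"] = np.log2(df["dt"])
    return df


class TestBC1:
    def test_complete_separation_detects_faster_heterozygotes(self):
        df = frame_from_tokens(["HET"] * 20 + ["HOM1"] * 20, [2.0] * 20 + [2.4] * 20)
        r = popvalidate.bc1_local_test(df, "L")
        assert r.direction == "het_faster"
        assert r.p_value < 1e-3

    def test_single_class_rejected(self):
        df = frame_from_tokens(["HET"] * 10, [2.0] * 10)
        with pytest.raises(PopulationError):
            popvalidate.bc1_local_test(df, "L")

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            df = frame_from_tokens(
                ["HET"] * 15 + ["HOM1"] * 15, 2.0 ** rng.normal(1.0, 0.1, 30))
            ps.append(popvalidate.bc1_local_test(df, "L").p_value)
        assert 0.01 < np.mean(np.array(ps) < 0.5) < 0.75
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_dominant_locus_detected_only_against_recessive_parent(self, biparental_vt):
        # P2 allele fully dominant and faster: BC1 to P1 (slow hom) separates
        # Het from Hom; BC1 to P2 has identical class means.
        locus = TraitLocus("chr1", int(biparental_vt.pos[4]), 0.2, -0.2, -0.2)
        arch = TraitArchitecture(loci=[locus], noise_sd=0.02)
        rc = RecombinationConfig(1.0)
        counts = {"P1": 0, "P2": 0}
        n_seeds = 10
        for seed in range(n_seeds):
            for bc_parent in ("P1", "P2"):
                pop = simdata.simulate_bc1_cross(
                    biparental_vt, "P1", "P2", bc_parent, rc, n_tetrads=30, seed=5 + seed)
                ph = simdata.phenotype(pop.individuals, arch, replicates=3, seed=60 + seed)
                frame = popvalidate.population_frame(
                    pop, ph, {"L": ("chr1", int(biparental_vt.pos[4]))})
                r = popvalidate.bc1_local_test(frame, "L")
                counts[bc_parent] += r.direction == "het_faster"
        assert counts["P1"] == n_seeds          # dominant allele always detected
        assert counts["P2"] <= 2                # no real signal against the carrier


class TestThreeGroup:
    def test_planted_co_dominant_locus_fully_separated(self, biparental_vt):
        frame = make_f2_frame(biparental_vt, (0.3, 0.0, -0.3), 0.005, 15, 20, seed=1)
        r = popvalidate.f2_three_group_test(frame, "L1")
        assert len({r.letters[t] for t in r.letters}) == 3
        means = r.group_means_dt
        assert means["HOM2"] < means["HET"] < means["HOM1"]

    def test_planted_over_dominant_het_distinct_and_fastest(self, biparental_vt):
        frame = make_f2_frame(biparental_vt, (0.02, -0.3, -0.02), 0.02, 15, 20, seed=2)
        r = popvalidate.f2_three_group_test(frame, "L1")
        assert min(r.group_means_dt, key=r.group_means_dt.get) == "HET"
        assert not set(r.letters["HET"]) & set(r.letters["HOM1"])
        assert not set(r.letters["HET"]) & set(r.letters["HOM2"])

    def test_null_shares_a_letter_most_of_the_time(self, biparental_vt):
        shared = 0
        n = 100
        for seed in range(n):
            frame = make_f2_frame(biparental_vt, (0.0, 0.0, 0.0), 0.05, 8, 10, seed=100 + seed)
            r = popvalidate.f2_three_group_test(frame, "L1")
            letters = [set(r.letters[t]) for t in r.letters]
            shared += bool(letters[0] & letters[1] & letters[2])
        assert shared / n >= 0.85

    def test_all_singleton_classes_rejected(self):
        df = frame_from_tokens(["HOM1", "HET", "HOM2"], [2.0, 2.1, 2.2])
        with pytest.raises(PopulationError):
            popvalidate.f2_three_group_test(df, "L")


class TestADTest:
    def test_noise_free_over_dominance_call(self):
        df = frame_from_tokens(
            ["HOM1"] * 10 + ["HOM2"] * 10 + ["HET"] * 10,
            [2.0] * 10 + [4.0] * 10 + [1.5] * 10)
        r = popvalidate.f2_ad_test(df, "L", scale="dt")
        assert r.call == "over_dominant"
        assert r.decomposition.d == pytest.approx(1.5)
        assert r.decomposition.a == pytest.approx(1.0)

    def test_co_dominant_recovery(self, biparental_vt):
        # planted a = 0.32, d = 0 on log2DT
        frame = make_f2_frame(biparental_vt, (0.32, 0.0, -0.32), 0.05, 15, 20, seed=3)
        r = popvalidate.f2_ad_test(frame, "L1")
        assert r.call == "co_dominant"
        n1 = (frame["L1"] == "HOM1").sum()
        n2 = (frame["L1"] == "HOM2").sum()
        se = 0.5 * (0.05 / np.sqrt(3)) * np.sqrt(1 / n1 + 1 / n2)
        assert abs(r.decomposition.a - 0.32) < 3 * se

    def test_full_dominance_is_neither_over_nor_co(self):
        rng = np.random.default_rng(4)
        # d == a exactly: het mean sits on one homozygote mean
        dts = 2.0 ** np.concatenate([
            rng.normal(1.2, 0.02, 100), rng.normal(0.8, 0.02, 100),
            rng.normal(0.8, 0.02, 100)])
        df = frame_from_tokens(["HOM1"] * 100 + ["HOM2"] * 100 + ["HET"] * 100, dts)
        r = popvalidate.f2_ad_test(df, "L")
        assert r.call == "dominant"

    def test_missing_class_rejected(self):
        df = frame_from_tokens(["HOM1"] * 5 + ["HET"] * 5, [2.0] * 5 + [2.2] * 5)
        with pytest.raises(PopulationError):
            popvalidate.f2_ad_test(df, "L")


class TestEpistasis:
    def test_planted_het_het_synergy_detected(self, biparental_vt):
        frame = make_f2_frame(
            biparental_vt, (0.01, -0.05, -0.01), 0.05, 16, 22, seed=5, gamma=-0.1)
        r = popvalidate.epistasis_stratified(frame, "L1", "L2")
        assert r.direction == "synergistic"
        assert r.d_full > r.d_excl
        assert r.p_d_change < 0.05

    def test_independent_loci_usually_none(self, biparental_vt):
        none = 0
        n = 40
        for seed in range(n):
            frame = make_f2_frame(
                biparental_vt, (0.01, -0.05, -0.01), 0.05, 12, 16,
                seed=300 + seed, gamma=0.0)
            r = popvalidate.epistasis_stratified(frame, "L1", "L2")
            none += r.direction == "none"
        assert none / n >= 0.85

    def test_a_not_systematically_changed_by_het_only_interaction(self, biparental_vt):
        diffs, sig = [], 0
        n = 30
        for seed in range(n):
            frame = make_f2_frame(
                biparental_vt, (0.1, -0.05, -0.1), 0.05, 12, 16,
                seed=600 + seed, gamma=-0.1)
            r = popvalidate.epistasis_stratified(frame, "L1", "L2")
            diffs.append(r.a_full - r.a_excl)
            sig += r.p_a_change < 0.05
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(n)
        assert sig / n < 0.25

    def test_conditioning_without_heterozygotes_rejected(self):
        df = pd.DataFrame({
            "L1": ["HOM1"] * 4 + ["HET"] * 4 + ["HOM2"] * 4,
            "L2": ["HOM1"] * 12,
            "dt": np.linspace(2, 3, 12),
        })
        df["log2dt"] = np.log2(df["dt"])
        with pytest.raises(PopulationError):
            popvalidate.epistasis_stratified(df, "L1", "L2")

    def test_same_locus_rejected(self):
        df = frame_from_tokens(["HOM1", "HET", "HOM2"] * 4, [2.0] * 12)
        with pytest.raises(PopulationError):
            popvalidate.epistasis_stratified(df, "L", "L")


class TestReplacementFactorial:
    @staticmethod
    def _table(cell_means, noise_sd, n_per_cell, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for (g, b), mu in cell_means.items():
            for _ in range(n_per_cell):
                rows.append((g, b, 2.0 ** (np.log2(mu) + rng.normal(0, noise_sd))))
        return pd.DataFrame(rows, columns=["genotype", "background", "dt"])

    def test_additive_cell_means_have_zero_interaction(self):
        means = {}
        g_eff = {"HOM1": 0.0, "HET": -0.1, "HOM2": 0.05}
        b_eff = {"B1": 0.0, "Hybrid": -0.3, "B2": 0.1}
        for g in g_eff:
            for b in b_eff:
                means[(g, b)] = 2.0 ** (1.5 + g_eff[g] + b_eff[b])
        t = self._table(means, 0.0, 2, 0)
        r = popvalidate.replacement_factorial(t)
        assert r.anova.loc["C(genotype):C(background)", "sum_sq"] == pytest.approx(0, abs=1e-18)

    def test_background_specific_genotype_effect_detected(self):
        # hybrid-background het fastest; parental backgrounds show opposite
        # dominance patterns -> strong interaction
        means = {
            ("HOM1", "Hybrid"): 2.21, ("HET", "Hybrid"): 2.14, ("HOM2", "Hybrid"): 2.17,
            ("HOM1", "B1"): 3.44, ("HET", "B1"): 3.07, ("HOM2", "B1"): 2.99,
            ("HOM1", "B2"): 2.99, ("HET", "B2"): 3.04, ("HOM2", "B2"): 2.71,
        }
        detected = 0
        for seed in range(20):
            t = self._table(means, 0.02, 4, seed)
            r = popvalidate.replacement_factorial(t)
            detected += r.p_interaction < 0.05
        assert detected >= 15
        t = self._table(means, 0.02, 4, 99)
        r = popvalidate.replacement_factorial(t)
        if r.p_interaction < 0.05:
            assert set(r.per_background) == {"Hybrid", "B1", "B2"}

    def test_background_label_permutation_preserves_pvalues(self):
        means = {(g, b): 2.0 + 0.1 * i for i, (g, b) in enumerate(
            (g, b) for g in ("HOM1", "HET", "HOM2") for b in ("B1", "B2"))}
        t = self._table(means, 0.05, 3, 7)
        r1 = popvalidate.replacement_factorial(t)
        swapped = t.assign(background=t["background"].map({"B1": "B2", "B2": "B1"}))
        r2 = popvalidate.replacement_factorial(swapped)
        assert r2.p_interaction == pytest.approx(r1.p_interaction)
        assert r2.p_genotype == pytest.approx(r1.p_genotype)

    def test_empty_cell_rejected(self):
        # 2x2 design with one cell absent
        t = self._table({("HOM1", "B1"): 2.0, ("HET", "B1"): 2.1,
                         ("HOM1", "B2"): 2.2}, 0.05, 3, 1)
        with pytest.raises(PopulationError):
            popvalidate.replacement_factorial(t)

    def test_single_factor_level_rejected(self):
        t = self._table({("HOM1", "B1"): 2.0, ("HET", "B1"): 2.1}, 0.05, 3, 1)
        with pytest.raises(PopulationError):
            popvalidate.replacement_factorial(t)
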