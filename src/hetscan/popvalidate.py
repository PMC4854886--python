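"""Candidate-locus validation in segregating populations.

Implements the follow-up analyses run after the genome scan: two-group
local-heterozygote tests in BC1 backcross populations, three-group
Tukey–Kramer comparisons in the F2, mode-of-inheritance calls from
per-individual a/d assignments, the heterozygote-exclusion stratification
test for epistasis, and the replacement-strain genotype x background
factorial ANOVA.

Analyses operate on a tidy population frame with one row per individual:
genotype-token columns (HOM1/HET/HOM2) per candidate locus, plus ``dt``
(replicate-mean doubling time) and ``log2dt``. Group-comparison tests run
on log2DT; group means are also reported on the DT scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import hetmetrics

TOKENS = ("HOM1", "HET", "HOM2")


class PopulationError(ValueError):
    """Raised when a population lacks the genotype classes a test needs."""


def population_frame(pop, ph: pd.DataFrame, loci: dict) -> pd.DataFrame:
    """Tidy analysis frame for a SegregantPopulation.

    ``loci`` maps locus name -> (chrom, pos). Phenotypes are reduced to one
    replicate-mean DT per individual; log2dt = log2(mean DT).
    """
    dt = ph.groupby("strain")["dt"].mean()
    ids = [ind.id for ind in pop.individuals]
    df = pd.DataFrame({"individual": ids})
    for name, (chrom, pos) in loci.items():
        df[name] = pop.genotype_tokens(chrom, pos)
    df["dt"] = dt.reindex(ids).to_numpy()
    if df["dt"].isna().any():
        raise PopulationError("individuals without phenotypes")
    df["log2dt"] = np.log2(df["dt"])
    return df


def _class_values(df: pd.DataFrame, locus: str, scale: str = "log2dt") -> dict:
    return {
        tok: df.loc[df[locus] == tok, scale].to_numpy()
        for tok in TOKENS
        if (df[locus] == tok).any()
    }


# ---------------------------------------------------------------------------
# BC1: two-group local test
# ---------------------------------------------------------------------------

@dataclass
class TwoGroupResult:
    locus: str
    hom_token: str
    n_het: int
    n_hom: int
    mean_het_dt: float
    mean_hom_dt: float
    p_value: float
    direction: str  # het_faster | het_slower | none


def bc1_local_test(df: pd.DataFrame, locus: str, alpha: float = 0.05) -> TwoGroupResult:
    """Wilcoxon rank-sum of local heterozygotes vs local homozygotes.

    A BC1 population segregates only Het and one Hom class at each locus;
    the test runs on log2DT, means are reported on the DT scale.
    """
    classes = _class_values(df, locus)
    if "HET" not in classes:
        raise PopulationError(f"no heterozygotes at {locus}")
    hom_toks = [t for t in ("HOM1", "HOM2") if t in classes]
    if not hom_toks:
        raise PopulationError(f"no homozygotes at {locus}")
    hom_tok = hom_toks[0] if len(hom_toks) == 1 else None
    if hom_tok is None:
        raise PopulationError(f"{locus} has both homozygote classes; not a BC1 locus")
    het, hom = classes["HET"], classes[hom_tok]
    if min(het.size, hom.size) < 2:
        raise PopulationError(f"genotype class with < 2 members at {locus}")
    p = float(stats.mannwhitneyu(het, hom, alternative="two-sided").pvalue)
    mean_het = float(df.loc[df[locus] == "HET", "dt"].mean())
    mean_hom = float(df.loc[df[locus] == hom_tok, "dt"].mean())
    if p < alpha:
        direction = "het_faster" if mean_het < mean_hom else "het_slower"
    else:
        direction = "none"
    return TwoGroupResult(locus, hom_tok, het.size, hom.size, mean_het, mean_hom, p, direction)


# ---------------------------------------------------------------------------
# F2: three-group Tukey–Kramer with letter display
# ---------------------------------------------------------------------------

@dataclass
class ThreeGroupResult:
    locus: str
    group_means_dt: dict
    group_sizes: dict
    pairwise_p: dict        # frozenset({tok, tok}) -> p
    letters: dict           # tok -> letter string
    alpha: float


def _letter_display(order: list, not_different: set) -> dict:
    """Compact letter display from maximal cliques of the NSD graph."""
    g = nx.Graph()
    g.add_nodes_from(order)
    g.add_edges_from(not_different)
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(order.index(t) for t in c))
    letters = {t: "" for t in order}
    for k, clique in enumerate(cliques):
        for t in clique:
            letters[t] += chr(ord("a") + k)
    return letters


def f2_three_group_test(df: pd.DataFrame, locus: str, alpha: float = 0.05) -> ThreeGroupResult:
    """All-pairs Tukey–Kramer comparison of the genotype classes on log2DT.

    Two-class populations fall back to the single pairwise comparison
    (Tukey–Kramer with two groups reduces to it). Letters group classes
    that are not significantly different, ordered by ascending DT.
    """
    classes = _class_values(df, locus)
    classes = {t: v for t, v in classes.items() if v.size >= 2}
    if len(classes) < 2:
        raise PopulationError(f"fewer than 2 usable genotype classes at {locus}")
    toks = [t for t in TOKENS if t in classes]
    values = np.concatenate([classes[t] for t in toks])
    labels = np.concatenate([[t] * classes[t].size for t in toks])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise, not_diff = {}, set()
    for (g1, g2), p, rej in zip(
        [(tk.groupsunique[i], tk.groupsunique[j]) for i, j in
         zip(*np.triu_indices(len(tk.groupsunique), 1))],
        tk.pvalues, tk.reject,
    ):
        pairwise[frozenset((g1, g2))] = float(p)
        if not rej:
            not_diff.add((g1, g2))
    means_dt = {t: float(df.loc[df[locus] == t, "dt"].mean()) for t in toks}
    order = sorted(toks, key=lambda t: means_dt[t])
    return ThreeGroupResult(
        locus=locus,
        group_means_dt=means_dt,
        group_sizes={t: int(classes[t].size) for t in toks},
        pairwise_p=pairwise,
        letters=_letter_display(order, not_diff),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# F2: a-vs-d mode-of-inheritance test
# ---------------------------------------------------------------------------

@dataclass
class ADTestResult:
    locus: str
    decomposition: hetmetrics.DominanceDecomposition
    a_sample: np.ndarray = field(repr=False)
    d_sample: np.ndarray = field(repr=False)
    p_a_vs_d: float
    p_d_zero: float
    call: str  # over_dominant | under_dominant | co_dominant | dominant


def assign_ad_values(df: pd.DataFrame, locus: str, scale: str = "log2dt"):
    """Per-individual a/d assignment at one locus of an F2 frame.

    Wraps :func:`hetmetrics.assign_ad_values` on the genotype-class value
    vectors; errors when a homozygote class is missing (fall back to the
    two-group BC1-style comparison in that case).
    """
    classes = _class_values(df, locus, scale)
    for tok in TOKENS:
        if tok not in classes:
            raise PopulationError(f"genotype class {tok} missing at {locus}")
    return hetmetrics.assign_ad_values(classes["HOM1"], classes["HOM2"], classes["HET"])


def _two_sample(x, y, method: str) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if method == "wilcoxon":
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    if method == "t":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    raise ValueError(f"unknown method {method!r}")


def _midparent_contrast_p(h1, h2, het) -> float:
    """Welch-type t-test of the contrast mu_het - (mu_hom1 + mu_hom2)/2 = 0.

    Testing "d = 0" as a one-sample test of the d-values ignores the
    sampling error of the estimated mid-parent and is anti-conservative;
    the linear contrast carries the correct standard error.
    """
    parts = [
        (het.var(ddof=1) / het.size, het.size),
        (h1.var(ddof=1) / (4 * h1.size), h1.size),
        (h2.var(ddof=1) / (4 * h2.size), h2.size),
    ]
    var = sum(v for v, _ in parts)
    if var == 0:
        est = het.mean() - (h1.mean() + h2.mean()) / 2
        return 1.0 if est == 0 else 0.0
    df = var ** 2 / sum(v ** 2 / (n - 1) for v, n in parts)
    t = (het.mean() - (h1.mean() + h2.mean()) / 2) / math.sqrt(var)
    return float(2 * stats.t.sf(abs(t), df))


def f2_ad_test(df: pd.DataFrame, locus: str, method: str = "wilcoxon",
               alpha: float = 0.05, scale: str = "log2dt") -> ADTestResult:
    """Mode-of-inheritance call from the a-sample vs d-sample comparison.

    The call logic: *co-dominant* when d is indistinguishable from zero but
    significantly below a; *over-dominant* when d exceeds a significantly
    with d > 0 (faster heterozygotes); *under-dominant* when d < 0 with
    |d| > a and the a-vs-d difference significant; otherwise *dominant*
    (full/partial dominance). The d = 0 check is always the mid-parent
    contrast t-test (see :func:`_midparent_contrast_p`); ``method`` selects
    the a-vs-d comparison.
    """
    a_sample, d_sample, _m = assign_ad_values(df, locus, scale)
    classes = _class_values(df, locus, scale)
    dec = hetmetrics.dominance_decomposition(
        classes["HOM1"].mean(), classes["HOM2"].mean(), classes["HET"].mean(),
        scale=scale,
    )
    p_ad = _two_sample(a_sample, d_sample, method)
    p_d0 = _midparent_contrast_p(classes["HOM1"], classes["HOM2"], classes["HET"])
    a, d = dec.a, dec.d
    if p_d0 >= alpha and p_ad < alpha and d < a:
        call = "co_dominant"
    elif p_ad < alpha and d > a and d > 0:
        call = "over_dominant"
    elif p_ad < alpha and d < 0 and abs(d) > a:
        call = "under_dominant"
    else:
        call = "dominant"
    return ADTestResult(
        locus=locus, decomposition=dec, a_sample=a_sample, d_sample=d_sample,
        p_a_vs_d=p_ad, p_d_zero=p_d0, call=call,
    )


# ---------------------------------------------------------------------------
# epistasis by heterozygote exclusion
# ---------------------------------------------------------------------------

@dataclass
class EpistasisResult:
    focal_locus: str
    conditioning_locus: str
    a_full: float
    d_full: float
    doa_full: float
    a_excl: float
    d_excl: float
    doa_excl: float
    p_d_change: float
    p_a_change: float
    n_full: int
    n_excl: int
    direction: str  # synergistic | antagonistic | none


def epistasis_stratified(df: pd.DataFrame, focal: str, conditioning: str,
                         alpha: float = 0.05, method: str = "wilcoxon",
                         scale: str = "log2dt") -> EpistasisResult:
    """Heterozygote-exclusion test for epistasis between two loci.

    The focal locus decomposition is recomputed on the subset excluding
    conditioning-locus heterozygotes. The change in d is tested as a
    two-sample contrast of focal-heterozygote d-values (deviations from the
    full-population mid-parent) between the conditioning-Het and
    conditioning-Hom strata — the "with vs without" comparison of
    overlapping samples has no valid two-sample null, while this stratified
    form tests the identical interaction contrast. The analogous a-contrast
    is expected null for purely het-x-het interactions.
    """
    if focal == conditioning:
        raise PopulationError("focal and conditioning loci must differ")
    cond_het = df[conditioning] == "HET"
    if not cond_het.any():
        raise PopulationError(f"no heterozygotes at conditioning locus {conditioning}")
    a_full, d_full, m_full = assign_ad_values(df, focal, scale)
    dec_full = f2_ad_test(df, focal, method=method, scale=scale).decomposition

    excl = df[~cond_het]
    try:
        dec_excl = f2_ad_test(excl, focal, method=method, scale=scale).decomposition
    except PopulationError as e:
        raise PopulationError(
            f"stratum excluding {conditioning} heterozygotes: {e}") from e

    # stratified contrasts on deviations from the *full*-population mid-parent
    focal_het = df[focal] == "HET"
    d_het_stratum = (m_full - df.loc[focal_het & cond_het, scale]).to_numpy()
    d_hom_stratum = (m_full - df.loc[focal_het & ~cond_het, scale]).to_numpy()
    if d_het_stratum.size == 0 or d_hom_stratum.size == 0:
        empty = "conditioning-Het" if d_het_stratum.size == 0 else "conditioning-Hom"
        raise PopulationError(f"empty {empty} stratum among focal heterozygotes")
    p_d = _two_sample(d_het_stratum, d_hom_stratum, method)

    sign = 1.0 if df.loc[df[focal] == "HOM1", scale].mean() >= \
        df.loc[df[focal] == "HOM2", scale].mean() else -1.0
    signs = df[focal].map({"HOM1": sign, "HOM2": -sign})
    a_dev = (signs * (df[scale] - m_full)).to_numpy()
    focal_hom = df[focal].isin(("HOM1", "HOM2")).to_numpy()
    a_het_stratum = a_dev[focal_hom & cond_het.to_numpy()]
    a_hom_stratum = a_dev[focal_hom & ~cond_het.to_numpy()]
    if a_het_stratum.size and a_hom_stratum.size:
        p_a = _two_sample(a_het_stratum, a_hom_stratum, method)
    else:
        p_a = math.nan

    if p_d < alpha and dec_full.d > dec_excl.d:
        direction = "synergistic"
    elif p_d < alpha and dec_full.d < dec_excl.d:
        direction = "antagonistic"
    else:
        direction = "none"
    return EpistasisResult(
        focal_locus=focal, conditioning_locus=conditioning,
        a_full=dec_full.a, d_full=dec_full.d, doa_full=dec_full.d_over_a,
        a_excl=dec_excl.a, d_excl=dec_excl.d, doa_excl=dec_excl.d_over_a,
        p_d_change=p_d, p_a_change=p_a,
        n_full=len(df), n_excl=len(excl),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# replacement-strain factorial analysis
# ---------------------------------------------------------------------------

@dataclass
class FactorialResult:
    anova: pd.DataFrame
    p_genotype: float
    p_background: float
    p_interaction: float
    per_background: dict  # background -> ThreeGroupResult (when interaction significant)


def replacement_factorial(table: pd.DataFrame, alpha: float = 0.05) -> FactorialResult:
    """Two-way fixed-effects ANOVA of log2DT on genotype x background.

    ``table`` needs columns ``genotype`` (HOM1/HET/HOM2), ``background``
    and ``dt`` (or ``log2dt``); every cell must hold >= 2 replicates. When
    the interaction is significant, genotypes are compared within each
    background with Tukey–Kramer letters.
    """
    df = table.copy()
    if "log2dt" not in df.columns:
        if (df["dt"] <= 0).any():
            raise ValueError("non-positive DT values")
        df["log2dt"] = np.log2(df["dt"])
    if df["genotype"].nunique() < 2 or df["background"].nunique() < 2:
        raise PopulationError("need >= 2 levels of both genotype and background")
    cells = df.groupby(["genotype", "background"]).size().unstack()
    if cells.isna().any().any() or (cells < 2).any().any():
        raise PopulationError("each genotype x background cell needs >= 2 replicates")
    model = ols("log2dt ~ C(genotype) * C(background)", data=df).fit()
    table_a = anova_lm(model, typ=2)
    p_g = float(table_a.loc["C(genotype)", "PR(>F)"])
    p_b = float(table_a.loc["C(background)", "PR(>F)"])
    p_i = float(table_a.loc["C(genotype):C(background)", "PR(>F)"])
    per_bg = {}
    if p_i < alpha:
        for bg, sub in df.groupby("background"):
            frame = pd.DataFrame({
                "geno": sub["genotype"].to_numpy(),
                "dt": sub["dt"].to_numpy() if "dt" in sub.columns
                else 2.0 ** sub["log2dt"].to_numpy(),
                "log2dt": sub["log2dt"].to_numpy(),
            })
            per_bg[bg] = f2_three_group_test(frame, "geno", alpha=alpha)
    return FactorialResult(
        anova=table_a, p_genotype=p_g, p_background=p_b, p_interaction=p_i,
        per_background=per_bg,
    )
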