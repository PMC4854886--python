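"""Genome-wide over-dominance scan and hybrid-background refinement.

For every haplotype window the diallel hybrids are divided, per candidate
haplotype pair, into local genotypic groups — Hom1 (both parents carry
haplotype 1), Het (one parent each), Hom2 — and the heterotic values of the
Het group are compared with both Hom groups (two two-sample tests, summary
p = max of the two, so significance requires differing from *both*
homozygous groups). Among admissible pairs the most significant grouping is
chosen; windows are classified over-dominant when the heterozygote mean
exceeds both homozygote means at the chosen significance level, and the
whole scan is corrected by Benjamini–Hochberg FDR.

The background-specific refinement keeps windows in which one focal hybrid
is locally heterozygous, re-calls haplotypes from a richer polymorphism
track, and retests with per-hybrid degree-of-dominance (d/a) values using
both Kruskal–Wallis and Tukey–Kramer comparisons.

Note: choosing the most significant haplotype pair and then reporting its
p-value inherits a selection bias; the null-calibration tests quantify it.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import hetmetrics, ioformats
from .windows import HaplotypeWindow, WindowConfig, call_haplotypes, enumerate_windows

OVER = "over_dominant"
UNDER = "under_dominant"
NONE = "none"

#: largest per-group sample size for which exact two-sample KS p-values are used
KS_EXACT_MAX = 25


@dataclass
class ScanConfig:
    alpha: float = 0.05
    fdr_q: float = 0.1
    test: str = "ks"  # ks | kruskal_wallis | tukey_kramer
    min_group_size: int = 3
    statistic: str = "heterotic_value"  # heterotic_value | d_over_a

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.fdr_q < 1):
            raise ValueError("alpha and fdr_q must lie in (0, 1)")
        if self.test not in ("ks", "kruskal_wallis", "tukey_kramer"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.statistic not in ("heterotic_value", "d_over_a"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class GenotypicGrouping:
    window_id: str
    hap1: int
    hap2: int
    hom1_ids: list
    het_ids: list
    hom2_ids: list

    @property
    def sizes(self) -> tuple:
        return (len(self.hom1_ids), len(self.het_ids), len(self.hom2_ids))


@dataclass
class WindowTestResult:
    window: HaplotypeWindow
    grouping: GenotypicGrouping
    mean_hom1: float
    mean_het: float
    mean_hom2: float
    p_het_vs_hom1: float
    p_het_vs_hom2: float
    p_summary: float
    classification: str
    q_value: float = math.nan
    passed_fdr: bool = False

    def as_record(self) -> dict:
        w, g = self.window, self.grouping
        return {
            "window_id": w.window_id, "chrom": w.chrom,
            "start_pos": w.start_pos, "end_pos": w.end_pos,
            "n_snps": w.n_snps, "n_haplotypes": w.n_haplotypes,
            "hap1": g.hap1, "hap2": g.hap2,
            "n_hom1": len(g.hom1_ids), "n_het": len(g.het_ids), "n_hom2": len(g.hom2_ids),
            "mean_hom1": self.mean_hom1, "mean_het": self.mean_het, "mean_hom2": self.mean_hom2,
            "p_het_hom1": self.p_het_vs_hom1, "p_het_hom2": self.p_het_vs_hom2,
            "p_summary": self.p_summary, "q_value": self.q_value,
            "classification": self.classification,
        }


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.as_record() for r in results], columns=ioformats.SCAN_RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# statistical primitives
# ---------------------------------------------------------------------------

def two_sample_p(x, y, test: str) -> float:
    """Two-sample p-value under the configured test.

    KS uses the exact null distribution when both samples have at most
    ``KS_EXACT_MAX`` members (group sizes in a 120-hybrid diallel are
    small), asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values identical: no evidence either way
    if test == "ks":
        method = "exact" if min(x.size, y.size) <= KS_EXACT_MAX else "asymp"
        with warnings.catch_warnings():
            # ties (e.g. zero-clamped heterotic values) make scipy fall back
            # to the asymptotic p; that behaviour is intended here
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(stats.ks_2samp(x, y, method=method).pvalue)
    if test == "kruskal_wallis":
        return float(stats.kruskal(x, y).pvalue)
    if test == "tukey_kramer":
        return float(stats.tukey_hsd(x, y).pvalue[0, 1])
    raise ValueError(f"unknown test {test!r}")


def bh_fdr(pvalues, q: float = 0.1):
    """Benjamini–Hochberg step-up: per-item q-values and pass flags."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    passed, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, passed


# ---------------------------------------------------------------------------
# per-window grouping and testing
# ---------------------------------------------------------------------------

def _hybrid_labels(window: HaplotypeWindow, design: pd.DataFrame):
    lab = {p: int(l) for p, l in zip(window.parents, window.labels)}
    out = []
    for r in design.itertuples():
        out.append((r.diploid_id, lab[r.parent1], lab[r.parent2]))
    return out


def _groups_for_pair(hyb_labels, h1: int, h2: int):
    hom1 = [i for i, l1, l2 in hyb_labels if l1 == h1 and l2 == h1]
    hom2 = [i for i, l1, l2 in hyb_labels if l1 == h2 and l2 == h2]
    het = [i for i, l1, l2 in hyb_labels if {l1, l2} == {h1, h2}]
    return hom1, het, hom2


def test_window(grouping: GenotypicGrouping, values, cfg: ScanConfig,
                window: HaplotypeWindow | None = None) -> WindowTestResult:
    """Compare the Het group with both Hom groups and classify the window.

    Orientation: larger statistic = stronger heterozygote advantage (true
    for both heterotic values and d/a), so over-dominance requires the Het
    mean to exceed both Hom means with summary p below alpha.
    """
    g1 = np.asarray([values[i] for i in grouping.hom1_ids], dtype=float)
    gh = np.asarray([values[i] for i in grouping.het_ids], dtype=float)
    g2 = np.asarray([values[i] for i in grouping.hom2_ids], dtype=float)
    if min(g1.size, gh.size, g2.size) < 2:
        raise ValueError("each genotypic group needs at least 2 hybrids")
    p1 = two_sample_p(gh, g1, cfg.test)
    p2 = two_sample_p(gh, g2, cfg.test)
    p_summary = max(p1, p2)
    m1, mh, m2 = g1.mean(), gh.mean(), g2.mean()
    if p_summary < cfg.alpha and mh > m1 and mh > m2:
        cls = OVER
    elif p_summary < cfg.alpha and mh < m1 and mh < m2:
        cls = UNDER
    else:
        cls = NONE
    return WindowTestResult(
        window=window, grouping=grouping,
        mean_hom1=float(m1), mean_het=float(mh), mean_hom2=float(m2),
        p_het_vs_hom1=p1, p_het_vs_hom2=p2, p_summary=p_summary,
        classification=cls,
    )


def group_hybrids(window: HaplotypeWindow, design: pd.DataFrame, values,
                  cfg: ScanConfig, min_carriers: int = 3) -> GenotypicGrouping | None:
    """Choose the most significant genotypic grouping of one window.

    Candidate haplotype pairs are restricted to haplotypes carried by at
    least ``min_carriers`` parents; a pair is admissible when all three
    groups reach ``cfg.min_group_size``. Among admissible pairs the one
    minimizing the summary p is returned (ties: larger total membership,
    then haplotype label order); ``None`` when no pair survives.
    """
    hyb_labels = _hybrid_labels(window, design)
    eligible = [h for h in range(window.n_haplotypes) if window.carriers[h] >= min_carriers]
    best = None
    floor = max(cfg.min_group_size, 2)
    for h1, h2 in itertools.combinations(eligible, 2):
        hom1, het, hom2 = _groups_for_pair(hyb_labels, h1, h2)
        if min(len(hom1), len(het), len(hom2)) < floor:
            continue
        grouping = GenotypicGrouping(window.window_id, h1, h2, hom1, het, hom2)
        res = test_window(grouping, values, cfg, window=window)
        key = (res.p_summary, -(len(hom1) + len(het) + len(hom2)), (h1, h2))
        if best is None or key < best[0]:
            best = (key, grouping)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# the genome-wide scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    results: list
    log: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)


def genome_scan(
    vt: ioformats.VariantTable,
    design: pd.DataFrame,
    ph: pd.DataFrame,
    cfg: ScanConfig | None = None,
    wcfg: WindowConfig | None = None,
    condition: str | None = None,
) -> ScanResult:
    """Run the sliding-window over-dominance scan over a diallel.

    Per-hybrid heterotic values (or d/a, per ``cfg.statistic``) are computed
    from replicate-mean strain DTs; every admissible window is grouped and
    tested; BH correction is applied once over all tested windows.
    """
    cfg = cfg or ScanConfig()
    wcfg = wcfg or WindowConfig()
    strain_dt = ioformats.strain_means(ph, condition)
    missing = [
        s for s in itertools.chain(
            design["diploid_id"], design["parent1"], design["parent2"])
        if s not in strain_dt.index
    ]
    if missing:
        raise ValueError(f"strains without phenotypes: {sorted(set(missing))[:5]} ...")
    if cfg.statistic == "heterotic_value":
        values = hetmetrics.heterotic_values_for_design(design, strain_dt)
    else:
        values = hetmetrics.doa_values_for_design(design, strain_dt)

    wins = enumerate_windows(vt, wcfg)
    log = Counter(windows_enumerated=len(wins))
    results = []
    for w in wins:
        grouping = group_hybrids(w, design, values, cfg, min_carriers=wcfg.min_carriers)
        if grouping is None:
            log["skipped_no_admissible_grouping"] += 1
            continue
        results.append(test_window(grouping, values, cfg, window=w))
    log["windows_tested"] = len(results)
    if results:
        qvals, passed = bh_fdr([r.p_summary for r in results], cfg.fdr_q)
        for r, qv, ok in zip(results, qvals, passed):
            r.q_value = float(qv)
            r.passed_fdr = bool(ok)
    chrom_order = {c: k for k, c in enumerate(vt.chroms)}
    results.sort(key=lambda r: (chrom_order[r.window.chrom], r.window.start_pos))
    log["classified_over_dominant"] = sum(r.classification == OVER for r in results)
    log["classified_under_dominant"] = sum(r.classification == UNDER for r in results)
    return ScanResult(results=results, log=dict(log))


# ---------------------------------------------------------------------------
# hybrid-background refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinedWindowResult:
    window: HaplotypeWindow
    grouping: GenotypicGrouping
    mean_hom1: float
    mean_het: float
    mean_hom2: float
    p_kruskal: float
    p_tukey_het_hom1: float
    p_tukey_het_hom2: float
    classification: str
    q_kruskal: float = math.nan
    passed_fdr: bool = False


def refine_background(
    results,
    focal_hybrid: str,
    alt_vt: ioformats.VariantTable,
    design: pd.DataFrame,
    ph: pd.DataFrame,
    cfg: ScanConfig | None = None,
    min_carriers: int = 3,
    condition: str | None = None,
):
    """Background-specific re-analysis of candidate windows.

    Keeps windows whose Het group contains ``focal_hybrid``; re-calls
    haplotypes over the same genomic spans from ``alt_vt`` (a richer
    polymorphism track, e.g. SNPs plus indels); drops windows where the
    focal parents share a haplotype or either focal haplotype has fewer
    than ``min_carriers`` parent carriers; regroups on the focal haplotype
    pair and retests per-hybrid d/a with a 3-group Kruskal–Wallis test and
    Tukey–Kramer pairwise comparisons, BH-corrected over retained windows.

    Returns ``(refined_results, log_dict)``.
    """
    cfg = cfg or ScanConfig(statistic="d_over_a", test="kruskal_wallis")
    row = design[design["diploid_id"] == focal_hybrid]
    if row.empty:
        raise ValueError(f"focal hybrid {focal_hybrid!r} not in the cross design")
    fp1, fp2 = row.iloc[0]["parent1"], row.iloc[0]["parent2"]

    strain_dt = ioformats.strain_means(ph, condition)
    values = hetmetrics.doa_values_for_design(design, strain_dt)

    log = Counter()
    refined = []
    for r in results:
        if focal_hybrid not in r.grouping.het_ids:
            log["dropped_focal_not_heterozygous"] += 1
            continue
        w = r.window
        lo, hi = alt_vt.chrom_bounds(w.chrom) if w.chrom in alt_vt.chroms else (0, 0)
        sel = np.flatnonzero(
            (alt_vt.pos[lo:hi] >= w.start_pos) & (alt_vt.pos[lo:hi] <= w.end_pos)
        ) + lo
        if sel.size == 0:
            log["dropped_no_alt_sites"] += 1
            continue
        labels, carriers = call_haplotypes(alt_vt, int(sel[0]), int(sel[-1]))
        aw = HaplotypeWindow(
            chrom=w.chrom, start_idx=int(sel[0]), end_idx=int(sel[-1]),
            start_pos=int(alt_vt.pos[sel[0]]), end_pos=int(alt_vt.pos[sel[-1]]),
            parents=alt_vt.parents, labels=labels, carriers=carriers,
        )
        l1, l2 = aw.label_of(fp1), aw.label_of(fp2)
        if l1 == l2:
            log["dropped_focal_parents_share_haplotype"] += 1
            continue
        h1, h2 = min(l1, l2), max(l1, l2)
        if carriers[h1] < min_carriers or carriers[h2] < min_carriers:
            log["dropped_haplotype_below_min_carriers"] += 1
            continue
        hom1, het, hom2 = _groups_for_pair(_hybrid_labels(aw, design), h1, h2)
        if min(len(hom1), len(het), len(hom2)) < 2:
            log["dropped_group_too_small"] += 1
            continue
        grouping = GenotypicGrouping(aw.window_id, h1, h2, hom1, het, hom2)
        g1 = values[hom1].to_numpy()
        gh = values[het].to_numpy()
        g2 = values[hom2].to_numpy()
        if np.ptp(np.concatenate([g1, gh, g2])) == 0:
            p_kw = 1.0
            pt1 = pt2 = 1.0
        else:
            p_kw = float(stats.kruskal(g1, gh, g2).pvalue)
            pt1 = two_sample_p(gh, g1, "tukey_kramer")
            pt2 = two_sample_p(gh, g2, "tukey_kramer")
        m1, mh, m2 = g1.mean(), gh.mean(), g2.mean()
        if p_kw < cfg.alpha and mh > m1 and mh > m2:
            cls = OVER
        elif p_kw < cfg.alpha and mh < m1 and mh < m2:
            cls = UNDER
        else:
            cls = NONE
        refined.append(RefinedWindowResult(
            window=aw, grouping=grouping,
            mean_hom1=float(m1), mean_het=float(mh), mean_hom2=float(m2),
            p_kruskal=p_kw, p_tukey_het_hom1=pt1, p_tukey_het_hom2=pt2,
            classification=cls,
        ))
    log["windows_retained"] = len(refined)
    if refined:
        qvals, passed = bh_fdr([r.p_kruskal for r in refined], cfg.fdr_q)
        for r, qv, ok in zip(refined, qvals, passed):
            r.q_kruskal = float(qv)
            r.passed_fdr = bool(ok)
    return refined, dict(log)
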