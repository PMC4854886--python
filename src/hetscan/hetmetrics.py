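"""Heterosis statistics: heterotic value, dominance decomposition, d/a.

Conventions (doubling time DT, hours; smaller DT = faster growth):

* heterotic value — signed fractional DT advantage of a hybrid beyond the
  parental range: ``(FP-Hy)/FP`` when the hybrid beats its faster parent,
  ``(SP-Hy)/SP`` when it trails its slower parent, 0 inside the closed
  parental range.
* dominance decomposition of a locus from its three genotype-class means:
  mid-parent ``m = (hom1+hom2)/2``, additive deviation ``a = |hom1-hom2|/2``
  (reported non-negative), dominant deviation ``d = m - het`` oriented so
  positive d means faster-growing heterozygotes. ``d/a`` is undefined (NaN)
  when the homozygote classes are indistinguishable (a below ``EPS_A``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: homozygote-mean half-difference below which d/a is undefined
EPS_A = 1e-9

ORIENTATION = "faster_positive"


@dataclass(frozen=True)
class HeteroticValue:
    fp: float       # DT of the faster (smaller-DT) parent
    sp: float       # DT of the slower parent
    hy: float       # DT of the hybrid
    value: float    # signed unitless fraction; 0 inside [fp, sp]


@dataclass(frozen=True)
class DominanceDecomposition:
    m: float
    a: float
    d: float
    d_over_a: float          # NaN when undefined (a <= EPS_A)
    scale: str               # "dt" or "log2dt"
    orientation: str = ORIENTATION

    @property
    def d_over_a_defined(self) -> bool:
        return not math.isnan(self.d_over_a)


def heterotic_value(p1_dt: float, p2_dt: float, hy_dt: float) -> HeteroticValue:
    """Heterotic value of one hybrid from strain-level DTs (all > 0)."""
    if min(p1_dt, p2_dt, hy_dt) <= 0:
        raise ValueError("doubling times must be positive")
    fp, sp = min(p1_dt, p2_dt), max(p1_dt, p2_dt)
    if hy_dt < fp:
        value = (fp - hy_dt) / fp
    elif hy_dt > sp:
        value = (sp - hy_dt) / sp
    else:
        value = 0.0
    return HeteroticValue(fp=fp, sp=sp, hy=hy_dt, value=value)


def dominance_decomposition(
    hom1_mean: float, hom2_mean: float, het_mean: float, scale: str = "dt"
) -> DominanceDecomposition:
    """m, a, d, d/a from the three genotype-class means (faster-positive d)."""
    if scale not in ("dt", "log2dt"):
        raise ValueError(f"unknown scale {scale!r}")
    m = (hom1_mean + hom2_mean) / 2.0
    a = abs(hom1_mean - hom2_mean) / 2.0
    d = m - het_mean
    doa = d / a if a > EPS_A else math.nan
    return DominanceDecomposition(m=m, a=a, d=d, d_over_a=doa, scale=scale)


def degree_of_dominance(p1_dt: float, p2_dt: float, hy_dt: float) -> float:
    """Per-hybrid d/a from parental and hybrid DTs (NaN if parents tie)."""
    return dominance_decomposition(p1_dt, p2_dt, hy_dt).d_over_a


def assign_ad_values(hom1_values, hom2_values, het_values):
    """Per-individual a- and d-deviations from the overall mid-parent value.

    ``m`` is the midpoint of the two homozygote class means. Heterozygote i
    gets ``d_i = m - x_i``; homozygote i gets ``a_i = s_c (x_i - m)`` with
    ``s_c = +1`` for the slower-mean (larger-mean) homozygote class and -1
    for the faster, so each class-mean of a_i is non-negative. The pooled
    mean of a_i equals ``|hom1_mean - hom2_mean| / 2`` exactly and the mean
    of d_i equals ``m - het_mean`` exactly.

    Returns ``(a_sample, d_sample, m)``.
    """
    h1 = np.asarray(hom1_values, dtype=float)
    h2 = np.asarray(hom2_values, dtype=float)
    het = np.asarray(het_values, dtype=float)
    if h1.size == 0 or h2.size == 0:
        raise ValueError("both homozygote classes must be present")
    if het.size == 0:
        raise ValueError("no heterozygotes to assign d-values")
    m = (h1.mean() + h2.mean()) / 2.0
    s1 = 1.0 if h1.mean() >= h2.mean() else -1.0
    a_sample = np.concatenate([s1 * (h1 - m), -s1 * (h2 - m)])
    d_sample = m - het
    return a_sample, d_sample, m


def heterotic_values_for_design(design, strain_dt) -> "pd.Series":
    """Heterotic value per hybrid of a cross design.

    ``strain_dt`` maps strain id -> replicate-mean DT and must cover every
    hybrid (by ``diploid_id``) and every parent.
    """
    import pandas as pd

    vals = {}
    for r in design.itertuples():
        vals[r.diploid_id] = heterotic_value(
            strain_dt[r.parent1], strain_dt[r.parent2], strain_dt[r.diploid_id]
        ).value
    return pd.Series(vals, name="heterotic_value")


def doa_values_for_design(design, strain_dt) -> "pd.Series":
    """Per-hybrid degree of dominance (d/a) on the DT scale."""
    import pandas as pd

    vals = {}
    for r in design.itertuples():
        vals[r.diploid_id] = degree_of_dominance(
            strain_dt[r.parent1], strain_dt[r.parent2], strain_dt[r.diploid_id]
        )
    return pd.Series(vals, name="d_over_a")
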