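# Methods

## Scope and model

`hetscan` maps loci whose *mode of inheritance* — not merely allelic
substitution — affects a growth trait. The unit of analysis is a diallel
collection: n homozygous (haploid-derived) parents crossed in all
n(n−1)/2 combinations, each hybrid phenotyped for doubling time (DT) under
one condition. Because heterosis is a property of heterozygosity, the scan
associates *local heterozygosity* (inferred from parental haplotypes) with
a *heterotic phenotype* rather than associating alleles with trait values.

All group comparisons run on log2DT; the heterotic value and the
per-hybrid degree of dominance are computed on the DT scale from
replicate-mean, plate-normalized strain DTs. Both scales are carried in
the phenotype table.

### Heterotic value

Defined piecewise: (FP−Hy)/FP when the hybrid beats its faster parent,
(SP−Hy)/SP when it trails its slower parent, and exactly 0 on the closed
parental interval (a hybrid tying a parent scores 0). Zero-clamping
concentrates the scan's signal in hybrids that exceed the parental range;
roughly half the hybrids carry a zero under realistic conditions, which
the exact-KS machinery treats as ties (conservatively).

### Dominance decomposition

From genotype-class means: m = (Hom1+Hom2)/2, a = |Hom1−Hom2|/2 (reported
non-negative), d = m − Het. The sign convention is *faster-positive*:
because smaller DT means faster growth, a heterozygote below the
mid-parent yields d > 0. The raw "Het − m" form is the negation. d/a is
undefined (NaN, excluded from group summaries) when a ≤ 1e−9 on the
analysis scale, so near-identical homozygote classes cannot contribute
unbounded ratios.

### Per-individual a/d assignment (F2)

With m fixed at the midpoint of the two homozygote class means,
heterozygote i receives d_i = m − x_i and homozygote i receives
a_i = s_c (x_i − m), with s_c = +1 for the slower-mean class and −1 for
the faster, making both class means of a_i non-negative. Identities used
as test oracles: mean(a_i) = |Hom1−Hom2|/2 and mean(d_i) = m − mean(Het),
exactly, for any group sizes.

## The scan

**Windows.** For each SNP start index the window grows from 3 SNPs until
its haplotype partition (exact equality of allele-code vectors) has 2–9
haplotypes *and* at least two haplotypes carried by ≥ 3 parents, up to 10
SNPs; the first admissible span is emitted (windows overlap; duplicates
are dropped). The sliding/growth rule is deliberately the simplest one
that is brute-force checkable; the enumeration is tested against an
exhaustive oracle over all (start, length) pairs. `max_haplotypes` is a
soft bound because observed haplotype counts can exceed the configured
range on real data; lifting it is a config change, not a code change.

**Grouping and testing.** Per window, hybrids whose two parental
haplotypes are (h,h), (h,k), (k,k) for a candidate pair h≠k form
Hom1/Het/Hom2. Candidate pairs are restricted to haplotypes with ≥ 3
parent carriers and groups of ≥ 3 hybrids. Het is compared to each Hom
group with a two-sample KS test; the summary p is the max of the two, so
significance demands differing from *both* homozygous groups. Among
candidate pairs the minimal summary p wins (ties: larger membership, then
label order). Classification requires the Het mean to exceed (over-) or
trail (under-dominance) both Hom means at α = 0.05. BH FDR (q = 0.1) is
applied once across all tested windows of a scan.

Two caveats are inherent to this design and documented rather than
"fixed": (i) selecting the most significant pair and then reporting its p
inflates significance — the null-calibration suite quantifies the net
effect, which remains well below α because the max-of-two summary and the
tie-heavy KS are strongly conservative; (ii) loci whose minor allele is
carried by fewer than 3 parents are structural blind spots: no admissible
haplotype pair can tag them.

KS p-values are exact when both groups have ≤ 25 members (group sizes in a
120-hybrid diallel are small) and asymptotic otherwise. Windows where all
statistic values coincide return p = 1.

**Background refinement.** Candidate windows containing one focal hybrid
in their Het group are re-called from a richer polymorphism track (e.g.
SNPs + indels encoded as extra allele-coded sites — the downstream algebra
is identical, so no alignment parsing is needed), dropped when the focal
parents share a haplotype or either focal haplotype has < 3 carriers, then
retested on per-hybrid d/a with a three-group Kruskal–Wallis test and
Tukey–Kramer pairwise comparisons, BH-corrected over the retained set.

## Population validation

* **BC1**: Wilcoxon rank-sum (Mann–Whitney) between local heterozygotes
  and the single available homozygote class, on log2DT.
* **F2 three-group**: Tukey–Kramer across Hom1/Het/Hom2 with compact
  letter displays computed from maximal cliques of the
  not-significantly-different graph.
* **Mode of inheritance**: the a-sample and d-sample are compared with a
  Wilcoxon rank-sum test by default (a t-test variant is available; both
  agree in direction for clear effects). The "d ≈ 0" part of the
  co-dominant call uses a Welch t-test of the linear contrast
  μ_Het − (μ_Hom1+μ_Hom2)/2 rather than a one-sample test of the d-values:
  the one-sample form ignores the sampling error of the estimated
  mid-parent and rejects a true d = 0 at roughly 3–4× the nominal rate at
  n = 300. Calls: co-dominant (d≈0 and significantly < a), over-dominant
  (d > a, significant, d > 0), under-dominant (d < 0, |d| > a,
  significant), otherwise dominant.
* **Epistasis by heterozygote exclusion**: the focal locus decomposition
  is recomputed on the subset without conditioning-locus heterozygotes.
  The significance of the d change is assessed as a two-sample contrast of
  focal-heterozygote deviations (from the full-population mid-parent)
  between the conditioning-Het and conditioning-Hom strata — a
  "full set vs subset" comparison uses overlapping samples and has no
  valid two-sample null, while the stratified form tests the identical
  interaction contrast. Direction is synergistic when d_full > d_excl with
  a significant change; the analogous a-contrast is expected null for
  purely het×het interactions and is reported as a specificity check.
* **Replacement factorial**: two-way fixed-effects ANOVA of log2DT on
  genotype × background with interaction; a significant interaction
  triggers per-background Tukey–Kramer letter comparisons.

## Synthetic data

The generator emulates the study designs end to end with a planted truth:

* **Parents** are mosaics of a small number of founder haplotypes
  (default 4) with geometric block lengths (mean 5 SNPs), every site
  biallelic and polymorphic among founders. This produces windows with
  2–7+ local haplotypes — the structure the grouping logic needs — unlike
  i.i.d. SNPs.
* **Meiosis**: each tetrad consists of two independent complementary
  chromatid pairs; one member of a pair takes parent-1 alleles exactly
  where the other takes parent-2, so 2:2 segregation holds exactly at
  every site. Crossovers are Poisson per chromosome (default mean 1, a
  free parameter — no attempt is made to fit a genetic map), breakpoints
  uniform over inter-SNP intervals, no interference (flag reserved).
* **Phenotypes**: log2DT = baseline + Σ locus effects (per genotype) +
  Σ γ·1[both loci heterozygous] + N(0, σ²); DT = 2^log2DT × plate factor.
  Defaults: baseline 1.5 (DT ≈ 2.8 h, a realistic doubling time for
  stressed growth at 37 °C), σ = 0.05 log2DT per replicate, 3 replicates,
  planted over-dominant effect −0.15 log2DT on the heterozygote (≈ 5× the
  strain-level noise — a clear but minor effect), synergy γ = −0.1.
  Plate effects are multiplicative on DT, matching the reference-strain
  ratio normalization. Planted loci are placed at sites whose minor allele
  is carried by ≥ 5 parents (`pick_balanced_site`), since skewed sites are
  unmappable by construction.
* **Crosses**: the diallel is all unordered parent pairs; BC1 crosses
  every F1 spore to one parent; the F2 mates two disjoint spore subsets
  (default 16 × 24 → 384 diploids) in all between-subset pairs.
  Mating-type and drug-marker bookkeeping is abstracted to "two disjoint
  subsets"; cross failures/viability are not modeled.

What passing tests on these data do **not** show: the simulator has no
growth-curve measurement error structure, no mitochondrial or mating-type
genetics, no population structure among parents beyond founder mosaics,
and phenotype noise is homoscedastic Gaussian on log2DT. Absolute window
counts and candidate counts from real genome-scale data are therefore not
reproduced — at the simulated scale a scan tests a few hundred windows,
not tens of thousands.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere (VCF convention); the BED
  export is 0-based half-open.
* Sites with missing parental genotypes are dropped on load and counted
  (the scan needs complete haplotype calls per window).
* Plate normalization multiplies each plate's DTs by
  (global reference mean)/(plate reference mean), per condition; it is
  idempotent and preserves within-plate ratios exactly. A plate without
  the reference strain is an error naming the plate.
* Haplotype labels are dense integers ordered by descending carrier count
  (ties by first occurrence), so label 0 is always the most frequent
  local haplotype and relabeling is stable under parent-column
  permutations (as a partition).
* Degenerate inputs: identical values in both test groups return p = 1;
  windows with no admissible haplotype pair return no result rather than
  an error; d/a is NaN when a is numerically zero.
* Test problem sizes (two 150-SNP chromosomes, 10–20 seeds per Monte-Carlo
  claim, 384-diploid F2) were chosen so the full validation suite
  exercises every stage at statistically meaningful power while remaining
  quick to run on a laptop; all Monte-Carlo acceptance thresholds carry
  binomial slack consistent with the seed counts used.

## Known limitations

* The scan's selection-then-test step means reported per-window p-values
  are not calibrated individually; only the pipeline-level false
  classification rate is (and is verified by simulation).
* The KS test on zero-inflated heterotic values relies on tie-handling
  conservatism; power against small shifts is accordingly limited.
* Pseudo-over-dominance (linked dominant loci in repulsion) is
  indistinguishable from true over-dominance at window resolution and is
  not modeled or decomposed.
* BC1 analyses compare only the two locally available genotype classes;
  reciprocal backcrosses are reported side by side, never pooled.
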