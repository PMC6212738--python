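# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package, in the order the pipeline runs them.

## Trait derivation

Six reproduction traits are computed from litter-level sow records, one
aggregated record per sow:

* PWL, BAL — pigs weaned and born alive, totals divided by litter count.
* W2CL — mean wean-to-conception interval; an open last litter (no
  recorded interval) is excluded from numerator and denominator.
* LSY — litters per sow per year: (total gestation days / 115) /
  (herd days / 365). Scaling all day counts and herd days by the same
  factor leaves LSY invariant.
* PWSY — defined as LSY × PWL; the output table satisfies this identity
  exactly.
* NPD — non-productive days. The defining phrase is grammatically
  ambiguous; the default reading is 365 − (mean productive days per
  litter) × LSY, which stays in [0, 365] for plausible records and agrees
  with LSY ≈ (365 − NPD)/cycle length. The literal left-to-right reading
  (365 − total productive days) × LSY is available through
  `npd_formula="literal"`. Neither is asserted as canonical; NPD values
  outside [0, 365] are flagged, never clamped.

Fixed-effect levels (farm, parity, farrow month/year) come from the last
litter, matching the model's "last farrow-month, last farrow-year, last
parity and farm" factors.

## Genotype quality control

Filter order is fixed: (1) SNP call rate, (2) sample call rate, (3) MAF,
(4) monomorphic markers, (5) Mendelian conflicts — each on the survivors
of the previous step, so MAF reflects retained samples. Defaults: call
rates 0.90, MAF 0.05, conflict rate 0.01. A Mendelian conflict is an
opposite-homozygote parent/offspring pair; a conflicted pair removes the
*offspring* (the parent may anchor other progeny). The order and the
offspring rule are this package's choices where chip-QC practice varies;
both are configurable. Removal bookkeeping is a partition: every input
marker/sample is either kept or removed with exactly one primary reason.

## Relationship matrices

* A: tabular method with inbreeding; A⁻¹: Henderson's rules with
  Meuwissen–Luo inbreeding coefficients (no dense A formed on that path).
* A22: subset of the dense A over genotyped animals; its inverse is taken
  from the dense block itself — subsetting A⁻¹ would be wrong.
* G = ZDZ'q with z_ij = code − 2p_j, missing calls mean-imputed (centered
  zero; QC caps missingness first), and p from the current genotyped
  population — no base-population correction, matching the frequency
  definition the scan uses.
* The scale q is applied in two stages: a base division by
  Σ_j d_j 2p_j(1−p_j), so that reweighting D preserves the overall scale,
  then a factor matching mean(diag G) to mean(diag A22). Both constants
  are recorded on the returned object.
* Blending G ← (1−τ)G + τA22 with default τ = 0.05 before inversion. This
  is not cosmetic: with current-population frequencies the centered
  genotype columns sum to exactly zero, so unblended G annihilates the
  all-ones vector and is singular by construction. τ = 0 is accepted for
  matrix construction (the unblended G is also what back-solving uses) but
  inverting it raises an error that points at blending.

## Mixed model and EM-REML

Henderson's equations are assembled dense, single- or multi-trait (trait
Kronecker structure Σ_a⁻¹ ⊗ K⁻¹); a symmetric factorization with a
pseudo-inverse fallback handles rank-deficient fixed blocks. Fixed factors
are one-hot coded against the first-observed level; estimable functions,
and hence REML estimates and GEBVs, are invariant to that choice (tested).

EM-REML was chosen over AI-REML: derivative-free, monotone in the
restricted likelihood, and adequate at the package's problem sizes; AI
acceleration is a natural extension. Updates: σ²_a ← (û'K⁻¹û +
tr(K⁻¹C^{uu}))/q with C^{uu} in variance units, residual via the classic
y'(y − Xβ̂ − Zû)/(n − rank X) form (symmetrized across traits in the
multivariate case). Convergence: relative parameter change < 1e-8, at most
1000 rounds, non-convergence flagged on the result rather than raised.
Components are floored at 1e-10 σ²_p for numerical safety; EM itself keeps
them non-negative.

Two code paths share these updates. The generic dense path rebuilds and
inverts the coefficient matrix each round. When a single trait is analyzed
and every animal has exactly one record, a canonical-decomposition path
absorbs the fixed block once, diagonalizes L⁻¹SL⁻ᵀ (K⁻¹ = LLᵀ,
S = I − X(X'X)⁺X') and iterates in O(n²) per round; the two paths agree to
6+ digits (tested) and the canonical path was additionally verified
against direct Nelder–Mead maximization of the restricted likelihood.

Multi-trait runs require identical record sets across traits (the
simulator produces balanced data). The unbalanced multi-trait analyses of
field datasets are approximated by this balanced design — a documented
limitation.

## The weighted scan

Per trait: D = I → build G → solve the single-step model → back-solve
û = qDZ'G⁻¹â_g → reweight d_i = û_i²2p_i(1−p_i) → normalize Σd_i = m →
rebuild G → repeat (two rounds by default; zero rounds gives classical
unweighted effects). Variance components stay fixed across rounds — the
weights change G, not σ². Each trait drives its own weight trajectory and
re-solves the multivariate system with its own weighted G, preserving
per-trait region semantics.

Back-solving always uses the *unblended* G: blending is a numerical device
for H⁻¹, not part of the SNP-effect map. Because the unblended G is
exactly singular with null space span{1} (see above), GEBVs are
mean-centered across the genotyped animals first — breeding values are
defined only up to the base — and the solve is deflated on the null
direction (G + mean(diag G)·11'/n), which equals the Moore–Penrose action
on the orthogonal complement of 1. The reconstruction identity then holds
to machine precision in the form Zû = â_g − mean(â_g); an exact Zû = â_g
is mathematically impossible with current-population frequencies, and the
tests assert the centered form at 1e-8. A ridge option (G + εI) exists for
ill-conditioned cases.

Window scoring: for every chromosome with at least `window_size` (default
5) markers, every start index gives a window; windows never span
chromosome boundaries. pct = 100 · Var(Σ_{j∈window} z_jû_j)/σ²_a over
genotyped animals, sample variance (ddof = 1). The denominator is the REML
total additive variance by default; `denominator="empirical"` uses
Var(Zû), under which a single all-marker window scores exactly 100%.
Selection keeps windows ≥ 1% (inclusive), merges overlapping windows per
trait into regions, and reports each region at its best window's percent.
No p-values are computed anywhere: the 1% rule is a screening threshold
and its null exceedance rate is data-dependent (the worked example in the
README shows typical null regions at small n).

## Annotation

A selected SNP inside a gene interval is "within-gene"; otherwise the
nearest gene boundary on the chromosome within 2.0 Mb gives an
upstream/downstream call with its distance; ties go to the smaller start
coordinate. "Upstream" means the SNP precedes the gene start in chromosome
coordinates — a fixed convention that ignores strand, chosen because
published region tables use the coordinate sense loosely and a package
must pick one and document it. Distances print in kb truncated (not
rounded) to two decimals, matching the convention of the tables this
report format mirrors. BED input is converted to 1-based inclusive
coordinates on ingest; GFF3 is taken as-is; everything internal is 1-based
inclusive.

## The synthetic generator

What it emulates: discrete non-overlapping generations under random
mating with a configurable boar fraction (commercial herds run few boars
against many sows); chip-style biallelic markers with founder MAF drawn
uniformly from a range, gene-dropped through the pedigree with Poisson
recombination along each chromosome (Haldane map, default 1 Morgan —
without linkage, 5-SNP windows would be uninteresting); a genotyped subset
filled from the youngest generation backwards; missing calls at a flat
rate; six correlated traits whose default additive/residual covariances
and correlation structure follow published Large White sow estimates
(heritabilities 0.07–0.25, the near-perfect negative LSY–NPD correlation);
categorical fixed effects with level effects scaled to fractions of the
phenotypic SD (farm 0.25, parity 0.15, month/year 0.10); and planted QTL
whose Hardy–Weinberg variance is carved out of the target additive
covariance, the remainder realized by the Mendelian-sampling recursion
(founders ~ N(0, Σ_poly); non-founders: parent average plus a deviation
with variance (0.5 − 0.25(F_s+F_d))Σ_poly).

Because printed, rounded correlation tables are not exactly positive
semi-definite, the default covariance targets are eigenvalue-clipped to
the nearest PSD matrices.

What it does not emulate — and hence what passing tests do not show about
real data: ancestral linkage disequilibrium (founders are in linkage
equilibrium, so marker LD is family-derived only), selection, overlapping
generations, genotyping-batch effects, unbalanced trait recording, and
herd-specific litter or culling distributions (the sow-record layer's
gestation ≈ 115 d, lactation ≈ 24 d, truncated-Poisson litter counts are
plausible defaults, deliberately not calibrated to any particular herd).

Determinism: one global seed; each stage draws from its own
`default_rng([seed, stage])` stream in a documented order, so the full
data triple is bit-for-bit reproducible and phenotype generation can
re-materialize the complete gene-dropped matrix independently of the
observed subset.

## Problem sizes used by the test suite and acceptance script

The algebra/identity suites run 20 simulations of ~120 animals, 60–100
genotyped, 200 markers. The heritability-recovery experiment uses 250
full-sib families of four with phenotyped parents (n ≈ 1500), the most
informative n≈1500 design found by an exact Fisher-information analysis
(0.5·tr(PV_iPV_j) with the delta method): across all family structures
reachable at that size — family sizes 2–10, boar:sow ratios down to 1:10,
one to three generations — the asymptotic SE of ĥ² is 0.042–0.052. Single
replicates therefore scatter roughly ±0.1 around the true 0.25 even
though the estimator is exact REML; the *mean* across 20 replicates
recovers h² to ±0.02. Pushing the per-replicate scatter below ±0.06 with
high probability would require n ≈ 5000+, outside the desk scale this
package targets. The QTL-detection experiment uses 600 animals, 450
genotyped, 500 linked markers and one common-variant QTL (planted at the
marker with founder MAF nearest 0.35; a rare-allele QTL tests MAF, not the
method) at 20% of additive variance: after two weighting rounds the QTL's
window is the top-ranked window genome-wide in ~9 of 10 seeds.

## Known limitations

* Dense linear algebra throughout: intended for up to a few thousand
  animals and tens of thousands of markers, not national evaluations
  (no APY, no iteration-on-data).
* No permanent-environment/repeatability, maternal, or dominance effects;
  no unknown-parent groups or metafounders.
* EM-REML converges slowly near variance boundaries (expected for EM);
  the non-convergence flag, not an exception, reports it.
* Multi-trait REML requires balanced records across traits.
* Annotation is strictly local-file based; no network lookups.
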