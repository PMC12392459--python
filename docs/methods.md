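# Methods

## Scope and model

`fastgrowth` analyses the output of unidirectional nonequilibrium ("fast
growth") alchemical solvation calculations: for each solute/solvent leg, an
ensemble of N per-trajectory recoupling work values W_i (kcal/mol) produced by
switching on the solute–solvent interactions along a common schedule, usually
in two stages — Lennard-Jones switching (W_lj) followed by recharging (W_qq).
Everything upstream of the work values (MD, QM charge derivation, solvent
parameterization) is out of scope; the package starts at plain-text work
files and CSV tables.

Three estimators of the solvation free energy are implemented:

* **Jarzynski**: ΔG = −RT ln⟨e^{−βW}⟩, β = 1/(RT), R = 1.987204×10⁻³
  kcal mol⁻¹ K⁻¹. Valid for any work distribution but strongly biased at
  finite N when βσ is large, because the average is dominated by the rarely
  sampled low-work tail.
* **Crooks-Gaussian**: ΔG = ⟨W⟩ − βσ²/2, exact when P(W) is normal. σ² is the
  unbiased (N−1) sample variance; at N = 200 the biased/unbiased distinction
  is far below the statistical error, but one convention must be fixed and
  the confidence-interval formula uses the same σ.
* **Convolution**: when the two stage works are independent random variables,
  the total-work distribution is the convolution of the stage distributions,
  and applying Jarzynski to all N_lj·N_qq pairwise stage sums samples the
  low-work tail far better than the N direct totals. The double exponential
  sum factorizes into the product of the per-stage averages, so the estimate
  is computed as the *sum of per-stage Jarzynski estimates* — exact, O(N),
  and never materializes the N² array. Stage independence can be checked
  empirically with `stage_independence` (Pearson ρ and Kendall τ-b on the
  paired stage works).

## Estimator selection

`select_estimator` applies an Anderson–Darling normality gate to the
per-trajectory **total** works (W_lj,i + W_qq,i when stage-resolved input is
given):

1. A\*² < 0.34 (p ≈ 0.5) — the ensemble is comfortably normal: Gaussian
   estimate.
2. 0.34 ≤ A\*² ≤ 0.754 — borderline: keep the Gaussian estimate only if it
   agrees with the Jarzynski estimate on the same totals to within
   0.2 kcal/mol; the gap is recorded in the result.
3. Otherwise — convolution estimate; this branch requires stage-resolved
   works and raises a descriptive error without them.

The A\*² statistic is the normality Anderson–Darling statistic with both
parameters estimated from the sample and the small-sample modification
A\*² = A²(1 + 0.75/N + 2.25/N²). It is affine invariant, needs N ≥ 8, and is
undefined for zero-variance samples; constant ensembles short-circuit to the
Gaussian branch (where ΔG equals the common work value exactly). All three
thresholds live in `DecisionPolicy` and are overridable.

Numerical choices: every exponential average goes through max-shifted
log-sum-exp; the normal CDF values inside A\*² are clipped to
[1e−300, 1−1e−16] to keep the logs finite for extreme standardized values.

## Confidence intervals

For Gaussian estimates the 95% half-width is the analytic

    δΔG = z · ( σ/√n + β σ²/√(2n) ),   z = 1.96.

The first term is the standard error of ⟨W⟩; the second follows from
Var(s²) ≈ 2σ⁴/n for normal samples via the delta method applied to βs²/2.
The two terms are summed (not combined in quadrature), which makes the
interval deliberately conservative: at σ = 2 kcal/mol, N = 200, T = 300 K its
true coverage is ≈99% rather than 95%. The test suite measures 98.2%
empirical coverage over 500 replicate ensembles.

For convolution/Jarzynski estimates, each stage is resampled with replacement
B = 1000 times, the Jarzynski estimate recomputed per replicate, and the
stage error taken as z·sd(replicates); the two stage errors add in
quadrature. Each stage's resampling stream is seeded from (seed, content
hash), so the half-width is reproducible and exactly invariant under
exchanging the stage labels. A percentile-bootstrap variant is available via
`CIConfig(percentile=True)`.

**Limitation**: the bootstrap tracks the true sampling spread of the
Jarzynski estimator only in the near-linear regime (βσ ≲ 1). For strongly
dissipative ensembles (βσ ≈ 1.7, e.g. unit-variance works at 300 K) the
exponential average is heavy-tailed and the bootstrap is systematically low —
we measured a mean bootstrap/Monte-Carlo ratio of ≈0.75 with large
seed-to-seed scatter. The Monte-Carlo agreement test therefore runs at
σ = 0.3 kcal/mol; half-widths reported for strongly dissipative data should
be treated as lower bounds (which is also why the decision tree prefers the
Gaussian estimate whenever the ensemble supports it).

## LogP assembly

LogP = (ΔG_w − ΔG_o)/(RT ln 10); the octanol→water transfer free energy is
LogP·RT ln 10 (≈1.372 kcal/mol per LogP unit at 300 K — the factor is always
computed from the temperature, never the rounded 1.37). Half-widths of the
two legs propagate in quadrature, the legs being independent calculations.
Compounds missing a leg are skipped with a warning. All solutes are assumed
neutral; no ionization-state correction is applied.

## Benchmark metrics

`metric_row` computes the seven-number summary used for solvation benchmarks,
with these fixed conventions:

* **MSE** = mean(experimental − calculated): a method that overestimates the
  magnitude of negative free energies gives positive MSE.
* **Regression**: OLS of calculated (y) on experimental (x).
* **CCC** (Lin): 2·cov/(var_x + var_y + (x̄−ȳ)²) with population (1/n)
  moments; satisfies |CCC| ≤ |ρ| and penalizes departures from the identity
  line, unlike ρ.
* **Kendall τ**: τ-b (tie-corrected; equals τ-a without ties).

Named outliers can be excluded (recorded in the result); exclusion below
n = 3 is an error. `ccc_matrix` gives the symmetric pairwise-CCC matrix
across protocols.

## Packaged benchmark and `reproduce`

The package ships an 11-compound neutral-solute benchmark: experimental and
computed ΔG_w/ΔG_o under four fixed-charge protocols (AM1/BCC,
RESP/HF/6-31G*, RESP-QM/MM, ABCG2), the published per-protocol LogP table,
and the published metric rows. `fastgrowth reproduce` re-derives the LogP
column of a chosen protocol from the free-energy legs and recomputes all
metric rows, comparing each cell with the published value at ±0.02 (LogP
entries) and ±0.015 (metrics). The published tables are printed at two
decimals while they were evidently derived from unrounded inputs, so
re-derived values can shift by one unit in the last digit; the tolerances
absorb that. The AM1/BCC rows are reported but not gated: that protocol's
free energies were imported into the benchmark from an earlier study at
different precision, and its published LogP column is not reproducible from
the packaged legs (deviations up to ~1 LogP unit).

## Conformer charge arithmetic

Charge sets fitted on individual conformers are combined by unweighted
averaging (with a per-atom relative spread report, δq/|q̄|; 0.03–0.06 is
typical) or by a population-weighted convex combination (weights must be a
simplex point to 1e−6), e.g. 0.67·Q_compact + 0.33·Q_extended when two
conformational basins were charged separately. Net charge is exactly linear
under combination; no renormalization to integer net charge is applied
(an explicit `check_net_charge` helper exists for validation). Per-atom-type
mean charges support protocol comparisons.

## Synthetic generator

`synthetic_data` replaces the MD stages for validation:

* `gen_normal_works(dG*, σ, n, T, seed)` samples N(dG* + βσ²/2, σ²), making
  dG* the exact free energy (the Crooks-normal relation inverted).
* `MixtureSpec` defines a Gaussian-mixture work distribution whose exact free
  energy is closed-form via the per-component lognormal moment identity;
  well-separated components produce the skewed, non-normal ensembles that
  exercise the convolution branch.
* `gen_stage_works` couples two mixture marginals through a Gaussian copula
  at a requested correlation (0 → independent stages) without distorting the
  marginals; the mixture inverse CDF is solved by bracketed root finding.
* `gen_benchmark_table` draws "experimental" legs uniformly over the spans of
  the packaged benchmark (ΔG_w ∈ [−12,−1], ΔG_o ∈ [−18,−3] kcal/mol) and adds
  N(bias, noise²) per leg to make "calculated" values, defaulting to
  0.3 kcal/mol noise — the typical reported uncertainty of a 200-trajectory
  leg.

Defaults are N = 200 trajectories at T = 300 K. All generators are
bit-reproducible under a fixed seed.

What the generator does **not** emulate: trajectory-level time correlation,
soft-core switching artifacts, finite-size solvent effects, or any coupling
between the two stages beyond the copula rank correlation. Passing tests on
synthetic data therefore validate the estimator/statistics stack, not the
simulation protocol upstream of it.

## Validation problem sizes

The test suite uses N = 200 ensembles for routing and CI checks, 10⁵ draws
for law-of-large-numbers convergence checks (mixture Jarzynski within
0.05 kcal/mol of the closed form), 500 replicate ensembles for bias/coverage
measurement, 1000 random stage pairs for the convolution-factorization
property (tolerance 1e−10 kcal/mol), and 1000 bootstrap/fresh-sample
replicates for CI calibration. The whole suite runs in well under a minute.
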