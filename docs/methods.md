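# Methods

## Kinetic model and the relative-rate scale

Per-cell transcript abundance after transcription arrest is modeled as
first-order decay, `m_gi(t) = m_gi(0)·2^(−k_abs_gi·t)`, with rates in
log2-units/hour so that the regression runs directly on log2 intensities
(half-life = `1/k_abs` h; no ln↔log2 conversions anywhere).  Equal-mass
hybridization means the array measures each transcript's share of the pool:
`log2 m_gi(t) − log2 M_i(t)` up to a constant, where `M_i(t)` is the
per-cell pool mass.  Because the pool declines at the mean cellular rate λ̄,
the measurable slope is the *relative* rate `k = k_abs − λ̄`; a transcript
decaying at exactly the cell-wide average traces a flat profile.  λ̄ is not
lost: it is recovered from the harvest design as minus the OLS slope of
`log2(yield/cells)` on time.

Estimation is plain OLS of log2 intensity on time (5 points: 0, 0.5, 1, 2,
4 h), `k = −slope`, with the slope's t-test (n−2 = 3 df) as the
per-fit significance.  No heteroscedasticity weighting is applied — the
design gives no weights — and the per-individual test behind the fast/slow
classification is the same OLS t-test, the standard reading of "k
significantly different from zero".  Zero-residual series are flagged as
exact fits (se = 0; p = 0, or 1 for a perfectly flat line).  Missing fits
are excluded from the 80%-of-individuals denominator of the classification.

## What the synthetic generator emulates (and what it does not)

`synth.simulate_study` reproduces the study design end to end: a panel of
individuals assayed at the five harvest times, increasing cell numbers
(default `⌈10⁶·2^(λ̄t)⌉`, offsetting pool decay so equal RNA mass is
available), equal-mass measurement, Gaussian log2 array noise, genotypes
with planted cis effects, and a design table whose yields encode λ̄ exactly.
Key choices, each a field of `SimConfig`:

- **λ̄ = 0.3 log2-units/h** (pool half-life ≈ 3.3 h), typical of
  mammalian cell lines.
- **Array noise σ = 0.2 log2** per observation.  The emulated platform's
  noise level is not fixed by the design, so this is a package default,
  exposed in the config.
- **Rate variation is log-normal** (`sd_log2_k_gene = 0.6` across genes,
  `sd_log2_k_individual = 0.1` across individuals): rates are positive scale
  parameters, and additive Gaussian spreads would cross zero.
- **Planted decay QTLs** shift `k_abs` additively by `decay_effect_a` per
  minor allele with a random sign.  Genes receiving a negative effect get a
  baseline-rate floor of `2|a|·2^(5·sd_ind) + 0.05` so every individual's
  rate stays positive to 5σ of individual variation; a final validation
  still rejects any configuration that produces a non-positive rate.
- **Steady-state coupling**: baselines obey `m(0) = transcription/k_abs`,
  so a pure decay QTL automatically induces a concordant expression effect.
  `coupling_rho` plants a proportional transcription effect,
  `b = ρ·[2/(λ̄·ln2)]·a` log2 units per allele — a deterministic scaling
  rather than a noisy correlation, because ρ = 0 must yield *pure* decay
  QTLs; the net allelic expression effect flips sign (discordance) around
  ρ ≈ 0.5.
- **Two mean-rate modes**: `"exact"` imposes λ̄ (clean identities — the
  noiseless estimator recovers planted rates to 1e-10), `"pool"` lets λ̄
  emerge from the simulated transcript pool (realism checks, e.g. a
  single-rate transcriptome measures k ≡ 0).  Default `"exact"`.
- **Genotypes** are independent biallelic variants, Binomial(2, f) with f
  uniform in `maf_range`, folded to cohort-minor coding; monomorphic draws
  are redrawn.  No linkage disequilibrium is simulated — nearby-variant
  hitchhiking in the scans comes only from finite-sample correlation.

Features of real data the generator does **not** emulate: probe-level bead
variance and background (the detection mask is generated, not modeled),
LD structure, imputation uncertainty, batch effects, and transcriptome-scale
array distributions (see the quantile-normalization caveat below).  Passing
tests therefore validate the estimators and their calibration under the
stated design, not robustness to those artifacts.

## Preprocessing

Across-array quantile normalization (ties get averaged ranks; all-constant
arrays are left unchanged; fractional tied ranks interpolate the reference)
replaces the platform-specific variance-stabilization internals of the
original arrays: the estimator only needs comparable scales across the
5·N arrays.  **Caveat**: with genome-scale features (~20k probes) the
common-distribution assumption is mild, but on few-hundred-gene synthetic
cubes forcing identical array distributions erases real inter-individual
slope differences and attenuates planted effects — truth-recovery analyses
therefore run on the un-normalized cube, and the pipeline exposes
`quantile_normalize` as a switch.

Detection filtering keeps features detected in ≥ 80% of individuals at the
untreated harvest AND at the final harvest (both thresholds share
`min_frac`, boundary inclusive).  Probe→gene aggregation is the unweighted
mean.  The SNP-in-probe correction regresses the per-individual steady-state
vector (only — not each time point) on the in-probe dosage and substitutes
centered residuals when the slope is significant at 0.05.

## Association and FDR

Permutations reshuffle individual labels of the decay matrix consistently
across genes within a permutation, preserving the gene-gene correlation
structure of decay — the conservative choice.  Permuted p-values are pooled
into one empirical null; `FDR(t) = [#null ≤ t / n_perms] / max(1, #obs ≤ t)`
and per-gene q-values are the running minimum, clipped to [0, 1].  The
default is 3 permutations (matching the emulated study); Monte Carlo
analyses here use 20.  Tail overlap uses nearest-rank quantiles with strict
exceedance, so ties at the boundary fall outside the tail.

## QTL mapping

Hidden confounders are removed by regressing each gene on the top
eigenvectors of the individual×individual **correlation** matrix of the
phenotype (13 by default, capped at n−2 in small panels; the desk-scale
analyses in `scripts/acceptance.py` use 2, matched to their 50-individual,
200-gene studies).  Note a limitation of correlation-matrix PCA: column
standardization reduces a rank-one confounder with unequal per-individual
magnitudes to its sign pattern, so such a confounder is only fully removed
when its magnitudes are equal.  PCs are estimated once and **not**
re-estimated inside permutations; permutations shuffle the residualized
phenotype (the standard, cheaper choice).

Windows span 25 kb beyond both transcript ends; BED half-open annotations
are converted to 1-based inclusive bounds before comparison with VCF
positions (the single conversion point is `qtl.cis_window`).  Boundary
positions are included; the MAF filter is strict (> 0.10).  Only additive
models are fit; the expression phenotype is rank-inverse-normal transformed
per gene before PC correction (standard eQTL practice), the decay phenotype
is left on its natural scale.  Trans mapping is not implemented.

At joint QTLs, "concordant" means opposite signs of the expression and
decay effects at the same variant under the same minor-allele coding (the
allele lowering expression speeds decay); a zero effect is "undefined".

## Overlap toolkit

`min_p_transform` is the order-statistic CDF `1 − (1 − min(p_a, p_b))²`,
the unique monotone transform making the minimum of two independent uniform
p-values uniform under the joint null.  **This closed form is a
reconstruction**: it is the package's choice of calibration for the
two-phenotype minimum, stated here rather than inherited.

`pi0_storey_bootstrap` evaluates `π0(λ) = #{p > λ}/(m(1−λ))` on the grid
0, 0.05, …, 0.95 and picks λ minimizing the bootstrap MSE against the 0.1
quantile of π0(λ) over the grid — the formulation in the released `qvalue`
software.  Targeting the plain grid minimum instead biases π0 downward
under a full null (measured: ~3% of full-null draws fell below 0.95; the
quantile target kept 40/40 above, with mixture recovery unchanged).  The
estimate is clipped to [0, 1] with a percentile bootstrap CI at the
selected λ.

Overlap arithmetic is hypergeometric: expectation `n_a·n_b/n_total`, upper
tail for enrichment, and union fractions reported as percent to one decimal.

## Numerical notes and known limitations

- All OLS paths share one closed-form routine (`_regression.ols_slope`)
  verified against statsmodels to 1e-10; exact fits are detected at
  relative residual 1e-12.
- Randomness flows from one root seed through `numpy.random.SeedSequence`
  spawns; identical configurations reproduce bit-for-bit, and the pipeline
  manifest records input hashes, seed and parameters.
- The Monte Carlo analyses use 200-gene × 50-individual studies with 20
  replicates and 20 permutations — sizes chosen so each summary is stable
  at the tolerances tested while the whole suite stays desk-scale.
- With the default σ = 0.2 and the 0/0.5/1/2/4 h design, the per-fit slope
  sd is σ/√10 ≈ 0.063, so the per-entry mean absolute error of k̂ is
  ≈ 0.050 log2-units/h analytically; recovery is unbiased (|bias| < 0.001).
- The detection mask in the generator is a simple intensity threshold;
  real platforms derive detection from negative-control beads, which is out
  of scope (the mask is an input to the filter, however produced).
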