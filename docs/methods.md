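# Methods

`abcmk` estimates the proportion of amino-acid substitutions fixed by
positive selection (α), split into weakly (αW) and strongly (αS) beneficial
components, together with the deleterious distribution of fitness effects
(DFE), from pooled polymorphism and divergence counts. The engine is a set
of analytic expectations under an equilibrium Wright–Fisher model, wrapped
in a Poisson sampling scheme and an ABC loop. This note records the model,
the numerical conventions, and the places where the design was genuinely
open.

## Model

New nonsynonymous mutations fall into three fitness classes:

* **deleterious**, with population-scaled coefficients −2Ns drawn from a
  Gamma distribution with shape `gam_shape` (default 0.184) and mean
  magnitude `gam_mean` (default 457). The shape below 1 concentrates mass
  near zero, so this class carries the nearly-neutral spectrum as well;
  no separate neutral nonsynonymous class is needed.
* **weakly beneficial**, a point mass at 2Ns = `s_weak` (default 10),
* **strongly beneficial**, a point mass at 2Ns = `s_strong` (default 500).

Synonymous mutations are neutral. All coefficients are stored as positive
scaled magnitudes with the sign applied at class level.

### Frequency spectra

The expected density of derived alleles at population frequency x for a
point coefficient is the standard equilibrium diffusion result

    psi(x; S) = theta / (x(1-x)) * (e^S - e^{Sx}) / (e^S - 1),  S = 4Ns,

evaluated on the grid x = i/2N, i = 1..2N−1. The three algebraic branches
implemented (S < 0, S > 0, |S| → 0) each keep every exponent non-positive,
so the evaluation is overflow-free for arbitrarily strong selection and the
neutral limit θ/x is taken analytically. A useful exact identity,
psi(x; S) + psi(1−x; −S) = θ/(x(1−x)), is used as a property test.

The deleterious class integrates the point spectrum over the Gamma DFE by
fixed-order Gauss–Legendre quadrature in the quantile domain (128 nodes),
which absorbs the density singularity at zero that small shapes produce.
Sample spectra are the binomial projection of the population spectrum onto
2n chromosomes; the projection matrix is cached per (N, n). The projection
is deliberately applied even when n = N — it carries the sampling variance
of the sequencing sample.

### Fixation rates

Per nonsynonymous mutation the expected fixation rates are

* neutral: 1/(2Ne),
* deleterious: the Gamma-average of Kimura's fixation probability, which
  telescopes into a closed form in the Hurwitz zeta function. Writing
  β = shape/mean for the Gamma *rate* over |2Ns| (0.184/457 ≈ 4.02e−4),

      E[d−] = 2^−a B^−a β^a [ ζ(a, 1 − 1/(2NB) + β/2B) − ζ(a, 1 + β/2B) ],

  with a the shape and B the background-selection strength. scipy's zeta
  does not cover exponents below one, so the analytic continuation is
  implemented in `abcmk.special.hurwitz_zeta` (vectorised Euler–Maclaurin,
  ~1e−12 relative, validated against mpmath). The closed form is also
  verified against direct DFE quadrature to 1e−6 relative in the tests; the
  closed form is the production path.
* beneficial: Kimura's diffusion form (1 − e^{−2s})/(1 − e^{−4Ns}) for
  unscaled s < 0.1, and the branching-process fixed point
  p = 1 − e^{−(1+s)p} for larger s, where the diffusion form overshoots
  (at s = 0.5 the branching value is 0.583 vs 0.632). Beneficial class
  rates carry an additional factor 1/2 relative to the tabulated mutation
  probabilities `p_weak`/`p_strong` (a new mutant is a single heterozygous
  copy); both conventions were fixed by requiring that the solved
  probabilities reproduce the published reference solves, which they do to
  ≤ 2.4% (most to ≤ 1.7%, see the acceptance notes below).

α is the beneficial share of the total nonsynonymous fixation rate,
αW and αS its weak and strong components.

### Background selection and interference

BGS enters in two ways:

1. **Effective size.** Deleterious/neutral fixation and *all* frequency
   spectra are evaluated at Ne = B·N: spectra use θe = Bθ and Se = B·S.
2. **Interference on weak beneficials.** The coding locus sits between two
   deleterious flanks of length L (default 1e5 bp), per-site mutation rate
   μ_flank, coefficient magnitude |2Nt|, per-base scaled recombination ρ.
   The fixation probability of a focal beneficial allele is reduced by

       Phi(s) = [ prod_{l=1..L} exp(−2 μ t / (t + 2s + r l)^2) ]^2,

   the square covering both flanks. The inner sum telescopes into
   first-order polygamma values, giving a closed form checked against the
   literal per-site product to 1e−8; ρ = 0 uses the direct limit. Setting
   s = 0 recovers the classical linked-neutral diversity reduction, which
   defines B self-consistently: `solve_flanking_mu` inverts Phi(0) = B
   exactly (the exponent is linear in μ). Strongly beneficial alleles have
   Phi ≈ 1 and are left untouched.

Per-site B values can be binned (default width 2.5%) to midpoints so all
sites in a bin share one Ne and one interference strength.

### Solving a scenario

α is a model output, so target (α, αW) must be converted into the
beneficial mutation probabilities. Because the class rates are linear in
(p_weak, p_strong), the solve is exact linear algebra rather than an
iterative root search; the round trip is machine-precision and a 1e−6
residual check guards the contract. Targets are solved in the no-BGS
reference (B = 1); `realized_alpha_under_B` then reports the α actually
realized at a given B (deleterious class at Ne, weak class times Phi).
Any α < 1 is attainable, so prior draws never need redrawing.

## Poisson sampling

Counts of fixations and of polymorphic sites per frequency bin are
independent Poisson variables (a Poisson random field). For ABC summaries
the scheme conditions on the observed data's *totals* rather than absolute
rates, which removes branch-length and mutation-rate nuisance parameters:

* the observed total fixation count (nonsynonymous + synonymous) is split
  across classes in proportion to the model's per-site substitution rates,
  with synonymous sites entering at weight (1 − nonsyn_fraction)/2Ne;
* the observed *per-bin* total SFS (PN(x) + PS(x)) is split between the
  nonsynonymous mixture and the synonymous neutral spectrum by the model's
  expected per-bin share, then Poisson-resampled.

Keeping the per-bin totals of the data means the overall SFS shape —
including demographic distortion the equilibrium model does not describe —
is inherited by every simulated summary, while the model controls the
nonsynonymous/synonymous contrast that carries the selection signal. The
class-total variant (each class total distributed over bins in proportion
to its expected spectrum) is also provided (`sample_polymorphism`) and is
the one whose conservation-in-expectation property is contractual.

### Synthetic data generator

`generate_dataset` emulates a pooled set of G coding loci (defaults:
G = 5e4 genes of 2 kb, 75% nonsynonymous sites, θ = ρ = 0.001, N = n = 500,
B = 0.999) under a solved scenario. Expected per-gene divergence uses a
branch scale of 0.01 substitutions per neutral site (human–chimpanzee-like
synonymous divergence, giving ≈ 5 synonymous fixations per 2 kb gene);
polymorphism uses the expected sample spectra with the 1/(2N) grid spacing
folded in (≈ 3–4 synonymous SNPs per gene). Pooled counts are drawn
directly at pooled means — sums of independent Poissons are Poisson, so
this is distributionally identical to summing per-gene draws, and the
moment equivalence is tested. Per-gene totals and (for modest G) full
per-gene SFS vectors are available for bootstrap work. The generator keeps
the class identity of every sampled variant, so estimator bias can be
decomposed (e.g. rebuilding the dataset without beneficial polymorphism).

What the generator does **not** emulate: non-equilibrium demography,
physical linkage within and between coding loci (BGS enters only through
the analytic Ne/Phi approximations), ancestral-state misidentification,
and gene-length or mutation-rate heterogeneity (all genes share one
length). Tests passing on this generator therefore certify the inference
machinery under its own model class, not robustness on real data.

## MK statistics

`cumulative_alpha` builds α(x) = 1 − (DS/DN)(PN(x)/PS(x)) with PN, PS
counted at derived allele count ≥ x (the cumulative form used as ABC
summaries); `binned_alpha` is the per-frequency-class form of the classic
asymptotic-MK estimate. Thresholds with PS(x) = 0 are flagged invalid, not
dropped. A polarization guard (`max_daf`, default 0.7 in the CLI for
empirical data, off for synthetic data) excludes likely mispolarized
high-frequency variants.

`amk_fit` fits a + b·e^{−cx} by unweighted trust-region least squares with
multi-start over c ∈ {1, 2, 5, 10, 50} (ties by residual norm), x
normalized to (0, 1], singletons excluded by default, and reports the fit
at x = 1. The per-bin curve is the one used for asymptotic-MK point
estimates (it reproduces the reference bias values; the cumulative curve's
fit is systematically higher on purged data). Confidence intervals, when
needed, come from gene-level bootstrap rather than an analytic form.
`classic_mk` and `fww_mk` (frequency-threshold variant, default cutoff
0.15) complete the family.

## ABC

* **Priors** (demographic-equilibrium defaults): α ~ U[0, 0.9], sW ~
  U[1, 10], sS ~ U[200, 2000], deleterious mean |2Ns| ~ U[200, 1000],
  shape 0.184·2^U[−2,2], flanking |2Nt| ~ U[500, 1000], B ~ U[0.1, 0.999].
  The prior table gives no rule for splitting α; αW ~ U[0, α] is drawn as
  the least-informative partition (configurable).
* **Grid.** 1e5 draws are solved vectorised (< 1 s) and stored columnar
  with their realized (α, αW, αS) at the drawn B — the quantities the
  posterior is formed over.
* **Summaries.** Cumulative α(x) at derived-count thresholds chosen by
  sample-size class — (2, 5, 20, 50, 200, 661, 925), (2, 5, 20, 50, 200,
  500, 700) or (2, 4, 5, 10, 20, 30, 50, 70) — singletons never included.
  Per-draw spectra are reconstructed from a precomputed basis of projected
  spectra on a 384-point log grid of |4Ns| (Gamma bin masses for the
  mixture, log-linear interpolation for the point classes); the basis path
  agrees with the direct computation to ~2e−3 relative and makes a full
  1e5-row summary simulation a ~20 s operation on one CPU.
* **Rejection.** Euclidean distance after per-dimension MAD
  standardisation (zero-spread dimensions dropped with a warning);
  ceil(tolerance × rows) nearest draws accepted (tolerance 0.025 → 2500
  of 1e5). Draws with undefined summaries are never accepted.
* **Adjustment.** Weighted local-linear regression (Epanechnikov weights
  in distance, small ridge for singular designs), translating draws along
  the fitted plane to the observed summary. Adjusted α components are
  clamped to [0, 1] with the clamp count reported; no tangent transform is
  applied by default.
* **Posterior summaries.** Mode by Gaussian KDE maximum (Silverman
  bandwidth, 512-point grid) and central 95% quantile interval.

## Control-set matching

The case/control machinery grows a control multiset whose per-feature
means track the test-set means within a relative tolerance (default 5%),
with any single gene capped at 1.2% of the set. The growth rule — accept
the best of a random candidate batch unless it worsens the current worst
relative deviation beyond a granularity slack that shrinks as 1/(k+1) —
exists because discrete features (a binary immune flag) make strict
stepwise tolerance unattainable in small sets; a final swap-repair pass
plus a hard audit of all feature means is the actual contract. Empirical
p-values are add-one upper-tail by default:
p = (1 + #{null ≥ obs})/(1 + n_null).

## Numerical choices and degenerate inputs

* Solver residual tolerance 1e−6 on the α scale (achieved ~1e−16).
* Branching-process iteration: 200 fixed-point steps (converges
  geometrically; matches the defining equation to 1e−12 in tests).
* α(x) with PS(x) = 0 → flagged NaN; exponential fit requires ≥ 4 usable
  points and raises with diagnostics after all multi-starts fail.
* Zero recombination, B = 1, p± = 0, D = 0 and empty spectra all take
  explicit limit branches rather than dividing by zero.
* All randomness flows through `numpy.random.Generator` objects seeded at
  the interface; no global RNG state.

## Known limitations

* The realized-α map under strong BGS is approximate: evaluating the
  deleterious class at Ne = BN substantially inflates deleterious fixation
  at B ≤ 0.4, and linked-site forward simulations realize a much smaller
  inflation (the classical flanking-diversity closed form also overstates
  the realized diversity reduction when the flanking deleterious load is
  high, so the B *label* and the realized B diverge). Predictions at
  B ≥ 0.8 are accurate; at B = 0.2 the predicted α can sit far below the
  forward-simulated value for the same label. Inference is less affected
  than prediction, because B is itself a free parameter matched through
  the summaries.
* Scenario solves expressed in 2Ns units are independent of N only to
  first order in the unscaled s; the strong class (2Ns = 500) shifts by a
  few percent between population sizes, and crossing the diffusion/
  branching regime boundary (s = 0.1) shifts it more.
* Equilibrium-only analytics: demographic robustness is an empirical
  property of the totals-conditioning, not a modeled feature.
* Interference of beneficial alleles with each other is outside the
  approximation (weak-BGS-dominated regimes only).
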