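# abcmk

Inference of the **rate and strength of adaptive protein evolution** from
polymorphism and divergence counts.

The classic McDonald–Kreitman contrast estimates the proportion of
adaptive nonsynonymous substitutions as

    alpha = 1 − (DS/DN) · (PN/PS),

but weakly selected polymorphism biases it: weakly *deleterious* variants
inflate PN at low frequency, and weakly *beneficial* variants inflate PN at
high frequency, so even the asymptotic-MK extension — fitting
a + b·e^{−cx} to the frequency-resolved curve α(x) and reading off x = 1 —
underestimates α whenever weak adaptation contributes. `abcmk` addresses
this by modelling α(x) directly: it computes analytic expected frequency
spectra and fixation rates under a Gamma distribution of deleterious
fitness effects (shape β, mean γ in 2Ns units) plus weak/strong beneficial
point masses (2Ns = sW, sS), accounts for background selection through an
effective population size Ne = B·N and an interference factor Φ on weakly
beneficial fixations, converts the expectations into stochastic summary
statistics by Poisson sampling conditioned on the observed totals, and
infers (α, αW, αS, γ, β, B) by Approximate Bayesian Computation with
local-linear regression adjustment. Because the expectations are analytic,
a full 10^5-draw reference table is built in under a second and a complete
inference runs in well under a minute on one CPU — no forward simulation.

Intended users: population geneticists with pooled unfolded SFS and
branch-specific divergence counts (e.g. human polymorphism with divergence
mapped on the human branch) who want DFE-aware estimates of adaptation
rate and strength, and a matched-control machinery for contrasting gene
sets.

## Worked example

```python
from abcmk import SelectionModel, solve_scenario, generate_dataset, \
    build_parameter_grid, PriorSpec
from abcmk.mk import binned_alpha, amk_fit
from abcmk.abc import infer

# 1. A scenario: equilibrium population, N = n = 500 diploids, Gamma DFE
#    (shape 0.184, mean |2Ns| = 457), sW = 10, sS = 500, negligible BGS.
#    Solve the beneficial mutation probabilities for alpha=0.4, alphaW=0.1:
scen = solve_scenario(0.4, 0.1, SelectionModel(N=500, n=500, B=0.999))
print(scen.model.p_weak, scen.model.p_strong)   # 0.00389  0.000397
print(scen.rates().alpha)                        # 0.3997 realized at B=0.999

# 2. A pooled synthetic dataset of 5e4 two-kb genes under that scenario:
ds = generate_dataset(scen, 50_000, seed=3)
print(ds.pooled.DN, ds.pooled.DS)                # 288071 250221

# 3. The asymptotic-MK estimate is biased low by weak adaptation:
print(amk_fit(binned_alpha(ds.pooled)).alpha_hat)        # 0.298  (true 0.40)
print(amk_fit(binned_alpha(ds.nonsyn_minus)).alpha_hat)  # 0.335  (beneficial
                                                         #  variants removed)

# 4. ABC recovers the truth from the same biased data:
grid = build_parameter_grid(PriorSpec(), 100_000, seed=11)
post = infer(ds.pooled, grid, seed=5, tolerance=0.025)
print(post.summary.loc["alpha"].round(3))
# mode 0.391, 95% CI [0.351, 0.458] — covering the true 0.4
```

The numbers shown are the output of this exact code. Step 3 quantifies the
weak-adaptation bias the package exists to correct: the exponential-fit
estimate sits ~0.1 below the truth with all alleles, and removing the
(synthetically labelled) beneficial polymorphism recovers only part of the
gap, because weakly deleterious variants bias the fit too. Step 4 shows the
ABC posterior centred on the generating value.

## Command line

```bash
abcmk rates --ndraws 100000 --seed 7 --out grid.tsv      # reference table
abcmk simulate --alpha 0.4 --alpha-weak 0.1 --bvalue 0.999 \
      --genes 50000 --seed 3 --out counts.tsv            # synthetic data
abcmk amk counts.tsv --max-daf 1.0 --out amk.json        # alpha(x) + fit
abcmk infer counts.tsv --grid grid.tsv --seed 5 --out-prefix run1
abcmk match-controls test.tsv pool.tsv --features expression,gc3,length \
      --size 1000 --seed 1 --out controls.tsv
```

Input counts are TSV of pre-aggregated unfolded SFS (wide or long
encoding; 1-based derived-allele-count columns) plus per-gene DN/DS; see
`abcmk.io`. Every output embeds the package version, seed and settings as
`#` header lines.

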