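# seedshadow

Tools for measuring how the loss of fruit-eating birds changes tree
recruitment, built around the classic island contrast of the Marianas:
forests that have lost their frugivores to an invasive snake versus nearby
islands with intact disperser communities.  The package estimates seed
-dispersal kernels from seed-trap counts in mapped stands by hierarchical
Bayesian inverse modelling, fits the binomial regression stages through
which birds act on recruitment (gut-passage effects on germination,
distance-dependent ingestion, distance-dependent seedling mortality), and
combines everything into one integrative number: the ratio of
seed-to-seedling survival without birds to survival with birds.

## The model in brief

Seed rain around a parent tree follows an isotropic 2D dispersal kernel —
power-exponential `f(r) ∝ exp(−(r/a)^p)` with p = 0.5, or 2Dt
`f(r) ∝ (1 + r²/a²)^−(p+1)` with p = 1 — whose scale `a` (metres) may
differ between islands with and without birds.  The expected season-total
count in trap j at site s is

    μ_js = A · Σ_i β_s b_i f(r_ij),        log β_s ~ N(μ_β, σ_β²)

summing all mapped conspecific trees i (basal area b_i), with
negative-binomial counts, Var = μ(1 + k₁) + k₂μ².  MCMC over
(μ_β, σ_β, β_s, a, k₁, k₂) with Gelman–Rubin diagnostics; six candidate
models (2 kernels × 3 island-scale hypotheses) compared by DIC.

Recruitment stages are binomial GLM/GLMMs selected by AICc with 95%
profile-likelihood intervals.  Seed-to-seedling survival is

    φ = ∫ p(r) [ p(I|r) p(G|I=1,r) + (1−p(I|r)) p(G|I=0,r) ] p(S1|r) p(S2|r) dr

and the impact of disperser loss is the Monte-Carlo distribution of
φ_absent / φ_present with kernel scales drawn from the posterior and stage
coefficients from their sampling distributions.

Because the motivating field data are not freely downloadable, the package
ships a first-class synthetic-study generator (`seedshadow.synthetic`)
that emulates the design — 13 wedge-shaped 17-trap arrays (221 traps),
three-treatment germination trials, 1,120 outplanted seedlings, 900 sown
seeds per distance class — with known ground truth, including the true φ
ratio, so the whole pipeline is testable end to end.  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from seedshadow import bayes_fit, recruitment, stage_glms, synthetic

world = synthetic.simulate_world(synthetic.WorldConfig(seed=2))

model = bayes_fit.build_model(world.stand(), "power_exponential", "guam_vs_rest")
draws = bayes_fit.fit_mcmc(model, n_chains=3, n_retain=500, burn_in=2500,
                           thin=4, seed=9)
print("no-bird scale a (m):", round(draws.scale_draws("Guam").mean(), 2))
print("bird-island scale a (m):", round(draws.scale_draws("Rota").mean(), 2))

early = world.seed_addition.assign(n_sown=lambda d: d.n_germinated.clip(lower=1))
fits = {
    "germination": stage_glms.fit_germination_glm(world.germination),
    "ingestion_distance": stage_glms.fit_ingestion_distance(world.traps),
    "seedling_survival": stage_glms.fit_seedling_survival(world.survival_plots),
    "field_germination": stage_glms.fit_field_germination(world.seed_addition),
    "field_early_survival": stage_glms.fit_field_germination(
        early, response="n_surviving"),
}
result = recruitment.propagate_uncertainty(draws, fits, n_draws=400, seed=13)
s = result.summary()
print(f"decline: {100*s['decline_mean']:.0f}% "
      f"(95% CI {100*s['decline_q2.5']:.0f}–{100*s['decline_q97.5']:.0f}%)")
print("true ratio:", round(world.ground_truth["ratio"], 3))
```

Output:

```
no-bird scale a (m): 0.48
bird-island scale a (m): 2.85
decline: 68% (95% CI 56–80%)
true ratio: 0.278
```

The fitted kernel scales sit close to the generating truths (0.5 m without
birds, 3.4 m with birds), and the predicted recruitment decline — seeds on
the bird-free island pile up under the parent, stay uningested (losing the
severalfold germination benefit of gut passage) and die at the higher
near-parent rate — has a 95% interval covering the generator's true
survival ratio of 0.278 (a 72% decline).

The same pipeline is available from the shell:

```sh
seedshadow simulate --seed 5 --out data
seedshadow fit-kernel --data data --kernel pexp --hypothesis guam --seed 5 --out kfit
seedshadow fit-stages --data data --out stages
seedshadow integrate --data data --kernel-fit kfit --seed 5 --out result
seedshadow report --result result
```

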