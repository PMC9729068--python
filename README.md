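# migsci

**What happens when gene flow between two species is continuous, but you
model it as a single pulse of introgression?** `migsci` provides the
analytic and simulation machinery to answer that question for pairwise
genomic data: closed-form coalescent-time densities under migration and
introgression models, Kullback–Leibler computation of the *pseudo-true*
parameter values that a misspecified introgression model converges to,
a structured-coalescent simulator for species networks, and
maximum-likelihood fitting of per-locus sequence-difference counts.

It is aimed at phylogeneticists and population geneticists studying
model misspecification in multispecies-coalescent inference of gene flow
— for example, to predict how an estimated introgression probability φ̂
and introgression time τ̂ relate to a true migration rate *M* and
gene-flow period.

## Models

All times (τ) and population sizes (θ = 4*N*μ) are in expected mutations
per site; the pairwise coalescent rate in a population is 2/θ.

* **MSC-M** (migration): species *A* and *B* diverge at τ_R; *A* sends
  migrants to *B* at *M* migrants per generation. Variants: **IM**
  (migration throughout (0, τ_R)), **IIM** (until τ_T, then isolation),
  **SC** (secondary contact from τ_T onward). Backward in time, a *B*
  lineage jumps to *A* at the mutation-scaled rate w = 4M/θ_B, giving a
  three-state Markov chain over {AB, AA, A} whose transition
  probabilities yield piecewise-exponential densities f(t) of the
  pairwise coalescent time.
* **MSci** (introgression): gene flow collapsed to a pulse at τ_S, where
  each *B* lineage jumps to the donor side with probability φ.

For *x* observed differences at *n* sites, sites are i.i.d. JC, so
x | t ~ Binomial(n, 3/4·(1 − e^{−8t/3})), and the marginal likelihood is
f(x|Θ) = ∫ f(x|t) f(t|Θ) dt (with a Poisson(2nt) variant that admits an
incomplete-gamma closed form).

When data generated under MSC-M are fitted with MSci, the ML estimates
converge (as the number of loci L → ∞) to the pseudo-true values Θ*
minimizing the KL divergence D(f_gen ‖ f_fit). Key results the package
computes and tests:

* the expected total migrant proportion φ₀ = 1 − e^{−4MΔτ/θ_B};
* the fitted introgression time collapses to the *end* of the gene-flow
  period when coalescent times are observed (τ_S* = 0 for IM/SC, τ_T for
  IIM), and sits just above it for finite n;
* closed-form low-migration approximations for φ*, with the ordering
  φ₀ > φ*(SC) > φ*(IIM) = φ*(IM): recent gene flow is easier to recover.

## Worked example

```python
from dataclasses import replace
from migsci import preset_scenario, phi0, minimize_kl, fit_ml, simulate_dataset
from migsci.klfit import FitMethodSpec

im = preset_scenario("fig1-im").mscm          # IM: tau_R=0.002, M=0.2
print("w =", im.w)                            # w = 80.0
print("phi0 =", round(phi0(im.M, im.delta_tau, im.theta_B), 4))
# phi0 = 0.1479

# where does a fitted introgression model end up with infinite data?
pt = minimize_kl(im, "b", n=None, restarts=2, seed=1)
print(pt.params.tau_S, pt.params.tau_R, round(pt.params.phi, 4))
# 0.0 0.002 0.0989

# finite-n ML fit to a simulated dataset approaches the finite-n pseudo-truth
ds = simulate_dataset(replace(preset_scenario("fig1-im"), L=4000, S=1),
                      seed=1, emit="counts")
fit = fit_ml(ds.counts, model="msci",
             spec=FitMethodSpec.for_method("b", im), restarts=2, seed=1)
print({k: round(v, 6) for k, v in fit.estimates().items()})
# {'tau_R': 0.002003, 'tau_S': 0.000567, 'theta_R': 0.01,
#  'theta_S': 0.002, 'phi': 0.110023}
```

Reading: even though migration is spread over (0, 0.002), the fitted
introgression time is pinned near the recent end of the gene-flow period
(exactly 0 with known coalescent times; 0.0006 at n = 1000 sites), the
species divergence time τ_R is recovered accurately, and the fitted
introgression probability (0.099 asymptotically, 0.11 in this dataset)
is close to, but below, the expected migrant proportion φ₀ = 0.148.

A thin CLI mirrors the library:

```bash
migsci density --preset fig1-iim --grid 0:0.02:200
migsci klfit --gen im --method b --n inf --m-grid 0.05,0.1,0.2
migsci simulate --scenario fig1-sc --set L=100 --set S=1 --seed 17 --emit counts --out out/
migsci mlfit --model msci --method e --data out/counts.tsv --seed 7
```

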