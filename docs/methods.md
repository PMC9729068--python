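# Methods

## Models and conventions

Time runs from the present (0) into the past, measured in expected
mutations per site; population sizes are θ = 4Nμ in the same units, so a
pair of lineages in a population of size θ coalesces at rate 2/θ. Two
species *A* and *B* diverged at τ_R from an ancestor of size θ_R.

**Migration models (MSC-M).** Forward-time migration from *A* to *B* at
*M* migrants per generation appears backward in time as each *B* lineage
jumping into *A* at the mutation-scaled rate w = 4M/θ_B. For one
sequence per species, the process during the gene-flow period is a
three-state Markov chain over {AB, AA, A} with generator rates w
(AB→AA) and 2/θ_A (AA→A). Its transition matrix is computed in closed
form; the pairwise coalescent-time density f(t) is then assembled
piecewise from chain probabilities at epoch boundaries:

* **IM** — gene flow on (0, τ_R);
* **IIM** — gene flow on (τ_T, τ_R); f(t) = 0 below τ_T, and the model
  is exactly the IM model time-shifted by τ_T for pairwise data;
* **SC** — gene flow on (0, τ_T); lineages already in *A* can coalesce
  during the isolation phase (τ_T, τ_R).

The density depends on (M, θ_B) only through w. The IIM/SC ghost branch
on the recipient side carries its own size θ_T in the data structures;
the pairwise density uses w = 4M/θ_B, which presumes θ_T = θ_B during
the gene-flow period (true of all study presets).

**Introgression model (MSci).** A pulse at τ_S sends each *B* lineage to
the donor branch *S* (size θ_S, on the *A* side) with probability φ:
f(t) = φ·(2/θ_S)e^{−2(t−τ_S)/θ_S} on (τ_S, τ_R), and a mixed exponential
of the escaped and non-introgressed mass beyond τ_R. With one sequence
per species, exactly (τ_R, τ_S, θ_R, θ_S, φ) are identifiable; θ_A, θ_B
and θ_H are flagged non-identifiable.

Densities are represented as `PiecewiseDensity` objects — sums of
coef·(t−off)^p·e^{−rate(t−off)} terms per interval with a single pure
exponential tail — shared by quadrature, KL, moments, CDF and the
simulator tests. Masses, CDF values and moments of the tail are exact;
interior moments use adaptive quadrature (tolerance 1e-8).

## Sequence likelihoods

Under JC, x | t ~ Binomial(n, p(t)) with p(t) = 3/4·(1 − e^{−8t/3})
(the binomial coefficient is included so the pmf normalizes; it cancels
in likelihood ratios). The Poisson variant uses mean 2nt. Marginal
likelihoods f(x|Θ) = ∫ f(x|t) f(t) dt are computed three ways:

1. **Adaptive quadrature** (reference): Gauss–Kronrod per density piece,
   absolute tolerance 1e-12, with the exponential tail mapped exactly to
   (0, 1] by u = e^{−rate(t−τ_R)}.
2. **Closed form** (Poisson only): each density term reduces to
   differences of regularized upper incomplete gamma functions; derived
   here independently and certified against route 1 at 1e-10 in the test
   suite (including at the removable singularity w = 2/θ_A, where the
   density piece degenerates to c·w·t·e^{−wt} and the closed form picks
   up a t-power term).
3. **Fixed Gauss–Legendre grid** (160 nodes per piece), vectorized over
   all x at once; used inside optimization loops and validated against
   route 1 at 1e-10. A log-sum-exp variant supplies log-marginals that
   survive extreme counts and very long sequences.

Numerical stability near w = 2/θ_A: the transition probability
P(AB→AA) is evaluated via the expm1-based form w·t·e^{−ct}·φ₁((c−w)t)
inside a window |(c−w)t| < 1e-4 and the direct two-exponential form
outside it, which is uniformly accurate and overflow-free (verified
against `scipy.linalg.expm` at 1e-10 across a randomized grid).

## Pseudo-true parameters by KL minimization

When data are generated under MSC-M and fitted with MSci, the MLE
converges to the minimizer of D(f_gen ‖ f_fit). Two data regimes:

* **n = ∞** (coalescent times observed): D = ∫ f_gen(t) log(f_gen/f_fit) dt,
  integrated piecewise over the union of breakpoints with an analytic
  tail. If the fitted support excludes generating support (τ_S above the
  generating minimum), D = +∞ — detected analytically, which is why the
  fitted introgression time is bounded by the generating support minimum
  in this regime and the boundary optima τ_S* = 0 (IM/SC) and
  τ_S* = τ_T (IIM) are attained exactly.
* **finite n**: D = Σ_x f_gen(x) log(f_gen(x)/f_fit(x)), summed over x
  until the cumulative generating mass reaches 1 − 1e-12 (capped at n
  for the binomial model; the Poisson support is unbounded, so a mass
  criterion replaces a fixed upper limit).

**Fitting methods a–e** fix or free subsets of the five identifiable
parameters: a — (τ_R, φ) free, τ_S at the end of the gene-flow period,
θs at truth; b — adds τ_S; c — τ_S = 0, four free; d — all five free;
e — θ_R = θ_S tied, four free.

**Optimizer.** Bounded L-BFGS-B followed by a Nelder-Mead polish, on the
scale (log θ, φ linear in [0,1], τ_S linear in its bound, log gap with
τ_R = τ_S + gap so the ordering constraint is built in). Bounded search
was chosen over smooth transforms because the scientifically meaningful
optima sit exactly on boundaries (τ_S* = 0, φ* = 0 at M = 0), which a
logit/sigmoid parameterization can only approach asymptotically.
Default 4 restarts (first truth-informed, others log-uniform);
convergence tolerances 1e-15 (objective) and 1e-12 (gradient), with the
derivative-free polish sharpening past finite-difference resolution —
this is what brings the numerically independent IM and IIM fits to agree
in φ* to ~1e-9, as the time-shift identity requires. Failures of all
restarts raise with per-restart diagnostics.

**Closed forms.** φ₀ = 1 − e^{−4MΔτ/θ_B} (Δτ the gene-flow duration) and
the low-migration φ* approximations for IM/IIM/SC are implemented as
algebraic functions, valid for wθ_A < 2 (a domain error beyond). They
imply φ₀ > φ*(SC) > φ*(IIM) = φ*(IM); both the closed forms and the full
numerical KL minimization reproduce this ordering in the tests.

## Simulator

The structured coalescent runs backward in time on a species network
(branches with sizes, migration bands, hybrid nodes). Within an epoch
(between consecutive node ages or band endpoints) total rates are
constant: coalescence k(k−1)/θ per population, plus w = 4M/θ_recipient
per lineage in an active band's recipient. Event times are exact
competing exponentials truncated at epoch boundaries — no time
discretization. At a hybrid node each lineage picks the donor parent
independently with probability φ; zero-length hybrid edges express
simultaneous-donor introgression, and a bridge branch expresses
donor/recipient nodes at different ages. Lineage population paths and
migration-jump counts are recorded on the gene tree.

Sequences evolve by JC along the gene tree (i.i.d. sites, root uniform
on {A,C,G,T}). For one-pair data an exact shortcut draws
x ~ Binomial(n, p(t)) directly from the pair's coalescent time, which is
distributionally identical to evolving the two-tip tree (tested by a
two-sample KS check).

Per-locus RNG substreams are keyed by (seed, locus index), so datasets
are byte-reproducible and extending L leaves earlier loci unchanged.

**Study scenarios.** The named presets reproduce the two-species designs
(θ₀ = 0.002 thin / θ₁ = 0.01 thick branches, gene-flow period θ₀,
M = 0.2, L = 4000 loci, S = 4 sequences per species, n = 1000 sites) and
the four-species introgression/migration designs (n = 500), the
three-species IIM design, and the ghost-species scenarios, including the
two-step migration relay through an extinct lineage. Where branch-size
assignments are encoded only graphically in the source designs, the
defaults place the donor tip thin and the recipient-side and ancestral
branches thick — the assignment that reproduces the printed migrant
proportion φ₀ = 0.148 — and the secondary-contact root age defaults to
2θ₀. These are configurable through the network data structures.

## Maximum-likelihood fitting

Loci are i.i.d., so data reduce to multiplicity-weighted unique (x, n)
pairs before fitting. The same bounded optimizer maximizes the marginal
log-likelihood under MSci (any method a–e) or under the migration
models (with θ_B held fixed, since the pairwise density identifies only
w = 4M/θ_B). Standard errors come from a central-difference Hessian of
the negative log-likelihood on the internal scale, mapped to natural
parameters by the delta method; parameters estimated on a boundary get
NaN. Because the φ–θ_S (and at small L, φ–τ_S) ridge makes the
likelihood non-quadratic, the package also provides signed-root
likelihood-ratio z-scores via profile likelihood
(`mlfit.profile_lr_zscore`), which are parameterization-invariant and
remain calibrated on the ridge; the recovery checks in the test suite
use these, while curvature SEs are what `MLFit.se` reports.

## What the synthetic data do and do not emulate

The generator reproduces the study conditions exactly as specified:
independent loci, no recombination within loci, JC mutation, constant
rates of gene flow in time and across loci, and at most the preset
numbers of species and samples. It does not emulate rate variation
across sites or loci, selection against introgressed alleles,
recombination, sequencing error, or alignment uncertainty — so passing
tests demonstrate correctness of the coalescent/likelihood machinery
under the stated models, not robustness of inference on real genomes.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to keep Monte-Carlo error
well below the tested effects: KS tests of simulator-versus-density use
10^5 replicates (unit-test variants 2×10^4), the empirical-marginal
chi-square uses 10^5 loci, parameter recovery uses 30 replicates of
L = 4000 loci, and the misspecification-convergence check compares
L = 10^3 (median of three replicates) with L = 10^5. The SE-scaling law
is checked on the well-identified two-parameter fit, since weakly
identified ridge parameters do not obey the L^{−1/2} law at small L.

## Known limitations

* Closed-form densities and likelihoods cover one sequence per species;
  multi-sequence and multi-species data can be simulated but not fitted.
* Only the JC model (and its Poisson approximation) is implemented.
* The KL analysis is one-directional (migration truth, introgression
  fit); the reverse direction is out of scope.
* Under the pairwise KL analysis at very high migration (M ≥ 1.4), the
  fitted divergence time drops far below the truth as documented, but
  the fitted root size compensates *downward* (toward the fast
  mid-interval decay), not upward; root-size overestimation is a
  feature of multi-sequence analyses outside this package's fitting
  scope.
* Wald SEs under-cover for ridge-confounded parameters; use the
  profile-likelihood z-scores for calibrated uncertainty there.
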