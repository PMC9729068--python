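"""Pseudo-true MSci parameters for data generated under migration models.

When pairwise data are generated under a continuous-migration model
(IM/IIM/SC) but fitted with the episodic-introgression MSci model, the ML
estimates converge (as the number of loci grows) to the *pseudo-true*
values that minimize the Kullback-Leibler divergence from the generating
marginal distribution to the fitted one:

``D(gen || fit) = sum_x f_gen(x) log[f_gen(x) / f_fit(x)]``

for sequences of ``n`` sites, or the corresponding integral over the
coalescent time ``t`` when the coalescent times are observed directly
(the ``n = inf`` regime).

Five fitting protocols (methods ``a``-``e``) differ in which of the five
identifiable MSci parameters ``(tau_R, tau_S, theta_R, theta_S, phi)`` are
free; see :func:`FitMethodSpec.for_method`.

The module also provides the expected total proportion of migrants
``phi0 = 1 - exp(-4 M dtau / theta_B)`` accumulated over a gene-flow
period of length ``dtau``, and the low-migration closed-form
approximations to the pseudo-true introgression probability ``phi*`` for
each generating model, which satisfy the ordering
``phi0 > phi*(SC) > phi*(IIM) = phi*(IM)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .densities import PiecewiseDensity, density_for, mscm_density, msci_density
from .likelihood import MarginalCalculator, marginal_pmf
from .params import MSCMParams, MSciParams

__all__ = [
    "phi0",
    "phi_star_closed_form",
    "FitMethodSpec",
    "PseudoTrueFit",
    "kl_divergence",
    "minimize_kl",
    "sweep_migration_rate",
    "MIGRATION_RATE_GRID",
]

#: migration-rate grid of the two-species study scenarios
MIGRATION_RATE_GRID = (
    0.01, 0.02, 0.03, 0.04, 0.05, 0.07, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0, 1.5, 2.0,
)


def phi0(M: float, delta_tau: float, theta_B: float) -> float:
    """Expected total proportion of migrant ancestry under continuous migration.

    A lineage in the recipient species B jumps backward into the donor at
    rate ``4*M/theta_B``; over a gene-flow period of length ``delta_tau``
    the probability that it traces back to the donor is
    ``1 - exp(-4*M*delta_tau/theta_B)``.
    """
    if M < 0 or delta_tau < 0:
        raise ValueError("M and delta_tau must be nonnegative")
    if theta_B <= 0:
        raise ValueError("theta_B must be positive")
    return -math.expm1(-4.0 * M * delta_tau / theta_B)


def phi_star_closed_form(params: MSCMParams) -> float:
    """Low-migration closed form for the pseudo-true introgression probability.

    Derived in the ``n = inf`` regime under the simplifying assumptions
    that the fitted divergence time and root size match the truth, the
    introgression time sits at the end of the gene-flow period, and the
    fitted density matches the truth beyond ``tau_R``.  Accurate at low
    migration rates; singular as ``w*theta_A -> 2``.
    """
    bad = params.validate()
    if bad:
        raise ValueError("invalid MSCMParams: " + "; ".join(bad))
    w, thA = params.w, params.theta_A
    if w * thA >= 2.0:
        raise ValueError(
            "phi* closed form requires w*theta_A < 2 "
            f"(got {w * thA:.4f}); use minimize_kl instead"
        )
    p0 = phi0(params.M, params.delta_tau, params.theta_B)
    c = 2.0 / thA
    if params.variant in ("IM", "IIM"):
        span = params.tau_R - params.tau_T  # tau_T = 0 for IM
        depl = 1.0 - math.exp(-c * span)
        return (p0 - 0.5 * w * thA * depl) / ((1.0 - 0.5 * w * thA) * depl)
    # SC
    leak = (
        w * thA / (2.0 - w * thA)
        * (math.exp(-w * params.tau_T) - math.exp(-c * params.tau_T))
        * math.exp(-c * (params.tau_R - params.tau_T))
    )
    return (p0 - leak) / (1.0 - math.exp(-c * params.tau_R))


# ---------------------------------------------------------------------------
# KL divergence
# ---------------------------------------------------------------------------


def _is_infinite_n(n) -> bool:
    return n is None or (isinstance(n, float) and math.isinf(n)) or n == "inf"


def kl_divergence(gen, fit, n=None, mutation_model: str = "binomial_jc") -> float:
    """KL divergence from the generating to the fitted marginal distribution.

    ``gen`` and ``fit`` may be parameter objects or prebuilt densities.
    With ``n = None`` (or ``inf``) the divergence is computed between the
    coalescent-time densities; a fitted support that excludes part of the
    generating support yields ``+inf``.  With finite ``n`` it is the sum
    over the difference counts ``x``.
    """
    fg = gen if isinstance(gen, PiecewiseDensity) else density_for(gen)
    fi = fit if isinstance(fit, PiecewiseDensity) else density_for(fit)
    if _is_infinite_n(n):
        return _kl_density(fg, fi)
    return _kl_finite_n(fg, fi, int(n), mutation_model)


def _kl_density(fm: PiecewiseDensity, fi: PiecewiseDensity) -> float:
    if fi.support_min > fm.support_min + 1e-14:
        return math.inf
    knots = sorted(
        set(fm.breakpoints) | set(fi.breakpoints) | {fm.support_min}
    )
    knots = [k for k in knots if k >= fm.support_min]
    total = 0.0
    for a, b in zip(knots[:-1], knots[1:]):
        if b - a <= 0:
            continue

        def integrand(t):
            m = fm(t)
            if m <= 0:
                return 0.0
            i = fi(t)
            if i <= 0:
                return math.inf
            return m * math.log(m / i)

        with warnings.catch_warnings():
            # f log f has an integrable derivative singularity where the
            # generating density vanishes at a piece boundary
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, _ = integrate.quad(integrand, a, b, epsabs=1e-12, limit=200)
        total += val
    # analytic tail beyond the last knot: both densities are single
    # exponentials A e^{-r (t-b)} there
    b = knots[-1]
    am, rm, sm = fm.tail
    Ai, ri, si = fi.tail
    Am = am * math.exp(-rm * (b - sm))
    Bi = Ai * math.exp(-ri * (b - si))
    if Am > 0:
        if Bi <= 0:
            return math.inf
        total += (Am / rm) * math.log(Am / Bi) + Am * (ri - rm) / rm**2
    return total


def _x_grid(fm_density: PiecewiseDensity, n: int, mutation_model: str) -> np.ndarray:
    """Range of x that carries all but ~1e-12 of the generating mass."""
    amp, rate, start = fm_density.tail
    t_hi = start + 40.0 / rate
    x_hi = int(2 * n * t_hi + 12 * math.sqrt(2 * n * t_hi) + 20)
    if mutation_model == "binomial_jc":
        x_hi = min(x_hi, n)
    return np.arange(0, x_hi + 1)


def _kl_finite_n(
    fm: PiecewiseDensity, fi: PiecewiseDensity, n: int, mutation_model: str
) -> float:
    xs = _x_grid(fm, n, mutation_model)
    pm = marginal_pmf(xs, n, fm, mutation_model)
    pi = marginal_pmf(xs, n, fi, mutation_model)
    keep = pm > 0
    if np.any(pi[keep] <= 0):
        return math.inf
    pm, pi = pm[keep], pi[keep]
    return float(np.sum(pm * (np.log(pm) - np.log(pi))))


# ---------------------------------------------------------------------------
# fitting methods a-e
# ---------------------------------------------------------------------------

_ALL_PARAMS = ("tau_R", "tau_S", "theta_R", "theta_S", "phi")


@dataclass(frozen=True)
class FitMethodSpec:
    """Which MSci parameters are free, fixed, or tied in a fit.

    ``free`` lists free parameter names; ``fixed`` maps fixed names to
    values; ``tie_thetas`` enforces ``theta_R == theta_S`` with a single
    free size parameter.
    """

    method: str
    free: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    tie_thetas: bool = False

    @classmethod
    def for_method(cls, method: str, gen) -> "FitMethodSpec":
        """Standard protocols for fitting MSci to MSC-M generated data.

        - ``a``: free (tau_R, phi); tau_S fixed at the end of the gene-flow
          period (0 for IM/SC, tau_T for IIM); theta_R, theta_S fixed at
          the generating values (theta_R, theta_A).
        - ``b``: as ``a`` but tau_S free as well.
        - ``c``: tau_S = 0 fixed; (tau_R, theta_R, theta_S, phi) free.
        - ``d``: all five parameters free.
        - ``e``: theta_R = theta_S tied; (tau_R, tau_S, theta, phi) free.

        ``gen`` may also be an ``MSciParams`` truth (self-fit checks), in
        which case the fixed values are taken from it directly.
        """
        if isinstance(gen, MSciParams):
            ts_fix, th_R, th_S = gen.tau_S, gen.theta_R, gen.theta_S
        else:
            ts_fix, th_R, th_S = gen.t_min_support, gen.theta_R, gen.theta_A
        if method == "a":
            return cls("a", ("tau_R", "phi"),
                       {"tau_S": ts_fix, "theta_R": th_R, "theta_S": th_S})
        if method == "b":
            return cls("b", ("tau_R", "tau_S", "phi"),
                       {"theta_R": th_R, "theta_S": th_S})
        if method == "c":
            return cls("c", ("tau_R", "theta_R", "theta_S", "phi"), {"tau_S": 0.0})
        if method == "d":
            return cls("d", _ALL_PARAMS)
        if method == "e":
            return cls("e", ("tau_R", "tau_S", "theta_R", "phi"), tie_thetas=True)
        raise ValueError(f"unknown fitting method {method!r}; use one of a-e")

    def build_params(self, values: dict[str, float]) -> MSciParams:
        merged = dict(self.fixed)
        merged.update(values)
        if self.tie_thetas:
            merged["theta_S"] = merged["theta_R"]
        return MSciParams(
            tau_R=merged["tau_R"],
            tau_S=merged["tau_S"],
            theta_R=merged["theta_R"],
            theta_S=merged["theta_S"],
            phi=merged["phi"],
        )


@dataclass(frozen=True)
class PseudoTrueFit:
    """Result of a KL (or likelihood) optimization over MSci parameters."""

    params: MSciParams
    objective: float
    method: FitMethodSpec
    n: float
    converged: bool
    restarts: int
    message: str = ""

    @property
    def kl(self) -> float:
        return self.objective


# internal bounded parameterization: tau_R is represented as
# tau_S + gap so the ordering tau_S < tau_R is built in
_THETA_BOUNDS = (1e-5, 1.0)
_GAP_BOUNDS = (1e-7, 0.2)


def _objective_factory(gen_density, spec: FitMethodSpec, n, mutation_model,
                       tau_s_max: float):
    free = spec.free
    finite = not _is_infinite_n(n)
    if finite:
        xs = _x_grid(gen_density, int(n), mutation_model)
        pm = marginal_pmf(xs, int(n), gen_density, mutation_model)
        keep = pm > 0
        xs, pm = xs[keep], pm[keep]
        calc = MarginalCalculator(xs, int(n), mutation_model)
        entropy_part = float(np.sum(pm * np.log(pm)))

    names = []
    bounds = []
    for name in free:
        if name == "tau_R":
            names.append("gap")
            bounds.append(_GAP_BOUNDS)
        elif name == "tau_S":
            names.append("tau_S")
            bounds.append((0.0, tau_s_max))
        elif name in ("theta_R", "theta_S"):
            names.append("log_" + name)
            bounds.append(tuple(np.log(_THETA_BOUNDS)))
        elif name == "phi":
            names.append("phi")
            bounds.append((0.0, 1.0))

    def decode(vec) -> MSciParams:
        vals = dict(zip(names, vec))
        out = {}
        if "phi" in vals:
            out["phi"] = vals["phi"]
        for th in ("theta_R", "theta_S"):
            if "log_" + th in vals:
                out[th] = math.exp(vals["log_" + th])
        tau_S = vals.get("tau_S", spec.fixed.get("tau_S", 0.0))
        out["tau_S"] = tau_S
        if "gap" in vals:
            out["tau_R"] = tau_S + vals["gap"]
        return spec.build_params(out)

    def objective(vec) -> float:
        p = decode(vec)
        if p.validate():
            return 1e12
        fi = msci_density(p)
        if finite:
            pi = calc.pmf(fi)
            if np.any(pi <= 0):
                return 1e12
            return entropy_part - float(np.sum(pm * np.log(pi)))
        val = _kl_density(gen_density, fi)
        return 1e12 if math.isinf(val) else val

    return objective, decode, bounds, names


def minimize_kl(
    gen: MSCMParams | MSciParams,
    spec: FitMethodSpec | str,
    n=None,
    mutation_model: str = "binomial_jc",
    restarts: int = 4,
    seed: int = 0,
    start: MSciParams | None = None,
) -> PseudoTrueFit:
    """Pseudo-true MSci parameters minimizing the KL divergence from ``gen``.

    Bounded quasi-Newton (L-BFGS-B) over the method's free parameters with
    a Nelder-Mead polish, best of ``restarts`` starting points (the first
    start is truth-informed, the rest are drawn log-uniformly).  In the
    ``n = inf`` regime the introgression time is bounded above by the
    generating support minimum, since any larger value has infinite
    divergence.
    """
    if isinstance(spec, str):
        spec = FitMethodSpec.for_method(spec, gen)
    if isinstance(gen, MSciParams):
        gen_density = msci_density(gen)
        t_min, th_R0, th_S0 = gen.tau_S, gen.theta_R, gen.theta_S
        p0_guess = max(gen.phi, 1e-3)
    else:
        gen_density = mscm_density(gen)
        t_min, th_R0, th_S0 = gen.t_min_support, gen.theta_R, gen.theta_A
        p0_guess = min(phi0(gen.M, gen.delta_tau, gen.theta_B), 0.999)
    if _is_infinite_n(n):
        tau_s_max = t_min
        n_eff = math.inf
    else:
        tau_s_max = 0.1
        n_eff = int(n)
    objective, decode, bounds, names = _objective_factory(
        gen_density, spec, n, mutation_model, tau_s_max
    )

    rng = np.random.default_rng(seed)
    starts = []
    informed = {
        "gap": gen.tau_R - min(t_min, tau_s_max),
        "tau_S": min(t_min, tau_s_max),
        "log_theta_R": math.log(th_R0),
        "log_theta_S": math.log(th_S0),
        "phi": max(p0_guess, 1e-3),
    }
    if start is not None:
        informed.update({
            "gap": start.tau_R - start.tau_S,
            "tau_S": min(start.tau_S, tau_s_max),
            "log_theta_R": math.log(start.theta_R),
            "log_theta_S": math.log(start.theta_S),
            "phi": start.phi,
        })
    starts.append([np.clip(informed[k], lo, hi) for k, (lo, hi) in zip(names, bounds)])
    for _ in range(max(restarts, 1) - 1):
        vec = []
        for k, (lo, hi) in zip(names, bounds):
            if k.startswith("log_"):
                vec.append(rng.uniform(math.log(1e-4), math.log(0.1)))
            elif k == "gap":
                vec.append(math.exp(rng.uniform(math.log(1e-4), math.log(0.05))))
            else:
                vec.append(rng.uniform(lo, hi))
        starts.append(vec)

    best = None
    messages = []
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        # derivative-free polish sharpens the optimum beyond finite-difference
        # gradient resolution
        res2 = optimize.minimize(
            objective, res.x, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 4000},
        )
        cand = res2 if res2.fun <= res.fun else res
        cand_x = np.clip(cand.x, [b[0] for b in bounds], [b[1] for b in bounds])
        cand_fun = objective(cand_x)
        messages.append(str(res.message))
        if best is None or cand_fun < best[1]:
            best = (cand_x, cand_fun, res.success or res2.success)
    if best is None or not math.isfinite(best[1]):
        raise RuntimeError(
            "KL minimization failed for all restarts: " + " | ".join(messages)
        )
    params = decode(best[0])
    return PseudoTrueFit(
        params=params,
        objective=best[1],
        method=spec,
        n=n_eff,
        converged=bool(best[2]),
        restarts=len(starts),
        message=messages[0],
    )


def sweep_migration_rate(
    variant_template: MSCMParams,
    spec: FitMethodSpec | str,
    M_grid=MIGRATION_RATE_GRID,
    n=None,
    mutation_model: str = "binomial_jc",
    restarts: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Pseudo-true MSci parameters along a migration-rate grid.

    Each grid point is warm-started from its neighbor.  Returns a table
    with columns ``M, tau_R, tau_S, theta_R, theta_S, phi, kl``.
    """
    rows = []
    prev = None
    for M in M_grid:
        gen = replace(variant_template, M=float(M))
        mspec = (FitMethodSpec.for_method(spec, gen)
                 if isinstance(spec, str) else spec)
        fit = minimize_kl(
            gen, mspec, n=n, mutation_model=mutation_model,
            restarts=restarts, seed=seed, start=prev,
        )
        prev = fit.params
        rows.append(
            {
                "M": M,
                "tau_R": fit.params.tau_R,
                "tau_S": fit.params.tau_S,
                "theta_R": fit.params.theta_R,
                "theta_S": fit.params.theta_S,
                "phi": fit.params.phi,
                "kl": fit.objective,
            }
        )
    return pd.DataFrame(rows)
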