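"""Maximum-likelihood fitting of gene-flow models to pairwise count data.

Loci are independent, so the log-likelihood for per-locus difference
counts ``(x_l, n_l)`` is ``sum_l log f(x_l | theta)`` with the marginal
``f(x | theta)`` integrating the conditional JC (or Poisson) probability
over the model's coalescent-time density.  As the number of loci grows,
the MLE under a correctly specified model converges to the truth, and
under a misspecified MSci model it converges to the KL pseudo-true values
computed by :mod:`migsci.klfit`.

Standard errors come from the observed-information curvature of the
log-likelihood on the internal (log/linear) optimization scale, mapped
back by the delta method; parameters estimated on a boundary get ``nan``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .densities import PiecewiseDensity, density_for, mscm_density, msci_density
from .klfit import FitMethodSpec
from .likelihood import LocusCount, MarginalCalculator, marginal_pmf
from .params import MSCMParams, MSciParams

__all__ = ["MLFit", "loglik", "fit_ml", "compare_fits", "profile_lr_zscore"]


def _grouped(data) -> tuple[np.ndarray, np.ndarray, int]:
    """Unique (x, n) pairs with multiplicities; requires a common n."""
    if not data:
        raise ValueError("data must be a nonempty list of LocusCount")
    ns = {c.n for c in data}
    if len(ns) > 1:
        raise ValueError("all loci must share the same number of sites n")
    n = ns.pop()
    ctr = Counter(c.x for c in data)
    xs = np.array(sorted(ctr))
    counts = np.array([ctr[x] for x in xs], dtype=float)
    return xs, counts, n


def loglik(params, data, mutation_model: str = "binomial_jc") -> float:
    """Log-likelihood of per-locus counts under a gene-flow model.

    ``params`` may be MSciParams, MSCMParams, or a prebuilt density.
    Returns ``-inf`` (rather than raising) if any observed count has zero
    probability under the model.
    """
    xs, counts, n = _grouped(data)
    density = params if isinstance(params, PiecewiseDensity) else density_for(params)
    logpmf = MarginalCalculator(xs, n, mutation_model).logpmf(density)
    if np.any(np.isneginf(logpmf)):
        return -math.inf
    return float(counts @ logpmf)


@dataclass(frozen=True)
class MLFit:
    """Maximum-likelihood fit of a gene-flow model to pairwise counts."""

    model: str
    params: object
    se: dict[str, float]
    loglik: float
    L: int
    n: int
    converged: bool
    restarts: int
    method: FitMethodSpec | None = None
    data_key: tuple = ()

    def estimates(self) -> dict[str, float]:
        if isinstance(self.params, MSciParams):
            return {k: getattr(self.params, k) for k in MSciParams.IDENTIFIABLE}
        p = self.params
        out = {"tau_R": p.tau_R, "theta_A": p.theta_A, "theta_R": p.theta_R, "M": p.M}
        if p.variant != "IM":
            out["tau_T"] = p.tau_T
        return out


# ---------------------------------------------------------------------------
# internal parameterization (log for sizes/gaps, linear for times and phi)
# ---------------------------------------------------------------------------


def _msci_parameterization(spec: FitMethodSpec, tau_s_max: float):
    names, bounds = [], []
    for name in spec.free:
        if name == "tau_R":
            names.append("log_gap")
            bounds.append((math.log(1e-7), math.log(0.2)))
        elif name == "tau_S":
            names.append("tau_S")
            bounds.append((0.0, tau_s_max))
        elif name in ("theta_R", "theta_S"):
            names.append("log_" + name)
            bounds.append((math.log(1e-5), math.log(1.0)))
        elif name == "phi":
            names.append("phi")
            bounds.append((0.0, 1.0))

    def decode(vec) -> MSciParams:
        vals = dict(zip(names, vec))
        out = {}
        if "phi" in vals:
            out["phi"] = float(np.clip(vals["phi"], 0.0, 1.0))
        for th in ("theta_R", "theta_S"):
            key = "log_" + th
            if key in vals:
                out[th] = math.exp(vals[key])
        tau_S = vals.get("tau_S", spec.fixed.get("tau_S", 0.0))
        out["tau_S"] = max(tau_S, 0.0)
        if "log_gap" in vals:
            out["tau_R"] = out["tau_S"] + math.exp(vals["log_gap"])
        return spec.build_params(out)

    def jacobian(vec) -> tuple[list[str], np.ndarray]:
        """Rows: natural identifiable params; cols: internal vector."""
        p = decode(vec)
        vals = dict(zip(names, vec))
        nat = list(MSciParams.IDENTIFIABLE)
        J = np.zeros((len(nat), len(names)))
        for j, nm in enumerate(names):
            if nm == "log_gap":
                J[nat.index("tau_R"), j] = p.tau_R - p.tau_S
            elif nm == "tau_S":
                J[nat.index("tau_S"), j] = 1.0
                J[nat.index("tau_R"), j] = 1.0  # tau_R = tau_S + gap
            elif nm == "log_theta_R":
                J[nat.index("theta_R"), j] = p.theta_R
                if spec.tie_thetas:
                    J[nat.index("theta_S"), j] = p.theta_S
            elif nm == "log_theta_S":
                J[nat.index("theta_S"), j] = p.theta_S
            elif nm == "phi":
                J[nat.index("phi"), j] = 1.0
        return nat, J

    return names, bounds, decode, jacobian


def _mscm_parameterization(variant: str, theta_B: float):
    names = ["log_tau_R", "log_theta_A", "log_theta_R", "log_M"]
    bounds = [
        (math.log(1e-5), math.log(0.2)),
        (math.log(1e-5), math.log(1.0)),
        (math.log(1e-5), math.log(1.0)),
        (math.log(1e-6), math.log(20.0)),
    ]
    if variant != "IM":
        names.append("frac_tau_T")  # tau_T as a fraction of tau_R
        bounds.append((1e-6, 1.0 - 1e-6))

    def decode(vec) -> MSCMParams:
        vals = dict(zip(names, vec))
        tau_R = math.exp(vals["log_tau_R"])
        tau_T = tau_R * vals.get("frac_tau_T", 0.0)
        return MSCMParams(
            variant=variant,
            tau_R=tau_R,
            tau_T=tau_T,
            theta_A=math.exp(vals["log_theta_A"]),
            theta_B=theta_B,
            theta_T=theta_B,
            theta_R=math.exp(vals["log_theta_R"]),
            M=math.exp(vals["log_M"]),
        )

    return names, bounds, decode, None


def _num_hessian(f, x, steps):
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            hi, hj = steps[i], steps[j]
            if i == j:
                H[i, i] = (f(x + 2 * hi * _e(k, i)) - 2 * f(x) + f(x - 2 * hi * _e(k, i))) / (
                    4 * hi**2
                )
            else:
                fpp = f(x + hi * _e(k, i) + hj * _e(k, j))
                fpm = f(x + hi * _e(k, i) - hj * _e(k, j))
                fmp = f(x - hi * _e(k, i) + hj * _e(k, j))
                fmm = f(x - hi * _e(k, i) - hj * _e(k, j))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi * hj)
    return H


def _e(k, i):
    v = np.zeros(k)
    v[i] = 1.0
    return v


def fit_ml(
    data,
    model: str = "msci",
    spec: FitMethodSpec | None = None,
    mutation_model: str = "binomial_jc",
    restarts: int = 3,
    seed: int = 0,
    theta_B: float = 0.01,
    start: dict | None = None,
) -> MLFit:
    """Maximize the pairwise-count likelihood under a gene-flow model.

    ``model`` is ``"msci"`` or one of ``"im"``, ``"iim"``, ``"sc"``.  For
    MSci, ``spec`` restricts which of the five identifiable parameters are
    free (all five by default).  For the migration models, ``theta_B`` is
    held fixed, since the density depends on ``M`` and ``theta_B`` only
    through their ratio.
    """
    xs, counts, n = _grouped(data)
    L = int(counts.sum())
    rng = np.random.default_rng(seed)

    if model == "msci":
        if spec is None:
            spec = FitMethodSpec("d", MSciParams.IDENTIFIABLE)
        names, bounds, decode, jacobian = _msci_parameterization(spec, tau_s_max=0.1)
        build_density = msci_density
    elif model in ("im", "iim", "sc"):
        names, bounds, decode, jacobian = _mscm_parameterization(
            model.upper(), theta_B
        )
        build_density = mscm_density
    else:
        raise ValueError(f"unknown model {model!r}")

    calc = MarginalCalculator(xs, n, mutation_model)

    def negll(vec) -> float:
        p = decode(vec)
        if p.validate():
            return 1e12
        pmf = calc.pmf(build_density(p))
        if np.any(pmf <= 0):
            return 1e12
        return -float(counts @ np.log(pmf)) / L

    starts = []
    # moment-based start: mean coalescent time from mean mismatch fraction
    pbar = min(float((counts @ xs) / (L * n)), 0.70)
    tbar = max(-3.0 / 8.0 * math.log1p(-4.0 * pbar / 3.0), 1e-5)
    default = {
        "log_gap": math.log(max(tbar, 1e-5)),
        "tau_S": min(0.3 * tbar, 0.1),
        "log_theta_R": math.log(max(tbar, 1e-4)),
        "log_theta_S": math.log(max(0.3 * tbar, 1e-4)),
        "phi": 0.2,
        "log_tau_R": math.log(max(0.7 * tbar, 1e-5)),
        "log_theta_A": math.log(max(0.3 * tbar, 1e-4)),
        "log_M": math.log(0.2),
        "frac_tau_T": 0.5,
    }
    if start:
        default.update(start)
    starts.append(
        [float(np.clip(default[k], lo, hi)) for k, (lo, hi) in zip(names, bounds)]
    )
    for _ in range(max(restarts, 1) - 1):
        vec = []
        for k, (lo, hi) in zip(names, bounds):
            if k.startswith("log_"):
                center = default[k]
                vec.append(float(np.clip(center + rng.uniform(-2, 2), lo, hi)))
            else:
                vec.append(rng.uniform(lo, hi))
        starts.append(vec)

    best = None
    msgs = []
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500},
        )
        res2 = optimize.minimize(
            negll, res.x, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 1500},
        )
        cand = res2 if res2.fun <= res.fun else res
        msgs.append(str(res.message))
        if best is None or cand.fun < best.fun:
            best = cand
            best_success = res.success or res2.success
    if best is None or best.fun >= 1e11:
        raise RuntimeError("ML fit failed for all restarts: " + " | ".join(msgs))

    params = decode(best.x)
    ll = -best.fun * L

    # curvature-based standard errors on the internal scale
    se: dict[str, float] = {}
    if jacobian is not None:
        at_bound = [
            not (lo + 1e-9 < v < hi - 1e-9)
            for v, (lo, hi) in zip(best.x, bounds)
        ]
        steps = np.array(
            [1e-3 * max(abs(v), 1e-2) if k.startswith("log_") else
             (1e-3 if k == "phi" else 1e-3 * max(abs(v), 1e-3))
             for k, v in zip(names, best.x)]
        )
        nat, J = jacobian(best.x)
        se = {k: math.nan for k in nat}
        free_idx = [i for i, ab in enumerate(at_bound) if not ab]
        if free_idx:
            Hfull = _num_hessian(lambda v: negll(v) * L, best.x, steps)
            Hf = Hfull[np.ix_(free_idx, free_idx)]
            try:
                cov_int = np.linalg.inv(Hf)
                Jf = J[:, free_idx]
                cov_nat = Jf @ cov_int @ Jf.T
                diag = np.diag(cov_nat)
                for i, k in enumerate(nat):
                    if diag[i] > 0 and not any(
                        at_bound[j] and abs(J[i, j]) > 0 for j in range(len(names))
                    ):
                        se[k] = math.sqrt(diag[i])
            except np.linalg.LinAlgError:
                pass

    return MLFit(
        model=model,
        params=params,
        se=se,
        loglik=ll,
        L=L,
        n=n,
        converged=bool(best_success),
        restarts=len(starts),
        method=spec if model == "msci" else None,
        data_key=(L, n, int(counts @ xs)),
    )


def profile_lr_zscore(
    data,
    fit: MLFit,
    param: str,
    value: float,
    mutation_model: str = "binomial_jc",
    restarts: int = 1,
    seed: int = 0,
) -> float:
    """Signed-root likelihood-ratio z-score for ``param = value``.

    ``z = sign(est - value) * sqrt(2 * (ll_max - ll_profile(value)))``,
    where the profile log-likelihood re-optimizes the other free
    parameters with ``param`` held at ``value``.  Unlike Wald
    (curvature-based) z-scores, this calibration is parameterization-
    invariant and remains accurate along the flat phi/theta_S ridge of
    weakly identified MSci fits.

    A parameter that is fixed (or tied) in the fit's method returns 0.0
    when ``value`` matches its fitted value and ``inf`` otherwise.
    """
    if fit.model != "msci":
        raise ValueError("profile z-scores are implemented for MSci fits")
    spec = fit.method
    if spec.tie_thetas and param == "theta_S":
        param = "theta_R"
    est = fit.estimates()[param]
    if param not in spec.free:
        fixed_val = spec.fixed.get(param)
        return 0.0 if fixed_val == value else math.inf
    sub = FitMethodSpec(
        spec.method,
        tuple(f for f in spec.free if f != param),
        {**spec.fixed, param: value},
        spec.tie_thetas,
    )
    p = fit.params
    start = {
        "log_gap": math.log(max(p.tau_R - p.tau_S, 1e-7)),
        "tau_S": p.tau_S,
        "log_theta_R": math.log(p.theta_R),
        "log_theta_S": math.log(p.theta_S),
        "phi": p.phi,
    }
    pfit = fit_ml(
        data, model="msci", spec=sub, mutation_model=mutation_model,
        restarts=restarts, seed=seed, start=start,
    )
    dll = max(fit.loglik - pfit.loglik, 0.0)
    return math.copysign(math.sqrt(2.0 * dll), est - value)


def compare_fits(fits: list[MLFit]) -> pd.DataFrame:
    """Tabulate fits of different models to the same dataset.

    Columns: model, per-parameter estimates (prefixed), log-likelihood and
    the difference to the best fit.  Raises if the fits are not on the
    same data.
    """
    if not fits:
        raise ValueError("need at least one fit")
    keys = {f.data_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different datasets")
    best = max(f.loglik for f in fits)
    rows = []
    for f in fits:
        row = {"model": f.model, "loglik": f.loglik, "delta_loglik": f.loglik - best}
        for k, v in f.estimates().items():
            row[f"est_{k}"] = v
            row[f"se_{k}"] = f.se.get(k, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
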