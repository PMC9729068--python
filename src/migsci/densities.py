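"""Closed-form pairwise coalescent-time densities under gene-flow models.

For one sequence sampled from each of two species, the backward-in-time
process of migration and coalescence over the gene-flow period is a
three-state Markov chain over {AB, AA, A}:

* ``AB`` -- one lineage in each species (initial state);
* ``AA`` -- the B lineage has jumped (backwards) into A;
* ``A``  -- the two lineages have coalesced.

Its generator has migration rate ``w = 4*M/theta_B`` out of ``AB`` and
coalescent rate ``2/theta_A`` out of ``AA``.  The pairwise coalescent-time
densities under the IM, IIM, SC and MSci models are piecewise sums of
(polynomial x exponential) terms derived from the chain's transition
probabilities; they are represented here as :class:`PiecewiseDensity`
objects shared by the quadrature, KL and simulation-validation code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .params import MSCMParams, MSciParams

__all__ = [
    "transition_matrix",
    "PiecewiseDensity",
    "mscm_density",
    "msci_density",
    "density_mscm",
    "density_msci",
    "density_moments",
]

# relative-threshold below which 2 - theta_A*w is treated as exactly zero
# (the prefactor w/(c - w) of the two-exponential pieces is singular there)
_SINGULAR_TOL = 1e-8


def _p_ab_aa(w: float, c: float, t: np.ndarray) -> np.ndarray:
    """P[AB -> AA](t) = w/(c-w) (e^{-wt} - e^{-ct}), stable at w = c.

    Away from the singularity the two-exponential form is exact and
    overflow-free; within a small window around ``(c-w)t = 0`` the
    series-safe form ``w t e^{-ct} (e^{(c-w)t}-1)/((c-w)t)`` takes over.
    """
    d = (c - w) * t
    near = np.abs(d) < 1e-4
    out = np.empty_like(t)
    if near.any():
        tn = t[near]
        dn = d[near]
        phi1 = np.ones_like(dn)
        nz = dn != 0
        phi1[nz] = np.expm1(dn[nz]) / dn[nz]
        out[near] = w * tn * np.exp(-c * tn) * phi1
    far = ~near
    if far.any():
        tf = t[far]
        out[far] = w / (c - w) * (np.exp(-w * tf) - np.exp(-c * tf))
    return out


def transition_matrix(w: float, theta_A: float, t) -> np.ndarray:
    """Transition probabilities of the migration/coalescent chain over time t.

    States are ordered (AB, AA, A).  The matrix is the exponential of the
    chain's generator, evaluated in closed form; the removable singularity
    at ``w = 2/theta_A`` is handled by an ``expm1``-based formulation that
    is uniformly stable.

    ``t`` may be a scalar or an array; arrays give a stacked ``(..., 3, 3)``
    result.
    """
    if w < 0:
        raise ValueError("migration rate w must be nonnegative")
    if theta_A <= 0:
        raise ValueError("theta_A must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be nonnegative")
    c = 2.0 / theta_A
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    e_w = np.exp(-w * t)
    e_c = np.exp(-c * t)
    p01 = _p_ab_aa(w, c, t)
    if scalar:
        t, e_w, e_c, p01 = t[0], e_w[0], e_c[0], p01[0]
        t = np.asarray(t)
    P = np.zeros(t.shape + (3, 3))
    P[..., 0, 0] = e_w
    P[..., 0, 1] = p01
    P[..., 0, 2] = 1.0 - e_w - p01
    P[..., 1, 1] = e_c
    P[..., 1, 2] = 1.0 - e_c
    P[..., 2, 2] = 1.0
    return P


# ---------------------------------------------------------------------------
# piecewise exponential densities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpTerm:
    """One term ``coef * (t - offset)^tpow * exp(-rate*(t - offset))``."""

    coef: float
    rate: float
    offset: float
    tpow: int = 0


@dataclass(frozen=True)
class PiecewiseDensity:
    """Density on (0, inf) that is a sum of exponential terms per interval.

    ``breakpoints`` are the interior knots ``(b_0=0, b_1, ..., b_k)``;
    piece ``i`` lives on ``(b_i, b_{i+1})`` and the final piece on
    ``(b_k, inf)``.  The final piece is always a single pure exponential,
    which permits exact tail integration everywhere downstream.
    """

    breakpoints: tuple[float, ...]
    pieces: tuple[tuple[ExpTerm, ...], ...]
    model: str

    def __post_init__(self):
        if len(self.pieces) != len(self.breakpoints):
            raise ValueError("need exactly one piece per breakpoint")
        tail = self.pieces[-1]
        if len(tail) != 1 or tail[0].tpow != 0:
            raise ValueError("tail piece must be a single pure exponential")

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.zeros_like(t)
        bps = list(self.breakpoints) + [np.inf]
        for i, terms in enumerate(self.pieces):
            mask = (t >= bps[i]) & (t < bps[i + 1])
            if not mask.any():
                continue
            ts = t[mask]
            acc = np.zeros_like(ts)
            for tm in terms:
                s = ts - tm.offset
                acc += tm.coef * s**tm.tpow * np.exp(-tm.rate * s)
            out[mask] = acc
        return float(out[0]) if scalar else out

    @property
    def support_min(self) -> float:
        """Smallest time with positive density."""
        bps = list(self.breakpoints)
        for b, terms in zip(bps, self.pieces):
            if any(tm.coef != 0 for tm in terms):
                return b
        return bps[-1]

    @property
    def tail(self) -> tuple[float, float, float]:
        """(amplitude, rate, start) of the final exponential piece."""
        tm = self.pieces[-1][0]
        return tm.coef, tm.rate, self.breakpoints[-1]

    # -- exact integrals ----------------------------------------------------

    @staticmethod
    def _term_integral(tm: ExpTerm, a: float, b: float) -> float:
        """Integral of the term over (a, b); b may be inf."""
        r = tm.coef
        lo, hi = a - tm.offset, (b - tm.offset) if math.isfinite(b) else math.inf

        def F(s: float) -> float:
            # integral from 0 to s of u^p e^{-rate u} du
            if tm.rate == 0:
                return s ** (tm.tpow + 1) / (tm.tpow + 1)
            if math.isinf(s):
                return math.factorial(tm.tpow) / tm.rate ** (tm.tpow + 1)
            if tm.tpow == 0:
                return -math.expm1(-tm.rate * s) / tm.rate
            # tpow == 1
            return (1.0 - (1.0 + tm.rate * s) * math.exp(-tm.rate * s)) / tm.rate**2

        return r * (F(hi) - F(lo))

    def piece_masses(self) -> np.ndarray:
        bps = list(self.breakpoints) + [math.inf]
        return np.array(
            [
                sum(self._term_integral(tm, bps[i], bps[i + 1]) for tm in terms)
                for i, terms in enumerate(self.pieces)
            ]
        )

    def integral(self) -> float:
        """Total mass on (0, inf), computed exactly term by term."""
        return float(self.piece_masses().sum())

    def cdf(self, t) -> np.ndarray | float:
        """Cumulative distribution function, exact term by term."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.zeros_like(t)
        bps = list(self.breakpoints) + [math.inf]
        cum = np.concatenate([[0.0], np.cumsum(self.piece_masses())])
        for i, terms in enumerate(self.pieces):
            lo, hi = bps[i], bps[i + 1]
            mask = (t >= lo) & (t < hi)
            if mask.any():
                vals = cum[i] + np.array(
                    [
                        sum(self._term_integral(tm, lo, ti) for tm in terms)
                        for ti in t[mask]
                    ]
                )
                out[mask] = vals
        return float(out[0]) if scalar else out


def _chain_pieces(
    w: float, theta_A: float, t0: float, t1: float
) -> tuple[ExpTerm, ...]:
    """Density terms ``c * P[AB,AA](t - t0)`` on (t0, t1).

    Near the removable singularity ``w = 2/theta_A`` the two-exponential
    form is replaced by its analytic limit ``c*w*(t-t0)*e^{-w(t-t0)}``.
    """
    c = 2.0 / theta_A
    if abs(2.0 - theta_A * w) < _SINGULAR_TOL:
        return (ExpTerm(c * w, w, t0, tpow=1),)
    amp = c * w / (c - w)
    return (ExpTerm(amp, w, t0), ExpTerm(-amp, c, t0))


def mscm_density(p: MSCMParams) -> PiecewiseDensity:
    """Pairwise coalescent-time density under IM, IIM, or SC.

    The IM density is the IIM density with ``tau_T = 0``.  The density is a
    function of ``M`` and ``theta_B`` only through ``w = 4*M/theta_B``.
    """
    bad = p.validate()
    if bad:
        raise ValueError("invalid MSCMParams: " + "; ".join(bad))
    w = p.w
    c = 2.0 / p.theta_A
    rR = 2.0 / p.theta_R
    if p.variant in ("IM", "IIM"):
        delta = p.tau_R - p.tau_T
        P = transition_matrix(w, p.theta_A, delta)
        tail_amp = (P[0, 0] + P[0, 1]) * rR
        if p.tau_T > 0:
            bps = (0.0, p.tau_T, p.tau_R)
            pieces = (
                (),
                _chain_pieces(w, p.theta_A, p.tau_T, p.tau_R),
                (ExpTerm(tail_amp, rR, p.tau_R),),
            )
        else:
            bps = (0.0, p.tau_R)
            pieces = (
                _chain_pieces(w, p.theta_A, 0.0, p.tau_R),
                (ExpTerm(tail_amp, rR, p.tau_R),),
            )
    else:  # SC: migration over (0, tau_T), then isolation until tau_R
        P = transition_matrix(w, p.theta_A, p.tau_T)
        mid_amp = P[0, 1] * c
        tail_amp = (P[0, 1] * math.exp(-c * (p.tau_R - p.tau_T)) + P[0, 0]) * rR
        bps = (0.0, p.tau_T, p.tau_R)
        pieces = (
            _chain_pieces(w, p.theta_A, 0.0, p.tau_T),
            (ExpTerm(mid_amp, c, p.tau_T),),
            (ExpTerm(tail_amp, rR, p.tau_R),),
        )
    return PiecewiseDensity(bps, pieces, p.variant.lower())


def msci_density(p: MSciParams) -> PiecewiseDensity:
    """Pairwise coalescent-time density under the two-species MSci model.

    Zero below ``tau_S``; an exponential pulse of weight ``phi`` in the
    donor population S on ``(tau_S, tau_R)``; a mixture of the escaped mass
    and the non-introgressed mass coalescing in the root beyond ``tau_R``.
    """
    bad = p.validate()
    if bad:
        raise ValueError("invalid MSciParams: " + "; ".join(bad))
    rS = 2.0 / p.theta_S
    rR = 2.0 / p.theta_R
    tail_amp = (p.phi * math.exp(-rS * (p.tau_R - p.tau_S)) + (1.0 - p.phi)) * rR
    if p.tau_S > 0:
        bps = (0.0, p.tau_S, p.tau_R)
        pieces = (
            (),
            (ExpTerm(p.phi * rS, rS, p.tau_S),),
            (ExpTerm(tail_amp, rR, p.tau_R),),
        )
    else:
        bps = (0.0, p.tau_R)
        pieces = (
            (ExpTerm(p.phi * rS, rS, 0.0),),
            (ExpTerm(tail_amp, rR, p.tau_R),),
        )
    return PiecewiseDensity(bps, pieces, "msci")


def density_mscm(t, p: MSCMParams):
    """Evaluate the IM/IIM/SC coalescent-time density at ``t``."""
    return mscm_density(p)(t)


def density_msci(t, p: MSciParams):
    """Evaluate the MSci coalescent-time density at ``t``."""
    return msci_density(p)(t)


def density_for(params) -> PiecewiseDensity:
    """Dispatch to the appropriate density builder for a parameter object."""
    if isinstance(params, MSCMParams):
        return mscm_density(params)
    if isinstance(params, MSciParams):
        return msci_density(params)
    raise TypeError(f"no pairwise density for {type(params).__name__}")


def density_moments(density: PiecewiseDensity, tol: float = 1e-8):
    """Mean and variance of the coalescent time under a normalized density.

    Finite pieces are integrated by adaptive quadrature; the exponential
    tail contributes its shifted-exponential moments exactly.
    """
    total = density.integral()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"density is not normalized (mass {total:.8f})")
    bps = list(density.breakpoints)
    m1 = m2 = 0.0
    for i in range(len(bps) - 1):
        a, b = bps[i], bps[i + 1]
        if a == b:
            continue
        m1 += integrate.quad(lambda t: t * density(t), a, b, epsabs=tol)[0]
        m2 += integrate.quad(lambda t: t * t * density(t), a, b, epsabs=tol)[0]
    amp, rate, start = density.tail
    mass = amp / rate
    mu = start + 1.0 / rate
    m1 += mass * mu
    m2 += mass * (mu**2 + 1.0 / rate**2)
    return m1, m2 - m1**2
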