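"""Fractional-order operators and the constant-phase reduction of
multi-timescale adaptation.

A bank of first-order high-pass (adaptive) stages with well-separated time
constants can mimic a fractional differentiator ``(i w)^alpha`` over a
finite band.  The signature of fractional dynamics is a frequency-
independent phase advance ``alpha*pi/2``; the adaptation constants ``A_n``
are fitted so the summed phase of the stages is as close to that constant
as possible (Nelder-Mead on a log-frequency grid).

Also provided: the gamma-function superposition identity expressing a
power-law decay ``t**(-k)`` as a weighted continuum of exponentials, a
Gruenwald-Letnikov discretization of the (Riemann-Liouville) fractional
derivative, and step responses of high-pass stages / cascades.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, signal as sps
from scipy.special import gamma as gamma_fn

from .filters import FilterCascade, HighPassStage, LowPassStage

__all__ = [
    "FractionalOrder",
    "PhaseFitResult",
    "SampledSignal",
    "frac_phase",
    "frac_transfer",
    "fit_gains_constant_phase",
    "gamma_superposition",
    "fractional_derivative",
    "step_response",
    "fractional_step_response",
]

_N_FIT_FREQS = 50  # log-spaced points used by the phase fit objective


@dataclass(frozen=True)
class FractionalOrder:
    """Order of fractional differentiation, in [0, 1].

    ``alpha = 0`` is the identity, ``alpha = 1`` the first derivative;
    non-integer orders in between carry power-law memory.
    """

    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class SampledSignal:
    """Real signal on a strictly increasing time grid (seconds).

    Operators with memory (:func:`fractional_derivative`) additionally
    require the grid to be uniform; see :attr:`dt`.
    """

    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("t and values must be equal-length 1-d arrays")
        if t.size < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)

    @property
    def is_uniform(self) -> bool:
        dt = np.diff(self.t)
        return bool(np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12))

    @property
    def dt(self) -> float:
        """Sample interval; only defined for uniform grids."""
        if not self.is_uniform:
            raise ValueError("time grid is not uniform")
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class PhaseFitResult:
    """Adaptation constants fitted for a constant-phase approximation.

    ``residual`` is the maximum absolute deviation (radians) of the
    cascade phase from the target ``alpha*pi/2`` over the fit band.
    """

    taus: tuple
    A_values: tuple
    alpha: float
    band: tuple
    mode: str
    residual: float
    iterations: int = 0
    converged: bool = True

    def cascade(self, g: float = 1.0) -> FilterCascade:
        """High-pass cascade realizing the fit (per-stage gain ``g``)."""
        A = self.A_values if len(self.A_values) == len(self.taus) else self.A_values * len(self.taus)
        return FilterCascade(
            highpass=tuple(HighPassStage(g=g, tau=t, A=a) for t, a in zip(self.taus, A))
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "taus": list(self.taus),
                "A_values": list(self.A_values),
                "alpha": self.alpha,
                "band": list(self.band),
                "mode": self.mode,
                "residual": self.residual,
                "iterations": self.iterations,
                "converged": self.converged,
            },
            indent=2,
        )


def frac_phase(alpha: float) -> float:
    """Frequency-independent phase advance of ``(i w)^alpha``: ``alpha*pi/2``."""
    FractionalOrder(alpha)
    return alpha * math.pi / 2.0


def frac_transfer(alpha: float, g: float, f) -> np.ndarray:
    """Fractional differentiator ``H(i w) = g * (i*2*pi*f)^alpha``.

    Evaluated as ``g*(2*pi*f)**alpha * exp(i*alpha*pi/2)`` so the phase is
    exactly constant across the grid.
    """
    FractionalOrder(alpha)
    if g <= 0:
        raise ValueError("g must be > 0")
    freqs = np.atleast_1d(np.asarray(getattr(f, "freqs", f), dtype=float))
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be > 0 Hz")
    return g * (2.0 * np.pi * freqs) ** alpha * np.exp(1j * frac_phase(alpha))


def _cascade_phase(taus: np.ndarray, A: np.ndarray, freqs_hz: np.ndarray) -> np.ndarray:
    """Summed phase of high-pass stages: arctan(w*tau) - arctan(w*tau/A)."""
    w = 2.0 * np.pi * freqs_hz[:, None]
    return np.sum(np.arctan(w * taus) - np.arctan(w * taus / A), axis=1)


def fit_gains_constant_phase(
    taus: Sequence[float],
    alpha: float,
    band: Sequence[float],
    mode: str = "shared",
    max_iter: int = 4000,
) -> PhaseFitResult:
    """Fit adaptation constants so the cascade phase is ~``alpha*pi/2``.

    Parameters
    ----------
    taus
        Distinct positive time constants (seconds) of the adaptive stages.
    alpha
        Target fractional order in [0, 1].
    band
        ``(f_lo, f_hi)`` in Hz; the squared phase deviation is minimized
        on 50 log-spaced frequencies spanning the band.
    mode
        ``"shared"`` fits one A for all stages, ``"per-stage"`` one per
        stage.  The per-stage fit is seeded from the shared solution and
        therefore never reports a larger residual.

    Notes
    -----
    The search runs over ``A = 1 + exp(u)`` so the nominally unconstrained
    Nelder-Mead simplex respects ``A > 1``.
    """
    FractionalOrder(alpha)
    taus = np.asarray(taus, dtype=float)
    if taus.ndim != 1 or taus.size == 0 or np.any(taus <= 0):
        raise ValueError("taus must be positive")
    if len(set(taus.tolist())) != taus.size:
        raise ValueError("taus must be distinct")
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi:
        raise ValueError("band must satisfy 0 < f_lo < f_hi")
    if mode not in ("shared", "per-stage"):
        raise ValueError("mode must be 'shared' or 'per-stage'")

    freqs = np.logspace(np.log10(f_lo), np.log10(f_hi), _N_FIT_FREQS)
    target = frac_phase(alpha)

    if alpha == 0.0:
        # no adaptation: A = 1 gives identically zero phase
        nA = 1 if mode == "shared" else taus.size
        return PhaseFitResult(
            taus=tuple(taus), A_values=(1.0,) * nA, alpha=alpha,
            band=(f_lo, f_hi), mode=mode, residual=0.0,
        )

    def expand(u: np.ndarray) -> np.ndarray:
        return 1.0 + np.exp(u)

    def objective(u: np.ndarray) -> float:
        dev = _cascade_phase(taus, expand(np.broadcast_to(u, taus.shape)), freqs) - target
        return float(np.sum(dev * dev))

    def max_dev(A: np.ndarray) -> float:
        return float(np.max(np.abs(_cascade_phase(taus, A, freqs) - target)))

    u0 = np.array([math.log(alpha)])  # A0 = 1 + alpha: correct small-alpha limit
    res_shared = optimize.minimize(
        objective, u0, method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-14},
    )
    A_shared = expand(np.broadcast_to(res_shared.x, taus.shape))
    shared_resid = max_dev(A_shared)

    if mode == "shared":
        return PhaseFitResult(
            taus=tuple(taus), A_values=(float(1.0 + math.exp(res_shared.x[0])),),
            alpha=alpha, band=(f_lo, f_hi), mode=mode, residual=shared_resid,
            iterations=int(res_shared.nit), converged=bool(res_shared.success),
        )

    res = optimize.minimize(
        objective, np.full(taus.size, res_shared.x[0]), method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-14},
    )
    A = expand(res.x)
    resid = max_dev(A)
    if resid > shared_resid:  # shared solution is a point of this space
        A, resid = A_shared, shared_resid
    return PhaseFitResult(
        taus=tuple(taus), A_values=tuple(float(a) for a in A), alpha=alpha,
        band=(f_lo, f_hi), mode=mode, residual=resid,
        iterations=int(res_shared.nit + res.nit),
        converged=bool(res_shared.success and res.success),
    )


def gamma_superposition(k: float, t: float) -> float:
    """Evaluate ``t**(-k)`` as a weighted superposition of exponentials.

    Numerically computes ``(1/Gamma(k)) * int_0^inf lam^(k-1) e^(-lam t) dlam``,
    the gamma-function identity by which a power-law decay is an infinite
    mixture of exponential decays with weights ``lam^(k-1)``.
    """
    if k <= 0 or t <= 0:
        raise ValueError("k and t must be > 0")

    def integrand(lam: float) -> float:
        return lam ** (k - 1.0) * math.exp(-lam * t)

    # split at the kernel scale to tame the lam -> 0 singularity for k < 1
    split = 1.0 / t
    v1, e1 = integrate.quad(integrand, 0.0, split, limit=500, epsabs=0, epsrel=1e-11)
    v2, e2 = integrate.quad(integrand, split, np.inf, limit=500, epsabs=0, epsrel=1e-11)
    total = (v1 + v2) / gamma_fn(k)
    if not np.isfinite(total) or (e1 + e2) > 1e-7 * abs(v1 + v2):
        raise ArithmeticError(
            f"quadrature failed: value={v1 + v2}, abserr={e1 + e2}"
        )
    return float(total)


def _gl_weights(alpha: float, n: int) -> np.ndarray:
    """Gruenwald-Letnikov binomial weights w_m = (-1)^m C(alpha, m)."""
    w = np.empty(n)
    w[0] = 1.0
    for m in range(1, n):
        w[m] = w[m - 1] * (1.0 - (alpha + 1.0) / m)
    return w


def fractional_derivative(sig: SampledSignal, alpha: float) -> SampledSignal:
    """Discrete fractional derivative of order ``alpha`` in [0, 1].

    Uses the Gruenwald-Letnikov scheme
    ``D^alpha f(t_j) = h^(-alpha) * sum_m w_m f(t_{j-m})`` on the uniform
    grid, the standard consistent discretization of the Riemann-Liouville
    integral with the signal taken to be zero before the first sample.
    The output is non-local: each sample depends on the full history.
    """
    FractionalOrder(alpha)
    h = sig.dt
    n = sig.values.size
    if alpha == 0.0:
        return SampledSignal(sig.t, sig.values.copy())
    w = _gl_weights(alpha, n)
    out = sps.fftconvolve(sig.values, w)[:n] * h ** (-alpha)
    return SampledSignal(sig.t, out)


def step_response(cascade, t: np.ndarray) -> SampledSignal:
    """Unit-step response of a filter stage or cascade on time grid ``t``.

    For a single high-pass stage the closed form is
    ``g*(1/A + (1 - 1/A)*exp(-A*t/tau))``: an instantaneous jump to ``g``
    decaying to the DC gain ``g/A``.  Cascades are evaluated through the
    rational transfer function (products of the stage polynomials in s).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if isinstance(cascade, HighPassStage):
        st = cascade
        return SampledSignal(
            t, st.g * (1.0 / st.A + (1.0 - 1.0 / st.A) * np.exp(-st.A * t / st.tau))
        )
    if isinstance(cascade, LowPassStage):
        return SampledSignal(t, cascade.k * (1.0 - np.exp(-t / cascade.tau)))
    num, den = np.array([1.0]), np.array([1.0])
    for st in cascade.highpass:
        num = np.polymul(num, st.g * np.array([st.tau, 1.0]))
        den = np.polymul(den, np.array([st.tau, st.A]))
    for st in cascade.lowpass:
        num = np.polymul(num, np.array([st.k]))
        den = np.polymul(den, np.array([st.tau, 1.0]))
    # partial fractions of H(s)/s give the step response analytically,
    # valid on arbitrary (e.g. log-spaced) time grids
    r, p, k_direct = sps.residue(num, np.polymul(den, [1.0, 0.0]))
    y = np.zeros(t.shape, dtype=complex)
    seen: dict = {}
    for ri, pi in zip(r, p):
        key = complex(np.round(pi, 12))
        m = seen.get(key, 0) + 1
        seen[key] = m
        y += ri * t ** (m - 1) * np.exp(pi * t) / math.factorial(m - 1)
    return SampledSignal(t, np.real(y))


def fractional_step_response(alpha: float, t: np.ndarray) -> SampledSignal:
    """Step response of the fractional differentiator: ``t**(-alpha)/Gamma(1-alpha)``.

    A power-law decay -- the hallmark of scale-free adaptation.  Samples
    at ``t = 0`` evaluate to ``inf`` for ``alpha > 0``.
    """
    FractionalOrder(alpha)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(divide="ignore"):
        vals = t ** (-alpha) / gamma_fn(1.0 - alpha)
    return SampledSignal(t, vals)
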