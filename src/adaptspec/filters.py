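"""Closed-form linear filter models of neural adaptation.

Spike-frequency adaptation (SFA) and linearized short-term synaptic
depression (STD) are first-order high-pass filters; passive membrane
integration is a first-order low-pass.  Cascades of such stages, composed
multiplicatively in the frequency domain, shape the power spectral density
of the population signal.  All public functions take frequencies in Hz;
the angular frequency ``omega = 2*pi*f`` is applied internally, i.e. the
Laplace variable is ``s = i*2*pi*f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "SFAParams",
    "STDLinParams",
    "HighPassStage",
    "LowPassStage",
    "FilterCascade",
    "FrequencyGrid",
    "sfa_transfer",
    "std_linear_transfer",
    "cascade_response",
    "cascade_magnitude_sq",
    "dc_output_power",
    "dc_peak_input",
    "shaped_psd",
    "psd_slope",
]


@dataclass(frozen=True)
class SFAParams:
    """Spike-frequency adaptation as a linear high-pass filter.

    The underlying system is ``y = gamma*x - c*a`` with
    ``tau*da/dt = -a + F*y``: the adaptation variable ``a`` integrates the
    firing-rate output and feeds back subtractively.

    Parameters
    ----------
    gamma, c
        Positive gain constants (input->output and adaptation->output).
    F
        Strength of the output's drive onto the adaptation variable,
        in (0, 1).  ``F = 0`` is allowed as the no-adaptation limit.
    tau
        Effective adaptation time constant in seconds.
    """

    gamma: float = 1.0
    c: float = 1.0
    F: float = 0.5
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.c < 0:
            raise ValueError("gamma must be > 0 and c >= 0")
        if not 0 <= self.F < 1:
            raise ValueError("F must lie in [0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0 seconds")

    @property
    def dc_gain(self) -> float:
        return self.gamma / (1.0 + self.c * self.F)


@dataclass(frozen=True)
class STDLinParams:
    """Short-term synaptic depression linearized about a steady state.

    The full system ``y = gamma*x*a``, ``tau*da/dt = 1 - a - x*F*a`` is
    nonlinear in ``x*a``; for small fluctuations around the mean
    presynaptic rate ``x0`` the steady state is ``a0 = 1/(1 + x0*F)`` and
    the small-signal transfer function is a high-pass whose gain shrinks
    with ``x0``.
    """

    gamma: float = 1.0
    F: float = 0.5
    tau: float = 1.0
    x0: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not 0 <= self.F < 1:
            raise ValueError("F must lie in [0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0 seconds")
        if self.x0 < 0:
            raise ValueError("steady-state input x0 must be >= 0")

    @property
    def a0(self) -> float:
        """Steady-state depression level, in (0, 1]."""
        return 1.0 / (1.0 + self.x0 * self.F)

    @property
    def dc_gain(self) -> float:
        return self.gamma / (1.0 + self.x0 * self.F) ** 2


@dataclass(frozen=True)
class HighPassStage:
    """Generic adaptive mechanism: ``H(s) = g*(tau*s + 1)/(tau*s + A)``.

    ``A >= 1`` is the adaptation constant; ``A`` closer to 1 means less
    adaptation (``A = 1`` is a pure gain).  DC gain is ``g/A``, the
    high-frequency gain is ``g``.
    """

    g: float = 1.0
    tau: float = 1.0
    A: float = 1.0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0 seconds")
        if self.A < 1:
            raise ValueError("adaptation constant A must be >= 1")

    def response(self, freqs_hz: np.ndarray) -> np.ndarray:
        s = 2j * np.pi * np.asarray(freqs_hz, dtype=float)
        return self.g * (self.tau * s + 1.0) / (self.tau * s + self.A)


@dataclass(frozen=True)
class LowPassStage:
    """Passive membrane filtering: ``H(s) = k/(tau*s + 1)``."""

    k: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0 seconds")

    def response(self, freqs_hz: np.ndarray) -> np.ndarray:
        s = 2j * np.pi * np.asarray(freqs_hz, dtype=float)
        return self.k / (self.tau * s + 1.0)


@dataclass(frozen=True)
class FilterCascade:
    """Series composition of adaptive (high-pass) and membrane (low-pass)
    stages; the response at any frequency is the product of the stage
    responses."""

    highpass: tuple = field(default_factory=tuple)
    lowpass: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "highpass", tuple(self.highpass))
        object.__setattr__(self, "lowpass", tuple(self.lowpass))
        if not self.highpass and not self.lowpass:
            raise ValueError("cascade must contain at least one stage")

    @property
    def stages(self) -> tuple:
        return self.highpass + self.lowpass


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive frequencies in Hz."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-d array")
        if np.any(f <= 0):
            raise ValueError("frequencies must be > 0 Hz")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs", f)

    @classmethod
    def logspace(cls, f_lo: float, f_hi: float, n: int = 200) -> "FrequencyGrid":
        return cls(np.logspace(np.log10(f_lo), np.log10(f_hi), n))

    def __len__(self) -> int:
        return len(self.freqs)


Freqs = Union[FrequencyGrid, Sequence[float], np.ndarray]


def _as_freqs(f: Freqs) -> np.ndarray:
    if isinstance(f, FrequencyGrid):
        return f.freqs
    return FrequencyGrid(np.asarray(f, dtype=float)).freqs


def sfa_transfer(p: SFAParams, f: Freqs) -> np.ndarray:
    """Complex SFA transfer function ``gamma*(tau*s+1)/(tau*s+1+c*F)``."""
    s = 2j * np.pi * _as_freqs(f)
    return p.gamma * (p.tau * s + 1.0) / (p.tau * s + 1.0 + p.c * p.F)


def std_linear_transfer(p: STDLinParams, f: Freqs) -> np.ndarray:
    """Complex small-signal STD transfer function.

    ``H(s) = gamma/(1+x0*F) * (tau*s+1)/(tau*s+1+x0*F)``; the leading
    factor is the steady-state depression ``a0``.
    """
    s = 2j * np.pi * _as_freqs(f)
    return (p.gamma * p.a0) * (p.tau * s + 1.0) / (p.tau * s + 1.0 + p.x0 * p.F)


def cascade_response(c: FilterCascade, f: Freqs) -> np.ndarray:
    """Product of all stage responses on the frequency grid."""
    freqs = _as_freqs(f)
    out = np.ones(freqs.shape, dtype=complex)
    for stage in c.stages:
        out = out * stage.response(freqs)
    return out


def cascade_magnitude_sq(
    sfa: SFAParams, std: STDLinParams, lp: LowPassStage, f: Freqs
) -> np.ndarray:
    """|H|^2 of the SFA -> STD -> membrane low-pass cascade, closed form.

    The SFA and STD stages contribute sigmoidal high-pass factors
    ``(tau^2 w^2 + 1)/(tau^2 w^2 + (1+cF)^2)`` (resp. ``(1+x0 F)^2``),
    scaled by the squared gains; the membrane contributes a Lorentzian.
    Agrees with ``|sfa_transfer * std_linear_transfer * lp.response|^2``.
    """
    w2 = (2.0 * np.pi * _as_freqs(f)) ** 2
    pref = (sfa.gamma**2 * std.gamma**2 * lp.k**2) / (1.0 + std.x0 * std.F) ** 2
    sfa_term = (sfa.tau**2 * w2 + 1.0) / (sfa.tau**2 * w2 + (1.0 + sfa.c * sfa.F) ** 2)
    std_term = (std.tau**2 * w2 + 1.0) / (std.tau**2 * w2 + (1.0 + std.x0 * std.F) ** 2)
    lp_term = 1.0 / (lp.tau**2 * w2 + 1.0)
    return pref * sfa_term * std_term * lp_term


def dc_output_power(n: int, F: float, gamma: float, x0: float) -> float:
    """Steady-state (DC) output power of ``n`` STD timescales sharing one F.

    ``|Y(0)|^2 = x0 * gamma^(2n) / (1 + x0*F)^(4n)`` -- non-monotonic in
    the steady-state input rate ``x0``: more input initially raises the
    output, but depression eventually wins.
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if not 0 < F < 1:
        raise ValueError("F must lie in (0, 1)")
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    return x0 * gamma ** (2 * n) / (1.0 + x0 * F) ** (4 * n)


def dc_peak_input(n: int, F: float) -> float:
    """Input rate maximizing :func:`dc_output_power`: ``1/(4nF - F)``."""
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if not 0 < F < 1:
        raise ValueError("F must lie in (0, 1); F = 0 has no finite peak")
    return 1.0 / (4.0 * n * F - F)


def shaped_psd(c: FilterCascade, input_psd: np.ndarray, f: Freqs) -> np.ndarray:
    """PSD of the cascade output for a given input PSD:
    ``output = input_psd * |H|^2``."""
    freqs = _as_freqs(f)
    psd = np.asarray(input_psd, dtype=float)
    if psd.shape != freqs.shape:
        raise ValueError("input_psd and frequency grid must have equal length")
    if np.any(psd < 0):
        raise ValueError("input_psd must be non-negative")
    return psd * np.abs(cascade_response(c, freqs)) ** 2


def psd_slope(psd: np.ndarray, f: Freqs, band: Sequence[float]) -> float:
    """Least-squares log10-log10 slope of a PSD restricted to a band.

    Returns the spectral exponent estimate: ``d log10(P) / d log10(f)``
    over ``band = (f_lo, f_hi)`` inclusive.  At least 5 grid points must
    fall inside the band.
    """
    freqs = _as_freqs(f)
    psd = np.asarray(psd, dtype=float)
    if psd.shape != freqs.shape:
        raise ValueError("psd and frequency grid must have equal length")
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi:
        raise ValueError("band must satisfy 0 < f_lo < f_hi")
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    if sel.sum() < 5:
        raise ValueError("need at least 5 frequency points inside the band")
    if np.any(psd[sel] <= 0):
        raise ValueError("PSD must be positive inside the band")
    slope, _ = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)
    return float(slope)
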