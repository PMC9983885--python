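"""Two-timescale short-term synaptic depression (STD).

Each synapse carries a fast (``d``, tau = 0.6 s) and a slow (``D``,
tau = 9 s) depression variable.  Between presynaptic spikes both relax
exponentially toward 1 (full recovery); at each spike the conductance
amplitude ``G = d * D`` is read out with the resources available at spike
arrival, after which ``d`` and ``D`` are depressed multiplicatively
(``d -> f_d * d``, ``D -> f_D * D``).  Facilitation is omitted.  The
summed amplitude trains of a population, filtered by a causal 0.3 s
exponential, form the LFP proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np

from .neuron import SpikeTrain

__all__ = [
    "STDParams",
    "DepressionState",
    "AmplitudeTrain",
    "propagate",
    "run_train",
    "amplitudes_to_signal",
]


@dataclass(frozen=True)
class STDParams:
    """Per-spike depression factors and recovery time constants.

    High STD: ``f_d = 0.4``, ``f_D = 0.995``; Low STD: ``f_d = 0.7``,
    ``f_D = 0.999``.
    """

    f_d: float = 0.4
    f_D: float = 0.995
    tau_d: float = 0.6  # s
    tau_D: float = 9.0  # s
    filter_tau: float = 0.3  # s, LFP-proxy exponential kernel

    def __post_init__(self) -> None:
        if not (0 < self.f_d <= 1 and 0 < self.f_D <= 1):
            raise ValueError("per-spike factors must lie in (0, 1]")
        if min(self.tau_d, self.tau_D, self.filter_tau) <= 0:
            raise ValueError("time constants must be > 0")

    @classmethod
    def high(cls) -> "STDParams":
        return cls(f_d=0.4, f_D=0.995)

    @classmethod
    def low(cls) -> "STDParams":
        return cls(f_d=0.7, f_D=0.999)

    @classmethod
    def from_level(cls, level: str) -> "STDParams":
        if level == "high":
            return cls.high()
        if level == "low":
            return cls.low()
        raise ValueError("STD level must be 'low' or 'high'")


@dataclass(frozen=True)
class DepressionState:
    """Fast/slow depression variables in (0, 1] and the last spike time."""

    d: float = 1.0
    D: float = 1.0
    t_last: float = -np.inf

    def __post_init__(self) -> None:
        if not (0 < self.d <= 1 and 0 < self.D <= 1):
            raise ValueError("d and D must lie in (0, 1]")


@dataclass(frozen=True)
class AmplitudeTrain:
    """Conductance amplitudes ``G_i = d_i * D_i`` at spike times (s)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape:
            raise ValueError("times and amplitudes must have equal length")
        if a.size and (np.any(a <= 0) or np.any(a > 1)):
            raise ValueError("amplitudes must lie in (0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return len(self.times)


def propagate(
    params: STDParams, state: DepressionState, spike_time: float
) -> Tuple[DepressionState, DepressionState, float]:
    """Advance the synapse to ``spike_time``: recover, read out, depress.

    Recovery toward 1 over the inter-spike interval,
    ``d_pre = 1 - (1 - d) * exp(-dt/tau_d)`` (likewise ``D``); the
    amplitude is ``d_pre * D_pre`` (resources available at arrival); the
    post-spike state is ``(f_d * d_pre, f_D * D_pre)``.

    Returns ``(pre_spike_state, post_spike_state, amplitude)``.
    """
    if spike_time <= state.t_last:
        raise ValueError("spike times must be strictly increasing")
    dt = spike_time - state.t_last
    d_pre = 1.0 - (1.0 - state.d) * np.exp(-dt / params.tau_d)
    D_pre = 1.0 - (1.0 - state.D) * np.exp(-dt / params.tau_D)
    amp = d_pre * D_pre
    pre = DepressionState(d=d_pre, D=D_pre, t_last=spike_time)
    post = DepressionState(d=params.f_d * d_pre, D=params.f_D * D_pre, t_last=spike_time)
    return pre, post, amp


def run_train(
    params: STDParams, spikes: Union[SpikeTrain, Sequence[float], np.ndarray]
) -> AmplitudeTrain:
    """Apply the depression recursion from rest (d = D = 1) over a train."""
    times = np.asarray(getattr(spikes, "times", spikes), dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be strictly increasing")
    amps = np.empty(times.size)
    d = D = 1.0
    t_last = -np.inf
    for i, t in enumerate(times):
        dt = t - t_last
        d = 1.0 - (1.0 - d) * np.exp(-dt / params.tau_d)
        D = 1.0 - (1.0 - D) * np.exp(-dt / params.tau_D)
        amps[i] = d * D
        d *= params.f_d
        D *= params.f_D
        t_last = t
    return AmplitudeTrain(times=times, amplitudes=amps)


def amplitudes_to_signal(
    trains: Sequence[AmplitudeTrain],
    filter_tau: float,
    dt: float,
    duration: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sum amplitude impulse trains and filter with a causal exponential.

    Each amplitude contributes ``G_i * exp(-(t - t_i)/filter_tau)`` for
    ``t >= t_i``; contributions add linearly across spikes and neurons.
    The kernel is evaluated with exact spike-time phase (no binning of
    spike times onto the sample grid).

    Parameters
    ----------
    trains
        Amplitude trains (one per presynaptic neuron).
    filter_tau, dt, duration
        Kernel time constant, sample interval and signal length, seconds.

    Returns
    -------
    (t, signal)
        Uniform time grid ``0, dt, ..., <= duration`` and the filtered sum.
    """
    if filter_tau <= 0 or dt <= 0 or duration <= 0:
        raise ValueError("filter_tau, dt and duration must be > 0")
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt
    imp = np.zeros(n)
    for tr in trains:
        if len(tr) == 0:
            continue
        if tr.times[0] < 0 or tr.times[-1] > duration:
            raise ValueError("spike times must lie within [0, duration]")
        # deposit each impulse into the first sample at/after the spike,
        # pre-decayed to that sample time so kernel phase is exact
        j = np.ceil(tr.times / dt - 1e-12).astype(np.int64)
        j = np.minimum(j, n - 1)
        phase = np.exp(-(j * dt - tr.times) / filter_tau)
        np.add.at(imp, j, tr.amplitudes * phase)
    decay = np.exp(-dt / filter_tau)
    from scipy.signal import lfilter

    sig = lfilter([1.0], [1.0, -decay], imp)
    return t, sig
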