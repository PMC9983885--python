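"""Three adaptation timescales approximate a fractional differentiator.

Fits the adaptation constants A of a 0.05/0.5/5 s high-pass cascade so
its phase is close to the constant alpha*pi/2 over 0.05-5 Hz, then checks
the resulting power-law amplitude response.
"""

import numpy as np

import adaptspec as a

taus, band = [0.05, 0.5, 5.0], (0.05, 5.0)
for alpha in (0.1, 0.3, 0.5):
    fit = a.fit_gains_constant_phase(taus, alpha, band, mode="shared")
    print(f"alpha={alpha}: shared A={fit.A_values[0]:.4f}, "
          f"max phase deviation {fit.residual:.4f} rad "
          f"(target phase {a.frac_phase(alpha):.4f} rad)")

# amplitude response of the fitted cascade follows ~ (2*pi*f)^alpha
alpha = 0.1
fit = a.fit_gains_constant_phase(taus, alpha, band, mode="shared")
f = np.array([0.1, 1.0])
mag = np.abs(a.cascade_response(fit.cascade(), f))
print(f"alpha={alpha}: |H(1 Hz)|/|H(0.1 Hz)| = {mag[1]/mag[0]:.4f}, "
      f"power law predicts 10^alpha = {10**alpha:.4f}")

# the same power law in the time domain: Gruenwald-Letnikov derivative
t = np.linspace(0, 2, 2001)
d = a.fractional_derivative(a.SampledSignal(t, t.copy()), 0.5)
print(f"D^0.5 applied to f(t)=t, at t=1: {d.values[1000]:.5f} "
      f"(closed form 2/sqrt(pi) = {2/np.sqrt(np.pi):.5f})")
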