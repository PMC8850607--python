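"""Simulate the bounded PERCLOS dynamic and identify its parameters.

PERCLOS (fraction of a one-minute window with the eyes at least 80% closed)
is modelled as X_i = 0.5*(1 + tanh(a X_{i-1} + b + eps)), which keeps every
trajectory inside (0, 1).  Because the squash is invertible, the parameters
come back out by plain least squares on the atanh-transformed values.
"""

import numpy as np

from perclos import DEFAULT_STATE, fit_state_model, one_step_residuals, simulate_states

# ~540 minutes of driving on the 30-second grid
x = simulate_states(DEFAULT_STATE, n_steps=1080, x0=0.2, seed=1)
print(f"simulated {len(x)} steps; PERCLOS range "
      f"[{x.values.min():.3f}, {x.values.max():.3f}], mean {x.values.mean():.3f}")

fit = fit_state_model(x)
print(f"generating parameters: a={DEFAULT_STATE.a}, b={DEFAULT_STATE.b}, "
      f"sigma_eps2={DEFAULT_STATE.sigma_eps2}")
print(f"recovered parameters:  a={fit.a:.3f}, b={fit.b:.3f}, "
      f"sigma_eps2={fit.sigma_eps2:.4f}  ({fit.n_pairs} transition pairs)")

rep = one_step_residuals(x, fit.model)
print(f"one-step prediction RMSE on the PERCLOS scale: {rep.rmse:.4f}")
print("(the residual is the latent noise compressed by the tanh squash, so "
      "it is small where the trajectory sits in a saturated regime)")
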