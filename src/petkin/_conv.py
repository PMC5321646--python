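"""Exact convolution of a piecewise-linear input with decaying exponentials.

The workhorse for every model in the package: tissue responses, spectral
basis functions and reference-model basis functions are all convolutions
``u(t) * exp(-lam*t)`` of a sampled input ``u``.  On a uniform grid with the
input linear within each step, the convolution obeys an exact first-order
recursion, which we run as an IIR filter (``scipy.signal.lfilter``) so the
cost is a single C-speed pass per exponential.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

__all__ = ["exp_conv", "UniformGrid"]


def _step_coefficients(lam: float, dt: float):
    """IIR coefficients for y' = -lam*y + u with u piecewise linear.

    y[n] = E*y[n-1] + b_prev*u[n-1] + b_now*u[n], E = exp(-lam*dt).
    """
    x = lam * dt
    if x < 1e-12:
        return 1.0 - x, dt / 2.0, dt / 2.0
    E = np.exp(-x)
    phi1 = -np.expm1(-x) / lam          # int_0^dt e^{-lam(dt-s)} ds
    if x < 1e-3:
        # series for 1 - e^{-x}(1+x); direct form cancels catastrophically
        g = x * x / 2.0 - x**3 / 3.0 + x**4 / 8.0 - x**5 / 30.0
    else:
        g = 1.0 - E * (1.0 + x)
    i1 = dt * phi1 - g / (lam * lam)    # int_0^dt s e^{-lam(dt-s)} ds
    b_now = i1 / dt
    b_prev = phi1 - b_now
    return E, b_prev, b_now


def exp_conv(u: np.ndarray, dt: float, lam: float) -> np.ndarray:
    """``(u * exp(-lam t))(t_n)`` for ``u`` sampled on a uniform grid.

    ``u`` is treated as linear between samples and zero before the first
    sample; the output starts at exactly 0.
    """
    if lam < 0:
        raise ValueError("decay rate must be non-negative")
    E, b_prev, b_now = _step_coefficients(lam, dt)
    y = lfilter([b_now, b_prev], [1.0, -E], u)
    if u[0] != 0.0:
        # lfilter assumes u[-1]=y[-1]=0, giving y[0]=b_now*u[0]; the true
        # convolution starts at zero, and the discrepancy decays as E^n.
        y = y - (b_now * u[0]) * E ** np.arange(u.size)
    y[0] = 0.0
    return y


class UniformGrid:
    """Uniform evaluation grid aligned with a frame schedule.

    Precomputes the frame-averaging operator (trapezoidal integration over
    each frame divided by its duration) so that repeated model evaluations
    during fitting reduce to filters plus one small mat-vec.
    """

    def __init__(self, schedule, dt_s: float = 0.5):
        if dt_s <= 0 or dt_s > 0.5 + 1e-9:
            raise ValueError("grid step must be in (0, 0.5] s")
        # choose a step that divides every frame boundary (frame bounds are
        # conventionally whole or half seconds; otherwise the nearest grid
        # node stands in for the boundary, a sub-millisecond approximation)
        bounds = schedule.ends_s
        step = dt_s
        for _ in range(10):
            if np.all(np.abs(np.round(bounds / step) - bounds / step) < 1e-9):
                break
            step /= 2.0
        self.dt_s = step
        self.dt_min = step / 60.0
        n = int(round(schedule.total_s / step)) + 1
        self.times_min = np.arange(n) * self.dt_min
        self.schedule = schedule
        i0 = np.round(schedule.starts_s / step).astype(int)
        i1 = np.round(schedule.ends_s / step).astype(int)
        W = np.zeros((schedule.n_frames, n))
        for f, (a, b) in enumerate(zip(i0, i1)):
            W[f, a:b + 1] = 1.0
            W[f, a] = 0.5
            W[f, b] = 0.5
        # normalise by the span the weights actually cover so that frame
        # averages of constants are exact even when a non-grid boundary was
        # rounded to the nearest node
        self._W = W / (i1 - i0)[:, None]

    def sample(self, curve, delay: float = 0.0) -> np.ndarray:
        """Sample a curve on the grid (delay shifts the curve later)."""
        from .curves import evaluate_curve
        return evaluate_curve(curve, self.times_min, delay)

    def frame_average(self, y_grid: np.ndarray) -> np.ndarray:
        return self._W @ y_grid

    def conv_frames(self, u_grid: np.ndarray, lam: float) -> np.ndarray:
        """Frame-averaged ``u * exp(-lam t)`` in one call."""
        return self.frame_average(exp_conv(u_grid, self.dt_min, lam))

    def frame_consistent(self, frame_values: np.ndarray,
                         n_iter: int = 100) -> np.ndarray:
        """Grid curve whose frame averages reproduce ``frame_values``.

        Naive linear interpolation through the frame midpoints does not
        average back to the measured frame values (it clips the early peak),
        which biases any convolution built from it.  This reconstructs a
        piecewise-linear curve, zero at t=0 with nodes at the frame
        midpoints, iterating the node values until applying the
        frame-average operator returns the measurements.
        """
        v = np.asarray(frame_values, dtype=float)
        nodes = v.copy()
        t = np.concatenate(([0.0], self.schedule.midpoints_min))
        tol = 1e-12 * max(float(np.max(np.abs(v))), 1.0)
        for _ in range(n_iter):
            y = np.interp(self.times_min, t, np.concatenate(([0.0], nodes)))
            resid = v - self.frame_average(y)
            if float(np.max(np.abs(resid))) < tol:
                break
            nodes = nodes + resid
        return y
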