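"""Arterial input functions: parent-fraction fitting and metabolite correction.

Radiolabelled metabolites accumulate in plasma after injection, so the total
plasma activity overestimates the concentration of authentic (parent) tracer
available to the brain.  The standard correction multiplies the total plasma
curve by a fitted parent-fraction model.  Here the population parent fraction
is a single exponential with an optional plateau,

    f(t) = offset + amplitude * exp(-rate * t),

clipped to [0, 1] on evaluation.  The pure single exponential (no plateau) is
available via ``with_offset=False``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .curves import SampledCurve

__all__ = ["ParentFractionModel", "fit_parent_fraction",
           "apply_metabolite_correction", "InsufficientDataError",
           "FitFailureError"]


class InsufficientDataError(ValueError):
    """Too few samples to identify the requested model."""


class FitFailureError(RuntimeError):
    """Optimizer failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclasses.dataclass(frozen=True)
class ParentFractionModel:
    """Single-exponential parent-fraction model with optional plateau."""

    amplitude: float
    rate: float
    offset: float = 0.0

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        for v in (self.amplitude, self.rate, self.offset):
            if not np.isfinite(v):
                raise ValueError("parameters must be finite")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        f = self.offset + self.amplitude * np.exp(-self.rate * t)
        return np.clip(f, 0.0, 1.0)


def fit_parent_fraction(samples: SampledCurve, with_offset: bool = True) -> ParentFractionModel:
    """Least-squares fit of the parent-fraction model to measured fractions.

    Parameters
    ----------
    samples : SampledCurve
        Fraction-kind curve of measured parent fractions (>= 3 samples).
    with_offset : bool
        If False, fix the plateau at zero (pure single exponential).
    """
    if samples.kind != "fraction":
        raise TypeError(f"expected a fraction curve, got kind={samples.kind!r}")
    if len(samples) < 3:
        raise InsufficientDataError("parent-fraction fit requires at least 3 samples")
    t, y = samples.times, samples.values

    if with_offset:
        def resid(p):
            return p[2] + p[0] * np.exp(-p[1] * t) - y
        x0 = np.array([max(y[0] - y[-1], 0.1), 0.05, y[-1]])
        lb, ub = [0.0, 0.0, 0.0], [1.0, np.inf, 1.0]
    else:
        def resid(p):
            return p[0] * np.exp(-p[1] * t) - y
        x0 = np.array([max(y[0], 0.5), 0.05])
        lb, ub = [0.0, 0.0], [1.0, np.inf]

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitFailureError("parent-fraction fit did not converge", diagnostics=sol)
    if with_offset:
        amp, rate, off = sol.x
    else:
        (amp, rate), off = sol.x, 0.0
    return ParentFractionModel(amplitude=amp, rate=rate, offset=off)


def apply_metabolite_correction(plasma_total: SampledCurve,
                                model: ParentFractionModel) -> SampledCurve:
    """Multiply a total-plasma curve pointwise by the parent fraction."""
    if plasma_total.kind != "plasma_total":
        raise TypeError(f"expected a plasma_total curve, got kind={plasma_total.kind!r}")
    corrected = plasma_total.values * model(plasma_total.times)
    return SampledCurve(plasma_total.times, corrected, "plasma_parent")
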