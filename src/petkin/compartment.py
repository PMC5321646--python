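"""Forward compartment models (1T, 2T, 3T) and macro-parameter algebra.

The three-tissue configuration has a parallel (two-branch) topology: a free
compartment C1 exchanging with plasma (K1, k2), a specific-binding
compartment C2 off C1 (k3, k4), and a slow non-specific compartment C3 also
off C1 (k5, k6).  This is the unique two-branch wiring whose total
distribution volume is

    V_T = (K1/k2) * [1 + k3/k4 + k5/k6]

with both binding terms scaled by the free-compartment volume.  One- and
two-tissue models are the k5=k6 (and k3=k4) absent special cases.

Measured PET activity includes a fractional intravascular blood signal:
frame value = frame average of (1 - vB)*C_T(t) + vB*C_blood(t).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._conv import UniformGrid, exp_conv
from .curves import FrameSchedule, SampledCurve

__all__ = ["MicroParams", "MacroParams", "macro_from_micro", "dvr_minus_one",
           "impulse_response", "model_tac"]


@dataclasses.dataclass(frozen=True)
class MicroParams:
    """Compartment rate constants.

    K1 in mL·cm⁻³·min⁻¹, k2..k6 in min⁻¹, vB dimensionless.  Model order is
    implied by which rates are present: 1T (K1, k2), 2T (+k3, k4),
    3T (+k5, k6).
    """

    K1: float
    k2: float
    k3: float | None = None
    k4: float | None = None
    k5: float | None = None
    k6: float | None = None
    vB: float = 0.05

    def __post_init__(self):
        rates = [self.K1, self.k2] + [r for r in (self.k3, self.k4, self.k5, self.k6)
                                      if r is not None]
        if any(r < 0 for r in rates):
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.vB <= 1.0:
            raise ValueError("blood volume fraction must be in [0, 1]")
        if (self.k3 is None) != (self.k4 is None) or (self.k5 is None) != (self.k6 is None):
            raise ValueError("k3/k4 and k5/k6 must be given in pairs")
        if self.k5 is not None and self.k3 is None:
            raise ValueError("a 3T model requires k3/k4 in addition to k5/k6")

    @property
    def n_tissue(self) -> int:
        return 1 + (self.k3 is not None) + (self.k5 is not None)


@dataclasses.dataclass(frozen=True)
class MacroParams:
    """Macro parameters derived from rate constants."""

    VT: float
    BPND: float | None = None
    DVRminus1: float | None = None


def macro_from_micro(params: MicroParams) -> MacroParams:
    """Distribution volume and binding potential from rate constants.

    V_T = (K1/k2) * [1 + k3/k4 + k5/k6] (absent branches contribute zero);
    BP_ND = k3/k4 when the specific compartment is present.
    """
    if params.k2 <= 0:
        raise ValueError("k2 must be positive to define V_T")
    total = 1.0
    bpnd = None
    if params.k3 is not None:
        if params.k4 <= 0:
            raise ValueError("k4 must be positive when k3 is present")
        bpnd = params.k3 / params.k4
        total += bpnd
    if params.k5 is not None:
        if params.k6 <= 0:
            raise ValueError("k6 must be positive when k5 is present")
        total += params.k5 / params.k6
    return MacroParams(VT=params.K1 / params.k2 * total, BPND=bpnd)


def dvr_minus_one(VT: float, VT_reference: float) -> float:
    """Indirect binding potential: BP_ND = V_T / V_T(reference) - 1."""
    if VT_reference <= 0:
        raise ValueError("reference V_T must be positive")
    return VT / VT_reference - 1.0


def _rate_matrix(params: MicroParams):
    """State matrix A and input vector b for dC/dt = A C + b Cp(t)."""
    if params.n_tissue == 1:
        A = np.array([[-params.k2]])
    elif params.n_tissue == 2:
        A = np.array([[-(params.k2 + params.k3), params.k4],
                      [params.k3, -params.k4]])
    else:
        A = np.array([
            [-(params.k2 + params.k3 + params.k5), params.k4, params.k6],
            [params.k3, -params.k4, 0.0],
            [params.k5, 0.0, -params.k6],
        ])
    b = np.zeros(A.shape[0])
    b[0] = params.K1
    return A, b


def impulse_response(params: MicroParams):
    """Exponential decomposition of the tissue impulse response.

    Returns ``(weights, rates)`` such that the response of total tissue
    concentration to a unit plasma impulse is ``sum_i w_i exp(-rate_i t)``.
    Coincident eigenvalues (the ``t e^{-lam t}`` limit) are handled by an
    infinitesimal symmetric split of the degenerate pair, accurate to well
    below every fitting tolerance used here.
    """
    A, b = _rate_matrix(params)
    for attempt in range(4):
        eigvals, V = np.linalg.eig(A)
        lam = -np.real(eigvals)
        if lam.size == 1:
            return np.array([params.K1]), lam
        gaps = np.abs(np.subtract.outer(lam, lam))
        np.fill_diagonal(gaps, np.inf)
        scale = max(lam.max(), 1e-6)
        if gaps.min() > 1e-7 * scale and np.all(np.abs(np.imag(eigvals)) < 1e-12 * scale):
            break
        # split degenerate eigenvalues by perturbing the diagonal
        A = A - np.diag(scale * 1e-7 * (1 + np.arange(A.shape[0], dtype=float)))
    weights = np.real(V.sum(axis=0) * np.linalg.solve(V, b.astype(complex)))
    lam = np.maximum(lam, 0.0)
    return weights, lam


def _tissue_on_grid(params: MicroParams, cp_grid: np.ndarray, grid: UniformGrid):
    weights, rates = impulse_response(params)
    ct = np.zeros_like(cp_grid)
    for w, lam in zip(weights, rates):
        ct += w * exp_conv(cp_grid, grid.dt_min, lam)
    return ct


def tac_frames(params: MicroParams, cp_grid: np.ndarray, cb_grid: np.ndarray,
               grid: UniformGrid) -> np.ndarray:
    """Frame-averaged PET values from pre-sampled input grids (fast path)."""
    ct = _tissue_on_grid(params, cp_grid, grid)
    pet = (1.0 - params.vB) * ct + params.vB * cb_grid
    return grid.frame_average(pet)


def model_tac(params: MicroParams, parent_plasma: SampledCurve,
              whole_blood: SampledCurve, schedule: FrameSchedule,
              delay: float = 0.0, dt_s: float = 0.5) -> SampledCurve:
    """Simulate the measured tissue TAC for a compartment configuration.

    The tissue curve is the analytic convolution of the (delayed) parent
    plasma input with the model's exponential impulse response; the measured
    value per frame is the frame average of ``(1-vB)*C_T + vB*C_blood``.
    Returns a tissue curve sampled at frame midpoints.
    """
    grid = UniformGrid(schedule, dt_s)
    cp = grid.sample(parent_plasma, delay)
    cb = grid.sample(whole_blood, delay)
    frames = tac_frames(params, cp, cb, grid)
    return schedule.frame_curve(frames)
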