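"""Spectral analysis: non-negative exponential decomposition of a TAC.

The tissue curve is modeled as a non-negative sum of plasma-convolved
exponentials,

    C_T(t) = sum_j alpha_j * (Cp * exp(-beta_j t))(t),   alpha_j >= 0,

on a fixed logarithmic grid of decay rates beta_j.  The non-negative
least-squares solution needs no assumption about the number of tissue
compartments; the distribution volume follows as V_T = sum_j alpha_j/beta_j
and the number of contiguous nonzero clusters in the spectrum ("peaks")
indicates how many kinetically distinct compartments the data support.

Defaults follow the common rodent protocol used throughout this package:
50 basis functions with decay rates between 0.001 and 1 s^-1 (0.06 to
60 min^-1 internally).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from ._conv import UniformGrid
from .curves import FrameSchedule, SampledCurve

__all__ = ["SpectralAnalysis", "SpectralResult", "spectral_fit", "count_components"]

SECONDS_PER_MIN = 60.0


@dataclasses.dataclass(frozen=True)
class SpectralResult:
    """Spectrum, distribution volume and component count from one TAC."""

    betas: np.ndarray            # min^-1, log-spaced
    alphas: np.ndarray           # >= 0, mL·cm^-3·min^-1
    VT: float                    # sum(alpha/beta), mL·cm^-3
    n_components: int
    rss: float
    fitted: SampledCurve


def count_components(alphas: np.ndarray, threshold_fraction: float = 0.01) -> int:
    """Number of contiguous nonzero clusters above a relative threshold.

    Coefficients below ``threshold_fraction * max(alpha)`` are zeroed, then
    adjacent nonzero grid points merge into one cluster.  NNLS tends to put a
    true component's weight on one or two neighbouring grid points, so a
    cluster is the natural unit of a "peak".
    """
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0 or alphas.max() <= 0:
        return 0
    active = alphas > threshold_fraction * alphas.max()
    return int(np.sum(active[1:] & ~active[:-1]) + active[0])


class SpectralAnalysis(BaseEstimator):
    """Non-negative spectral decomposition of a tissue TAC.

    Parameters
    ----------
    n_basis : int
        Number of basis decay rates (log-spaced, endpoints included).
    beta_min_s, beta_max_s : float
        Decay-rate bounds in s^-1.
    threshold_fraction : float
        Relative cutoff used when counting spectral peaks.
    vB : float
        Blood volume fraction subtracted from the TAC before decomposition
        when a whole-blood curve is supplied (``subtract_blood=True``); the
        remaining signal is then scaled back to pure-tissue units.
    subtract_blood : bool
        Whether to apply the vB pre-correction (requires ``whole_blood``).
    """

    def __init__(self, n_basis: int = 50, beta_min_s: float = 0.001,
                 beta_max_s: float = 1.0, threshold_fraction: float = 0.01,
                 vB: float = 0.05, subtract_blood: bool = False,
                 dt_s: float = 0.5):
        self.n_basis = n_basis
        self.beta_min_s = beta_min_s
        self.beta_max_s = beta_max_s
        self.threshold_fraction = threshold_fraction
        self.vB = vB
        self.subtract_blood = subtract_blood
        self.dt_s = dt_s

    def fit(self, tac: SampledCurve, parent_plasma: SampledCurve,
            schedule: FrameSchedule, whole_blood: SampledCurve | None = None,
            delay: float = 0.0):
        if self.beta_min_s <= 0 or self.beta_min_s >= self.beta_max_s:
            raise ValueError("need 0 < beta_min < beta_max")
        if len(tac) != schedule.n_frames:
            raise ValueError("TAC length does not match the frame schedule")
        y = np.asarray(tac.values, dtype=float)

        grid = UniformGrid(schedule, self.dt_s)
        cp = grid.sample(parent_plasma, delay)
        if self.subtract_blood:
            if whole_blood is None:
                raise ValueError("subtract_blood=True requires a whole-blood curve")
            cb_frames = grid.frame_average(grid.sample(whole_blood, delay))
            y = (y - self.vB * cb_frames) / (1.0 - self.vB)

        betas = np.geomspace(self.beta_min_s, self.beta_max_s, self.n_basis) * SECONDS_PER_MIN
        basis = np.column_stack([grid.conv_frames(cp, b) for b in betas])
        scale = np.linalg.norm(basis, axis=0)
        live = scale > 0
        if not np.all(live):
            warnings.warn("singular spectral basis: some basis columns are zero",
                          RuntimeWarning, stacklevel=2)
        alphas = np.zeros(betas.size)
        if np.any(live):
            cond = scale[live].max() / scale[live].min()
            if cond > 1e12:
                warnings.warn("spectral basis badly conditioned "
                              f"(column norm ratio {cond:.1e})",
                              RuntimeWarning, stacklevel=2)
            alphas_scaled, _ = nnls(basis[:, live] / scale[live], y)
            alphas[live] = alphas_scaled / scale[live]
        fitted = basis @ alphas
        rss = float(np.sum((y - fitted) ** 2))

        self.betas_ = betas
        self.alphas_ = alphas
        self.vt_ = float(np.sum(alphas / betas))
        self.n_components_ = count_components(alphas, self.threshold_fraction)
        self.rss_ = rss
        self.fitted_ = schedule.frame_curve(fitted)
        return self

    def result_(self) -> SpectralResult:
        return SpectralResult(betas=self.betas_, alphas=self.alphas_,
                              VT=self.vt_, n_components=self.n_components_,
                              rss=self.rss_, fitted=self.fitted_)


def spectral_fit(tac, parent_plasma, schedule, n_basis: int = 50,
                 beta_min_s: float = 0.001, beta_max_s: float = 1.0,
                 **config) -> SpectralResult:
    """Functional wrapper around :class:`SpectralAnalysis`."""
    whole_blood = config.pop("whole_blood", None)
    delay = config.pop("delay", 0.0)
    est = SpectralAnalysis(n_basis=n_basis, beta_min_s=beta_min_s,
                           beta_max_s=beta_max_s, **config)
    est.fit(tac, parent_plasma, schedule, whole_blood=whole_blood, delay=delay)
    return est.result_()
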