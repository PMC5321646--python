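"""Reference-tissue quantification of BP_ND without blood sampling.

All three models express the target TAC as a functional of the reference
TAC after eliminating the (unmeasured) plasma input in the Laplace domain:

* SRTM   — target and reference both single-tissue; solved by the
  basis-function method (grid over the apparent target efflux
  theta = k2/(1+BP_ND), exact linear subproblem per theta).
* FRTM   — target two-tissue, reference single-tissue; 4-parameter
  nonlinear fit (R1, k2, k3, k4), BP_ND = k3/k4.
* SRTM-2C — target single-tissue, reference two-tissue; 5-parameter
  nonlinear fit of (R1, target apparent efflux k2a, reference k2', k3', k4').
  Under the shared non-displaceable volume assumption K1/k2 = K1'/k2',
  BP_ND = R1 k2'/k2a - 1.

All models assume the reference region is devoid of specific binding; when
it is not (a pseudo-reference), BP_ND is biased downward relative to the
plasma-input DVR-1.

Residuals are weighted by the square root of frame duration by default, the
usual weighting for framed PET data.  Because these models are structurally
mis-specified against multi-compartment tissue, the fitted parameters depend
on how the deterministic misfit is weighted; duration weighting makes the
discrete objective a quadrature of the continuous-time least-squares
criterion, so the estimates do not depend on how the acquisition happens to
be framed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator

from ._conv import UniformGrid, exp_conv
from .curves import FrameSchedule, SampledCurve
from .fitting import aic
from .input_functions import FitFailureError

__all__ = ["SRTM", "FRTM", "SRTM2C", "ReferenceFitResult",
           "fit_srtm", "fit_frtm", "fit_srtm_2c"]


@dataclasses.dataclass(frozen=True)
class ReferenceFitResult:
    """Outcome of a reference-tissue fit on one target TAC."""

    model_kind: str
    R1: float
    k2: float
    BPND: float
    rss: float
    n_frames: int
    n_free: int
    aic: float
    fitted: SampledCurve
    k3: float | None = None          # FRTM only
    ref_params: dict | None = None   # SRTM-2C only
    flags: tuple[str, ...] = ()


def _quadratic_roots(s1: float, s0: float):
    """Roots of s^2 + s1*s + s0 = 0 returned as positive decay rates.

    A degenerate (repeated) root pair is split infinitesimally so the
    two-exponential form remains valid in the limit.
    """
    disc = s1 * s1 - 4.0 * s0
    disc = max(disc, 0.0)
    r = np.sqrt(disc)
    if r < 1e-9 * max(s1, 1e-12):
        r = 1e-9 * max(s1, 1e-12)
    return (s1 + r) / 2.0, (s1 - r) / 2.0


def _split(a: float, b: float):
    """Nudge two decay rates apart if numerically coincident."""
    if abs(a - b) < 1e-9 * max(a, b, 1e-12):
        eps = 1e-9 * max(a, b, 1e-12)
        return a + eps, max(b - eps, 0.0)
    return a, b


class _ReferenceFitter(BaseEstimator):
    """Shared plumbing: grid setup, weighting, result packing."""

    model_kind = ""
    n_free = 0

    def __init__(self, weights: str = "frame_duration", multistart: int = 5,
                 random_state: int = 0, dt_s: float = 0.5):
        self.weights = weights
        self.multistart = multistart
        self.random_state = random_state
        self.dt_s = dt_s

    def _setup(self, target: SampledCurve, reference: SampledCurve,
               schedule: FrameSchedule):
        if len(target) != schedule.n_frames or len(reference) != schedule.n_frames:
            raise ValueError("target and reference must both match the schedule")
        grid = UniformGrid(schedule, self.dt_s)
        cr_grid = grid.frame_consistent(reference.values)
        y = np.asarray(target.values, dtype=float)
        cr = np.asarray(reference.values, dtype=float)
        if self.weights == "uniform":
            w = np.ones(schedule.n_frames)
        elif self.weights == "frame_duration":
            w = schedule.durations_min / schedule.durations_min.mean()
        else:
            raise ValueError(f"unknown weighting scheme {self.weights!r}")
        return grid, cr_grid, y, cr, np.sqrt(w)

    def _pack(self, schedule, y_fit, rss, **fields):
        self.rss_ = float(rss)
        self.n_frames_ = schedule.n_frames
        self.aic_ = aic(self.rss_, self.n_frames_, self.n_free)
        self.fitted_ = schedule.frame_curve(y_fit)
        flags = list(fields.pop("flags", ()))
        if fields["BPND"] <= -1:
            flags.append("non_physical_bpnd")
        self.flags_ = tuple(flags)
        for k, v in fields.items():
            setattr(self, k.lower() + "_", v)
        self._fields = fields

    def result_(self) -> ReferenceFitResult:
        return ReferenceFitResult(model_kind=self.model_kind,
                                  rss=self.rss_, n_frames=self.n_frames_,
                                  n_free=self.n_free, aic=self.aic_,
                                  fitted=self.fitted_, flags=self.flags_,
                                  **{k: v for k, v in self._fields.items()})


class SRTM(_ReferenceFitter):
    """Simplified reference tissue model, basis-function solution.

    For each candidate apparent efflux theta on a log grid, the model

        C_T = R1*C_r + phi * (C_r * exp(-theta t)),   phi = k2 - R1*theta,

    is linear in (R1, phi); the best theta by RSS wins and
    BP_ND = k2/theta - 1.
    """

    model_kind = "SRTM"
    n_free = 3

    def __init__(self, weights: str = "frame_duration", multistart: int = 5,
                 random_state: int = 0, dt_s: float = 0.5,
                 n_theta: int = 100, theta_min: float = 0.006,
                 theta_max: float = 6.0):
        super().__init__(weights, multistart, random_state, dt_s)
        self.n_theta = n_theta
        self.theta_min = theta_min
        self.theta_max = theta_max

    def fit(self, target: SampledCurve, reference: SampledCurve,
            schedule: FrameSchedule):
        grid, cr_grid, y, cr, sw = self._setup(target, reference, schedule)

        def solve(theta):
            basis = grid.conv_frames(cr_grid, theta)
            X = np.column_stack([cr, basis]) * sw[:, None]
            coef, _, _, _ = np.linalg.lstsq(X, y * sw, rcond=None)
            rss = float(np.sum((y * sw - X @ coef) ** 2))
            return rss, coef, X @ coef / sw

        thetas = np.geomspace(self.theta_min, self.theta_max, self.n_theta)
        rss_grid = np.array([solve(t)[0] for t in thetas])
        i = int(np.argmin(rss_grid))
        # refine theta between the neighbours of the best grid point so the
        # estimate is not quantised to the grid spacing
        lo, hi = thetas[max(i - 1, 0)], thetas[min(i + 1, thetas.size - 1)]
        sol = minimize_scalar(lambda lt: solve(np.exp(lt))[0],
                              bounds=(np.log(lo), np.log(hi)),
                              method="bounded", options={"xatol": 1e-10})
        theta = float(np.exp(sol.x))
        rss, (R1, phi), y_fit = solve(theta)
        k2 = phi + R1 * theta
        bpnd = k2 / theta - 1.0
        flags = []
        if i in (0, thetas.size - 1):
            flags.append("theta_at_grid_bound")
        self._pack(schedule, y_fit, rss, R1=R1, k2=k2, BPND=bpnd, flags=flags)
        self.theta_ = theta
        return self


class _NonlinearReferenceFitter(_ReferenceFitter):
    """Multistart log-space nonlinear least squares for FRTM / SRTM-2C."""

    _lo: np.ndarray
    _hi: np.ndarray

    def _predict_frames(self, x, cr, cr_grid, grid):
        raise NotImplementedError

    def _extra_starts(self, target, reference, schedule):
        return []

    def _fit_nls(self, target, reference, schedule):
        grid, cr_grid, y, cr, sw = self._setup(target, reference, schedule)

        def resid(logx):
            return sw * (self._predict_frames(np.exp(logx), cr, cr_grid, grid) - y)

        rng = np.random.default_rng(self.random_state)
        lo, hi = self._lo, self._hi
        starts = [np.sqrt(lo * hi)]
        starts += self._extra_starts(target, reference, schedule)
        while len(starts) < max(self.multistart, 1) + 1:
            starts.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        best = None
        for x0 in starts:
            x0 = np.clip(x0, lo, hi)
            sol = least_squares(resid, np.log(x0),
                                bounds=(np.log(lo), np.log(hi)),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if not np.isfinite(sol.cost):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailureError(f"{self.model_kind} fit failed for all starts")
        x = np.exp(best.x)
        y_fit = self._predict_frames(x, cr, cr_grid, grid)
        return x, float(2.0 * best.cost), y_fit, schedule


class FRTM(_NonlinearReferenceFitter):
    """Full reference tissue model (two-tissue target, one-tissue reference).

    The target-over-reference transfer function is
    R1 (s + k3 + k4)(s + k2') / ((s + a)(s + b)) with k2' = k2/R1 and a, b
    the two-tissue eigenrates; the fit runs over (R1, k2, k3, k4) and
    BP_ND = k3/k4.
    """

    model_kind = "FRTM"
    n_free = 4
    _lo = np.array([0.05, 0.001, 1e-6, 1e-3])
    _hi = np.array([5.0, 5.0, 5.0, 5.0])

    def _predict_frames(self, x, cr, cr_grid, grid):
        R1, k2, k3, k4 = x
        k2p = k2 / R1
        a, b = _split(*_quadratic_roots(k2 + k3 + k4, k2 * k4))
        A = (k3 + k4 - a) * (k2p - a) / (b - a)
        B = (k3 + k4 - b) * (k2p - b) / (a - b)
        conv = (A * exp_conv(cr_grid, grid.dt_min, a)
                + B * exp_conv(cr_grid, grid.dt_min, b))
        return R1 * (cr + grid.frame_average(conv))

    def fit(self, target, reference, schedule):
        (R1, k2, k3, k4), rss, y_fit, schedule = self._fit_nls(target, reference, schedule)
        self._pack(schedule, y_fit, rss, R1=R1, k2=k2, k3=k3, BPND=k3 / k4)
        self.k4_ = k4
        return self


class SRTM2C(_NonlinearReferenceFitter):
    """Simplified reference model with a two-tissue reference region.

    The reference is described by (k2r, k3r, k4r) and the target by a single
    apparent efflux k2a; with the shared non-displaceable volume assumption,
    BP_ND = R1 k2r / k2a - 1.  When the reference's second compartment fits
    to zero the model collapses exactly to SRTM.
    """

    model_kind = "SRTM2C"
    n_free = 5
    # (R1, k2a, k2r, k3r, k4r)
    _lo = np.array([0.05, 0.001, 0.001, 1e-6, 1e-3])
    _hi = np.array([5.0, 5.0, 5.0, 5.0, 5.0])

    def _predict_frames(self, x, cr, cr_grid, grid):
        R1, k2a, k2r, k3r, k4r = x
        g, d = _quadratic_roots(k2r + k3r + k4r, k2r * k4r)
        k2a, k4r = _split(k2a, k4r)
        A = (g - k2a) * (d - k2a) / (k4r - k2a)
        B = (g - k4r) * (d - k4r) / (k2a - k4r)
        conv = (A * exp_conv(cr_grid, grid.dt_min, k2a)
                + B * exp_conv(cr_grid, grid.dt_min, k4r))
        return R1 * (cr + grid.frame_average(conv))

    def _extra_starts(self, target, reference, schedule):
        # seed from the SRTM solution so the one-tissue-reference limit is
        # always reachable
        try:
            s = SRTM(weights=self.weights, dt_s=self.dt_s).fit(target, reference, schedule)
        except Exception:
            return []
        if s.r1_ <= 0 or s.k2_ <= 0:
            return []
        return [np.array([s.r1_, s.theta_, s.k2_ / s.r1_, 1e-6, 0.05])]

    def fit(self, target, reference, schedule):
        (R1, k2a, k2r, k3r, k4r), rss, y_fit, schedule = self._fit_nls(
            target, reference, schedule)
        bpnd = R1 * k2r / k2a - 1.0
        self._pack(schedule, y_fit, rss, R1=R1, k2=R1 * k2r, BPND=bpnd,
                   ref_params={"k2r": k2r, "k3r": k3r, "k4r": k4r})
        self.k2a_ = k2a
        return self


def fit_srtm(target, reference, schedule, **config) -> ReferenceFitResult:
    return SRTM(**config).fit(target, reference, schedule).result_()


def fit_frtm(target, reference, schedule, **config) -> ReferenceFitResult:
    return FRTM(**config).fit(target, reference, schedule).result_()


def fit_srtm_2c(target, reference, schedule, **config) -> ReferenceFitResult:
    return SRTM2C(**config).fit(target, reference, schedule).result_()
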