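"""Sampled concentration curves, frame schedules, and curve I/O.

All times are minutes post-injection and all rate constants are min^-1
internally; seconds appear only at the API boundary (frame definitions are
conventionally quoted in seconds).
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CurveKind",
    "SampledCurve",
    "FrameSchedule",
    "evaluate_curve",
    "read_curve",
    "write_curve",
    "read_tac_file",
]

#: Recognised curve kinds.
CurveKind = ("whole_blood", "plasma_total", "plasma_parent", "tissue", "fraction")


@dataclasses.dataclass(frozen=True)
class SampledCurve:
    """A time-stamped concentration (or fraction) series.

    Parameters
    ----------
    times : ndarray
        Sample times in minutes post-injection; non-negative, strictly
        increasing.
    values : ndarray
        Activity concentration in kBq/mL, or a dimensionless fraction for
        ``kind="fraction"``.
    kind : str
        One of ``whole_blood``, ``plasma_total``, ``plasma_parent``,
        ``tissue``, ``fraction``.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "tissue"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size == 0:
            raise ValueError("curve must contain at least one sample")
        if np.any(~np.isfinite(times)) or np.any(~np.isfinite(values)):
            raise ValueError("times and values must be finite")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if times[0] < 0:
            raise ValueError("times must be non-negative")
        if self.kind not in CurveKind:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.kind == "fraction" and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValueError("fraction curves must lie in [0, 1]")

    def __len__(self) -> int:
        return self.times.size

    def __call__(self, t, delay: float = 0.0):
        return evaluate_curve(self, t, delay)

    def with_values(self, values, kind: str | None = None) -> "SampledCurve":
        return SampledCurve(self.times, values, kind or self.kind)

    def scaled(self, factor: float) -> "SampledCurve":
        return self.with_values(self.values * factor)


def evaluate_curve(curve: SampledCurve, t, delay: float = 0.0):
    """Evaluate ``curve`` at time(s) ``t`` shifted by ``delay`` minutes.

    Piecewise-linear interpolation between samples; zero before the first
    sample and the last value held constant afterwards.  The delay shifts the
    curve later in time: ``evaluate_curve(c, t, d) == evaluate_curve(c, t - d, 0)``.
    """
    if not np.isfinite(delay):
        raise ValueError("delay must be finite")
    t = np.asarray(t, dtype=float)
    out = np.interp(t - delay, curve.times, curve.values,
                    left=0.0, right=curve.values[-1])
    return out if out.ndim else float(out)


class FrameSchedule:
    """Contiguous half-open acquisition frames ``[start, end)`` in seconds.

    The canonical rodent protocol here is 21 frames over 60 min
    (6x10, 4x30, 2x60, 1x120, 1x180, 4x300, 3x600 s).
    """

    def __init__(self, durations_s):
        durations = np.asarray(durations_s, dtype=float)
        if durations.ndim != 1 or durations.size == 0:
            raise ValueError("durations must be a non-empty 1-D sequence")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be strictly positive")
        self.durations_s = durations
        self.ends_s = np.cumsum(durations)
        self.starts_s = self.ends_s - durations

    @classmethod
    def from_bounds(cls, starts_s, ends_s) -> "FrameSchedule":
        starts = np.asarray(starts_s, dtype=float)
        ends = np.asarray(ends_s, dtype=float)
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
            raise ValueError("frames must be contiguous starting at 0")
        return cls(ends - starts)

    @property
    def n_frames(self) -> int:
        return self.durations_s.size

    @property
    def total_s(self) -> float:
        return float(self.ends_s[-1])

    @property
    def starts_min(self):
        return self.starts_s / 60.0

    @property
    def ends_min(self):
        return self.ends_s / 60.0

    @property
    def durations_min(self):
        return self.durations_s / 60.0

    @property
    def midpoints_min(self):
        return (self.starts_s + self.ends_s) / 2.0 / 60.0

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        return (isinstance(other, FrameSchedule)
                and np.array_equal(self.durations_s, other.durations_s))

    def __repr__(self) -> str:
        return f"FrameSchedule({self.n_frames} frames, {self.total_s:.0f} s)"

    def frame_curve(self, frame_values, kind: str = "tissue") -> SampledCurve:
        """Frame values as a SampledCurve sampled at frame midpoints."""
        return SampledCurve(self.midpoints_min, frame_values, kind)


# ---------------------------------------------------------------------------
# I/O: long-format CSV/TSV (time_min, value, kind) and PMOD-style .tac text
# ---------------------------------------------------------------------------

def read_curve(path) -> SampledCurve:
    """Read a curve from CSV/TSV with columns ``time_min, value, kind``."""
    sep = "\t" if str(path).endswith((".tsv", ".tac")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"time_min", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"curve file missing columns: {sorted(missing)}")
    kind = str(df["kind"].iloc[0]) if "kind" in df.columns else "tissue"
    return SampledCurve(df["time_min"].to_numpy(), df["value"].to_numpy(), kind)


def write_curve(curve: SampledCurve, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.DataFrame({"time_min": curve.times, "value": curve.values,
                       "kind": curve.kind})
    df.to_csv(path, sep=sep, index=False)


def read_tac_file(path_or_buffer) -> dict[str, SampledCurve]:
    """Read a PMOD-style multi-column .tac text file.

    First column is time (``time[seconds]`` or ``time[minutes]`` header, or a
    bare ``time`` column assumed to be minutes); each subsequent column is one
    region's activity.  Returns region name -> tissue curve.
    """
    if isinstance(path_or_buffer, (str, Path)):
        text = Path(path_or_buffer).read_text()
    else:
        text = path_or_buffer.read()
    df = pd.read_csv(io.StringIO(text), sep=r"\s+", comment="#")
    tcol = df.columns[0]
    times = df[tcol].to_numpy(dtype=float)
    if "sec" in tcol.lower():
        times = times / 60.0
    curves = {}
    for col in df.columns[1:]:
        curves[str(col)] = SampledCurve(times, df[col].to_numpy(dtype=float), "tissue")
    return curves
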