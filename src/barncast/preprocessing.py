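"""Sensor-series cleaning: 3-sigma outlier handling, min-max scaling, Savitzky-Golay smoothing.

The cleaning chain applied before forecasting is

    repair outliers  ->  smooth  ->  normalize

Outliers are flagged by the 3-sigma rule (residual about the per-channel mean
exceeding ``sigma_multiplier`` population standard deviations) and repaired by
linear interpolation between the nearest clean neighbours, which preserves the
30-minute time grid.  Min-max scaling maps each channel onto [0, 1] and is
invertible through :class:`NormalizationParams` so predictions can be reported
in physical units.  Smoothing is a Savitzky-Golay filter (local least-squares
polynomial fit); edge windows reuse the boundary polynomial so low-degree
polynomials pass through the filter unchanged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "RawSeries",
    "OutlierPolicy",
    "Replacement",
    "NormalizationParams",
    "SmoothingParams",
    "detect_outliers",
    "replace_outliers",
    "minmax_normalize",
    "denormalize",
    "savgol_smooth",
]


@dataclass
class RawSeries:
    """Timestamped multichannel sensor table.

    Parameters
    ----------
    frame:
        DataFrame indexed by strictly increasing timestamps (nominally
        30-minute spacing); one named column per sensor channel.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.frame) < 1:
            raise ValueError("RawSeries needs at least one row")
        idx = self.frame.index
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if len(idx) > 1 and idx.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")

    @property
    def channels(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "RawSeries":
        return RawSeries(self.frame.copy())

    @classmethod
    def from_csv(cls, path) -> "RawSeries":
        frame = pd.read_csv(path, index_col=0, parse_dates=True)
        return cls(frame.astype(float))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = out.index.name or "timestamp"
        out.to_csv(path, float_format="%.10g")


class Replacement(str, enum.Enum):
    LINEAR_INTERPOLATE = "linear-interpolate"
    PREVIOUS_VALUE = "previous-value"


@dataclass
class OutlierPolicy:
    """How outliers are flagged and repaired.

    ``sigma_multiplier`` is the number of standard deviations a residual
    (deviation from the channel mean) may reach before the point is called
    abnormal; 3.0 is the classical 3-sigma rule.
    """

    sigma_multiplier: float = 3.0
    replacement: Replacement = Replacement.LINEAR_INTERPOLATE

    def __post_init__(self) -> None:
        if self.sigma_multiplier <= 0:
            raise ValueError("sigma_multiplier must be positive")
        self.replacement = Replacement(self.replacement)


@dataclass
class NormalizationParams:
    """Per-channel min/max used by the [0, 1] scaling, for later inversion."""

    x_min: pd.Series
    x_max: pd.Series

    def __post_init__(self) -> None:
        if (self.x_max < self.x_min).any():
            raise ValueError("x_max must be >= x_min for every channel")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.x_min.index:
                fh.write(f"{name}.min={float(self.x_min[name])!r}\n")
                fh.write(f"{name}.max={float(self.x_max[name])!r}\n")

    @classmethod
    def from_file(cls, path) -> "NormalizationParams":
        lo: dict[str, float] = {}
        hi: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                key, val = line.split("=", 1)
                name, which = key.rsplit(".", 1)
                (lo if which == "min" else hi)[name] = float(val)
        return cls(pd.Series(lo), pd.Series(hi))


@dataclass
class SmoothingParams:
    """Savitzky-Golay window length (odd, in samples) and polynomial order."""

    window_length: int = 11
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError("window_length must be an odd integer >= 3")
        if self.polyorder < 0 or self.polyorder >= self.window_length:
            raise ValueError("polyorder must satisfy 0 <= polyorder < window_length")


def detect_outliers(series: RawSeries, policy: OutlierPolicy | None = None) -> pd.DataFrame:
    """Flag points whose residual about the channel mean exceeds k*sigma.

    Returns a boolean DataFrame aligned with ``series.frame``.  Channels with
    zero variance produce no flags.  Standard deviation is the population
    (ddof=0) value over the whole channel.
    """
    policy = policy or OutlierPolicy()
    frame = series.frame
    if len(frame) < 2:
        raise ValueError("need at least 2 points per channel to estimate sigma")
    mean = frame.mean(axis=0)
    sigma = frame.std(axis=0, ddof=0)
    resid = (frame - mean).abs()
    mask = resid.gt(policy.sigma_multiplier * sigma, axis=1)
    mask.loc[:, sigma == 0.0] = False
    return mask


def replace_outliers(
    series: RawSeries, mask: pd.DataFrame, policy: OutlierPolicy | None = None
) -> RawSeries:
    """Repair flagged points; unflagged points are left bit-identical.

    linear-interpolate: flagged points become the linear interpolation (in
    sample index) between the nearest unflagged neighbours; at the boundaries
    the nearest unflagged value is used instead.  previous-value: carry the
    last unflagged value forward (first point falls back to the next unflagged
    value).
    """
    policy = policy or OutlierPolicy()
    if mask.shape != series.frame.shape:
        raise ValueError("mask shape must match series")
    out = series.frame.copy()
    masked = out.where(~mask.to_numpy())
    if policy.replacement is Replacement.LINEAR_INTERPOLATE:
        filled = masked.interpolate(method="linear", limit_direction="both")
    else:
        filled = masked.ffill().bfill()
    # a fully flagged channel has nothing to interpolate from; keep original
    filled = filled.where(filled.notna(), out)
    result = out.where(~mask.to_numpy(), filled)
    return RawSeries(result)


def minmax_normalize(
    series: RawSeries, params: NormalizationParams | None = None
) -> tuple[RawSeries, NormalizationParams]:
    """Map each channel onto [0, 1] via (x - min) / (max - min).

    If ``params`` is given (e.g. statistics computed on a training split) it is
    applied as-is; otherwise min/max are taken from ``series``.  A degenerate
    channel (max == min) maps to all zeros by convention.
    """
    frame = series.frame
    if params is None:
        params = NormalizationParams(frame.min(axis=0), frame.max(axis=0))
    span = (params.x_max - params.x_min).replace(0.0, np.nan)
    normed = frame.sub(params.x_min, axis=1).div(span, axis=1).fillna(0.0)
    return RawSeries(normed), params


def denormalize(series: RawSeries, params: NormalizationParams) -> RawSeries:
    """Invert :func:`minmax_normalize`; degenerate channels recover the constant min."""
    span = params.x_max - params.x_min
    frame = series.frame.mul(span, axis=1).add(params.x_min, axis=1)
    return RawSeries(frame)


def denormalize_channel(values: np.ndarray, params: NormalizationParams, channel: str) -> np.ndarray:
    """Invert the scaling for a single named channel of plain values."""
    lo = float(params.x_min[channel])
    hi = float(params.x_max[channel])
    return np.asarray(values, dtype=float) * (hi - lo) + lo


def savgol_smooth(series: RawSeries, params: SmoothingParams | None = None) -> RawSeries:
    """Savitzky-Golay smoothing of every channel.

    Each output point is the centre value of the least-squares polynomial of
    degree ``polyorder`` fitted over the centred window; the edges use the
    polynomial fitted to the first/last window evaluated at the edge
    positions, so polynomials of degree <= polyorder are reproduced exactly
    everywhere (including the edges).
    """
    params = params or SmoothingParams()
    if len(series) < params.window_length:
        raise ValueError(
            f"series length {len(series)} is shorter than window_length {params.window_length}"
        )
    smoothed = savgol_filter(
        series.values, params.window_length, params.polyorder, axis=0, mode="interp"
    )
    return RawSeries(pd.DataFrame(smoothed, index=series.frame.index, columns=series.channels))
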