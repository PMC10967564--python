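"""Seeded generator of barn-like multichannel sensor series.

The study system is a mechanically ventilated pig barn sampled every 30
minutes: two instrumented pens (a: young pigs, b: adult pigs) measuring
temperature, humidity, CO2 and NH3 (H2S in pen a only), plus outdoor
temperature, humidity and wind speed -- 12 collected parameters, matching
the 12-input / single-output forecasting frame in which the history of all
12 channels predicts one channel's next value.

The generator composes, per channel, a diurnal sinusoid with an AR(1) noise
process (coefficient 0.9 by default, emulating slow sensor/environment
persistence), and couples the channels the way the real barn behaves
qualitatively: gas concentrations rise with CO2 (animal activity and reduced
ventilation at night) and indoor humidity, and fall with indoor temperature
and wind-driven ventilation; NH3 is the most strongly CO2-coupled gas, H2S
analogous but weaker and noisier.  Indoor temperature drops with wind speed.
Noiseless latents and anomaly masks are returned as ground truth so the
preprocessing chain can be scored exactly.

What this emulates and what it does not: correlation sign structure, diurnal
periodicity, autocorrelated noise and occasional sensor spikes are modelled;
ventilation control loops, animal growth and weather fronts are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import RawSeries

__all__ = [
    "BarnSimConfig",
    "GroundTruth",
    "simulate_barn",
    "inject_anomalies",
    "learnable_toy",
    "DEFAULT_CHANNELS",
]

# the 12 collected parameters: two instrumented pens (pen b carries no H2S
# sensor) plus the outdoor station
DEFAULT_CHANNELS = [
    "indoor_temp_a",
    "indoor_humidity_a",
    "co2_a",
    "nh3_a",
    "h2s_a",
    "indoor_temp_b",
    "indoor_humidity_b",
    "co2_b",
    "nh3_b",
    "outdoor_temp",
    "outdoor_humidity",
    "wind_speed",
]


@dataclass
class BarnSimConfig:
    """Simulation settings (defaults emulate a summer barn at 30-min sampling).

    Couplings are linear gains applied to standardized driver deviations:
    ``co2_to_nh3`` and ``humidity_to_nh3`` are positive (more CO2 / damper air
    -> more NH3), ``temp_to_gas`` and ``wind_to_temp`` enter with a negative
    sign (warmer indoor air / stronger wind-driven ventilation -> less gas /
    cooler barn).  ``anomaly_rate`` is the per-point probability of a sensor
    spike of ``anomaly_magnitude`` channel standard deviations.
    """

    n_days: int = 14
    step_minutes: int = 30
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    co2_to_nh3: float = 3.0
    humidity_to_nh3: float = 1.2
    temp_to_gas: float = 0.8
    wind_to_temp: float = 1.2
    diurnal_amplitude_temp: float = 5.0
    diurnal_amplitude_co2: float = 250.0
    ar_coeff: float = 0.9
    noise_scale: float = 1.0
    anomaly_rate: float = 0.0
    anomaly_magnitude: float = 8.0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0 <= self.anomaly_rate < 1:
            raise ValueError("anomaly_rate must be in [0, 1)")
        if not -1 < self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in (-1, 1)")

    @property
    def steps_per_day(self) -> int:
        return 1440 // self.step_minutes

    @property
    def n_steps(self) -> int:
        return self.n_days * self.steps_per_day


@dataclass
class GroundTruth:
    """Noiseless latent signals and the anomaly mask matching a generated series."""

    latents: pd.DataFrame
    anomaly_mask: pd.DataFrame


def _ar1(n: int, coeff: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with unit marginal variance times ``scale``."""
    innov_sd = scale * np.sqrt(1.0 - coeff**2)
    out = np.empty(n)
    out[0] = rng.normal(0.0, scale)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        out[t] = coeff * out[t - 1] + eps[t - 1]
    return out


def simulate_barn(
    config: BarnSimConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[RawSeries, GroundTruth]:
    """Generate a barn-like series plus its noiseless latents.

    The two pens share the barn-level latent drivers (so paired channels are
    strongly correlated) but carry independent sensor noise; pen b (adult
    pigs, higher mounting point) runs slightly warmer and gassier.
    """
    config = config or BarnSimConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = config.n_steps
    hours = np.arange(n) * config.step_minutes / 60.0
    # diurnal phase: afternoon temperature peak around 15:00
    day = 2.0 * np.pi * (hours - 15.0) / 24.0
    diurnal = np.cos(day)

    s = config.noise_scale
    a = config.ar_coeff

    out_temp_lat = 26.0 + config.diurnal_amplitude_temp * diurnal
    out_temp = out_temp_lat + _ar1(n, a, 1.2 * s, rng)
    out_hum_lat = 70.0 - 2.0 * diurnal
    out_hum = np.clip(out_hum_lat + _ar1(n, a, 4.0 * s, rng), 0.0, 100.0)
    wind_lat = 2.0 + 0.3 * diurnal
    wind = np.clip(wind_lat + _ar1(n, a, 0.9 * s, rng), 0.0, None)

    # barn-level latents shared by both pens
    in_temp_lat = (
        24.0
        + 0.4 * (out_temp - 26.0)
        + 1.5 * diurnal
        - config.wind_to_temp * (wind - 2.0)
    )
    in_temp_noise = _ar1(n, a, 0.5 * s, rng)
    in_hum_lat = 65.0 + 0.5 * (out_hum - 70.0) + _ar1(n, a, 2.0 * s, rng)
    # CO2 peaks at night (low ventilation, resting animals): inverted diurnal
    co2_lat = (
        850.0
        - config.diurnal_amplitude_co2 * diurnal
        - 40.0 * (wind - 2.0)
        + _ar1(n, a, 60.0 * s, rng)
    )
    co2_std = np.maximum(np.std(co2_lat), 1e-9)
    hum_std = np.maximum(np.std(in_hum_lat), 1e-9)
    temp_dev = in_temp_lat + in_temp_noise - 24.0
    nh3_lat = (
        10.0
        + config.co2_to_nh3 * (co2_lat - 850.0) / co2_std
        + config.humidity_to_nh3 * (in_hum_lat - 65.0) / hum_std
        - config.temp_to_gas * temp_dev / max(np.std(temp_dev), 1e-9)
    )
    h2s_lat = (
        0.30
        + 0.02 * config.co2_to_nh3 * (co2_lat - 850.0) / co2_std
        + 0.005 * (in_hum_lat - 65.0)
        - 0.01 * config.temp_to_gas * temp_dev
    )

    cols: dict[str, np.ndarray] = {}
    lats: dict[str, np.ndarray] = {}
    for pen, (dtemp, dgas) in zip("ab", [(0.0, 0.0), (0.8, 0.05)]):
        lats[f"indoor_temp_{pen}"] = in_temp_lat + dtemp
        cols[f"indoor_temp_{pen}"] = in_temp_lat + dtemp + in_temp_noise + _ar1(n, a, 0.2 * s, rng)
        lats[f"indoor_humidity_{pen}"] = in_hum_lat
        cols[f"indoor_humidity_{pen}"] = np.clip(in_hum_lat + _ar1(n, a, 1.0 * s, rng), 0.0, 100.0)
        lats[f"co2_{pen}"] = co2_lat
        cols[f"co2_{pen}"] = np.clip(co2_lat + _ar1(n, a, 25.0 * s, rng), 0.0, None)
        lats[f"nh3_{pen}"] = nh3_lat * (1.0 + dgas)
        # sensor noise at the instrument resolution (0.2 ppm for NH3)
        cols[f"nh3_{pen}"] = np.clip(nh3_lat * (1.0 + dgas) + _ar1(n, a, 0.2 * s, rng), 0.0, None)
        lats[f"h2s_{pen}"] = h2s_lat * (1.0 + dgas)
        cols[f"h2s_{pen}"] = np.clip(h2s_lat * (1.0 + dgas) + _ar1(n, a, 0.06 * s, rng), 0.0, None)
    lats["outdoor_temp"], cols["outdoor_temp"] = out_temp_lat, out_temp
    lats["outdoor_humidity"], cols["outdoor_humidity"] = out_hum_lat, out_hum
    lats["wind_speed"], cols["wind_speed"] = wind_lat, wind

    index = pd.date_range(
        "2023-07-01", periods=n, freq=f"{config.step_minutes}min", name="timestamp"
    )
    wanted = [c for c in config.channels if c in cols]
    frame = pd.DataFrame({c: cols[c] for c in wanted}, index=index)
    latents = pd.DataFrame({c: lats[c] for c in wanted}, index=index)
    mask = pd.DataFrame(False, index=index, columns=wanted)

    series = RawSeries(frame)
    if config.anomaly_rate > 0:
        series, mask = inject_anomalies(
            series, config.anomaly_rate, config.anomaly_magnitude, rng
        )
    return series, GroundTruth(latents=latents, anomaly_mask=mask)


def inject_anomalies(
    series: RawSeries,
    rate: float,
    magnitude: float,
    rng: np.random.Generator,
) -> tuple[RawSeries, pd.DataFrame]:
    """Spike randomly chosen points by +/- magnitude * channel std.

    Every point is independently selected with probability ``rate``; selected
    points are shifted by ``magnitude`` channel standard deviations with a
    random sign.  Unselected points are bit-identical.  Returns the spiked
    series and the boolean ground-truth mask.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    frame = series.frame.copy()
    values = frame.to_numpy(dtype=float)
    mask = rng.random(values.shape) < rate
    sigma = values.std(axis=0, ddof=0)
    signs = np.where(rng.random(values.shape) < 0.5, -1.0, 1.0)
    spiked = values + mask * signs * magnitude * sigma
    frame.iloc[:, :] = spiked
    return RawSeries(frame), pd.DataFrame(mask, index=frame.index, columns=frame.columns)


def learnable_toy(
    n_windows: int,
    lookback: int = 8,
    n_features: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Fast deterministic supervised fixture: target = w . x_last + noise.

    Features are i.i.d. standard normal, the target a fixed linear readout of
    the window's final step plus Gaussian noise, so the Bayes-optimal MSE is
    ``noise_sd**2`` by construction.  Returns a :class:`~barncast.pipeline.WindowedDataset`.
    """
    from .pipeline import WindowedDataset

    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_windows, lookback, n_features))
    w = np.linspace(-0.5, 0.5, n_features)
    y = x[:, -1, :] @ w + rng.normal(0.0, noise_sd, size=n_windows)
    return WindowedDataset(inputs=x, targets=y, target_channel="toy")
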