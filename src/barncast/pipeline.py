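"""End-to-end workflow: windowing, chronological split, correlation analysis,
swarm architecture search, final training, and evaluation.

The supervised framing is one-step-ahead: a window of ``lookback`` consecutive
steps of the 12 input channels predicts the target channel at the step right
after the window.  The 8:2 train/test split is chronological (no shuffling)
so no test-window input precedes information available at training time.

Architecture search runs the improved dung beetle optimizer over the
integer-relaxed box of the four hyperparameters (TCN filter counts F1, F2 and
GRU unit counts N1, N2); candidate fitness is validation MSE after a short
proxy training run, cached by rounded tuple so the "fitness unchanged for
three consecutive rounds" stall rule is well-defined.  The selected
architecture is retrained at full budget and scored with MSE / MAE / R2 on
the denormalized physical scale, alongside a persistence baseline (forecast =
last observed target value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forecaster as fc
from .dbo_core import SearchSpace
from .otdbo import OTDBOConfig, otdbo_optimize
from .preprocessing import (
    NormalizationParams,
    OutlierPolicy,
    RawSeries,
    SmoothingParams,
    detect_outliers,
    minmax_normalize,
    replace_outliers,
    savgol_smooth,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WindowedDataset",
    "SearchConfig",
    "EvaluationReport",
    "CorrelationMatrix",
    "make_windows",
    "chrono_split",
    "pearson_matrix",
    "compute_metrics",
    "ArchitectureFitness",
    "run_search",
    "final_train_and_evaluate",
    "persistence_baseline",
    "preprocess_series",
    "run_pipeline",
    "DEFAULT_BOUNDS",
]

# per-variable search boxes for (F1, F2, N1, N2): lower-layer sizes search
# [1, 32], upper-layer sizes [16, 128]
DEFAULT_BOUNDS = ((1, 32), (16, 128), (1, 32), (16, 128))


@dataclass
class WindowedDataset:
    """Sliding-window supervised set: (n, L, n_features) inputs, n scalar targets."""

    inputs: np.ndarray
    targets: np.ndarray
    target_channel: str
    timestamps: pd.DatetimeIndex | None = None
    feature_channels: list[str] | None = None

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 3:
            raise ValueError("inputs must be (n, L, n_features)")
        if len(self.inputs) != len(self.targets) or len(self.inputs) < 1:
            raise ValueError("inputs/targets lengths must match and be >= 1")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class SearchConfig:
    """Architecture-search settings.

    population 3 beetles, at most 50 rounds, stopping when the best fitness is
    unchanged (within ``stall_tol``) for ``stall_patience`` consecutive
    rounds; each candidate is trained for ``proxy_epochs`` only.
    """

    population: int = 3
    max_iterations: int = 50
    stall_patience: int = 3
    stall_tol: float = 1e-12
    bounds: tuple = DEFAULT_BOUNDS
    proxy_epochs: int = 20
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be >= 1")
        for lo, hi in self.bounds:
            if lo >= hi:
                raise ValueError("each bound must satisfy lower < upper")


@dataclass
class EvaluationReport:
    """MSE / MAE / R2 triple; R2 is None when the truth has zero variance."""

    mse: float
    mae: float
    r2: float | None

    def to_dict(self) -> dict:
        return {"MSE": self.mse, "MAE": self.mae, "R2": self.r2}


@dataclass
class CorrelationMatrix:
    """Pearson coefficients between channels; zero-variance entries are NaN."""

    channels: list[str]
    matrix: pd.DataFrame

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.matrix.loc[a, b])


def make_windows(
    series: RawSeries,
    lookback: int,
    target_channel: str,
    feature_channels: list[str] | None = None,
) -> WindowedDataset:
    """Frame the series into (lookback-block, next-step target) pairs.

    Window i covers steps [i, i+L); its target is the target channel at step
    i+L, so inputs use only data strictly before the target instant.  By
    default the input features are all channels including the target's own
    history (the 12-parameter-input / single-output framing: each parameter
    is predicted in turn from the joint history of all twelve).
    """
    if target_channel not in series.channels:
        raise KeyError(f"unknown target channel {target_channel!r}")
    if feature_channels is None:
        feature_channels = list(series.channels)
    n_total = len(series)
    if n_total <= lookback:
        raise ValueError(f"series length {n_total} must exceed lookback {lookback}")
    feats = series.frame[feature_channels].to_numpy(dtype=float)
    target = series.frame[target_channel].to_numpy(dtype=float)
    n = n_total - lookback
    idx = np.arange(lookback)[None, :] + np.arange(n)[:, None]
    return WindowedDataset(
        inputs=feats[idx],
        targets=target[lookback:],
        target_channel=target_channel,
        timestamps=series.frame.index[lookback:],
        feature_channels=list(feature_channels),
    )


def chrono_split(
    data: WindowedDataset, fraction: float = 0.8
) -> tuple[WindowedDataset, WindowedDataset]:
    """Chronological split: first floor(fraction*n) windows train, rest test."""
    n = len(data)
    if n < 5:
        raise ValueError("need at least 5 windows to split")
    cut = int(np.floor(fraction * n))
    if cut < 1 or cut >= n:
        raise ValueError("split fraction leaves an empty part")

    def take(sl: slice) -> WindowedDataset:
        ts = data.timestamps[sl] if data.timestamps is not None else None
        return WindowedDataset(
            data.inputs[sl], data.targets[sl], data.target_channel, ts, data.feature_channels
        )

    return take(slice(None, cut)), take(slice(cut, None))


def pearson_matrix(series: RawSeries) -> CorrelationMatrix:
    """Product-moment correlation between every pair of channels.

    Zero-variance channels yield NaN entries (flagged with a warning) rather
    than a silent 0.
    """
    frame = series.frame
    if len(frame) < 3:
        raise ValueError("need at least 3 points per channel")
    sigma = frame.std(axis=0, ddof=0)
    degenerate = sigma.index[sigma == 0.0].tolist()
    if degenerate:
        logger.warning("zero-variance channels have undefined correlations: %s", degenerate)
    matrix = frame.corr(method="pearson")
    return CorrelationMatrix(channels=list(frame.columns), matrix=matrix)


def compute_metrics(y: np.ndarray, y_hat: np.ndarray) -> EvaluationReport:
    """MSE, MAE and R2 = 1 - sum((yhat - y)^2) / sum((ybar - y)^2).

    With constant truth the R2 denominator vanishes; R2 is then None.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be equal-length and nonempty")
    err = y_hat - y
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y.mean() - y) ** 2))
    if ss_tot == 0.0:
        logger.warning("constant truth: R2 is undefined")
        r2 = None
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return EvaluationReport(mse=mse, mae=mae, r2=r2)


class ArchitectureFitness:
    """Callable objective for the search: rounded tuple -> proxy validation MSE.

    Positions are continuous 4-vectors (F1, F2, N1, N2); they are rounded to
    integers, a model is built and trained for ``proxy_epochs``, and the final
    validation MSE is the fitness.  Results are cached by rounded tuple, so
    repeated probes cost nothing and "fitness did not change" is exact.
    Training failures count as worst-case fitness (with a logged warning)
    instead of aborting the search.
    """

    def __init__(
        self,
        train: WindowedDataset,
        val: WindowedDataset,
        config: SearchConfig,
        lookback: int,
        n_features: int,
    ):
        self.train = train
        self.val = val
        self.config = config
        self.lookback = lookback
        self.n_features = n_features
        self.cache: dict[tuple[int, int, int, int], float] = {}
        self.evaluations = 0

    def round_position(self, position: np.ndarray) -> tuple[int, int, int, int]:
        ints = np.rint(np.asarray(position, dtype=float)).astype(int)
        clipped = [
            int(np.clip(v, lo, hi)) for v, (lo, hi) in zip(ints, self.config.bounds)
        ]
        return tuple(clipped)  # type: ignore[return-value]

    def __call__(self, position: np.ndarray) -> float:
        key = self.round_position(position)
        if key in self.cache:
            return self.cache[key]
        f1, f2, n1, n2 = key
        arch = fc.Architecture(
            f1=f1, f2=f2, n1=n1, n2=n2, lookback=self.lookback, n_features=self.n_features
        )
        try:
            model = fc.build_model(arch, seed=self.config.seed)
            train_cfg = fc.TrainConfig(
                learning_rate=self.config.learning_rate,
                epochs=self.config.proxy_epochs,
                batch_size=self.config.batch_size,
                seed=self.config.seed,
            )
            _, history = fc.train_model(model, self.train, self.val, train_cfg)
            fitness = float(history["val_loss"][-1])
        except FloatingPointError as exc:  # diverged candidate
            logger.warning("candidate %s failed to train: %s", key, exc)
            fitness = float(np.finfo(float).max)
        self.cache[key] = fitness
        self.evaluations += 1
        return fitness


def run_search(
    train: WindowedDataset,
    val: WindowedDataset,
    config: SearchConfig | None = None,
) -> tuple[fc.Architecture, pd.DataFrame]:
    """Swarm search for (F1, F2, N1, N2); returns best architecture + round log.

    The log has one row per round with the incumbent's hyperparameters and
    fitness: columns Training Rounds / Filter F1 / Filter F2 / Neuron Numbers
    N1 / Neuron Numbers N2 / Optimal Fitness.
    """
    config = config or SearchConfig()
    lookback = train.inputs.shape[1]
    n_features = train.inputs.shape[2]
    objective = ArchitectureFitness(train, val, config, lookback, n_features)
    space = SearchSpace(
        lower=[lo for lo, _ in config.bounds], upper=[hi for _, hi in config.bounds]
    )
    rows: list[dict] = []

    def log_round(t: int, position: np.ndarray, fitness: float) -> None:
        f1, f2, n1, n2 = objective.round_position(position)
        rows.append(
            {
                "Training Rounds": t,
                "Filter F1": f1,
                "Filter F2": f2,
                "Neuron Numbers N1": n1,
                "Neuron Numbers N2": n2,
                "Optimal Fitness": fitness,
            }
        )

    result = otdbo_optimize(
        objective,
        space,
        OTDBOConfig(
            n=config.population,
            t_max=config.max_iterations,
            stall_patience=config.stall_patience,
            stall_tol=config.stall_tol,
        ),
        seed=config.seed,
        callback=log_round,
    )
    f1, f2, n1, n2 = objective.round_position(result.best_position)
    best = fc.Architecture(f1=f1, f2=f2, n1=n1, n2=n2, lookback=lookback, n_features=n_features)
    return best, pd.DataFrame(rows)


def persistence_baseline(series: RawSeries, data: WindowedDataset) -> np.ndarray:
    """Forecast = last observed target value (the minimal reference model).

    For window i (targeting step i+L) the prediction is the target channel at
    step i+L-1.
    """
    target = series.frame[data.target_channel].to_numpy(dtype=float)
    lookback = data.inputs.shape[1]
    n = len(data)
    offset = len(target) - lookback - n  # windows may be a chronological tail
    start = lookback - 1 + offset
    return target[start : start + n]


def preprocess_series(
    series: RawSeries,
    outlier_policy: OutlierPolicy | None = None,
    smoothing: SmoothingParams | None = None,
    norm_params: NormalizationParams | None = None,
    train_fraction: float | None = 0.8,
) -> tuple[RawSeries, NormalizationParams]:
    """The cleaning chain: outlier repair -> smoothing -> [0,1] normalization.

    Normalization statistics are computed on the leading ``train_fraction`` of
    the timeline (to avoid leaking test-period extremes), or on the full
    series when ``train_fraction`` is None, unless explicit ``norm_params``
    are given.
    """
    policy = outlier_policy or OutlierPolicy()
    mask = detect_outliers(series, policy)
    repaired = replace_outliers(series, mask, policy)
    smoothed = savgol_smooth(repaired, smoothing or SmoothingParams())
    if norm_params is None and train_fraction is not None:
        cut = int(np.floor(train_fraction * len(smoothed)))
        head = RawSeries(smoothed.frame.iloc[:cut])
        _, norm_params = minmax_normalize(head)
    normalized, params = minmax_normalize(smoothed, norm_params)
    return normalized, params


def final_train_and_evaluate(
    arch: fc.Architecture,
    train: WindowedDataset,
    test: WindowedDataset,
    norm_params: NormalizationParams | None = None,
    epochs: int = 200,
    seed: int = 0,
    learning_rate: float = 0.001,
    batch_size: int = 8,
    patience: int | None = None,
) -> tuple[EvaluationReport, pd.DataFrame, fc.TCNGRURegressor]:
    """Train the selected architecture at full budget and score the test split.

    The final fit uses small batches (default 8): at a few hundred training
    windows this yields enough optimizer steps per epoch to converge within
    the fixed epoch budget.

    When ``norm_params`` is given, predictions and truth are mapped back to
    the physical scale of the target channel before computing MSE / MAE / R2.
    Returns (report, per-timestamp predicted-vs-actual table, trained model).
    """
    model = fc.build_model(arch, seed=seed)
    cfg = fc.TrainConfig(
        learning_rate=learning_rate,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
        patience=patience,
    )
    fc.train_model(model, train, test, cfg)
    pred = model.predict(test.inputs)
    truth = test.targets
    if norm_params is not None:
        from .preprocessing import denormalize_channel

        pred = denormalize_channel(pred, norm_params, test.target_channel)
        truth = denormalize_channel(truth, norm_params, test.target_channel)
    report = compute_metrics(truth, pred)
    table = pd.DataFrame(
        {
            "timestamp": test.timestamps
            if test.timestamps is not None
            else np.arange(len(truth)),
            "actual": truth,
            "predicted": pred,
        }
    )
    return report, table, model


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    architecture: fc.Architecture
    search_log: pd.DataFrame
    report: EvaluationReport
    baseline_report: EvaluationReport
    predictions: pd.DataFrame
    norm_params: NormalizationParams
    model: fc.TCNGRURegressor


def run_pipeline(
    series: RawSeries,
    target_channel: str,
    lookback: int = 48,
    search_config: SearchConfig | None = None,
    final_epochs: int = 200,
    seed: int = 0,
    smoothing: SmoothingParams | None = None,
) -> PipelineResult:
    """Full workflow on a raw series: clean, window, search, train, evaluate.

    The persistence baseline is evaluated on the same denormalized test split
    for reference.
    """
    search_config = search_config or SearchConfig(seed=seed)
    clean, norm_params = preprocess_series(series, smoothing=smoothing)
    windows = make_windows(clean, lookback, target_channel)
    train, test = chrono_split(windows)
    best_arch, log = run_search(train, test, search_config)
    report, table, model = final_train_and_evaluate(
        best_arch, train, test, norm_params, epochs=final_epochs, seed=seed
    )
    from .preprocessing import denormalize_channel

    base_pred = persistence_baseline(clean, test)
    base_report = compute_metrics(
        denormalize_channel(test.targets, norm_params, target_channel),
        denormalize_channel(base_pred, norm_params, target_channel),
    )
    return PipelineResult(
        architecture=best_arch,
        search_log=log,
        report=report,
        baseline_report=base_report,
        predictions=table,
        norm_params=norm_params,
        model=model,
    )
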