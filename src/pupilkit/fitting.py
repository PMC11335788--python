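"""Parameter estimation for the convolution model.

RF shape/timing parameters, the relative contrast weight, and (optionally)
the five free regional weights are found by minimizing the RMSE between the
z-scored observed pupil trace and the z-scored model prediction, pooled over
trials, with a Nelder–Mead simplex search.  Robustness is assessed with a
repeated random-split cross-validation: trials are divided into training
(70%) and testing (30%) sets, the split is redrawn independently for each of
five folds, and reported performance is the mean over the held-out sets.

Observed pupil traces are resampled onto the event-trace timestamps; blink
gaps up to 500 ms are linearly interpolated, longer gaps stay masked and are
excluded from the loss and the metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, signal

from .convolution_model import (
    COMPONENT_CONTRAST,
    COMPONENT_LUMINANCE,
    ModelSpec,
    RegionalWeights,
    build_kernel,
)
from .response_functions import ErlangParams, GammaPdfParams
from .video_events import EventTraces, Recording, RegionGrid


class ConfigError(ValueError):
    """Invalid fitting configuration."""


class FitDataError(ValueError):
    """No usable samples to fit on."""


@dataclass
class Trial:
    """One movie-viewing trial: event traces plus the aligned recording."""

    traces: EventTraces
    recording: Recording


_ERLANG_DEFAULTS = {
    "lum_n": 10.0,
    "lum_tmax": 0.3,
    "con_n": 3.0,
    "con_tmax": 0.5,
}
_GAMMA_DEFAULTS = {
    "lum_k": 14.0,
    "lum_theta": 0.05,
    "con_k": 4.0,
    "con_theta": 0.15,
}
_SHARED_DEFAULTS = {
    "contrast_weight": 0.5,
    "w2": 1.0,
    "w3": 1.0,
    "w4": 1.0,
    "w5": 1.0,
    "w6": 1.0,
}
_BOUNDS = {
    "lum_n": (0.5, 40.0),
    "con_n": (0.5, 40.0),
    "lum_tmax": (0.05, 2.0),
    "con_tmax": (0.05, 2.0),
    "lum_k": (1.05, 40.0),
    "con_k": (1.05, 40.0),
    "lum_theta": (0.01, 2.0),
    "con_theta": (0.01, 2.0),
    "contrast_weight": (0.0, 10.0),
    "w2": (0.0, 10.0),
    "w3": (0.0, 10.0),
    "w4": (0.0, 10.0),
    "w5": (0.0, 10.0),
    "w6": (0.0, 10.0),
}


@dataclass
class FitConfig:
    """Optimizer, cross-validation, and preprocessing settings."""

    train_fraction: float = 0.7
    n_folds: int = 5
    seed: int = 0
    maxiter: int = 4000
    xatol: float = 1e-4
    fatol: float = 1e-8
    n_restarts: int = 1
    delay: float = 0.2
    max_blink_gap: float = 0.5  # seconds of invalid pupil to interpolate over
    initial: dict = field(default_factory=dict)  # overrides of starting values
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)  # parameters held at a value

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie strictly between 0 and 1")
        if self.n_folds < 1:
            raise ConfigError("n_folds must be >= 1")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")


class EvalMetrics(NamedTuple):
    r2: float
    r: float
    rmse: float


@dataclass
class FitResult:
    """Best-fit parameters and cross-validated performance."""

    lum_params: object
    contrast_params: object
    contrast_weight: float
    weights: RegionalWeights
    fold_train: list[EvalMetrics]
    fold_test: list[EvalMetrics]
    test_r2_mean: float
    test_r2_sd: float
    test_r_mean: float
    test_rmse_mean: float
    bic: float
    n_free_parameters: int
    converged: bool
    param_values: dict


def evaluate(pred: np.ndarray, obs: np.ndarray) -> EvalMetrics:
    """R² (1 − SS_res/SS_tot), Pearson r, and RMSE between two series."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("series must have equal length")
    if obs.size < 2:
        raise ValueError("need at least two samples")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0 or pred.std() == 0:
        r = math.nan
        r2 = math.nan if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        return EvalMetrics(r2, r, rmse)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    r = float(np.corrcoef(pred, obs)[0, 1])
    return EvalMetrics(r2, r, rmse)


def bic(rss: float, n_samples: int, k_params: int) -> float:
    """Bayesian information criterion: n·ln(rss/n) + k·ln(n)."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n_samples <= k_params:
        raise ValueError("need more samples than parameters")
    return n_samples * math.log(rss / n_samples) + k_params * math.log(n_samples)


def make_folds(
    n_trials: int, config: FitConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent random train/test splits, one per fold, seeded.

    Each fold is a fresh random split (trials are *not* guaranteed to appear
    in a test set across folds).
    """
    if n_trials < 2:
        raise ConfigError("need at least two trials to split")
    n_train = int(round(config.train_fraction * n_trials))
    n_train = min(max(n_train, 1), n_trials - 1)
    rng = np.random.default_rng(config.seed)
    folds = []
    for _ in range(config.n_folds):
        perm = rng.permutation(n_trials)
        folds.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return folds


def interpolate_blinks(
    pupil: np.ndarray, valid: np.ndarray, rate: float, max_gap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate invalid runs up to ``max_gap`` s; mask longer ones."""
    pupil = np.asarray(pupil, dtype=float).copy()
    valid = np.asarray(valid, dtype=bool).copy()
    n = len(pupil)
    if valid.all() or not valid.any():
        return pupil, valid
    idx = np.arange(n)
    pupil[~valid] = np.interp(idx[~valid], idx[valid], pupil[valid])
    max_run = int(round(max_gap * rate))
    # re-mask runs longer than max_gap
    start = None
    out_valid = valid.copy()
    for i in range(n + 1):
        if i < n and not valid[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start <= max_run:
                out_valid[start:i] = True
            start = None
    return pupil, out_valid


@dataclass
class _PreparedTrial:
    group_lum: np.ndarray  # (n_steps, n_groups)
    group_con: np.ndarray
    obs_z: np.ndarray  # observed pupil, z-scored over valid samples
    mask: np.ndarray
    dt: float


def _group_matrix(grid: RegionGrid, use_regions: bool) -> np.ndarray:
    n_regions = grid.n_regions
    if not use_regions:
        return np.full((n_regions, 1), 1.0 / n_regions)
    groups = grid.weight_group_of_region()
    m = np.zeros((n_regions, RegionGrid.N_GROUPS))
    m[np.arange(n_regions), groups] = 1.0
    return m


def prepare_trial(trial: Trial, spec: ModelSpec, config: FitConfig) -> _PreparedTrial:
    """Resample the observation onto event timestamps and pre-group regions."""
    traces, rec = trial.traces, trial.recording
    pupil, valid = interpolate_blinks(rec.pupil, rec.valid, rec.rate, config.max_blink_gap)
    if not valid.any():
        raise FitDataError("recording has no valid pupil samples")
    obs = np.interp(traces.timestamps, rec.timestamps, pupil)
    mask = np.interp(traces.timestamps, rec.timestamps, valid.astype(float)) > 0.999
    if mask.sum() < 2:
        raise FitDataError("fewer than two valid samples after alignment")
    mu, sd = obs[mask].mean(), obs[mask].std()
    if sd == 0:
        raise FitDataError("observed pupil trace has zero variance")
    gm = _group_matrix(traces.grid, spec.use_regions)
    return _PreparedTrial(
        group_lum=traces.luminance_change @ gm,
        group_con=traces.contrast_change @ gm,
        obs_z=(obs - mu) / sd,
        mask=mask,
        dt=traces.dt,
    )


def param_names(spec: ModelSpec) -> list[str]:
    """Free-parameter layout for a model variant (before fixing any)."""
    names: list[str] = []
    erlang = spec.rf_family == "erlang"
    if COMPONENT_LUMINANCE in spec.components:
        names += ["lum_n", "lum_tmax"] if erlang else ["lum_k", "lum_theta"]
    if COMPONENT_CONTRAST in spec.components:
        names += ["con_n", "con_tmax"] if erlang else ["con_k", "con_theta"]
    if len(spec.components) > 1:
        names.append("contrast_weight")
    if spec.use_regions:
        names += ["w2", "w3", "w4", "w5", "w6"]
    return names


def _defaults(spec: ModelSpec) -> dict:
    d = dict(_SHARED_DEFAULTS)
    d.update(_ERLANG_DEFAULTS if spec.rf_family == "erlang" else _GAMMA_DEFAULTS)
    return d


def _unpack(values: dict, spec: ModelSpec, config: FitConfig):
    """Parameter dict → (lum_params, con_params, contrast_weight, weights)."""
    if spec.rf_family == "erlang":
        lum = ErlangParams(values["lum_n"], values["lum_tmax"], delay=config.delay)
        con = ErlangParams(values["con_n"], values["con_tmax"], delay=config.delay)
    else:
        lum = GammaPdfParams(1.0, values["lum_k"], values["lum_theta"], delay=config.delay)
        con = GammaPdfParams(1.0, values["con_k"], values["con_theta"], delay=config.delay)
    cw = values.get("contrast_weight", spec.contrast_weight)
    weights = RegionalWeights.from_free(
        [values.get(f"w{i}", 1.0) for i in range(2, 7)]
    )
    return lum, con, cw, weights


def _predict_raw(
    prepared: _PreparedTrial, spec: ModelSpec, config: FitConfig, values: dict
) -> np.ndarray:
    lum, con, cw, weights = _unpack(values, spec, config)
    if spec.use_regions:
        w = np.concatenate([[1.0], [values.get(f"w{i}", 1.0) for i in range(2, 7)]])
    else:
        w = np.ones(prepared.group_lum.shape[1])
    out = np.zeros(prepared.group_lum.shape[0])
    dt = prepared.dt
    if COMPONENT_LUMINANCE in spec.components:
        kernel = build_kernel(lum, spec.rf_family, dt, spec.kernel_duration)
        series = prepared.group_lum @ w
        out -= np.cumsum(signal.fftconvolve(series, kernel)[: len(series)]) * dt
    if COMPONENT_CONTRAST in spec.components:
        kernel = build_kernel(con, spec.rf_family, dt, spec.kernel_duration)
        series = prepared.group_con @ w
        out -= cw * signal.fftconvolve(series, kernel)[: len(series)]
    return out


def _zscore_masked(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mu, sd = x[mask].mean(), x[mask].std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - mu) / sd


def _pooled_pairs(
    prepared: Sequence[_PreparedTrial], spec: ModelSpec, config: FitConfig, values: dict
) -> tuple[np.ndarray, np.ndarray]:
    preds, obs = [], []
    for p in prepared:
        raw = _predict_raw(p, spec, config, values)
        preds.append(_zscore_masked(raw, p.mask)[p.mask])
        obs.append(p.obs_z[p.mask])
    return np.concatenate(preds), np.concatenate(obs)


def loss(
    trials: Sequence[Trial],
    lum_params,
    contrast_params,
    spec: ModelSpec,
    weights: Optional[RegionalWeights] = None,
    config: Optional[FitConfig] = None,
) -> float:
    """Pooled RMSE between z-scored observed and predicted pupil traces."""
    if not trials:
        raise FitDataError("no trials supplied")
    config = config or FitConfig()
    values = dict(_defaults(spec))
    if spec.rf_family == "erlang":
        values.update(
            lum_n=lum_params.n, lum_tmax=lum_params.t_max,
            con_n=contrast_params.n, con_tmax=contrast_params.t_max,
        )
    else:
        values.update(
            lum_k=lum_params.k, lum_theta=lum_params.theta,
            con_k=contrast_params.k, con_theta=contrast_params.theta,
        )
    values["contrast_weight"] = spec.contrast_weight
    if weights is not None:
        for i, v in enumerate(weights.as_array()[1:], start=2):
            values[f"w{i}"] = v
    prepared = [prepare_trial(t, spec, config) for t in trials]
    pred, obs = _pooled_pairs(prepared, spec, config, values)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _optimize_fold(
    prepared: Sequence[_PreparedTrial],
    spec: ModelSpec,
    config: FitConfig,
    free: list[str],
    x0_base: np.ndarray,
    bounds: list[tuple[float, float]],
    rng: np.random.Generator,
) -> tuple[dict, float, bool]:
    base = _defaults(spec)
    base.update(config.fixed)

    def objective(x: np.ndarray) -> float:
        values = dict(base)
        values.update(zip(free, x))
        pred, obs = _pooled_pairs(prepared, spec, config, values)
        return float(np.sqrt(np.mean((pred - obs) ** 2)))

    best = None
    converged = False
    for restart in range(config.n_restarts):
        if restart == 0:
            x0 = x0_base
        else:
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            x0 = np.clip(x0_base * rng.uniform(0.6, 1.4, size=len(free)), lo, hi)
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options=dict(
                maxiter=config.maxiter,
                xatol=config.xatol,
                fatol=config.fatol,
                adaptive=len(free) > 5,
            ),
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    values = dict(base)
    values.update(zip(free, best.x))
    return values, float(best.fun), converged


def fit(trials: Sequence[Trial], spec: ModelSpec, config: Optional[FitConfig] = None) -> FitResult:
    """Cross-validated simplex fit of the convolution model to trials.

    Deterministic given ``config.seed``.  Returns the parameters of the fold
    with the lowest training RMSE plus per-fold and pooled test metrics.
    """
    config = config or FitConfig()
    if not trials:
        raise FitDataError("no trials supplied")
    prepared = [prepare_trial(t, spec, config) for t in trials]
    folds = make_folds(len(trials), config)

    free = [n for n in param_names(spec) if n not in config.fixed]
    if not free:
        raise ConfigError("all parameters are fixed; nothing to fit")
    defaults = _defaults(spec)
    defaults.update(config.initial)
    x0 = np.array([defaults[n] for n in free])
    all_bounds = dict(_BOUNDS)
    all_bounds.update(config.bounds)
    bounds = [all_bounds[n] for n in free]
    rng = np.random.default_rng(config.seed)

    fold_train, fold_test = [], []
    best_values, best_train_rmse, converged_all = None, np.inf, True
    test_residuals: list[np.ndarray] = []
    for train_idx, test_idx in folds:
        train = [prepared[i] for i in train_idx]
        test = [prepared[i] for i in test_idx]
        values, train_rmse, conv = _optimize_fold(
            train, spec, config, free, x0, bounds, rng
        )
        converged_all &= conv
        pred_tr, obs_tr = _pooled_pairs(train, spec, config, values)
        pred_te, obs_te = _pooled_pairs(test, spec, config, values)
        fold_train.append(evaluate(pred_tr, obs_tr))
        fold_test.append(evaluate(pred_te, obs_te))
        test_residuals.append(obs_te - pred_te)
        if train_rmse < best_train_rmse:
            best_train_rmse, best_values = train_rmse, values

    lum, con, cw, weights = _unpack(best_values, spec, config)
    resid = np.concatenate(test_residuals)
    k = len(free)
    bic_value = bic(float(np.sum(resid**2)), len(resid), k)
    test_r2 = np.array([m.r2 for m in fold_test])
    return FitResult(
        lum_params=lum,
        contrast_params=con,
        contrast_weight=cw,
        weights=weights,
        fold_train=fold_train,
        fold_test=fold_test,
        test_r2_mean=float(test_r2.mean()),
        test_r2_sd=float(test_r2.std()),
        test_r_mean=float(np.mean([m.r for m in fold_test])),
        test_rmse_mean=float(np.mean([m.rmse for m in fold_test])),
        bic=bic_value,
        n_free_parameters=k,
        converged=converged_all,
        param_values=dict(best_values),
    )
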