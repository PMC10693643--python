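"""Approximate Bayesian Computation: rejection plus regression adjustment.

The reference table holds one row per simulation: the five drawn parameters
and the 46 summary statistics.  Inference standardises the statistics
(robust median/MAD scaling), keeps the closest ``tolerance`` fraction of
rows in Euclidean distance to the observed vector, and corrects the
retained parameters with a regression of (transformed) parameters on
standardised statistics — a single-hidden-layer neural network (default 4
units, averaged over several restarts) or weighted local-linear regression
— evaluated at the observed statistics:

    theta* = m(s_obs) + (theta - m(s)).

Parameters are mapped to an unbounded scale before regression via a logit
over their prior bounds (log-uniform parameters are first taken to log10
scale), which forces adjusted draws back inside the prior support.
Posterior summaries (median, 2.5/97.5 percentiles) use Epanechnikov
distance weights for the regression-adjusted methods.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import PARAM_NAMES, ModelConstants, PriorSpec

logger = logging.getLogger(__name__)


class InferenceError(RuntimeError):
    """ABC cannot proceed (degenerate statistics, empty acceptance, ...)."""


class TransformError(ValueError):
    """Value outside the transform's domain."""


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Simulated (parameters, statistics) table, the ABC substrate."""

    params: pd.DataFrame  # n_sim x 5, columns PARAM_NAMES
    stats: pd.DataFrame  # n_sim x n_stats
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.params.columns) != list(PARAM_NAMES):
            raise InferenceError(f"parameter columns must be {PARAM_NAMES}")
        if len(self.params) != len(self.stats):
            raise InferenceError("params and stats must have equal row counts")
        if self.params.isna().any().any():
            raise InferenceError("reference table has missing parameter values")

    def __len__(self) -> int:
        return len(self.params)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.provenance:
                fh.write("# " + json.dumps(self.provenance, sort_keys=True) + "\n")
            pd.concat([self.params, self.stats], axis=1).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        provenance = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                provenance = json.loads(first[1:].strip())
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
        return cls(
            params=df[list(PARAM_NAMES)].copy(),
            stats=df.drop(columns=list(PARAM_NAMES)),
            provenance=provenance,
        )

    def drop_rows(self, indices) -> "ReferenceTable":
        mask = np.ones(len(self), dtype=bool)
        mask[np.asarray(indices)] = False
        return ReferenceTable(
            self.params.iloc[mask].reset_index(drop=True),
            self.stats.iloc[mask].reset_index(drop=True),
            dict(self.provenance),
        )


@dataclass(frozen=True)
class ABCConfig:
    """Inference settings: acceptance tolerance, adjustment method, seeds."""

    tolerance: float = 0.10
    method: str = "neuralnet"  # neuralnet | loclinear | rejection
    hidden_units: int = 4
    n_restarts: int = 10
    weight_decay: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tolerance <= 1:
            raise InferenceError(f"tolerance must be in (0, 1], got {self.tolerance}")
        if self.hidden_units < 1:
            raise InferenceError("hidden_units must be >= 1")
        if self.method not in ("neuralnet", "loclinear", "rejection"):
            raise InferenceError(f"unknown method {self.method!r}")


# ---------------------------------------------------------------------------
# Standardisation and rejection
# ---------------------------------------------------------------------------


@dataclass
class StandardizedStats:
    """Statistics after robust scaling, plus the constants used."""

    table: np.ndarray  # n_sim x n_kept
    observed: np.ndarray  # n_kept
    kept_columns: list[str]
    center: np.ndarray
    scale: np.ndarray


def standardize(reference: ReferenceTable, observed) -> StandardizedStats:
    """Scale each statistic by (x - median) / MAD of the reference.

    Zero-inflated columns (typical of IBD/ROH bins at small genome sizes)
    can have zero MAD while still carrying signal; those fall back to
    standard-deviation scaling.  Columns with zero variance carry no usable
    spread and are dropped with a warning; the observed vector is
    transformed with the same constants.
    """
    obs = _observed_to_array(observed, reference.stats.columns)
    X = reference.stats.to_numpy(dtype=float)
    center = np.median(X, axis=0)
    scale = np.median(np.abs(X - center), axis=0)
    sd = X.std(axis=0)
    fallback = (scale == 0) & (sd > 0)
    scale = np.where(fallback, sd, scale)
    keep = scale > 0
    if not keep.any():
        raise InferenceError("all statistic columns are degenerate (zero spread)")
    if not keep.all():
        dropped = [c for c, k in zip(reference.stats.columns, keep) if not k]
        logger.warning("standardize: dropping zero-spread statistic columns %s", dropped)
    return StandardizedStats(
        table=(X[:, keep] - center[keep]) / scale[keep],
        observed=(obs[keep] - center[keep]) / scale[keep],
        kept_columns=[c for c, k in zip(reference.stats.columns, keep) if k],
        center=center[keep],
        scale=scale[keep],
    )


def _observed_to_array(observed, columns) -> np.ndarray:
    if hasattr(observed, "as_dict"):  # SummaryVector
        d = observed.as_dict()
        return np.array([d[c] for c in columns], dtype=float)
    if isinstance(observed, dict):
        return np.array([observed[c] for c in columns], dtype=float)
    arr = np.asarray(observed, dtype=float)
    if arr.shape != (len(columns),):
        raise InferenceError(f"observed vector length {arr.shape} != {len(columns)} statistics")
    return arr


def rejection_sample(std: StandardizedStats, tolerance: float):
    """Accept the ``ceil(tolerance * n)`` reference rows closest to the
    observed statistics in Euclidean distance (ties broken by row order).

    Returns (accepted row indices, their distances).
    """
    n = std.table.shape[0]
    k = math.ceil(tolerance * n)
    if k < 1:
        raise InferenceError(f"tolerance {tolerance} accepts no rows out of {n}")
    d = np.sqrt(((std.table - std.observed) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    return order, d[order]


# ---------------------------------------------------------------------------
# Parameter transform
# ---------------------------------------------------------------------------

_LOGIT_EPS_FRAC = 1e-9


def logit_transform(values, lower: float, upper: float) -> np.ndarray:
    """Map (lower, upper) to the real line: y = log((x-l)/(u-x)).

    Boundary values are nudged inward by 1e-9 * (upper - lower); values
    outside [lower, upper] raise.
    """
    if not lower < upper:
        raise TransformError(f"need lower < upper, got [{lower}, {upper}]")
    x = np.asarray(values, dtype=float)
    if np.any(x < lower) or np.any(x > upper):
        raise TransformError(f"values outside [{lower}, {upper}]")
    eps = _LOGIT_EPS_FRAC * (upper - lower)
    x = np.clip(x, lower + eps, upper - eps)
    return np.log((x - lower) / (upper - x))


def inverse_logit_transform(values, lower: float, upper: float) -> np.ndarray:
    """Inverse of :func:`logit_transform`; any real maps inside (l, u)."""
    if not lower < upper:
        raise TransformError(f"need lower < upper, got [{lower}, {upper}]")
    y = np.asarray(values, dtype=float)
    with np.errstate(over="ignore"):
        e = np.exp(-np.abs(y))
    frac = np.where(y >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    # strict interior even when the sigmoid saturates in floating point
    frac = np.clip(frac, _LOGIT_EPS_FRAC, 1.0 - _LOGIT_EPS_FRAC)
    return lower + (upper - lower) * frac


class ParamTransform:
    """Per-parameter bijection to an unbounded regression scale.

    Log-uniform parameters go through log10 first so that the logit operates
    on the scale on which their prior is flat.
    """

    def __init__(self, prior: PriorSpec):
        self.bounds: dict[str, tuple[float, float, bool]] = {}
        for name in PARAM_NAMES:
            p = prior[name]
            logscale = p.kind == "loguniform"
            lo, hi = (math.log10(p.low), math.log10(p.high)) if logscale else (p.low, p.high)
            self.bounds[name] = (lo, hi, logscale)

    def forward(self, params: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in PARAM_NAMES:
            lo, hi, logscale = self.bounds[name]
            x = params[name].to_numpy(dtype=float)
            if logscale:
                x = np.log10(x)
            cols.append(logit_transform(x, lo, hi))
        return np.column_stack(cols)

    def backward(self, Y: np.ndarray) -> pd.DataFrame:
        out = {}
        for j, name in enumerate(PARAM_NAMES):
            lo, hi, logscale = self.bounds[name]
            x = inverse_logit_transform(Y[:, j], lo, hi)
            out[name] = 10.0**x if logscale else x
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Regression adjustment and posterior summaries
# ---------------------------------------------------------------------------


@dataclass
class PosteriorResult:
    """Adjusted posterior draws, weights, and per-parameter summaries."""

    samples: pd.DataFrame  # natural scale, columns PARAM_NAMES
    weights: np.ndarray
    summary: pd.DataFrame  # index PARAM_NAMES, columns median/q2.5/q97.5
    method: str
    split_time_years: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t")


def weighted_quantile(values, q, weights) -> float:
    """Weighted quantile by interpolation of the weighted empirical CDF."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v)
    v, w = v[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(q, cw, v))


def _epanechnikov(distances: np.ndarray) -> np.ndarray:
    dmax = distances.max()
    if dmax == 0:
        w = np.ones_like(distances)
    else:
        w = 1.0 - (distances / dmax) ** 2
        if w.sum() == 0:  # all points at dmax
            w = np.ones_like(distances)
    return w / w.sum()


def _fit_neuralnet(X, Y, x_obs, cfg: ABCConfig):
    """Average single-hidden-layer network fits over restarts; return
    (fitted values at X, prediction at x_obs)."""
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPRegressor

    preds_X = np.zeros_like(Y)
    preds_obs = np.zeros(Y.shape[1])
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.n_restarts):
        mlp = MLPRegressor(
            hidden_layer_sizes=(cfg.hidden_units,),
            activation="logistic",
            solver="lbfgs",
            alpha=cfg.weight_decay,
            max_iter=500,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            mlp.fit(X, Y)
        preds_X += mlp.predict(X)
        preds_obs += np.atleast_2d(mlp.predict(x_obs.reshape(1, -1)))[0]
    return preds_X / cfg.n_restarts, preds_obs / cfg.n_restarts


def _fit_loclinear(X, Y, x_obs, weights):
    """Weighted linear regression; returns (fitted at X, prediction at x_obs)."""
    A = np.column_stack([np.ones(X.shape[0]), X])
    sw = np.sqrt(weights)
    beta, *_ = np.linalg.lstsq(A * sw[:, None], Y * sw[:, None], rcond=None)
    fitted = A @ beta
    pred = np.concatenate([[1.0], x_obs]) @ beta
    return fitted, pred


def regression_adjust(
    accepted_params: pd.DataFrame,
    accepted_stats: np.ndarray,
    observed_stats: np.ndarray,
    distances: np.ndarray,
    cfg: ABCConfig,
    prior: PriorSpec,
    constants: ModelConstants | None = None,
) -> PosteriorResult:
    """Adjust accepted parameter draws toward the observed statistics.

    With ``method='rejection'`` the accepted draws are returned unweighted
    and unadjusted.  A regression failure falls back to rejection with a
    warning rather than aborting the run.
    """
    if len(accepted_params) == 0:
        raise InferenceError("accepted set is empty")
    constants = constants or ModelConstants()
    transform = ParamTransform(prior)

    if cfg.method == "rejection":
        samples = accepted_params.reset_index(drop=True)
        weights = np.full(len(samples), 1.0 / len(samples))
        method = "rejection"
    else:
        weights = _epanechnikov(distances)
        theta = transform.forward(accepted_params)
        try:
            if cfg.method == "neuralnet":
                fitted, pred_obs = _fit_neuralnet(accepted_stats, theta, observed_stats, cfg)
            else:
                fitted, pred_obs = _fit_loclinear(accepted_stats, theta, observed_stats, weights)
            adjusted = pred_obs[None, :] + (theta - fitted)
            if not np.all(np.isfinite(adjusted)):
                raise InferenceError("non-finite adjusted values")
            samples = transform.backward(adjusted)
            method = cfg.method
        except Exception as exc:
            logger.warning("regression adjustment failed (%s); falling back to rejection", exc)
            samples = accepted_params.reset_index(drop=True)
            weights = np.full(len(samples), 1.0 / len(samples))
            method = "rejection-fallback"

    rows = {}
    for name in PARAM_NAMES:
        v = samples[name].to_numpy()
        rows[name] = {
            "median": weighted_quantile(v, 0.5, weights),
            "q2.5": weighted_quantile(v, 0.025, weights),
            "q97.5": weighted_quantile(v, 0.975, weights),
        }
    summary = pd.DataFrame(rows).T.loc[list(PARAM_NAMES)]
    gy = constants.generation_time_years
    split_years = {k: summary.loc["gen_split", k] * gy for k in ("median", "q2.5", "q97.5")}
    return PosteriorResult(samples, weights, summary, method, split_years)


def estimate_posterior(
    reference: ReferenceTable,
    observed,
    cfg: ABCConfig | None = None,
    prior: PriorSpec | None = None,
    constants: ModelConstants | None = None,
) -> PosteriorResult:
    """Full ABC: standardise, reject, regression-adjust, summarise."""
    cfg = cfg or ABCConfig()
    prior = prior or PriorSpec()
    std = standardize(reference, observed)
    idx, dist = rejection_sample(std, cfg.tolerance)
    return regression_adjust(
        reference.params.iloc[idx].reset_index(drop=True),
        std.table[idx],
        std.observed,
        dist,
        cfg,
        prior,
        constants,
    )
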