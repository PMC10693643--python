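"""Accuracy and calibration of the ABC estimator.

Pseudo-observed validation: rows of the reference table are held out one at
a time, their statistics treated as the observation, and the posterior
re-estimated from the remaining rows (leave-one-out, so the holdout's own
zero-distance self-match cannot flatter the estimator).  Point accuracy is
summarised by MAE/MSE/RMSE of posterior medians against the holdout's true
parameters; interval calibration by the frequency with which the truth
falls inside the [2.5, 97.5] percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import PARAM_NAMES, ModelConstants, PriorSpec
from .inference import ABCConfig, InferenceError, PosteriorResult, ReferenceTable, estimate_posterior


@dataclass
class ValidationReport:
    """Per-parameter point errors and interval coverage over holdouts."""

    table: pd.DataFrame  # index PARAM_NAMES; columns mae, mse, rmse, coverage
    n_holdout: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def holdout_validate(
    reference: ReferenceTable,
    n_holdout: int,
    cfg: ABCConfig | None = None,
    seed: int = 0,
    prior: PriorSpec | None = None,
    constants: ModelConstants | None = None,
    estimator=None,
) -> ValidationReport:
    """Leave-out pseudo-observed evaluation of the posterior estimator.

    ``estimator(reference, observed, cfg, prior, constants)`` may be
    injected for testing; it must return a :class:`PosteriorResult`.
    """
    cfg = cfg or ABCConfig()
    prior = prior or PriorSpec()
    n = len(reference)
    if not 0 < n_holdout < n:
        raise InferenceError(f"n_holdout must be in (0, {n}), got {n_holdout}")
    estimator = estimator or estimate_posterior
    rng = np.random.default_rng(seed)
    rows = rng.choice(n, size=n_holdout, replace=False)

    truths = np.empty((n_holdout, len(PARAM_NAMES)))
    medians = np.empty_like(truths)
    covered = np.zeros_like(truths, dtype=bool)
    for k, row in enumerate(rows):
        observed = reference.stats.iloc[row].to_dict()
        truth = reference.params.iloc[row]
        sub = reference.drop_rows([row])
        post: PosteriorResult = estimator(sub, observed, cfg, prior, constants)
        for j, name in enumerate(PARAM_NAMES):
            truths[k, j] = truth[name]
            medians[k, j] = post.summary.loc[name, "median"]
            covered[k, j] = (
                post.summary.loc[name, "q2.5"] <= truth[name] <= post.summary.loc[name, "q97.5"]
            )

    err = medians - truths
    table = pd.DataFrame(
        {
            "mae": np.abs(err).mean(axis=0),
            "mse": (err**2).mean(axis=0),
            "rmse": np.sqrt((err**2).mean(axis=0)),
            "coverage": covered.mean(axis=0),
        },
        index=list(PARAM_NAMES),
    )
    return ValidationReport(table, n_holdout)


def compare_tolerances(
    reference: ReferenceTable,
    tolerances,
    methods,
    n_holdout: int,
    seed: int = 0,
    base_cfg: ABCConfig | None = None,
    prior: PriorSpec | None = None,
    constants: ModelConstants | None = None,
) -> pd.DataFrame:
    """Grid of holdout errors over (tolerance, method) settings.

    Replays the model-selection step that picks the tolerance/architecture
    minimising average prediction error.  The same holdout rows (same seed)
    are used for every setting so rows are comparable.  Columns carry the
    per-parameter MAE plus ``mean_prediction_error``, the mean over
    parameters of MAE scaled by the prior's interquartile range so that
    parameters of different magnitudes contribute comparably.
    """
    if not tolerances or not methods:
        raise InferenceError("at least one tolerance and one method required")
    base_cfg = base_cfg or ABCConfig()
    prior = prior or PriorSpec()
    iqr = reference.params.quantile(0.75) - reference.params.quantile(0.25)
    records = []
    for tol in tolerances:
        for method in methods:
            cfg = ABCConfig(
                tolerance=tol, method=method, hidden_units=base_cfg.hidden_units,
                n_restarts=base_cfg.n_restarts, weight_decay=base_cfg.weight_decay,
                seed=base_cfg.seed,
            )
            report = holdout_validate(
                reference, n_holdout, cfg, seed=seed, prior=prior, constants=constants
            )
            rec = {"tolerance": tol, "method": method}
            for name in PARAM_NAMES:
                rec[f"mae_{name}"] = report.table.loc[name, "mae"]
            rec["mean_prediction_error"] = float(
                np.mean([report.table.loc[n, "mae"] / iqr[n] for n in PARAM_NAMES])
            )
            records.append(rec)
    return pd.DataFrame.from_records(records)
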