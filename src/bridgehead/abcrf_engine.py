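"""Random-forest ABC: model choice and parameter estimation.

Model choice trains a classification random forest on a reference table
of (model label, summary statistics) rows.  For an observed statistic
vector, each tree casts one vote; the selected model is the vote argmax.
The posterior probability of the selected model is approximated the way
the abcrf methodology prescribes: a regression forest is trained on the
out-of-bag (OOB) indicator "this training row was classified correctly"
against the summary statistics, and evaluated at the observed vector.
The OOB predictions also yield the confusion matrix, per-model
classification error (row-wise recall complement), per-model precision
(column-conditional), and the prior error rate.

Parameter estimation trains one regression forest per parameter on
simulations from the selected scenario and reads posterior medians and
quantiles from the forest's terminal-node weights: training rows that
share leaves with the observed vector receive weight, and weighted
empirical quantiles of the parameter draws approximate the posterior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .popgen_stats import StatCatalogue, SummaryStatVector
from .scenarios import PriorSpec, Scenario

log = logging.getLogger(__name__)

__all__ = [
    "TrainedForest",
    "ModelChoiceResult",
    "ParameterPosterior",
    "train_classifier",
    "classify",
    "oob_confusion",
    "regression_posterior",
    "estimate_params",
]


@dataclass
class TrainedForest:
    """A fitted classification forest plus its training bookkeeping."""

    clf: RandomForestClassifier
    stat_names: list[str]  # full training manifest (pre-drop)
    feature_names: list[str]  # columns actually used
    models: list[str]
    x: np.ndarray
    y: np.ndarray
    oob_pred: np.ndarray
    seed: int

    @property
    def n_trees(self) -> int:
        return self.clf.n_estimators


@dataclass
class ModelChoiceResult:
    """Votes, selected model, posterior probability, and OOB diagnostics."""

    votes: dict[str, int]
    selected_model: str
    posterior_probability: float
    oob_confusion: pd.DataFrame  # rows = simulated model, cols = classified
    per_model_error: pd.Series
    per_model_precision: pd.Series
    prior_error_rate: float
    n_trees: int


def _stat_columns(table: pd.DataFrame) -> list[str]:
    return [
        c for c in table.columns if c != "model" and not c.startswith("par_")
    ]


def train_classifier(
    table: pd.DataFrame, n_trees: int = 1000, seed: int = 0
) -> TrainedForest:
    """Fit a classification forest on a reference table.

    ``table`` needs a ``model`` column and summary-statistic columns
    (anything not named ``model``/``par_*``).  Constant or non-finite
    statistic columns are dropped with a warning.  OOB predictions are
    recorded per training row; rows that were in every bootstrap sample
    (possible with few trees) fall back to the forest's full prediction.
    """
    stat_names = _stat_columns(table)
    models = sorted(table["model"].unique())
    if len(models) < 2:
        raise ValueError("model choice requires at least 2 candidate models")
    counts = table["model"].value_counts()
    if counts.min() < 50:
        warnings.warn(
            f"fewer than 50 rows for model(s) {list(counts[counts < 50].index)}; "
            "OOB estimates will be noisy"
        )
    x_full = table[stat_names].to_numpy(dtype=np.float64)
    keep = []
    for j, name in enumerate(stat_names):
        col = x_full[:, j]
        if not np.all(np.isfinite(col)):
            warnings.warn(f"dropping non-finite statistic column {name!r}")
        elif np.all(col == col[0]):
            warnings.warn(f"dropping constant statistic column {name!r}")
        else:
            keep.append(j)
    if not keep:
        raise ValueError("no usable statistic columns")
    feature_names = [stat_names[j] for j in keep]
    x = x_full[:, keep]
    y = table["model"].to_numpy()
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # "some inputs do not have OOB"
        clf.fit(x, y)
    oob_df = clf.oob_decision_function_
    oob_pred = np.empty(len(y), dtype=object)
    has_oob = ~np.isnan(oob_df).any(axis=1) & (oob_df.sum(axis=1) > 0)
    oob_pred[has_oob] = clf.classes_[np.argmax(oob_df[has_oob], axis=1)]
    if (~has_oob).any():
        oob_pred[~has_oob] = clf.predict(x[~has_oob])
    return TrainedForest(
        clf=clf,
        stat_names=stat_names,
        feature_names=feature_names,
        models=[str(m) for m in clf.classes_],
        x=x,
        y=y,
        oob_pred=oob_pred.astype(str),
        seed=seed,
    )


def oob_confusion(
    forest: TrainedForest,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, float]:
    """OOB confusion matrix, per-model error, precision, prior error rate.

    Rows are the true (simulated) models, columns the classified models;
    row sums equal the per-model simulation counts.  ``error`` is
    1 - diagonal/row-sum; ``precision`` is the column-conditional
    probability that a dataset classified as X truly originated from X.
    """
    models = forest.models
    conf = pd.DataFrame(0, index=models, columns=models, dtype=np.int64)
    for true, pred in zip(forest.y, forest.oob_pred):
        conf.loc[true, pred] += 1
    diag = pd.Series(np.diag(conf.to_numpy()), index=models, dtype=np.float64)
    row_sums = conf.sum(axis=1)
    col_sums = conf.sum(axis=0)
    error = 1.0 - diag / row_sums.replace(0, np.nan)
    precision = (diag / col_sums.replace(0, np.nan)).fillna(0.0)
    prior_error_rate = float(1.0 - diag.sum() / conf.to_numpy().sum())
    return conf, error, precision, prior_error_rate


def _observed_row(forest: TrainedForest, observed: SummaryStatVector) -> np.ndarray:
    missing = [n for n in forest.stat_names if n not in observed.names]
    extra = [n for n in observed.names if n not in forest.stat_names]
    if missing or extra:
        raise ValueError(
            "observed statistics do not match the training manifest; "
            f"missing: {missing}; extra: {extra}"
        )
    series = observed.to_series()
    return series.loc[forest.feature_names].to_numpy(dtype=np.float64)[None, :]


def classify(
    forest: TrainedForest,
    observed: SummaryStatVector,
    with_posterior: bool = True,
) -> ModelChoiceResult:
    """Vote tally, model selection and posterior probability for one query.

    Votes are per-tree predicted labels (summing to the tree count); the
    selected model is the vote argmax with lexicographic tie-break.  The
    posterior probability regresses the OOB correct-classification
    indicator on the summary statistics and evaluates at the observation;
    ``with_posterior=False`` skips that (costly) regression and reports
    NaN, for vote-only workflows.
    """
    x_obs = _observed_row(forest, observed)
    tree_votes = np.array(
        [
            forest.clf.classes_[int(tree.predict(x_obs)[0])]
            for tree in forest.clf.estimators_
        ]
    )
    votes = {m: int((tree_votes == m).sum()) for m in forest.models}
    top = max(votes.values())
    winners = sorted(m for m, v in votes.items() if v == top)
    if len(winners) > 1:
        warnings.warn(f"vote tie among {winners}; selecting {winners[0]}")
    selected = winners[0]
    if with_posterior:
        correct = (forest.oob_pred == forest.y).astype(np.float64)
        reg = RandomForestRegressor(
            n_estimators=forest.n_trees,
            max_features="sqrt",
            random_state=forest.seed + 1,
            n_jobs=1,
        )
        reg.fit(forest.x, correct)
        posterior = float(np.clip(reg.predict(x_obs)[0], 0.0, 1.0))
    else:
        posterior = float("nan")
    conf, error, precision, prior_error = oob_confusion(forest)
    return ModelChoiceResult(
        votes=votes,
        selected_model=selected,
        posterior_probability=posterior,
        oob_confusion=conf,
        per_model_error=error,
        per_model_precision=precision,
        prior_error_rate=prior_error,
        n_trees=forest.n_trees,
    )


# ---------------------------------------------------------------------------
# Parameter estimation


@dataclass
class ParameterPosterior:
    """Posterior median and 0.05/0.95 quantiles per parameter."""

    table: pd.DataFrame  # index = parameter, columns = median, q05, q95
    not_estimable: list[str]

    def __getitem__(self, param: str) -> tuple[float, float, float]:
        row = self.table.loc[param]
        return float(row["q05"]), float(row["median"]), float(row["q95"])


def _weighted_quantile(
    values: np.ndarray, weights: np.ndarray, qs: tuple[float, ...]
) -> np.ndarray:
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    return np.array([v[np.searchsorted(cw, q, side="left")] for q in qs])


def regression_posterior(
    x: np.ndarray,
    y: np.ndarray,
    x_obs: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    quantiles: tuple[float, float, float] = (0.05, 0.5, 0.95),
) -> tuple[float, float, float]:
    """Posterior quantiles of one parameter from a regression forest.

    Training rows are weighted by how often they share a terminal node
    with the observed vector across trees (each leaf's occupants share
    its unit weight); quantiles are read from the weighted empirical
    distribution of the training parameter values.
    """
    reg = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, x.shape[1] // 3),
        min_samples_leaf=5,
        random_state=seed,
        n_jobs=1,
    )
    reg.fit(x, y)
    train_leaves = reg.apply(x)  # (n_rows, n_trees)
    obs_leaves = reg.apply(np.atleast_2d(x_obs))[0]  # (n_trees,)
    weights = np.zeros(x.shape[0])
    for t in range(train_leaves.shape[1]):
        in_leaf = train_leaves[:, t] == obs_leaves[t]
        n_in = in_leaf.sum()
        if n_in:
            weights[in_leaf] += 1.0 / n_in
    if weights.sum() == 0:
        weights[:] = 1.0
    q05, med, q95 = _weighted_quantile(y, weights, quantiles)
    return float(q05), float(med), float(q95)


def estimate_params(
    best_scenario: Scenario,
    prior: PriorSpec,
    observed: SummaryStatVector,
    sample_config,
    seed: int,
    n_sims: int = 5000,
    n_trees: int = 500,
    missing_profile: float | dict[str, float] = 0.0,
    catalogue: StatCatalogue | None = None,
    regional_groups: dict[str, tuple[str, ...]] | None = None,
    table: pd.DataFrame | None = None,
) -> ParameterPosterior:
    """Posterior quantiles for every parameter of the selected scenario.

    Simulates ``n_sims`` datasets under the scenario's prior (or reuses a
    provided reference table) and runs one quantile regression forest per
    parameter.  Parameters constant under the prior are flagged as not
    estimable rather than regressed.
    """
    from .coalsim import reference_table as _reference_table

    if table is None:
        table = _reference_table(
            best_scenario,
            prior,
            n_sims,
            sample_config,
            seed,
            missing_profile=missing_profile,
            catalogue=catalogue,
            regional_groups=regional_groups,
        )
    stat_names = [
        c for c in table.columns if c != "model" and not c.startswith("par_")
    ]
    par_names = [c for c in table.columns if c.startswith("par_")]
    x_full = table[stat_names].to_numpy(dtype=np.float64)
    usable = [
        j
        for j in range(x_full.shape[1])
        if np.all(np.isfinite(x_full[:, j])) and not np.all(x_full[:, j] == x_full[0, j])
    ]
    x = x_full[:, usable]
    obs_series = observed.to_series()
    x_obs = obs_series.loc[[stat_names[j] for j in usable]].to_numpy(np.float64)
    rows = {}
    not_estimable = []
    for i, par in enumerate(par_names):
        y = table[par].to_numpy(dtype=np.float64)
        if np.all(y == y[0]):
            not_estimable.append(par)
            log.warning("parameter %s constant under the prior; not estimable", par)
            continue
        q05, med, q95 = regression_posterior(
            x, y, x_obs, n_trees=n_trees, seed=seed + 1000 + i
        )
        rows[par] = {"median": med, "q05": q05, "q95": q95}
    return ParameterPosterior(
        table=pd.DataFrame(rows).T[["median", "q05", "q95"]],
        not_estimable=not_estimable,
    )
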