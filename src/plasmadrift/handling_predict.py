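"""Random-forest prediction of sample handling conditions under repeated
double cross-validation (rdCV) with recursive, unbiased variable selection.

Temperature is a two-class problem (4 vs 22 degC), delay time a regression
problem fitted per temperature.  Model tuning — here, the number of retained
variables — happens strictly inside inner cross-validation loops; the outer
folds only ever score models they never influenced, so the cross-validated
performance is an unbiased generalization estimate.  The whole scheme is
repeated over independent random partitions and the outer-fold predictions
are averaged per sample.  Significance of the observed fitness is assessed
by refitting the entire procedure on permuted outcomes.

Repeated measures per subject are handled by keeping all samples of one
subject inside the same fold (on by default whenever subject ids are given);
otherwise subject-specific metabolome levels leak between training and
validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .dataio import FeatureTable


class PredictError(ValueError):
    pass


@dataclass
class RdCvConfig:
    """Hyperparameters of the repeated double cross-validation scheme.

    n_rep:
        Number of independent repetitions of the double CV.
    n_outer, n_inner:
        Outer/inner fold counts; inner defaults to ``n_outer - 1``.
        Partitions are stratified by class (classification) or by outcome
        quantile (regression).
    var_ratio:
        Fraction of variables kept per recursive-elimination step; variables
        are ranked by forest importance within each inner training fold and
        pruned until 2 remain.
    n_trees:
        Trees per forest for the outer-fold prediction models and the final
        refit ensembles.
    n_trees_inner:
        Trees per forest inside the inner variable-elimination loops (they
        only rank variables and compare variable counts); defaults to
        ``n_trees``.
    fitness:
        ``'misclassification'`` (count, classification) or ``'rmsep'``
        (regression); ``None`` picks the task default.
    """

    n_rep: int = 20
    n_outer: int = 6
    n_inner: int | None = None
    var_ratio: float = 0.75
    n_trees: int = 500
    n_trees_inner: int | None = None
    fitness: str | None = None
    seed: int = 0
    group_aware: bool = True

    def __post_init__(self) -> None:
        if self.n_outer < 2:
            raise ValueError("n_outer must be >= 2")
        if self.n_inner is None:
            self.n_inner = self.n_outer - 1
        if self.n_inner < 2:
            raise ValueError("n_inner must be >= 2")
        if not (0 < self.var_ratio < 1):
            raise ValueError("var_ratio must lie in (0, 1)")
        if self.n_trees_inner is None:
            self.n_trees_inner = self.n_trees

    def to_dict(self) -> dict:
        return {
            "n_rep": self.n_rep,
            "n_outer": self.n_outer,
            "n_inner": self.n_inner,
            "var_ratio": self.var_ratio,
            "n_trees": self.n_trees,
            "n_trees_inner": self.n_trees_inner,
            "fitness": self.fitness,
            "seed": self.seed,
            "group_aware": self.group_aware,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RdCvConfig":
        return cls(**d)


@dataclass
class PredictionModel:
    """Fitted rdCV random-forest model.

    ``per_sample_prediction`` holds strictly cross-validated predictions:
    the prediction for sample *i* is averaged over outer-fold models whose
    training folds never contained *i*.  ``selected_variables`` holds three
    consensus variable sets (minimal, middle and maximal size across the
    repetitions' optima); external prediction uses forests refit on the full
    training data at each consensus set (the middle one by default).
    """

    task: str  # 'classification' | 'regression'
    feature_ids: list[str]
    selected_variables: dict[str, list[str]]
    per_sample_prediction: pd.DataFrame | pd.Series
    performance: dict
    config: RdCvConfig
    classes_: list | None = None
    training_majority_class: object | None = None
    #: embedded training data; enables loss-free refit on deserialization
    _train_X: pd.DataFrame | None = field(default=None, repr=False)
    _train_y: np.ndarray | None = field(default=None, repr=False)
    _ensembles: dict = field(default_factory=dict, repr=False)
    #: per-sample feature medians of training data, for tolerant prediction
    _feature_medians: pd.Series | None = field(default=None, repr=False)

    @property
    def fitness_(self) -> float:
        """Scalar model fitness (lower is better) used by permutation tests."""
        if self.task == "classification":
            return float(self.performance["n_misclassified"])
        return float(self.performance["rmsep"])

    def to_dict(self) -> dict:
        if self._train_X is None:
            raise PredictError("model carries no training data; cannot serialize")
        if self.task == "classification":
            psp = {
                "index": list(self.per_sample_prediction.index),
                "columns": [_jsonable(c) for c in self.per_sample_prediction.columns],
                "values": self.per_sample_prediction.to_numpy().tolist(),
            }
        else:
            psp = {
                "index": list(self.per_sample_prediction.index),
                "values": self.per_sample_prediction.to_numpy().tolist(),
            }
        return {
            "task": self.task,
            "feature_ids": list(self.feature_ids),
            "selected_variables": {k: list(v) for k, v in self.selected_variables.items()},
            "per_sample_prediction": psp,
            "performance": self.performance,
            "config": self.config.to_dict(),
            "classes": None if self.classes_ is None else [_jsonable(c) for c in self.classes_],
            "training_majority_class": _jsonable(self.training_majority_class),
            "train_y": [_jsonable(v) for v in self._train_y],
            "train_X": {
                "index": list(self._train_X.index),
                "values": self._train_X.to_numpy().tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionModel":
        config = RdCvConfig.from_dict(d["config"])
        feature_ids = [str(f) for f in d["feature_ids"]]
        X = pd.DataFrame(
            np.asarray(d["train_X"]["values"], dtype=float),
            index=d["train_X"]["index"],
            columns=feature_ids,
        )
        task = d["task"]
        if task == "classification":
            y = np.asarray(d["train_y"])
            psp = pd.DataFrame(
                np.asarray(d["per_sample_prediction"]["values"], dtype=float),
                index=d["per_sample_prediction"]["index"],
                columns=d["per_sample_prediction"]["columns"],
            )
        else:
            y = np.asarray(d["train_y"], dtype=float)
            psp = pd.Series(
                np.asarray(d["per_sample_prediction"]["values"], dtype=float),
                index=d["per_sample_prediction"]["index"],
            )
        model = cls(
            task=task,
            feature_ids=feature_ids,
            selected_variables={k: [str(f) for f in v] for k, v in d["selected_variables"].items()},
            per_sample_prediction=psp,
            performance=dict(d["performance"]),
            config=config,
            classes_=d["classes"],
            training_majority_class=d["training_majority_class"],
            _train_X=X,
            _train_y=y,
            _feature_medians=X.median(axis=0),
        )
        model._ensembles = _fit_ensembles(X, y, model.selected_variables, task, config)
        return model


# -- fold assignment ----------------------------------------------------------

def _assign_folds(
    y: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
    task: str,
    groups: np.ndarray | None,
) -> np.ndarray:
    """Stratified (and optionally group-aware) fold labels in [0, n_folds)."""
    n = len(y)
    if groups is None:
        units = np.arange(n)
        unit_of = np.arange(n)
    else:
        units, unit_of = np.unique(np.asarray(groups), return_inverse=True)
        units = np.arange(len(units))
    fold_of_unit = np.empty(len(units), dtype=int)

    if task == "classification":
        # summarize each unit by its first class; shuffle within class and deal
        unit_class = np.empty(len(units), dtype=object)
        for u in units:
            labels, counts = np.unique(y[unit_of == u], return_counts=True)
            unit_class[u] = labels[np.argmax(counts)]
        offset = int(rng.integers(n_folds))
        for cls_ in pd.unique(pd.Series(unit_class)):
            members = np.flatnonzero(unit_class == cls_)
            rng.shuffle(members)
            for i, u in enumerate(members):
                fold_of_unit[u] = (i + offset) % n_folds
    else:
        # order units by outcome (jittered for ties), deal snake-wise: folds
        # end up stratified across outcome quantiles
        unit_y = np.array([float(np.mean(y[unit_of == u])) for u in units])
        order = np.argsort(unit_y + rng.normal(0, 1e-9, len(units)), kind="stable")
        snake = []
        fold_seq = list(range(n_folds))
        for block in range(0, len(order), n_folds):
            snake.extend(fold_seq if (block // n_folds) % 2 == 0 else fold_seq[::-1])
        perm_start = int(rng.integers(n_folds))
        for i, u in enumerate(order):
            fold_of_unit[u] = (snake[i] + perm_start) % n_folds
    folds = fold_of_unit[unit_of]
    for f in range(n_folds):
        if not np.any(folds == f):
            raise PredictError(
                f"empty cross-validation fold (n={n}, n_folds={n_folds})"
            )
    return folds


def _elimination_counts(p: int, ratio: float, floor: int = 2) -> list[int]:
    counts = [p]
    while counts[-1] > floor:
        nxt = min(counts[-1] - 1, int(np.ceil(ratio * counts[-1])))
        counts.append(max(nxt, floor))
    return counts


def _new_forest(task: str, n_trees: int, seed: int):
    # mtry: sqrt(p) for classification, p/3 for regression (the conventional
    # random-forest defaults for each task)
    if task == "classification":
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )
    return RandomForestRegressor(
        n_estimators=n_trees, max_features=1 / 3, random_state=seed, n_jobs=1
    )


def _fold_fitness(task: str, model, Xva: np.ndarray, yva: np.ndarray) -> float:
    pred = model.predict(Xva)
    if task == "classification":
        return float(np.sum(pred != yva))
    return float(np.sqrt(np.mean((pred - yva) ** 2)))


# -- the rdCV engine ----------------------------------------------------------

def rdcv_fit(
    table: FeatureTable | pd.DataFrame,
    outcome: Sequence,
    config: RdCvConfig | None = None,
    groups: Sequence | None = None,
) -> PredictionModel:
    """Fit a random-forest model in repeated double cross-validation.

    Parameters
    ----------
    table:
        Samples x features predictors.
    outcome:
        Class labels (classification) or real hours (regression); the task is
        inferred from the dtype (non-numeric or <= 5 distinct numeric values
        with ``fitness='misclassification'`` force classification; pass
        temperatures as strings or set ``fitness`` explicitly when ambiguous).
    groups:
        Optional per-sample group ids (subject ids); all samples of a group
        stay in the same fold when ``config.group_aware`` is set.
    """
    config = config or RdCvConfig()
    X = table.data if isinstance(table, FeatureTable) else pd.DataFrame(table)
    X = X.rename(columns=str)
    y = np.asarray(outcome)
    if len(y) != len(X):
        raise PredictError("outcome length does not match sample count")
    task = _infer_task(y, config)
    if task == "regression":
        y = y.astype(float)
        if np.var(y) == 0:
            raise PredictError("degenerate outcome: zero-variance response")
        if len(np.unique(y)) < config.n_outer:
            raise PredictError(
                "degenerate outcome: fewer distinct values than outer folds"
            )
    else:
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise PredictError("degenerate outcome: single class")
        if counts.min() < config.n_outer:
            raise PredictError(
                f"class with {counts.min()} members cannot fill {config.n_outer} outer folds"
            )
    g = None
    if groups is not None and config.group_aware:
        g = np.asarray(groups)
        if len(g) != len(y):
            raise PredictError("groups length does not match sample count")

    p = X.shape[1]
    counts_seq = _elimination_counts(p, config.var_ratio)
    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5D])
    rep_seeds = ss.spawn(config.n_rep)
    Xv = X.to_numpy(dtype=float)

    n = len(y)
    best_counts: list[int] = []
    global_rank_sum = np.zeros(p)
    global_rank_n = 0
    if task == "classification":
        classes = np.unique(y)
        vote_sum = np.zeros((n, len(classes)))
        vote_n = np.zeros(n)
    else:
        pred_sum = np.zeros(n)
        pred_n = np.zeros(n)

    for rep, rep_ss in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_ss)
        outer = _assign_folds(y, config.n_outer, rng, task, g)
        for fold in range(config.n_outer):
            te = np.flatnonzero(outer == fold)
            tr = np.flatnonzero(outer != fold)
            sel, j_best, rank0 = _inner_select(
                Xv[tr], y[tr], None if g is None else g[tr],
                config, counts_seq, rng, task,
            )
            global_rank_sum += rank0
            global_rank_n += 1
            best_counts.append(len(sel))
            rf = _new_forest(task, config.n_trees, int(rng.integers(2**31)))
            rf.fit(Xv[np.ix_(tr, sel)], y[tr])
            if task == "classification":
                proba = rf.predict_proba(Xv[np.ix_(te, sel)])
                aligned = np.zeros((len(te), len(classes)))
                for ci, c in enumerate(rf.classes_):
                    aligned[:, np.flatnonzero(classes == c)[0]] = proba[:, ci]
                vote_sum[te] += aligned
                vote_n[te] += 1
            else:
                pred_sum[te] += rf.predict(Xv[np.ix_(te, sel)])
                pred_n[te] += 1

    # consensus variable counts across (rep x outer) optima
    bc = np.asarray(best_counts)
    n_min = int(bc.min())
    n_max = int(bc.max())
    n_mid = int(np.clip(round(float(np.exp(np.mean(np.log(bc))))), n_min, n_max))
    ranking = np.argsort(global_rank_sum, kind="stable")  # low rank sum = best
    fids = [str(c) for c in X.columns]
    selected = {
        "min": [fids[i] for i in ranking[:n_min]],
        "mid": [fids[i] for i in ranking[:n_mid]],
        "max": [fids[i] for i in ranking[:n_max]],
    }

    if task == "classification":
        votes = vote_sum / vote_n[:, None]
        psp = pd.DataFrame(votes, index=X.index, columns=list(classes))
        maj = classes[np.argmax([np.sum(y == c) for c in classes])]
        pred_class = _vote_to_class(votes, classes, maj)
        n_mis = int(np.sum(pred_class != y))
        performance = {
            "n_misclassified": n_mis,
            "misclass_rate": n_mis / n,
            "accuracy": 1 - n_mis / n,
        }
        classes_list, majority = list(classes), maj
    else:
        cv_pred = pred_sum / pred_n
        psp = pd.Series(cv_pred, index=X.index, name="predicted_h")
        press = float(np.sum((cv_pred - y) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        performance = {
            "q2": 1 - press / tss,
            "rmsep": float(np.sqrt(press / n)),
        }
        classes_list, majority = None, None

    model = PredictionModel(
        task=task,
        feature_ids=fids,
        selected_variables=selected,
        per_sample_prediction=psp,
        performance=performance,
        config=config,
        classes_=classes_list,
        training_majority_class=majority,
        _train_X=X.astype(float),
        _train_y=y,
        _feature_medians=X.median(axis=0),
    )
    model._ensembles = _fit_ensembles(model._train_X, y, selected, task, config)
    if task == "regression":
        fit_pred = model._ensembles["mid"][1].predict(
            model._train_X[model.selected_variables["mid"]].to_numpy()
        )
        rss = float(np.sum((fit_pred - y) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        model.performance["r2"] = 1 - rss / tss
    return model


def _infer_task(y: np.ndarray, config: RdCvConfig) -> str:
    if config.fitness == "misclassification":
        return "classification"
    if config.fitness == "rmsep":
        return "regression"
    return "regression" if np.issubdtype(y.dtype, np.number) else "classification"


def _inner_select(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None,
    config: RdCvConfig,
    counts_seq: list[int],
    rng: np.random.Generator,
    task: str,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Recursive variable elimination inside an inner CV loop.

    Per inner fold, forests are fit along a shared schedule of decreasing
    variable counts; each step keeps the top fraction by that fold's own
    importance ranking.  The variable count minimizing the mean held-out
    fitness wins (ties toward fewer variables) and the returned consensus set
    aggregates per-fold rankings at the winning step.  Also returns the
    full-width (step 0) mean importance ranks for global variable ranking.
    """
    p = X.shape[1]
    n_steps = len(counts_seq)
    folds = _assign_folds(y, config.n_inner, rng, task, groups)
    fitness = np.zeros((config.n_inner, n_steps))
    # rank matrix at the selected step: p+1 penalty for inactive variables
    step_ranks = np.full((config.n_inner, n_steps, p), p + 1.0)
    for i in range(config.n_inner):
        va = np.flatnonzero(folds == i)
        tr = np.flatnonzero(folds != i)
        active = np.arange(p)
        order_in_active: np.ndarray | None = None
        for j, c in enumerate(counts_seq):
            if len(active) > c:
                active = active[order_in_active[:c]]
            rf = _new_forest(task, config.n_trees_inner, int(rng.integers(2**31)))
            rf.fit(X[np.ix_(tr, active)], y[tr])
            fitness[i, j] = _fold_fitness(task, rf, X[np.ix_(va, active)], y[va])
            order_in_active = np.argsort(-rf.feature_importances_, kind="stable")
            step_ranks[i, j, active[order_in_active]] = np.arange(1, len(active) + 1)

    mean_fit = fitness.mean(axis=0)
    j_best = int(np.flatnonzero(mean_fit == mean_fit.min())[-1])  # fewest vars on tie
    rank_score = step_ranks[:, j_best, :].sum(axis=0)
    sel = np.argsort(rank_score, kind="stable")[: counts_seq[j_best]]
    rank0 = step_ranks[:, 0, :].mean(axis=0)
    return np.sort(sel), j_best, rank0


def _fit_ensembles(
    X: pd.DataFrame,
    y: np.ndarray,
    selected: dict[str, list[str]],
    task: str,
    config: RdCvConfig,
) -> dict:
    """Refit one forest per consensus variable set on the full training data.

    Seeds derive only from the config seed and the set name, so refitting on
    deserialization reproduces the forests exactly.
    """
    ensembles = {}
    for idx, key in enumerate(("min", "mid", "max")):
        ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0xF1, idx])
        seed = int(np.random.default_rng(ss).integers(2**31))
        cols = selected[key]
        rf = _new_forest(task, config.n_trees, seed)
        rf.fit(X[cols].to_numpy(dtype=float), y)
        ensembles[key] = (cols, rf)
    return ensembles


def _vote_to_class(votes: np.ndarray, classes: np.ndarray, majority) -> np.ndarray:
    """Majority vote; exact ties resolve toward the training-majority class."""
    out = np.empty(len(votes), dtype=classes.dtype)
    maj_idx = int(np.flatnonzero(classes == majority)[0])
    for i, row in enumerate(votes):
        top = np.flatnonzero(row == row.max())
        out[i] = classes[maj_idx] if maj_idx in top else classes[top[0]]
    return out


def rdcv_predict(
    model: PredictionModel,
    table: FeatureTable | pd.DataFrame,
    which: str = "mid",
    missing_tolerance: float = 0.05,
) -> np.ndarray:
    """Predict new samples with a consensus ensemble (``'mid'`` by default).

    Missing required variables up to ``missing_tolerance`` (as a fraction of
    the consensus set) are imputed with training medians; beyond that the
    prediction refuses to run.
    """
    if which not in model._ensembles:
        raise PredictError(f"no fitted ensemble {which!r}")
    X = table.data if isinstance(table, FeatureTable) else pd.DataFrame(table)
    cols, rf = model._ensembles[which]
    missing = [c for c in cols if c not in X.columns]
    if len(missing) > missing_tolerance * len(cols):
        raise PredictError(
            f"{len(missing)}/{len(cols)} required variables missing: {missing[:5]}"
        )
    Xa = X.reindex(columns=cols)
    if missing:
        warnings.warn(
            f"imputing {len(missing)} missing variable(s) with training medians",
            stacklevel=2,
        )
        for c in missing:
            Xa[c] = model._feature_medians[c]
    vals = Xa.to_numpy(dtype=float)
    if vals.shape[0] > 1 and np.all(vals.std(axis=0) == 0):
        warnings.warn("all predictor columns constant across samples", stacklevel=2)
    if model.task == "classification":
        proba = rf.predict_proba(vals)
        classes = np.asarray(model.classes_)
        aligned = np.zeros((len(vals), len(classes)))
        for ci, c in enumerate(rf.classes_):
            aligned[:, np.flatnonzero(classes == c)[0]] = proba[:, ci]
        return _vote_to_class(aligned, classes, model.training_majority_class)
    return rf.predict(vals)


# -- permutation analysis -----------------------------------------------------

@dataclass
class PermutationResult:
    """Null distribution of model fitness under permuted outcomes.

    ``p_empirical = (#{null at least as good as observed} + 1) / (n_perm + 1)``
    is bounded below by ``1/(n_perm + 1)``; ``p_parametric`` is the one-sided
    tail probability of the observed fitness under a Student-t distribution
    fitted to the null values, which can resolve far smaller p-values than
    the permutation count allows.
    """

    n_perm: int
    null_values: np.ndarray
    observed: float
    p_empirical: float
    p_parametric: float


def permutation_test(
    table: FeatureTable | pd.DataFrame,
    outcome: Sequence,
    config: RdCvConfig | None = None,
    n_perm: int = 100,
    perm_n_rep: int | None = 5,
    groups: Sequence | None = None,
) -> PermutationResult:
    """Assess model significance by refitting on permuted outcomes.

    Each permutation reruns the full rdCV procedure, optionally with a
    reduced repetition count ``perm_n_rep`` (None keeps the main model's);
    fitness is misclassification count or RMSEP, lower better.
    """
    if n_perm < 2:
        raise PredictError("n_perm must be >= 2")
    config = config or RdCvConfig()
    observed_model = rdcv_fit(table, outcome, config, groups=groups)
    observed = observed_model.fitness_

    perm_config = config if perm_n_rep is None else replace(
        config, n_rep=min(perm_n_rep, config.n_rep)
    )
    y = np.asarray(outcome)
    null_values = np.empty(n_perm)
    for i in range(n_perm):
        ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x9E, i])
        rng = np.random.default_rng(ss)
        y_perm = rng.permutation(y)
        pc = replace(perm_config, seed=int(rng.integers(2**31)))
        try:
            null_model = rdcv_fit(table, y_perm, pc, groups=groups)
            null_values[i] = null_model.fitness_
        except PredictError:
            null_values[i] = np.nan
    valid = null_values[np.isfinite(null_values)]
    if len(valid) < 2:
        raise PredictError("too few successful permutations")
    p_emp = (np.sum(valid <= observed) + 1) / (len(valid) + 1)
    if np.std(valid) == 0:
        p_par = 1.0 if observed >= valid[0] else 0.0
    else:
        df_, loc, scale = stats.t.fit(valid)
        p_par = float(stats.t.cdf(observed, df_, loc=loc, scale=scale))
    return PermutationResult(
        n_perm=len(valid),
        null_values=null_values,
        observed=observed,
        p_empirical=float(p_emp),
        p_parametric=p_par,
    )


def _jsonable(v):
    if v is None:
        return None
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
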