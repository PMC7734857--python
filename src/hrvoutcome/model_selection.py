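"""Outcome models and genetic-algorithm feature selection.

The unit of analysis is a cohort of ICU patients, each carrying a binary
discharge outcome (survivor / non-survivor), optional illness-severity
scores (APACHE II, APACHE III, SAPS — opaque numeric covariates here),
a per-epoch HRV feature table and a sliding-window distance-feature
table.  Rows of the design matrix are (patient, time point) pairs; the
classifier is a ridge-stabilised logistic regression fitted by Newton /
iteratively-reweighted least squares.

Cross-validation is patient-grouped and mirrors the study protocol:
five repeats of five folds, each test fold holding one non-survivor and
20% of the survivors with five randomly drawn time points per test
patient (25 test rows for the default cohort).  By default *all* rows of
test patients are excluded from training to prevent within-patient
leakage; ``paper_literal=True`` keeps the test patients' unselected time
points in the training data.

Feature-subset search is a binary-chromosome genetic algorithm whose
fitness is the cross-validated Youden index (sensitivity + specificity −
1 at the 0.5 probability cutoff), averaged over folds.  Repeated runs
vote on features; the final set is those selected in more than a
threshold fraction of runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .distance_features import DIST_PREFIX
from .hrv_features import FEATURE_NAMES

__all__ = [
    "SEVERITY_NAMES",
    "Patient",
    "CohortDataset",
    "CVScheme",
    "Fold",
    "GAConfig",
    "FittedClassifier",
    "SelectionResult",
    "build_design_matrix",
    "fit_logistic",
    "predict_prob",
    "make_folds",
    "training_rows",
    "youden_fitness",
    "ga_select",
]

logger = logging.getLogger(__name__)

#: Severity-score covariate names accepted by the design-matrix builder.
SEVERITY_NAMES = ("APACHE_II", "APACHE_III", "SAPS")

#: Outcome coding: the positive class is non-survival.
NON_SURVIVOR, SURVIVOR = 1, 0


@dataclass
class Patient:
    """One patient's label, severity scores and feature tables."""

    patient_id: str
    label: int  # 1 = non-survivor (positive class), 0 = survivor
    scores: dict[str, float] = field(default_factory=dict)
    features: pd.DataFrame | None = None
    distf: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.label not in (SURVIVOR, NON_SURVIVOR):
            raise ValueError("label must be 0 (survivor) or 1 (non-survivor)")


@dataclass
class CohortDataset:
    """The patient collection that the cross-validation scheme splits."""

    patients: list[Patient]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")
        self._by_id = {p.patient_id: p for p in self.patients}

    def __len__(self) -> int:
        return len(self.patients)

    def get(self, patient_id: str) -> Patient:
        return self._by_id[patient_id]

    @property
    def survivor_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients if p.label == SURVIVOR]

    @property
    def non_survivor_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients if p.label == NON_SURVIVOR]

    def valid_time_points(self, patient_id: str) -> list[int]:
        """Time points with a complete distance row and complete HRV row.

        These are the rows eligible for model building and for test-row
        sampling; validity is feature-set-agnostic so that identical
        folds can be reused across all compared models.
        """
        p = self.get(patient_id)
        if p.distf is None or p.features is None:
            return []
        dist_cols = [c for c in p.distf.columns if c.startswith(DIST_PREFIX)]
        feat = p.features.set_index("time_point")
        ok = []
        for _, row in p.distf.iterrows():
            tp = int(row["time_point"])
            if not np.all(np.isfinite(row[dist_cols].to_numpy(dtype=float))):
                continue
            if tp not in feat.index:
                continue
            if not np.all(np.isfinite(feat.loc[tp, list(FEATURE_NAMES)].to_numpy(dtype=float))):
                continue
            ok.append(tp)
        return ok

    def all_valid_rows(self) -> list[tuple[str, int]]:
        return [(p.patient_id, tp) for p in self.patients
                for tp in self.valid_time_points(p.patient_id)]


@dataclass(frozen=True)
class CVScheme:
    """Repeated, patient-grouped five-fold protocol of the analysis."""

    n_folds: int = 5
    n_repeats: int = 5
    time_points_per_patient: int = 5
    survivor_test_fraction: float = 0.2
    rng_seed: int = 0


@dataclass(frozen=True)
class Fold:
    """One evaluation cell: test patients and their sampled test rows."""

    repeat: int
    index: int
    test_patients: tuple[str, ...]
    test_rows: tuple[tuple[str, int], ...]

    def fingerprint(self) -> int:
        return hash((self.repeat, self.index, self.test_rows))


def _resolve_value(patient: Patient, tp: int, name: str,
                   feat_index: pd.DataFrame, dist_index: pd.DataFrame) -> float:
    if name in FEATURE_NAMES:
        if tp not in feat_index.index:
            raise ValueError(f"time point {tp} not available for patient {patient.patient_id}")
        return float(feat_index.at[tp, name])
    if name.startswith(DIST_PREFIX) and name[len(DIST_PREFIX):] in FEATURE_NAMES:
        if dist_index is None or tp not in dist_index.index:
            raise ValueError(f"time point {tp} has no distance window for patient {patient.patient_id}")
        return float(dist_index.at[tp, name])
    if name in SEVERITY_NAMES:
        if name not in patient.scores:
            raise ValueError(f"patient {patient.patient_id} has no {name} score")
        return float(patient.scores[name])
    valid = list(FEATURE_NAMES) + [DIST_PREFIX + f for f in FEATURE_NAMES] + list(SEVERITY_NAMES)
    raise ValueError(f"unknown feature {name!r}; valid names are {valid}")


def build_design_matrix(
    dataset: CohortDataset,
    feature_names: Sequence[str],
    rows: Sequence[tuple[str, int]],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, patient_ids) for the given (patient, time point) rows.

    Plain HRV parameters are taken at the row's time point, distance
    features at the same time-point index (the window starting there) and
    severity scores are constant within a patient.  Any missing value or
    unknown feature name raises.
    """
    feature_names = list(feature_names)
    if not feature_names:
        raise ValueError("feature set must be non-empty")
    feat_cache: dict[str, pd.DataFrame] = {}
    dist_cache: dict[str, pd.DataFrame] = {}
    X = np.empty((len(rows), len(feature_names)), dtype=float)
    y = np.empty(len(rows), dtype=int)
    pids: list[str] = []
    for i, (pid, tp) in enumerate(rows):
        p = dataset.get(pid)
        if pid not in feat_cache:
            feat_cache[pid] = p.features.set_index("time_point") if p.features is not None else pd.DataFrame()
            dist_cache[pid] = p.distf.set_index("time_point") if p.distf is not None else pd.DataFrame()
        for j, name in enumerate(feature_names):
            v = _resolve_value(p, int(tp), name, feat_cache[pid], dist_cache[pid])
            if not np.isfinite(v):
                raise ValueError(f"missing value for {name} at (patient {pid}, time point {tp})")
            X[i, j] = v
        y[i] = p.label
        pids.append(pid)
    return X, y, pids


@dataclass(frozen=True)
class FittedClassifier:
    """A fitted logistic model: intercept, coefficients and metadata."""

    intercept: float
    coef: np.ndarray
    feature_names: tuple[str, ...] | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _neg_penalized_loglik(beta: np.ndarray, X1: np.ndarray, y: np.ndarray, ridge: float) -> float:
    eta = X1 @ beta
    # log(1 + e^eta) - y*eta, computed stably
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    return nll + 0.5 * ridge * float(np.sum(beta[1:] ** 2))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    ridge: float = 1e-4,
    standardize: bool = False,
    max_iter: int = 200,
    tol: float = 1e-10,
    meta: dict | None = None,
) -> FittedClassifier:
    """Maximum-penalized-likelihood logistic fit by Newton's method.

    A small ridge penalty (default 1e-4, intercept unpenalized) keeps the
    optimum finite on separable data — a real concern with 25-row test
    folds — while leaving well-conditioned fits essentially untouched.
    The fit is deterministic given its inputs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size or X.shape[0] < 2:
        raise ValueError("need at least 2 rows with matching labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("degenerate fold: single-class training data")
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be coded 0/1")
    x_mean = x_scale = None
    if standardize:
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
        X = (X - x_mean) / x_scale
    n, k = X.shape
    X1 = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    pen_mask = np.ones(k + 1)
    pen_mask[0] = 0.0
    obj = _neg_penalized_loglik(beta, X1, y, ridge)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(X1 @ beta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X1.T @ (y - p) - ridge * pen_mask * beta
        H = (X1 * w[:, None]).T @ X1 + ridge * np.diag(pen_mask)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # backtracking line search on the penalized objective
        t = 1.0
        for _ in range(30):
            new_beta = beta + t * step
            new_obj = _neg_penalized_loglik(new_beta, X1, y, ridge)
            if new_obj <= obj + 1e-12:
                break
            t *= 0.5
        beta, obj = new_beta, new_obj
        if np.max(np.abs(t * step)) < tol:
            break
    md = dict(meta or {})
    md["n_iter"] = n_iter
    return FittedClassifier(
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        feature_names=tuple(feature_names) if feature_names is not None else None,
        x_mean=x_mean,
        x_scale=x_scale,
        meta=md,
    )


def predict_prob(model: FittedClassifier, X: np.ndarray,
                 feature_names: Sequence[str] | None = None) -> np.ndarray:
    """Predicted non-survival probabilities, strictly inside (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.size:
        raise ValueError(
            f"column mismatch: model has {model.coef.size} features, got {X.shape[1]}")
    if feature_names is not None and model.feature_names is not None:
        if tuple(feature_names) != model.feature_names:
            raise ValueError("column mismatch: feature names differ from the fitted model")
    if model.x_mean is not None:
        X = (X - model.x_mean) / model.x_scale
    eta = model.intercept + X @ model.coef
    return np.clip(expit(eta), 1e-12, 1.0 - 1e-12)


def make_folds(dataset: CohortDataset, scheme: CVScheme) -> list[Fold]:
    """Build the repeated patient-grouped folds of the protocol.

    Per repeat, non-survivors are permuted and dealt one per fold (by
    rotation when counts differ from the fold count); survivors are
    permuted and each fold takes ``floor(fraction · n_survivors)`` of
    them.  For each test patient, ``time_points_per_patient`` time points
    are drawn uniformly without replacement from the time points with a
    valid distance window; a patient with fewer valid windows contributes
    all of them (with a warning).  Fully reproducible from the scheme's
    seed.
    """
    rng = np.random.default_rng(scheme.rng_seed)
    surv = dataset.survivor_ids
    ns = dataset.non_survivor_ids
    if not surv or not ns:
        raise ValueError("cohort must contain both survivors and non-survivors")
    n_test_surv = int(scheme.survivor_test_fraction * len(surv) + 1e-9)
    if n_test_surv < 1:
        raise ValueError("survivor_test_fraction too small for this cohort")
    if scheme.n_folds * n_test_surv > len(surv):
        raise ValueError("not enough survivors for disjoint test folds")
    valid = {p.patient_id: dataset.valid_time_points(p.patient_id) for p in dataset.patients}
    folds: list[Fold] = []
    for r in range(scheme.n_repeats):
        ns_perm = list(rng.permutation(ns))
        sv_perm = list(rng.permutation(surv))
        for f in range(scheme.n_folds):
            test_pids = [ns_perm[f % len(ns_perm)]]
            test_pids += sv_perm[f * n_test_surv:(f + 1) * n_test_surv]
            rows: list[tuple[str, int]] = []
            for pid in test_pids:
                tps = valid[pid]
                if not tps:
                    raise ValueError(f"patient {pid} has no valid time points")
                k = scheme.time_points_per_patient
                if len(tps) < k:
                    warnings.warn(
                        f"patient {pid} has only {len(tps)} valid windows; "
                        f"using all of them instead of {k}")
                    k = len(tps)
                chosen = rng.choice(tps, size=k, replace=False)
                rows.extend((pid, int(t)) for t in sorted(chosen))
            folds.append(Fold(repeat=r, index=f, test_patients=tuple(test_pids),
                              test_rows=tuple(rows)))
    return folds


def training_rows(dataset: CohortDataset, fold: Fold,
                  paper_literal: bool = False) -> list[tuple[str, int]]:
    """Training rows for a fold.

    Grouped (default): every valid row of every patient *not* in the test
    fold — no patient contributes to both sides.  ``paper_literal=True``
    instead removes only the sampled test rows, keeping the test
    patients' other time points in training (the study's wording is
    ambiguous on this; the grouped split avoids within-patient leakage).
    """
    if paper_literal:
        test = set(fold.test_rows)
        return [rw for rw in dataset.all_valid_rows() if rw not in test]
    test_p = set(fold.test_patients)
    return [(pid, tp) for (pid, tp) in dataset.all_valid_rows() if pid not in test_p]


def _fold_youden(y_true: np.ndarray, probs: np.ndarray, cutoff: float) -> float:
    pred = probs > cutoff
    pos = y_true == 1
    neg = ~pos
    sens = float(np.sum(pred & pos)) / max(int(np.sum(pos)), 1)
    spec = float(np.sum(~pred & neg)) / max(int(np.sum(neg)), 1)
    return sens + spec - 1.0


def youden_fitness(
    features: Sequence[str],
    dataset: CohortDataset,
    scheme: CVScheme | None = None,
    folds: list[Fold] | None = None,
    cutoff: float = 0.5,
    paper_literal: bool = False,
    ridge: float = 1e-4,
) -> float:
    """Cross-validated Youden index of a feature set.

    For each fold: fit on the training rows, predict the test rows,
    classify at the probability cutoff and compute J = sensitivity +
    specificity − 1; the fitness is the mean J over folds.  An empty
    feature set scores −1 (the worst possible J).  Degenerate folds are
    logged and the remaining folds averaged.
    """
    features = list(features)
    if not features:
        return -1.0
    if folds is None:
        if scheme is None:
            raise ValueError("provide either folds or a scheme")
        folds = make_folds(dataset, scheme)
    js: list[float] = []
    for fold in folds:
        tr = training_rows(dataset, fold, paper_literal=paper_literal)
        X_tr, y_tr, _ = build_design_matrix(dataset, features, tr)
        X_te, y_te, _ = build_design_matrix(dataset, features, fold.test_rows)
        try:
            model = fit_logistic(X_tr, y_tr, feature_names=features, ridge=ridge)
        except ValueError as exc:
            logger.warning("degenerate fold (repeat %d, fold %d): %s",
                           fold.repeat, fold.index, exc)
            continue
        js.append(_fold_youden(y_te, predict_prob(model, X_te), cutoff))
    return float(np.mean(js)) if js else -1.0


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Standard small-GA defaults: tournament selection (size 3), uniform
    crossover at rate 0.8, per-bit mutation at 1/chromosome-length,
    two-member elitism.  ``n_runs`` independent restarts vote on the
    final feature set.
    """

    population_size: int = 50
    n_generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # None -> 1 / chromosome length
    tournament_size: int = 3
    elitism_count: int = 2
    n_runs: int = 100
    rng_seed: int = 0
    #: prefer the smaller chromosome when fitness ties; keeps drifting
    #: uninformative bits out of the selected sets
    parsimony_ties: bool = True

    def __post_init__(self) -> None:
        if self.population_size % 2 != 0 or self.population_size < 2:
            raise ValueError("population_size must be even and >= 2")
        if self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be smaller than the population")


@dataclass
class SelectionResult:
    """GA output: per-run winners, vote frequencies and the final set."""

    candidate_features: tuple[str, ...]
    run_best: list[tuple[tuple[int, ...], float]]
    best_fitness_history: list[list[float]]
    selection_frequency: dict[str, float]
    final_feature_set: list[str]
    config: GAConfig

    def to_dict(self) -> dict:
        return {
            "candidate_features": list(self.candidate_features),
            "runs": [
                {"chromosome": "".join(map(str, ch)), "fitness": fit}
                for ch, fit in self.run_best
            ],
            "selection_frequency": self.selection_frequency,
            "final_feature_set": self.final_feature_set,
        }


class _CVFitness:
    """Precomputed design matrix + fold indices for fast chromosome scoring."""

    def __init__(self, dataset: CohortDataset, candidates: Sequence[str],
                 folds: list[Fold], cutoff: float, paper_literal: bool, ridge: float):
        rows = dataset.all_valid_rows()
        self.X, self.y, _ = build_design_matrix(dataset, candidates, rows)
        pos = {rw: i for i, rw in enumerate(rows)}
        self.cutoff = cutoff
        self.ridge = ridge
        self._cache: dict[bytes, float] = {}
        self.folds: list[tuple[np.ndarray, np.ndarray]] = []
        for fold in folds:
            tr = training_rows(dataset, fold, paper_literal=paper_literal)
            tr_idx = np.array([pos[rw] for rw in tr], dtype=int)
            te_idx = np.array([pos[rw] for rw in fold.test_rows], dtype=int)
            self.folds.append((tr_idx, te_idx))

    def __call__(self, mask: np.ndarray) -> float:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return -1.0
        key = np.packbits(mask).tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        js: list[float] = []
        for tr_idx, te_idx in self.folds:
            X_tr = self.X[np.ix_(tr_idx, idx)]
            y_tr = self.y[tr_idx]
            try:
                # a bounded Newton run: on separable folds the decision
                # boundary stabilises long before the coefficients do
                model = fit_logistic(X_tr, y_tr, ridge=self.ridge, max_iter=25)
            except ValueError:
                continue
            probs = predict_prob(model, self.X[np.ix_(te_idx, idx)])
            js.append(_fold_youden(self.y[te_idx], probs, self.cutoff))
        result = float(np.mean(js)) if js else -1.0
        self._cache[key] = result
        return result


def _ga_run(fitness: Callable[[np.ndarray], float], length: int,
            config: GAConfig, rng: np.random.Generator
            ) -> tuple[np.ndarray, float, list[float]]:
    # Chromosomes are compared by (fitness, -subset size): among subsets
    # with an equal cross-validated Youden index the smaller one wins.
    # The parsimony tie-break stops uninformative bits from drifting
    # through fitness plateaus into the reported feature sets.
    P = config.population_size
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / length
    cache: dict[bytes, float] = {}

    def score(ch: np.ndarray) -> float:
        key = ch.tobytes()
        if key not in cache:
            cache[key] = fitness(ch.astype(bool))
        return cache[key]

    def rank(pop: np.ndarray, fits: np.ndarray) -> np.ndarray:
        if not config.parsimony_ties:
            return np.argsort(-fits, kind="stable")
        # primary: descending fitness; secondary: ascending subset size
        return np.lexsort((pop.sum(axis=1), -fits))

    def better(fit_a: float, size_a: int, fit_b: float, size_b: int) -> bool:
        if fit_a > fit_b:
            return True
        return config.parsimony_ties and fit_a == fit_b and size_a < size_b

    pop = rng.integers(0, 2, size=(P, length), dtype=np.int8)
    fits = np.array([score(ch) for ch in pop])
    best_idx = int(rank(pop, fits)[0])
    best_ch, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    history = [best_fit]

    def tournament() -> np.ndarray:
        contenders = rng.integers(0, P, size=config.tournament_size)
        win = contenders[0]
        for c in contenders[1:]:
            if better(fits[c], int(pop[c].sum()), fits[win], int(pop[win].sum())):
                win = c
        return pop[win]

    for _ in range(config.n_generations):
        order = rank(pop, fits)
        elites = pop[order[:config.elitism_count]].copy()
        children: list[np.ndarray] = []
        while len(children) < P - config.elitism_count:
            a, b = tournament().copy(), tournament().copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(length) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                flip = rng.random(length) < mut
                child[flip] ^= 1
                children.append(child)
        pop = np.vstack([elites, np.array(children[:P - config.elitism_count])])
        fits = np.array([score(ch) for ch in pop])
        gen_best = int(rank(pop, fits)[0])
        if better(float(fits[gen_best]), int(pop[gen_best].sum()), best_fit, int(best_ch.sum())):
            best_ch, best_fit = pop[gen_best].copy(), float(fits[gen_best])
        history.append(best_fit)
    return best_ch, best_fit, history


def ga_select(
    dataset: CohortDataset,
    scheme: CVScheme,
    config: GAConfig,
    candidate_features: Sequence[str] | None = None,
    threshold: float = 0.5,
    cutoff: float = 0.5,
    paper_literal: bool = False,
    ridge: float = 1e-4,
    fitness_fn: Callable[[np.ndarray], float] | None = None,
) -> SelectionResult:
    """Repeated-run GA search for the best-discriminating feature subset.

    Each run evolves binary chromosomes over the candidate features with
    the cross-validated Youden index as fitness (folds are built once
    from the scheme and shared by all runs and chromosomes).  The final
    feature set contains the features selected by more than *threshold*
    of the runs' best chromosomes; if none clears the threshold, the
    single most frequently selected feature is returned, ties broken by
    the higher mean fitness of the runs containing the feature.

    ``fitness_fn`` (a callable on boolean masks) replaces the CV fitness;
    it exists for calibration experiments and tests.
    """
    if candidate_features is None:
        candidate_features = list(FEATURE_NAMES) + [DIST_PREFIX + f for f in FEATURE_NAMES]
    candidates = tuple(candidate_features)
    if not candidates:
        raise ValueError("candidate feature list must be non-empty")
    if fitness_fn is None:
        folds = make_folds(dataset, scheme)
        fitness_fn = _CVFitness(dataset, candidates, folds, cutoff, paper_literal, ridge)
    length = len(candidates)
    run_best: list[tuple[tuple[int, ...], float]] = []
    histories: list[list[float]] = []
    for run in range(config.n_runs):
        rng = np.random.default_rng([config.rng_seed, run])
        ch, fit, hist = _ga_run(fitness_fn, length, config, rng)
        run_best.append((tuple(int(b) for b in ch), float(fit)))
        histories.append(hist)
    votes = np.array([ch for ch, _ in run_best], dtype=float)
    freq = votes.mean(axis=0)
    frequencies = {name: float(f) for name, f in zip(candidates, freq)}
    final = [name for name, f in frequencies.items() if f > threshold]
    if not final:
        best_f = freq.max()
        tied = [i for i, f in enumerate(freq) if f == best_f]
        if len(tied) > 1:
            def mean_fit(i: int) -> float:
                fits = [fit for (ch, fit) in run_best if ch[i] == 1]
                return float(np.mean(fits)) if fits else -np.inf
            tied.sort(key=mean_fit, reverse=True)
        final = [candidates[tied[0]]]
    return SelectionResult(
        candidate_features=candidates,
        run_best=run_best,
        best_fitness_history=histories,
        selection_frequency=frequencies,
        final_feature_set=final,
        config=config,
    )
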