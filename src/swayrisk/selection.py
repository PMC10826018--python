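"""Wrapper feature selection with binary metaheuristics, plus filter baselines.

A candidate feature subset (a binary mask over the posturographic
columns) is scored by the composite wrapper fitness

    fitness = w1 * GM + w2 * AUC + w3 * lambda,
    lambda  = 1 - |selected| / |total|,

where GM = sqrt(sensitivity * specificity) and AUC are mean stratified
cross-validation scores of an inner classifier restricted to the masked
columns (personal metrics, when supplied, bypass selection and are
always appended).  Three population metaheuristics search the mask
space — the Slime Mould Algorithm (SMA), Harris Hawks Optimization
(HHO), and the Artificial Bee Colony (ABC) — each operating on
continuous positions in [0, 1]^d that are binarized through an
S-shaped (sigmoid) transfer function.  Univariate filter baselines
(mutual information, ANOVA F-value) are provided for comparison.

Selectors are scikit-learn estimators (``fit(X, y)`` then ``transform``)
and compose with sklearn pipelines; :func:`select_features` is a thin
functional wrapper returning a :class:`SelectionResult`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif, mutual_info_classif
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted


# --------------------------------------------------------------------------
# fitness


def sparsity_term(mask: np.ndarray) -> float:
    """lambda = 1 - |selected| / |total|, in [0, 1)."""
    mask = np.asarray(mask, bool)
    if mask.size == 0:
        raise ValueError("mask must be non-empty")
    return 1.0 - mask.sum() / mask.size


def combine_fitness(
    gm: float, auc: float, lam: float, weights: tuple[float, float, float]
) -> float:
    """The composite wrapper objective w1*GM + w2*AUC + w3*lambda."""
    w1, w2, w3 = weights
    if min(w1, w2, w3) < 0 or w1 + w2 + w3 <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return w1 * gm + w2 * auc + w3 * lam


@dataclass(frozen=True)
class FitnessConfig:
    """Weights and cross-validation settings of the wrapper fitness."""

    w1: float = 0.4  # GM weight
    w2: float = 0.4  # AUC weight
    w3: float = 0.2  # sparsity weight
    cv_folds: int = 3
    inner_classifier: str = "complement_nb"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0 or self.w1 + self.w2 + self.w3 <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic (ties get average rank).

    Identical to the trapezoidal area under the empirical ROC curve.
    """
    y_true = np.asarray(y_true, int)
    ranks = stats.rankdata(np.asarray(scores, float))
    n1 = int(np.sum(y_true == 1))
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


class MaskFitness:
    """Callable scoring binary masks by cross-validated GM/AUC plus sparsity.

    The inner Complement NB is evaluated through a vectorized scoring
    path: per fold the per-class column sums (the sufficient statistics
    of the CNB fit) are computed once over all columns, so scoring a
    mask is a couple of matrix operations.  The path reproduces
    :class:`sklearn.naive_bayes.ComplementNB` decisions exactly (tested
    against it).  Results are memoized by mask, which also makes
    brute-force enumeration over small spaces cheap.  ``X_extra``
    columns bypass the mask and are always appended.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: FitnessConfig = FitnessConfig(),
        X_extra: np.ndarray | None = None,
    ) -> None:
        if config.inner_classifier != "complement_nb":
            raise ValueError(f"unknown inner classifier {config.inner_classifier!r}")
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(np.unique(self.y)) != 2:
            raise ValueError("fitness requires binary labels")
        if np.min(self.X) < 0 or (
            X_extra is not None and np.min(X_extra) < 0
        ):
            raise ValueError("Complement NB requires non-negative features")
        self.config = config
        self.X_extra = None if X_extra is None else np.asarray(X_extra, float)
        self.n_features = self.X.shape[1]
        self.evaluations = 0
        self._cache: dict[bytes, float] = {}

        full = (
            self.X
            if self.X_extra is None
            else np.hstack([self.X, self.X_extra])
        )
        cv = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
        # per fold: test block and the per-class training column sums
        self._folds = []
        for train_idx, test_idx in cv.split(full, self.y):
            ytr = self.y[train_idx]
            s1 = full[train_idx][ytr == 1].sum(axis=0)
            s0 = full[train_idx][ytr == 0].sum(axis=0)
            self._folds.append(
                {"s1": s1, "s0": s0, "X_test": full[test_idx], "y_test": self.y[test_idx]}
            )

    def _mask_columns(self, mask: np.ndarray) -> np.ndarray:
        cols = np.flatnonzero(mask)
        if self.X_extra is not None:
            extras = np.arange(self.X.shape[1], self.X.shape[1] + self.X_extra.shape[1])
            cols = np.concatenate([cols, extras])
        return cols

    def cv_scores(self, mask: np.ndarray) -> tuple[float, float]:
        """Mean cross-validated (GM, AUC) of the inner Complement NB."""
        mask = np.asarray(mask, bool)
        cols = self._mask_columns(mask)
        alpha = 1.0
        gms, aucs = [], []
        for fold in self._folds:
            # Complement NB sufficient statistics on the selected columns
            counts = np.stack([fold["s0"][cols], fold["s1"][cols]])  # (2, k)
            comp = alpha + counts.sum(axis=0) - counts  # complement counts
            flp = -(np.log(comp) - np.log(comp.sum(axis=1, keepdims=True)))
            jll = fold["X_test"][:, cols] @ flp.T
            score = jll[:, 1] - jll[:, 0]  # monotone in P(y=1|x)
            y_true = fold["y_test"]
            y_hat = (score >= 0).astype(int)
            pos = y_true == 1
            sens = float(np.mean(y_hat[pos] == 1)) if pos.any() else 0.0
            spec = float(np.mean(y_hat[~pos] == 0)) if (~pos).any() else 0.0
            gms.append(np.sqrt(sens * spec))
            aucs.append(rank_auc(y_true, score))
        return float(np.mean(gms)), float(np.mean(aucs))

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, bool)
        if mask.shape != (self.n_features,):
            raise ValueError("mask has wrong length")
        if not mask.any():
            raise ValueError("fitness is undefined for an empty mask; repair first")
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            return self._cache[key]
        gm, auc = self.cv_scores(mask)
        value = combine_fitness(gm, auc, sparsity_term(mask), self.config.weights)
        self._cache[key] = value
        self.evaluations += 1
        return value


# --------------------------------------------------------------------------
# result container


@dataclass
class SelectionResult:
    """Outcome of one feature-selection run."""

    algorithm: str
    mask: np.ndarray
    feature_names: list[str]
    best_fitness: float
    history: list[float]  # best-so-far fitness per epoch, non-decreasing
    evaluations: int
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def selected_names(self) -> list[str]:
        return [n for n, m in zip(self.feature_names, self.mask) if m]

    def to_json(self) -> str:
        payload = {
            "algorithm": self.algorithm,
            "selected": self.selected_names,
            "best_fitness": self.best_fitness,
            "history": list(self.history),
            "evaluations": self.evaluations,
            "seed": self.seed,
            "config": self.config,
        }
        return json.dumps(payload, indent=2)


# --------------------------------------------------------------------------
# binary encoding helpers


def _sigmoid_transfer(positions: np.ndarray, slope: float = 6.0) -> np.ndarray:
    """S-shaped transfer centred at 0.5, mapping positions to bit probabilities.

    The slope sets how deterministic the binarization is.  A moderate
    slope keeps residual stochasticity at the box faces (p ~ 0.05 for a
    saturated coordinate), which sustains exploration once the
    population's exploitation phases contract onto the incumbent; very
    steep transfers make masks effectively deterministic and prone to
    premature convergence.
    """
    return 1.0 / (1.0 + np.exp(-slope * (positions - 0.5)))


def _binarize(
    positions: np.ndarray, rng: np.random.Generator, slope: float = 6.0
) -> np.ndarray:
    probs = _sigmoid_transfer(positions, slope)
    bits = rng.random(positions.shape) < probs
    return _repair(bits, positions)


def _repair(bits: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Guarantee a non-empty mask: flip on the strongest position if needed."""
    bits = np.asarray(bits, bool)
    if bits.ndim == 1:
        if not bits.any():
            bits = bits.copy()
            bits[int(np.argmax(positions))] = True
        return bits
    out = bits.copy()
    for i in range(out.shape[0]):
        if not out[i].any():
            out[i, int(np.argmax(positions[i]))] = True
    return out


# --------------------------------------------------------------------------
# metaheuristic selectors


class _BaseMetaheuristicSelector(SelectorMixin, BaseEstimator):
    """Shared machinery: population loop, binarization, best-so-far tracking."""

    algorithm: str = "base"

    def __init__(
        self,
        population: int = 100,
        epochs: int = 100,
        w1: float = 0.4,
        w2: float = 0.4,
        w3: float = 0.2,
        cv_folds: int = 3,
        inner_classifier: str = "complement_nb",
        transfer_slope: float = 6.0,
        random_state: int = 0,
    ) -> None:
        self.population = population
        self.epochs = epochs
        self.w1 = w1
        self.w2 = w2
        self.w3 = w3
        self.cv_folds = cv_folds
        self.inner_classifier = inner_classifier
        self.transfer_slope = transfer_slope
        self.random_state = random_state

    # subclass hook: one epoch of position updates, in place
    def _update(
        self,
        positions: np.ndarray,
        fitness: np.ndarray,
        epoch: int,
        rng: np.random.Generator,
        state: dict,
    ) -> np.ndarray:
        raise NotImplementedError

    def _fitness_config(self) -> FitnessConfig:
        return FitnessConfig(
            w1=self.w1,
            w2=self.w2,
            w3=self.w3,
            cv_folds=self.cv_folds,
            inner_classifier=self.inner_classifier,
            seed=self.random_state,
        )

    def fit(self, X, y, X_extra=None, objective: Callable | None = None):
        """Search the mask space; ``objective`` overrides the CV fitness
        (used for oracle comparisons on analytic objectives)."""
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        X = np.asarray(X, float)
        n_features = X.shape[1]
        if objective is None:
            objective = MaskFitness(X, y, self._fitness_config(), X_extra=X_extra)

        rng = np.random.default_rng(self.random_state)
        positions = rng.random((self.population, n_features))

        best_mask: np.ndarray | None = None
        best_fit = -np.inf
        history: list[float] = []
        evaluations = 0

        def evaluate(pos_matrix: np.ndarray) -> np.ndarray:
            nonlocal best_mask, best_fit, evaluations
            fits = np.empty(len(pos_matrix))
            for i, pos in enumerate(pos_matrix):
                bits = _binarize(pos, rng, self.transfer_slope)
                f = objective(bits)
                evaluations += 1
                fits[i] = f
                if f > best_fit:
                    best_fit = f
                    best_mask = bits.copy()
            return fits

        state: dict = {"evaluate_one": None}

        def evaluate_one(pos: np.ndarray) -> float:
            nonlocal best_mask, best_fit, evaluations
            bits = _binarize(pos, rng, self.transfer_slope)
            f = objective(bits)
            evaluations += 1
            if f > best_fit:
                best_fit = f
                best_mask = bits.copy()
            return f

        state["evaluate_one"] = evaluate_one
        fitness = evaluate(positions)
        i0 = int(np.argmax(fitness))
        state["best_position"] = positions[i0].copy()
        best_pos_fit = float(fitness[i0])

        for epoch in range(self.epochs):
            positions = self._update(positions, fitness, epoch, rng, state)
            np.clip(positions, 0.0, 1.0, out=positions)
            fitness = evaluate(positions)
            i_best = int(np.argmax(fitness))
            if fitness[i_best] > best_pos_fit:
                best_pos_fit = float(fitness[i_best])
                state["best_position"] = positions[i_best].copy()
            history.append(best_fit)

        assert best_mask is not None
        self.n_features_in_ = n_features
        self.feature_names_in_ = (
            np.asarray(feature_names) if feature_names is not None else None
        )
        self.support_ = best_mask
        self.best_fitness_ = best_fit
        self.history_ = history
        self.n_evaluations_ = evaluations
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def result_(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        names = (
            list(self.feature_names_in_)
            if self.feature_names_in_ is not None
            else [f"x{i}" for i in range(self.n_features_in_)]
        )
        return SelectionResult(
            algorithm=self.algorithm,
            mask=self.support_.copy(),
            feature_names=names,
            best_fitness=float(self.best_fitness_),
            history=list(self.history_),
            evaluations=int(self.n_evaluations_),
            seed=self.random_state,
            config=self.get_params(),
        )


class SMASelector(_BaseMetaheuristicSelector):
    """Slime Mould Algorithm wrapper selector.

    Positions oscillate around the best-so-far solution with
    fitness-derived weights; a small restart probability (z = 0.03)
    keeps the population exploring.
    """

    algorithm = "SMA"
    _z = 0.03

    def _update(self, positions, fitness, epoch, rng, state):
        pop, d = positions.shape
        T = self.epochs
        t = epoch + 1
        order = np.argsort(fitness)[::-1]  # descending: best first
        bf, wf = fitness[order[0]], fitness[order[-1]]
        spread = bf - wf + 1e-12

        # oscillation weights, higher for the better half
        W = np.empty((pop, d))
        ranks = np.empty(pop, int)
        ranks[order] = np.arange(pop)
        r = rng.random((pop, d))
        lg = np.log10((bf - fitness)[:, None] / spread + 1.0)
        better_half = (ranks < pop // 2)[:, None]
        W = np.where(better_half, 1.0 + r * lg, 1.0 - r * lg)

        a = np.arctanh(max(1.0 - t / T, 1e-12))
        b = max(1.0 - t / T, 0.0)
        xb = state["best_position"]

        new = positions.copy()
        for i in range(pop):
            if rng.random() < self._z:
                new[i] = rng.random(d)
                continue
            p_i = np.tanh(abs(fitness[i] - bf) + 1e-12)
            vb = rng.uniform(-a, a, d)
            vc = rng.uniform(-b, b, d)
            ja, jb = rng.integers(0, pop, 2)
            cond = rng.random(d) < p_i
            approach = xb + vb * (W[i] * positions[ja] - positions[jb])
            # contraction toward the box midpoint: the original rule
            # contracts toward the origin, which is the domain centre in
            # the symmetric formulation but a deselection bias in [0,1]
            wander = 0.5 + vc * (positions[i] - 0.5)
            new[i] = np.where(cond, approach, wander)
        return new


class HHOSelector(_BaseMetaheuristicSelector):
    """Harris Hawks Optimization wrapper selector.

    The escaping-energy parameter schedules the switch from exploration
    to four exploitation strategies (soft/hard besiege, with and without
    Levy-flight rapid dives) around the best solution found so far.
    """

    algorithm = "HHO"

    @staticmethod
    def _levy(d: int, rng: np.random.Generator, beta: float = 1.5) -> np.ndarray:
        num = math.gamma(1 + beta) * np.sin(np.pi * beta / 2)
        den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
        sigma = (num / den) ** (1 / beta)
        u = rng.normal(0, sigma, d)
        v = rng.normal(0, 1, d)
        return 0.01 * u / np.abs(v) ** (1 / beta)

    def _update(self, positions, fitness, epoch, rng, state):
        pop, d = positions.shape
        T = self.epochs
        t = epoch + 1
        rabbit = state["best_position"]
        x_mean = positions.mean(axis=0)
        evaluate_one = state["evaluate_one"]

        new = positions.copy()
        for i in range(pop):
            E0 = 2 * rng.random() - 1
            E = 2 * E0 * (1 - t / T)
            J = 2 * (1 - rng.random())
            if abs(E) >= 1:  # exploration
                if rng.random() >= 0.5:
                    k = rng.integers(0, pop)
                    r1, r2 = rng.random(2)
                    new[i] = positions[k] - r1 * np.abs(
                        positions[k] - 2 * r2 * positions[i]
                    )
                else:
                    r3, r4 = rng.random(2)
                    new[i] = (rabbit - x_mean) - r3 * r4  # LB=0, UB=1
            else:  # exploitation
                r = rng.random()
                if r >= 0.5 and abs(E) >= 0.5:  # soft besiege
                    delta = rabbit - positions[i]
                    new[i] = delta - E * np.abs(J * rabbit - positions[i])
                elif r >= 0.5:  # hard besiege
                    new[i] = rabbit - E * np.abs(rabbit - positions[i])
                else:
                    anchor = positions[i] if abs(E) >= 0.5 else x_mean
                    y = rabbit - E * np.abs(J * rabbit - anchor)
                    y = np.clip(y, 0, 1)
                    if evaluate_one(y) > fitness[i]:
                        new[i] = y
                    else:
                        z = np.clip(y + rng.random(d) * self._levy(d, rng), 0, 1)
                        if evaluate_one(z) > fitness[i]:
                            new[i] = z
        return new


class ABCSelector(_BaseMetaheuristicSelector):
    """Artificial Bee Colony wrapper selector (standard bee-inspired form).

    Employed and onlooker bees perturb one coordinate toward a random
    partner with greedy acceptance; food sources unimproved for
    ``limit`` rounds are abandoned by scouts.
    """

    algorithm = "ABC"

    def __init__(
        self,
        population: int = 100,
        epochs: int = 100,
        w1: float = 0.4,
        w2: float = 0.4,
        w3: float = 0.2,
        cv_folds: int = 3,
        inner_classifier: str = "complement_nb",
        transfer_slope: float = 6.0,
        random_state: int = 0,
        limit: int = 20,
    ) -> None:
        super().__init__(
            population,
            epochs,
            w1,
            w2,
            w3,
            cv_folds,
            inner_classifier,
            transfer_slope,
            random_state,
        )
        self.limit = limit

    def _update(self, positions, fitness, epoch, rng, state):
        pop, d = positions.shape
        evaluate_one = state["evaluate_one"]
        trials = state.setdefault("trials", np.zeros(pop, int))
        fit = fitness.copy()

        def neighbor_search(i: int) -> None:
            j = rng.integers(0, d)
            k = rng.integers(0, pop - 1)
            if k >= i:
                k += 1
            v = positions[i].copy()
            v[j] = np.clip(
                v[j] + (2 * rng.random() - 1) * (v[j] - positions[k][j]), 0, 1
            )
            f_v = evaluate_one(v)
            if f_v > fit[i]:
                positions[i] = v
                fit[i] = f_v
                trials[i] = 0
            else:
                trials[i] += 1

        for i in range(pop):  # employed bees
            neighbor_search(i)
        shifted = fit - fit.min() + 1e-9  # onlookers: fitness-proportional
        probs = shifted / shifted.sum()
        for i in rng.choice(pop, size=pop, p=probs):
            neighbor_search(int(i))
        for i in range(pop):  # scouts
            if trials[i] > self.limit:
                positions[i] = rng.random(d)
                fit[i] = evaluate_one(positions[i])
                trials[i] = 0
        return positions


# --------------------------------------------------------------------------
# filter baselines


class FilterSelector(SelectorMixin, BaseEstimator):
    """Univariate top-k filter: mutual information or ANOVA F-value.

    Ranking ties are broken by column name (stable, deterministic).
    """

    def __init__(self, method: str = "f_value", k: int = 10, random_state: int = 0):
        self.method = method
        self.k = k
        self.random_state = random_state

    def fit(self, X, y):
        feature_names = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [f"x{i}" for i in range(np.asarray(X).shape[1])]
        )
        X = np.asarray(X, float)
        n_features = X.shape[1]
        if not 1 <= self.k <= n_features:
            raise ValueError(f"k must lie in [1, {n_features}]")
        if self.method == "f_value":
            scores, _ = f_classif(X, y)
            scores = np.nan_to_num(scores, nan=0.0)
        elif self.method == "mi":
            scores = mutual_info_classif(X, y, random_state=self.random_state)
            # the k-NN estimator jitters continuous features, which can give
            # a constant column a spuriously positive score; analytically
            # its mutual information is exactly 0
            scores[np.ptp(X, axis=0) == 0] = 0.0
        else:
            raise ValueError("method must be 'mi' or 'f_value'")
        order = sorted(
            range(n_features), key=lambda i: (-scores[i], feature_names[i])
        )
        mask = np.zeros(n_features, bool)
        mask[order[: self.k]] = True
        self.n_features_in_ = n_features
        self.feature_names_in_ = np.asarray(feature_names)
        self.scores_ = scores
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# --------------------------------------------------------------------------
# functional facade

_SELECTOR_CLASSES = {"SMA": SMASelector, "HHO": HHOSelector, "ABC": ABCSelector}


def make_selector(
    algorithm: str,
    population: int = 100,
    epochs: int = 100,
    k: int = 30,
    random_state: int = 0,
    **kwargs,
):
    """Instantiate a selector by name: SMA, HHO, ABC, MI, or F-value."""
    if algorithm in _SELECTOR_CLASSES:
        return _SELECTOR_CLASSES[algorithm](
            population=population, epochs=epochs, random_state=random_state, **kwargs
        )
    if algorithm in ("MI", "F-value"):
        method = "mi" if algorithm == "MI" else "f_value"
        return FilterSelector(method=method, k=k, random_state=random_state)
    raise ValueError(f"unknown selection algorithm {algorithm!r}")


def select_features(
    X,
    y,
    algorithm: str = "SMA",
    population: int = 100,
    epochs: int = 100,
    k: int = 30,
    random_state: int = 0,
    X_extra=None,
    **kwargs,
) -> SelectionResult:
    """Run one selection and return its :class:`SelectionResult`."""
    sel = make_selector(
        algorithm, population=population, epochs=epochs, k=k,
        random_state=random_state, **kwargs,
    )
    if isinstance(sel, FilterSelector):
        sel.fit(X, y)
        names = list(sel.feature_names_in_)
        ranked = sorted(
            range(len(names)), key=lambda i: (-sel.scores_[i], names[i])
        )
        best = float(sel.scores_[ranked[0]]) if len(ranked) else 0.0
        return SelectionResult(
            algorithm=algorithm,
            mask=sel.support_.copy(),
            feature_names=names,
            best_fitness=best,
            history=[best],
            evaluations=len(names),
            seed=random_state,
            config=sel.get_params(),
        )
    sel.fit(X, y, X_extra=X_extra)
    return sel.result_()


def brute_force_best_mask(objective: Callable, n_features: int) -> tuple[np.ndarray, float]:
    """Exhaustive search over all non-empty masks (oracle for small spaces)."""
    if n_features > 16:
        raise ValueError("brute force is limited to 16 features")
    best_mask, best_fit = None, -np.inf
    for code in range(1, 2**n_features):
        mask = np.array(
            [(code >> i) & 1 for i in range(n_features)], bool
        )
        f = objective(mask)
        if f > best_fit:
            best_fit, best_mask = f, mask
    return best_mask, float(best_fit)
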