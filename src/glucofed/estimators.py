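"""scikit-learn-style wrapper around the GE symbolic classifier.

``GrammaticalEvolutionClassifier`` evolves a single interpretable
forecasting expression on (X, y) and predicts glycemic bands, so it
drops into sklearn pipelines, cross-validation and grid search.  X must
carry the grammar's feature columns (``g0..gk``, ``i0..ih``, ``c0..ch``,
``dg1..dgk``); y is the integer band id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .bands import N_CLASSES, weighted_f1_from_labels
from .evolve import EAConfig, ExpressionEvaluator, run_ea
from .grammar import glucose_grammar
from .windows import feature_columns


class GrammaticalEvolutionClassifier(BaseEstimator, ClassifierMixin):
    """Grammatical-evolution band forecaster with weighted-F1 fitness.

    Parameters mirror :class:`~glucofed.evolve.EAConfig`; ``k`` and ``h``
    fix the grammar's history/horizon sizes and hence the expected
    feature columns.

    Attributes (after ``fit``)
    --------------------------
    best_expression_ : str
        The evolved formula, directly human-readable.
    best_fitness_ : float
        Training weighted F1 of the evolved expression.
    history_ : list[float]
        Best fitness per generation (monotone under elitism).
    classes_ : ndarray
        The 7 band ids.
    """

    def __init__(self, population_size: int = 50, generations: int = 50,
                 tournament_size: int = 4, p_crossover: float = 0.9,
                 p_mutation: float = 0.1, codon_size: int = 100_000,
                 max_init_depth: int = 10, max_depth: int = 17,
                 max_wraps: int = 2, k: int = 12, h: int = 6,
                 random_state: int = 0):
        self.population_size = population_size
        self.generations = generations
        self.tournament_size = tournament_size
        self.p_crossover = p_crossover
        self.p_mutation = p_mutation
        self.codon_size = codon_size
        self.max_init_depth = max_init_depth
        self.max_depth = max_depth
        self.max_wraps = max_wraps
        self.k = k
        self.h = h
        self.random_state = random_state

    def _frame(self, X) -> pd.DataFrame:
        cols = feature_columns(self.k, self.h)
        if isinstance(X, pd.DataFrame):
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ValueError(f"X is missing feature columns {missing[:4]}...")
            return X[cols].reset_index(drop=True)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(cols):
            raise ValueError(
                f"X must have {len(cols)} columns ({self.k=}, {self.h=}), "
                f"got shape {X.shape}")
        return pd.DataFrame(X, columns=cols)

    def fit(self, X, y):
        frame = self._frame(X)
        y = np.asarray(y, dtype=np.int64)
        if len(y) != len(frame):
            raise ValueError("X and y length mismatch")
        if len(y) == 0:
            raise ValueError("empty training set")
        if y.min() < 0 or y.max() >= N_CLASSES:
            raise ValueError("y must hold band ids 0..6")
        frame = frame.copy()
        frame["target_class"] = y
        config = EAConfig(
            population_size=self.population_size,
            generations=self.generations,
            tournament_size=self.tournament_size,
            p_crossover=self.p_crossover,
            p_mutation=self.p_mutation,
            codon_size=self.codon_size,
            max_init_depth=self.max_init_depth,
            max_depth=self.max_depth,
            max_wraps=self.max_wraps,
            seed=self.random_state,
        )
        grammar = glucose_grammar(self.k, self.h)
        best, history = run_ea(frame, grammar, config)
        self.best_expression_ = best.phenotype
        self.best_genome_ = list(best.genome)
        self.best_fitness_ = best.fitness
        self.history_ = history
        self.classes_ = np.arange(N_CLASSES)
        self.n_features_in_ = len(feature_columns(self.k, self.h))
        return self

    def _evaluator(self, X) -> ExpressionEvaluator:
        frame = self._frame(X).copy()
        frame["target_class"] = 0   # placeholder, predictions ignore it
        return ExpressionEvaluator(frame)

    def predict_value(self, X) -> np.ndarray:
        """Continuous forecast Ghat(t + h*dt) in mmol/L (may be non-finite
        for degenerate expressions)."""
        check_is_fitted(self, "best_expression_")
        return np.array(self._evaluator(X).predict_values(self.best_expression_))

    def predict(self, X) -> np.ndarray:
        """Predicted band ids; -1 marks a non-finite forecast."""
        check_is_fitted(self, "best_expression_")
        return self._evaluator(X).predict_classes(self.best_expression_)

    def score(self, X, y, sample_weight=None) -> float:
        """Weighted F1 (the fitness metric), not accuracy."""
        return weighted_f1_from_labels(np.asarray(y, dtype=np.int64),
                                       self.predict(X))
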