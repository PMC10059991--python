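"""Canned experiment protocols built from the library pieces.

The desk-scale replication compares federated against independent
evolution under one fixed protocol: a synthetic cohort of 4 learning
plus 2 held-out patients, population 50, 100 generations, migration
every 25 generations, repeated over several master seeds.  Per seed,
each regime's cross-evaluation selects a global model whose mean
weighted F1 on the held-out patients is the headline number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_cohort
from .evolve import EAConfig
from .federation import (MODE_FLEA, MODE_NONFL, ExperimentBundle,
                         FederationConfig, run_experiment)
from .grammar import Grammar, glucose_grammar
from .windows import preprocess_series, train_test_split


def cohort_sample_sets(config: CohortConfig, n_holdout: int,
                       test_fraction: float = 0.2,
                       k: int = 12, h: int = 6):
    """Simulate a cohort and split it into the three sample-set maps the
    experiment runner consumes (learning train/test, holdout test)."""
    if not 0 <= n_holdout < config.n_patients:
        raise ValueError("n_holdout must leave at least one learning patient")
    series = simulate_cohort(config, test_fraction=test_fraction)
    learning = series[: config.n_patients - n_holdout]
    holdout = series[config.n_patients - n_holdout:]
    train_sets, test_sets, holdout_sets = {}, {}, {}
    for s in learning:
        tr, te = train_test_split(preprocess_series(s, k=k, h=h))
        train_sets[s.patient_id], test_sets[s.patient_id] = tr, te
    for s in holdout:
        holdout_sets[s.patient_id] = train_test_split(
            preprocess_series(s, k=k, h=h))[1]
    return train_sets, test_sets, holdout_sets


@dataclass
class HeadlineComparison:
    """One seed's federated-vs-independent outcome.

    Each regime repeats the experiment over several runs (per-run seeds
    derived from the shared master seed) to average out initialization
    randomness — the study design this emulates did twenty runs per
    experiment — and is summarised by the mean, over runs, of its
    selected global model's held-out weighted F1.
    """

    seed: int
    flea: ExperimentBundle
    nonfl: ExperimentBundle

    @property
    def flea_holdout_mean(self) -> float:
        return float(np.mean(self.flea.holdout_means()))

    @property
    def nonfl_holdout_mean(self) -> float:
        return float(np.mean(self.nonfl.holdout_means()))

    @property
    def flea_wins(self) -> bool:
        """Federated regime at least matches the baseline on held-out data."""
        return self.flea_holdout_mean >= self.nonfl_holdout_mean


def compare_modes(master_seed: int,
                  cohort: CohortConfig | None = None,
                  n_holdout: int = 2,
                  ea: EAConfig | None = None,
                  migration_interval: int = 25,
                  runs: int = 20,
                  grammar: Grammar | None = None) -> HeadlineComparison:
    """Run both regimes on the same cohort with paired per-run seeds.

    The cohort is fixed (the data set does not change between replicates,
    matching a real study where the patients are who they are); the master
    seed drives only the evolutionary randomness.  The non-federated
    baseline uses identical per-slave, per-run seeds, so any difference
    is attributable purely to model migration.
    """
    cohort = cohort or CohortConfig(n_patients=6)
    ea = ea or EAConfig(population_size=50, generations=100)
    grammar = grammar or glucose_grammar()
    train_sets, test_sets, holdout_sets = cohort_sample_sets(cohort, n_holdout)
    bundles = {}
    for mode in (MODE_FLEA, MODE_NONFL):
        cfg = FederationConfig(ea=ea, migration_interval=migration_interval,
                               mode=mode, runs=runs, master_seed=master_seed)
        bundles[mode] = run_experiment(train_sets, test_sets, grammar, cfg,
                                       holdout_sets)
    return HeadlineComparison(master_seed, bundles[MODE_FLEA],
                              bundles[MODE_NONFL])


def derive_master_seeds(base_seed: int, n: int = 5) -> list[int]:
    """Canonical expansion of one base seed into n master seeds."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def headline_replication(seeds=None, base_seed: int = 0,
                         **kwargs) -> list[HeadlineComparison]:
    """The desk-scale replication across master seeds.

    ``seeds`` defaults to five master seeds derived from ``base_seed``.
    """
    if seeds is None:
        seeds = derive_master_seeds(base_seed)
    return [compare_modes(seed, **kwargs) for seed in seeds]


def replication_table(comparisons: list[HeadlineComparison]) -> pd.DataFrame:
    rows = [
        {
            "seed": c.seed,
            "flea_holdout_f1": c.flea_holdout_mean,
            "nonfl_holdout_f1": c.nonfl_holdout_mean,
            "flea_wins": c.flea_wins,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows).set_index("seed")
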