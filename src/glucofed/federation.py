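"""Master/slave federated evolution with synchronous best-model migration.

Every patient gets a *slave*: an independent GE population evolving on
that patient's private training samples.  A *master* periodically relays
each slave's best model to all the other slaves (migration); receiving
slaves score the immigrant models on their own local data and integrate
them by worst-replacement.  Only serialized models — genome, formula,
sender-side fitness — ever travel; raw samples never leave a slave, which
is the privacy contract of the whole design.

Transport is an in-process synchronous orchestrator: the master drives
all slaves in lockstep rounds through an explicit message contract, so
the protocol (not the wire) is what is implemented and tested.  The
non-federated baseline is the identical machinery with migration
disabled, which isolates the value of model exchange.

Migration fires after every completed multiple of the migration interval
— i.e. before producing the next generation, with the last exchange
landing right after the final generation when the interval divides the
schedule evenly.  That gives exactly ``floor(gmax / interval)``
communication phases per slave (five for the standard 500/100
configuration), and none at all when the interval exceeds the number of
generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import aggregate
from .evolve import (EAConfig, EvolutionState, ExpressionEvaluator,
                     Individual)
from .grammar import Grammar
from .stats import ResultMatrix

MODE_FLEA = "flea"
MODE_NONFL = "nonfl"


@dataclass(frozen=True)
class MigrationMessage:
    """What a slave is allowed to send: a model, never data.

    The expression is carried as its genome plus the rendered formula;
    ``fitness`` is the sender-side (local) training fitness.
    """

    slave_id: str
    generation: int
    genome: tuple[int, ...]
    phenotype: str | None
    fitness: float

    def to_individual(self) -> Individual:
        return Individual(list(self.genome), self.phenotype,
                          len(self.genome), self.fitness)


@dataclass(frozen=True)
class FederationConfig:
    """Settings of one federated (or baseline) experiment."""

    ea: EAConfig = field(default_factory=EAConfig)
    migration_interval: int = 100
    mode: str = MODE_FLEA
    runs: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (MODE_FLEA, MODE_NONFL):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.migration_interval <= 0 or self.runs <= 0:
            raise ValueError("migration_interval and runs must be positive")


def derive_seed(master_seed: int, run: int, slave_index: int) -> int:
    """Deterministic per-(run, slave) seed from the master seed."""
    ss = np.random.SeedSequence([master_seed, run, slave_index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


class SlaveNode:
    """One patient's evolving population plus its side of the protocol."""

    def __init__(self, slave_id: str, train_samples: pd.DataFrame,
                 grammar: Grammar, config: EAConfig):
        self.slave_id = slave_id
        self.evaluator = ExpressionEvaluator(train_samples)
        self.state = EvolutionState(grammar, self.evaluator, config)

    @property
    def generation(self) -> int:
        return self.state.generation

    def emigrant(self) -> MigrationMessage:
        best = self.state.best
        return MigrationMessage(self.slave_id, self.generation,
                                tuple(best.genome), best.phenotype,
                                best.fitness)

    def receive_immigrants(self, messages: list[MigrationMessage]) -> int:
        """Score foreign models on local data, then worst-replace.

        The genome is re-mapped locally: this both verifies that the
        serialized model deserializes to an evaluable expression and
        recovers its true used-codon count (crossover cut points depend
        on it).
        """
        from .grammar import map_genome

        immigrants = []
        for msg in messages:
            ind = msg.to_individual()
            phenotype, used = map_genome(ind.genome, self.state.grammar,
                                         max_wraps=self.state.config.max_wraps,
                                         max_depth=self.state.config.max_depth)
            if phenotype != msg.phenotype:
                raise ValueError(
                    f"immigrant from {msg.slave_id} does not deserialize "
                    "to the transmitted model")
            ind.used_codons = used
            ind.fitness = self.evaluator.fitness(phenotype)
            immigrants.append(ind)
        return self.state.integrate_immigrants(immigrants)

    def evaluate_model(self, msg: MigrationMessage) -> float:
        """Local fitness of a (final) foreign model."""
        return self.evaluator.fitness(msg.phenotype)


@dataclass
class FederationResult:
    mode: str
    final_models: list[MigrationMessage]
    #: fitness_table[i][j]: slave i's local fitness of slave j's final model
    local_fitness: pd.DataFrame
    histories: dict[str, list[float]]
    message_log: list[MigrationMessage]
    migration_rounds: int
    replacements: dict[str, int]


def run_federation(train_sets: dict[str, pd.DataFrame], grammar: Grammar,
                   config: FederationConfig, run_index: int = 0
                   ) -> FederationResult:
    """Execute one federated (or baseline) run over all slaves.

    The master relays best-model lists at every synchronous migration
    phase and, at termination, collects the final bests, broadcasts them,
    and gathers every slave's local fitness of every final model.  The
    master never touches raw samples.
    """
    ids = list(train_sets)
    slaves = [
        SlaveNode(pid, train_sets[pid], grammar,
                  replace(config.ea,
                          seed=derive_seed(config.master_seed, run_index, i)))
        for i, pid in enumerate(ids)
    ]
    log: list[MigrationMessage] = []
    rounds = 0
    replacements = {pid: 0 for pid in ids}
    for g in range(1, config.ea.generations + 1):
        for slave in slaves:
            slave.state.step()
        if config.mode == MODE_FLEA and g % config.migration_interval == 0:
            outbound = [s.emigrant() for s in slaves]   # slaves -> master
            log.extend(outbound)
            rounds += 1
            for i, slave in enumerate(slaves):          # master -> slaves
                foreign = [m for j, m in enumerate(outbound) if j != i]
                replacements[slave.slave_id] += slave.receive_immigrants(foreign)

    finals = [s.emigrant() for s in slaves]
    log.extend(finals)
    table = pd.DataFrame(
        [[s.evaluate_model(m) for m in finals] for s in slaves],
        index=ids, columns=[m.slave_id for m in finals],
    )
    return FederationResult(
        mode=config.mode,
        final_models=finals,
        local_fitness=table,
        histories={s.slave_id: list(s.state.history) for s in slaves},
        message_log=log,
        migration_rounds=rounds,
        replacements=replacements,
    )


# ---------------------------------------------------------------------------
# Cross-evaluation and global-model selection
# ---------------------------------------------------------------------------

@dataclass
class CrossEvalMatrix:
    """model-of-patient x evaluated-on-patient weighted-F1 table."""

    frame: pd.DataFrame

    def row_margins(self) -> pd.DataFrame:
        stats = [aggregate(row.to_numpy()) for _, row in self.frame.iterrows()]
        return pd.DataFrame(stats, index=self.frame.index, columns=["mean", "sd"])

    def col_margins(self) -> pd.DataFrame:
        stats = [aggregate(self.frame[c].to_numpy()) for c in self.frame.columns]
        return pd.DataFrame(stats, index=self.frame.columns, columns=["mean", "sd"])


def cross_evaluate(models: dict[str, str],
                   test_sets: dict[str, pd.DataFrame]) -> CrossEvalMatrix:
    """Score every patient's model on every patient's test samples.

    ``models`` maps patient id -> phenotype; cell (i, j) is model i's
    weighted F1 on patient j's test set.
    """
    evaluators = {pid: ExpressionEvaluator(df) for pid, df in test_sets.items()}
    rows = {
        mid: {pid: ev.fitness(phenotype) for pid, ev in evaluators.items()}
        for mid, phenotype in models.items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(test_sets)]
    return CrossEvalMatrix(frame)


def select_global_model(matrix: CrossEvalMatrix) -> str:
    """Model with the best average performance across all patients;
    ties resolve to the earlier row (lower patient id)."""
    means = matrix.row_margins()["mean"]
    best = means.idxmax()   # idxmax returns the first maximal label
    return str(best)


# ---------------------------------------------------------------------------
# Whole experiments
# ---------------------------------------------------------------------------

@dataclass
class RunOutcome:
    result: FederationResult
    cross_eval: CrossEvalMatrix
    global_model_id: str
    global_phenotype: str | None
    learning_scores: pd.Series          # global model on learning subjects
    holdout_scores: pd.Series | None    # global model on held-out subjects


@dataclass
class ExperimentBundle:
    mode: str
    outcomes: list[RunOutcome]

    def holdout_means(self) -> list[float]:
        return [float(o.holdout_scores.mean()) for o in self.outcomes
                if o.holdout_scores is not None]


def run_experiment(train_sets: dict[str, pd.DataFrame],
                   test_sets: dict[str, pd.DataFrame],
                   grammar: Grammar,
                   config: FederationConfig,
                   holdout_test_sets: dict[str, pd.DataFrame] | None = None,
                   ) -> ExperimentBundle:
    """Run the full protocol: evolve, cross-evaluate, select the global
    model, and (optionally) measure it on held-out patients.

    ``train_sets``/``test_sets`` cover the learning patients;
    ``holdout_test_sets`` are patients that never participate in
    evolution and only see the selected global model.
    """
    outcomes = []
    for run in range(config.runs):
        result = run_federation(train_sets, grammar, config, run_index=run)
        models = {m.slave_id: m.phenotype for m in result.final_models}
        matrix = cross_evaluate(models, test_sets)
        gid = select_global_model(matrix)
        phenotype = models[gid]
        learning = matrix.frame.loc[gid]
        holdout = None
        if holdout_test_sets:
            holdout_cm = cross_evaluate({gid: phenotype}, holdout_test_sets)
            holdout = holdout_cm.frame.loc[gid]
        outcomes.append(RunOutcome(result, matrix, gid, phenotype,
                                   learning, holdout))
    return ExperimentBundle(config.mode, outcomes)


def comparison_matrix(bundles: dict[str, RunOutcome]) -> ResultMatrix:
    """Subjects x algorithms weighted-F1 table for the statistics module.

    Each algorithm (bundle key) is represented by its selected global
    model's per-subject scores: learning subjects from the
    cross-evaluation row, held-out subjects from the generalization
    scores.
    """
    algos = list(bundles)
    columns = {}
    for name, outcome in bundles.items():
        scores = outcome.learning_scores
        if outcome.holdout_scores is not None:
            scores = pd.concat([scores, outcome.holdout_scores])
        columns[name] = scores
    frame = pd.DataFrame(columns)
    if frame.isna().any().any():
        raise ValueError("algorithms were evaluated on different subjects")
    return ResultMatrix(frame.to_numpy(), [str(i) for i in frame.index], algos)
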