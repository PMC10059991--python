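"""Generational Grammatical Evolution with weighted-F1 fitness.

One evolutionary run searches, for a single patient, the space of
forecasting expressions defined by the glucose grammar.  Fitness of an
expression is the class-frequency-weighted F1 of its predicted glycemic
bands against the true bands on the local training samples (higher is
better); invalid individuals — genomes whose derivation does not
terminate — score 0 and sort below every valid individual.

Operators follow standard GE practice: tournament selection,
variable-length one-point crossover with cut points inside the used
codons, per-individual int-flip mutation (a fixed number of single-codon
events), and elitism of one so the best-so-far fitness is monotone
non-decreasing.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import classify, weighted_f1_from_labels
from .grammar import EVAL_FUNCS, Grammar, map_genome, random_genome


@dataclass(frozen=True)
class EAConfig:
    """Evolution settings (defaults are the full-scale study settings)."""

    population_size: int = 200
    generations: int = 500
    tournament_size: int = 4
    p_crossover: float = 0.9
    p_mutation: float = 0.1
    mutation_events: int = 1
    codon_size: int = 100_000
    max_init_depth: int = 10
    max_depth: int = 17
    max_wraps: int = 2
    max_genome_length: int = 500
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_crossover, self.p_mutation):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        for name in ("population_size", "tournament_size", "codon_size",
                     "max_genome_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.generations < 0 or self.elitism < 0:
            raise ValueError("generations and elitism must be >= 0")


@dataclass
class Individual:
    genome: list[int]
    phenotype: str | None = None
    used_codons: int = 0
    fitness: float = 0.0

    @property
    def valid(self) -> bool:
        return self.phenotype is not None

    def copy(self) -> "Individual":
        return replace(self, genome=list(self.genome))


class ExpressionEvaluator:
    """Compiles and scores phenotype strings on a fixed sample table.

    Evaluation is fully vectorised: every feature column is a numpy
    array, protected functions keep everything total, and any non-finite
    prediction falls into the -1 sentinel band (pure misclassification).
    Compiled code and fitness are cached per phenotype, which preserves
    determinism because caching never touches the RNG.
    """

    def __init__(self, samples: pd.DataFrame):
        if len(samples) == 0:
            raise ValueError("empty sample set")
        self.n = len(samples)
        self.env = {name: samples[name].to_numpy(dtype=float)
                    for name in samples.columns
                    if name not in ("t", "split", "target_glucose", "target_class")}
        self.env.update(EVAL_FUNCS)
        self.y = samples["target_class"].to_numpy(dtype=np.int64)
        self._fitness_cache: dict[str, float] = {}
        self.evaluations = 0

    def predict_values(self, phenotype: str) -> np.ndarray:
        """Raw model output Ghat on every sample (may be non-finite)."""
        code = compile(phenotype, "<expr>", "eval")
        with np.errstate(all="ignore"):
            out = eval(code, {"__builtins__": {}}, self.env)  # noqa: S307
        return np.broadcast_to(np.asarray(out, dtype=float), (self.n,))

    def predict_classes(self, phenotype: str) -> np.ndarray:
        return classify(self.predict_values(phenotype))

    def fitness(self, phenotype: str | None) -> float:
        if phenotype is None:
            return 0.0
        cached = self._fitness_cache.get(phenotype)
        if cached is not None:
            return cached
        self.evaluations += 1
        try:
            score = weighted_f1_from_labels(self.y, self.predict_classes(phenotype))
        except (RecursionError, MemoryError, SyntaxError):
            score = 0.0   # pathologically deep expression: treat as invalid
        self._fitness_cache[phenotype] = score
        return score


def predict_expression(phenotype: str,
                       samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one forecasting expression on a sample table.

    Returns ``(values, classes)``: the continuous forecasts Ghat(t+h*dt)
    and their glycemic bands (-1 where the forecast is non-finite or
    non-positive).
    """
    frame = samples.copy()
    if "target_class" not in frame:
        frame["target_class"] = 0
    ev = ExpressionEvaluator(frame)
    values = np.array(ev.predict_values(phenotype))
    return values, classify(values)


def tournament_select(population: list[Individual], rng: np.random.Generator,
                      size: int = 4) -> Individual:
    """Best of ``size`` uniform draws with replacement; ties go to the
    earlier population index."""
    if not population:
        raise ValueError("empty population")
    idx = rng.integers(0, len(population), size=size)
    best = min(idx, key=lambda i: (-population[i].fitness, i))
    return population[int(best)]


def one_point_crossover(g1: list[int], g2: list[int], used1: int, used2: int,
                        rng: np.random.Generator,
                        p: float = 0.9) -> tuple[list[int], list[int]]:
    """Variable-length one-point crossover with per-parent cut points.

    Cut points are drawn within each parent's used codons (cut 0 swaps
    the whole genome); with probability 1-p the parents pass through
    unchanged.
    """
    if rng.random() >= p:
        return list(g1), list(g2)
    hi1 = max(used1, 1) if used1 else len(g1)
    hi2 = max(used2, 1) if used2 else len(g2)
    cut1 = int(rng.integers(0, min(hi1, len(g1)) + 1))
    cut2 = int(rng.integers(0, min(hi2, len(g2)) + 1))
    c1 = list(g1[:cut1]) + list(g2[cut2:])
    c2 = list(g2[:cut2]) + list(g1[cut1:])
    return (c1 or list(g1)), (c2 or list(g2))


def int_flip_mutation(genome: list[int], rng: np.random.Generator,
                      p: float = 0.1, events: int = 1,
                      codon_size: int = 100_000,
                      used_codons: int | None = None) -> list[int]:
    """With probability ``p``, apply ``events`` single-codon replacements
    at uniformly chosen positions (uniform new value in [0, codon_size)).

    When ``used_codons`` is given, mutation targets the expressed part of
    the genome (standard GE practice: flipping junk tail codons would be
    a silent no-op).
    """
    if rng.random() >= p:
        return list(genome)
    out = list(genome)
    hi = min(used_codons, len(out)) if used_codons else len(out)
    for _ in range(events):
        pos = int(rng.integers(0, hi))
        out[pos] = int(rng.integers(0, codon_size))
    return out


@dataclass
class EvolutionState:
    """A stepped GE run: initialise once, then advance generation by
    generation (the federation layer interleaves migrations between
    steps)."""

    grammar: Grammar
    evaluator: ExpressionEvaluator
    config: EAConfig
    rng: np.random.Generator = field(init=False)
    population: list[Individual] = field(init=False)
    generation: int = 0
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        self.population = []
        for _ in range(cfg.population_size):
            genome = random_genome(self.grammar, self.rng,
                                   codon_size=cfg.codon_size,
                                   max_init_depth=cfg.max_init_depth)
            self.population.append(self._make(genome))
        self.history.append(self.best.fitness)

    def _make(self, genome: list[int]) -> Individual:
        genome = genome[: self.config.max_genome_length]
        phenotype, used = map_genome(genome, self.grammar,
                                     max_wraps=self.config.max_wraps,
                                     max_depth=self.config.max_depth)
        return Individual(genome, phenotype, used,
                          self.evaluator.fitness(phenotype))

    @property
    def best(self) -> Individual:
        return min(self.population, key=lambda ind: -ind.fitness)

    def step(self) -> None:
        """Produce the next generation: elitism, tournament selection,
        crossover, mutation."""
        cfg = self.config
        elite = sorted(range(len(self.population)),
                       key=lambda i: (-self.population[i].fitness, i))
        new: list[Individual] = [self.population[i].copy()
                                 for i in elite[: cfg.elitism]]
        while len(new) < cfg.population_size:
            p1 = tournament_select(self.population, self.rng, cfg.tournament_size)
            p2 = tournament_select(self.population, self.rng, cfg.tournament_size)
            c1, c2 = one_point_crossover(p1.genome, p2.genome,
                                         p1.used_codons, p2.used_codons,
                                         self.rng, cfg.p_crossover)
            for child in (c1, c2):
                if len(new) >= cfg.population_size:
                    break
                child = child[: cfg.max_genome_length]
                _, used = map_genome(child, self.grammar,
                                     max_wraps=cfg.max_wraps,
                                     max_depth=cfg.max_depth)
                mutated = int_flip_mutation(child, self.rng, cfg.p_mutation,
                                            cfg.mutation_events, cfg.codon_size,
                                            used_codons=used)
                new.append(self._make(mutated))
        self.population = new
        self.generation += 1
        self.history.append(self.best.fitness)

    def integrate_immigrants(self, immigrants: list[Individual]) -> int:
        """Worst-replacement integration of already-locally-scored
        immigrants; returns the number of replacements made.

        Immigrants are tried best-first; each replaces the current worst
        population member iff its local fitness strictly exceeds that
        member's.  Population size never changes.
        """
        replaced = 0
        for im in sorted(immigrants, key=lambda ind: -ind.fitness):
            worst = min(range(len(self.population)),
                        key=lambda i: (self.population[i].fitness, -i))
            if im.fitness > self.population[worst].fitness:
                self.population[worst] = im.copy()
                replaced += 1
            else:
                break
        return replaced


def run_ea(samples: pd.DataFrame, grammar: Grammar, config: EAConfig,
           generation_hook=None) -> tuple[Individual, list[float]]:
    """Run a full GE optimisation on one patient's training samples.

    ``generation_hook(state)`` — if given — is called at the top of every
    generation loop iteration (generations 0 .. generations-1) before
    breeding; this is the federation layer's entry point for migration.
    Returns the final best individual and the best-fitness history
    (generation 0 entry is the best of the random initial population).
    """
    state = EvolutionState(grammar, ExpressionEvaluator(samples), config)
    for _ in range(config.generations):
        if generation_hook is not None:
            generation_hook(state)
        state.step()
    return state.best.copy(), list(state.history)
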