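"""Federation protocol tests: migration, privacy, cross-evaluation."""

import numpy as np
import pandas as pd
import pytest

import glucofed as gf
from glucofed.benchmark import (FLEA_CROSS_EVAL, FLEA_HELDOUT_F1,
                                NONFL_CROSS_EVAL, NONFL_HELDOUT_F1)
from glucofed.evolve import EAConfig
from glucofed.federation import (MODE_FLEA, MODE_NONFL, CrossEvalMatrix,
                                 FederationConfig, MigrationMessage,
                                 cross_evaluate, derive_seed, run_experiment,
                                 run_federation, select_global_model)
from glucofed.grammar import glucose_grammar
from glucofed.windows import preprocess_series


@pytest.fixture(scope="module")
def two_patients():
    cfg = gf.CohortConfig(n_patients=2, days=2.0, seed=3)
    sets = {}
    for i in range(2):
        s = gf.assign_split(gf.simulate_patient(cfg, i), 0.25)
        samples = preprocess_series(s)
        sets[s.patient_id] = {
            "train": samples[samples.split == "train"].reset_index(drop=True),
            "test": samples[samples.split == "test"].reset_index(drop=True),
        }
    return sets


@pytest.fixture(scope="module")
def grammar_():
    return glucose_grammar()


def _train(sets):
    return {pid: d["train"] for pid, d in sets.items()}


SMALL_EA = EAConfig(population_size=10, generations=20, seed=0)


class TestProtocol:
    def test_message_count_law(self, two_patients, grammar_):
        """floor(gmax / interval) outbound messages per slave."""
        cfg = FederationConfig(ea=SMALL_EA, migration_interval=5,
                               mode=MODE_FLEA, runs=1, master_seed=1)
        res = run_federation(_train(two_patients), grammar_, cfg)
        assert res.migration_rounds == 20 // 5
        # per round each slave sends one best-model message; the two final
        # models are logged on top of that
        assert len(res.message_log) == 2 * (20 // 5) + 2

    def test_single_slave_equals_nonfl(self, two_patients, grammar_):
        one = dict(list(_train(two_patients).items())[:1])
        fl = run_federation(one, grammar_, FederationConfig(
            ea=SMALL_EA, migration_interval=5, mode=MODE_FLEA, runs=1,
            master_seed=2))
        nf = run_federation(one, grammar_, FederationConfig(
            ea=SMALL_EA, migration_interval=5, mode=MODE_NONFL, runs=1,
            master_seed=2))
        assert fl.histories == nf.histories
        assert fl.final_models[0].phenotype == nf.final_models[0].phenotype

    def test_interval_beyond_gmax_equals_nonfl(self, two_patients, grammar_):
        fl = run_federation(_train(two_patients), grammar_, FederationConfig(
            ea=SMALL_EA, migration_interval=1000, mode=MODE_FLEA, runs=1,
            master_seed=2))
        nf = run_federation(_train(two_patients), grammar_, FederationConfig(
            ea=SMALL_EA, migration_interval=1000, mode=MODE_NONFL, runs=1,
            master_seed=2))
        assert fl.migration_rounds == 0
        assert fl.histories == nf.histories

    def test_migration_never_decreases_best(self, two_patients, grammar_):
        cfg = FederationConfig(ea=SMALL_EA, migration_interval=4,
                               mode=MODE_FLEA, runs=1, master_seed=3)
        res = run_federation(_train(two_patients), grammar_, cfg)
        for hist in res.histories.values():
            assert all(a <= b + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_privacy_of_messages(self, two_patients, grammar_):
        """No message field may carry sample-level data: only scalars,
        strings and the integer genome cross the wire."""
        cfg = FederationConfig(ea=SMALL_EA, migration_interval=10,
                               mode=MODE_FLEA, runs=1, master_seed=4)
        res = run_federation(_train(two_patients), grammar_, cfg)
        assert res.message_log
        for msg in res.message_log:
            assert isinstance(msg, MigrationMessage)
            assert isinstance(msg.slave_id, str)
            assert isinstance(msg.generation, int)
            assert isinstance(msg.fitness, float)
            assert msg.phenotype is None or isinstance(msg.phenotype, str)
            assert all(isinstance(c, int) for c in msg.genome)
            assert not any(isinstance(v, (np.ndarray, pd.DataFrame, pd.Series,
                                          dict, list))
                           for v in (msg.slave_id, msg.generation,
                                     msg.phenotype, msg.fitness))

    def test_seed_derivation_stable_and_bounded(self):
        assert derive_seed(0, 0, 0) == derive_seed(0, 0, 0)
        seeds = {derive_seed(5, r, s) for r in range(4) for s in range(4)}
        assert len(seeds) == 16
        assert all(0 <= s < 2 ** 31 for s in seeds)


class TestCrossEvaluation:
    def test_identical_patients_constant_rows(self, two_patients, grammar_):
        test = list(two_patients.values())[0]["test"]
        models = {"a": "(g0-0+0)+0", "b": "(g1-0+0)*1"}
        m = cross_evaluate(models, {"p1": test, "p2": test.copy()})
        assert m.frame.loc["a", "p1"] == m.frame.loc["a", "p2"]
        assert m.frame.loc["b", "p1"] == m.frame.loc["b", "p2"]

    def test_margins_match_aggregate(self):
        frame = pd.DataFrame(np.random.default_rng(0).uniform(size=(3, 4)),
                             index=list("abc"), columns=list("wxyz"))
        m = CrossEvalMatrix(frame)
        for label, row in frame.iterrows():
            mean, sd = gf.aggregate(row.to_numpy())
            assert m.row_margins().loc[label, "mean"] == pytest.approx(mean)
            assert m.row_margins().loc[label, "sd"] == pytest.approx(sd)

    def test_published_heldout_margins(self):
        m = CrossEvalMatrix(pd.DataFrame(
            [NONFL_HELDOUT_F1, FLEA_HELDOUT_F1], index=["non-FL", "FLEA"],
            columns=list("abcdef")))
        margins = m.row_margins()
        assert round(margins.loc["FLEA", "mean"], 4) == 0.6506
        assert round(margins.loc["non-FL", "mean"], 4) == 0.6345

    def test_global_model_selection_published_tables(self):
        assert select_global_model(
            CrossEvalMatrix(NONFL_CROSS_EVAL)) == "model 570"
        assert select_global_model(
            CrossEvalMatrix(FLEA_CROSS_EVAL)) == "model 575"

    def test_single_model_matrix(self):
        m = CrossEvalMatrix(pd.DataFrame([[0.5, 0.6]], index=["only"],
                                         columns=["a", "b"]))
        assert select_global_model(m) == "only"

    def test_tie_goes_to_lower_id(self):
        m = CrossEvalMatrix(pd.DataFrame([[0.5, 0.5], [0.5, 0.5]],
                                         index=["a", "b"], columns=["x", "y"]))
        assert select_global_model(m) == "a"


class TestExperiment:
    def test_single_patient_nonfl_reduces_to_run_ea(self, two_patients,
                                                    grammar_):
        from glucofed.evolve import run_ea
        from glucofed.federation import derive_seed
        from dataclasses import replace

        pid, data = list(two_patients.items())[0]
        cfg = FederationConfig(ea=SMALL_EA, mode=MODE_NONFL, runs=1,
                               master_seed=6)
        bundle = run_experiment({pid: data["train"]}, {pid: data["test"]},
                                grammar_, cfg)
        outcome = bundle.outcomes[0]
        ea = replace(SMALL_EA, seed=derive_seed(6, 0, 0))
        best, _ = run_ea(data["train"], grammar_, ea)
        assert outcome.global_phenotype == best.phenotype
        assert outcome.global_model_id == pid

    def test_experiment_bundle_shapes(self, two_patients, grammar_):
        cfg = FederationConfig(ea=SMALL_EA, migration_interval=10,
                               mode=MODE_FLEA, runs=2, master_seed=7)
        train = _train(two_patients)
        test = {pid: d["test"] for pid, d in two_patients.items()}
        bundle = run_experiment(train, test, grammar_, cfg,
                                holdout_test_sets=test)
        assert len(bundle.outcomes) == 2
        for oc in bundle.outcomes:
            assert oc.cross_eval.frame.shape == (2, 2)
            assert oc.global_model_id in train
            assert len(oc.holdout_scores) == 2
        assert len(bundle.holdout_means()) == 2
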