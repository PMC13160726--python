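import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from profuse.data_model import (
    CohortTable,
    DesignMatrix,
    Encoder,
    ModalityPartition,
    VariableSpec,
    stage_eligible,
)
from profuse.baselines import split_cohort
from profuse.fusion import (
    EmptyStageError,
    FittedChain,
    fit_chain,
    fit_residual_stage,
    fit_stage1,
    order_modalities,
)
from profuse.synthetic import default_params, generate, plant_signal


def two_block_cohort(n=600, d1=1.2, d2=1.2, seed=0, vars_per_block=2):
    params = default_params(n_samples=n, n_blocks=2, vars_per_block=vars_per_block,
                            effect=d1)
    params = plant_signal(params, "block2", d2)
    table, _ = generate(params, seed=seed)
    return table, params.partition()


class TestFitStage1:
    def test_separable_feature_training_accuracy_one(self):
        y = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        frame = pd.DataFrame({"flag": y.astype(float)},
                             index=[f"s{i}" for i in range(20)])
        stage = fit_stage1(DesignMatrix(frame, {}), y, family="decision_tree", seed=0)
        pred = stage.model.predict(frame.to_numpy())
        assert (pred == y).all()

    def test_empty_matrix_raises(self):
        frame = pd.DataFrame({"x": []})
        with pytest.raises(EmptyStageError):
            fit_stage1(DesignMatrix(frame, {}), np.array([]), family="gbt")

    def test_pure_noise_auc_near_chance(self):
        # oracle: labels independent of the feature -> test AUC ~ 0.5
        from profuse.metrics import auc
        aucs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 2000
            y = rng.integers(0, 2, n)
            x = rng.standard_normal((n, 1))
            frame = pd.DataFrame(x, columns=["noise"], index=[f"s{i}" for i in range(n)])
            stage = fit_stage1(DesignMatrix(frame.iloc[:1000], {}), y[:1000],
                               family="logistic", seed=s)
            p = stage.model.predict_proba(x[1000:])[:, 1]
            aucs.append(auc(p, y[1000:]))
        assert 0.45 < float(np.mean(aucs)) < 0.55

    def test_one_block_chain_equals_standalone(self):
        """Bitwise stage-1 equivalence under matched seed and oversampling."""
        table, partition = two_block_cohort(n=300)
        part1 = partition.prefix(1)
        chain = fit_chain(table, part1, families="gbt", seed=7)

        ids = stage_eligible(table, part1, 1)
        sub = table.subset(ids)
        enc = Encoder([table.spec(v) for v in part1.variables_upto(1)]).fit(sub, ids)
        standalone = fit_stage1(enc.transform(sub), sub.outcome.to_numpy(),
                                family="gbt", seed=7)

        X = enc.transform(sub).to_numpy()
        p_chain = chain.stages[0].model.predict_proba(X)[:, 1]
        p_alone = standalone.model.predict_proba(X)[:, 1]
        np.testing.assert_array_equal(p_chain, p_alone)


class TestResidualStage:
    def test_outcome_as_feature_drives_training_error_to_zero(self):
        table, partition = two_block_cohort(n=400, d1=0.8, seed=1)
        # replace block 2 by a copy of the outcome: a perfect corrector exists
        table.values["block2_v1"] = table.outcome.astype(float)
        table.values["block2_v2"] = table.outcome.astype(float)
        chain = fit_chain(table, partition, families="gbt", seed=0)
        pred = chain.predict(table)
        y = table.outcome.to_numpy()
        err = np.mean(np.abs(pred.trace[:, 1] - y))
        assert err < 0.05

    def test_constant_block_leaves_predictions_unchanged_stacking(self):
        """Stacking mode: a constant block carries no signal -> ~no change."""
        table, partition = two_block_cohort(n=1200, d1=1.2, seed=3)
        table.values["block2_v1"] = 0.0
        table.values["block2_v2"] = 0.0
        train, test = split_cohort(table, split_seed=0)
        chain = fit_chain(table.subset(train), partition, families="logistic",
                          residual_mode="stacking", seed=0)
        pred = chain.predict(table.subset(test))
        mad = np.nanmean(np.abs(pred.trace[:, 1] - pred.trace[:, 0]))
        assert mad < 0.02

    def test_constant_block_preserves_decisions_logit_residual(self):
        # the logit-residual corrector sharpens probabilities symmetrically
        # around 0.5, so hard decisions survive an uninformative block
        table, partition = two_block_cohort(n=1200, d1=1.2, seed=3)
        table.values["block2_v1"] = 0.0
        table.values["block2_v2"] = 0.0
        train, test = split_cohort(table, split_seed=0)
        chain = fit_chain(table.subset(train), partition, families="logistic",
                          residual_mode="logit_residual", seed=0)
        pred = chain.predict(table.subset(test))
        flips = np.mean((pred.trace[:, 1] >= 0.5) != (pred.trace[:, 0] >= 0.5))
        assert flips < 0.02

    def test_perfect_prior_yields_near_zero_residuals(self):
        table, partition = two_block_cohort(n=400, d1=0.5, seed=2)
        # block 1 holds the outcome itself -> stage 1 is (almost) perfect
        table.values["block1_v1"] = table.outcome.astype(float)
        table.values["block1_v2"] = table.outcome.astype(float)
        chain = fit_chain(table, partition, families="gbt",
                          residual_mode="logit_residual", seed=0)
        pred = chain.predict(table)
        np.testing.assert_allclose(pred.trace[:, 1], pred.trace[:, 0], atol=0.02)

    def test_requires_prior_stages(self):
        table, partition = two_block_cohort(n=100)
        empty_chain = FittedChain(partition=partition, stages=[],
                                  variables=list(table.variables))
        with pytest.raises(ValueError):
            fit_residual_stage(empty_chain, table, t=2)


class TestFitChain:
    def test_t1_chain_reduces_to_stage1(self):
        table, partition = two_block_cohort(n=200)
        chain = fit_chain(table, partition.prefix(1), families="logistic", seed=0)
        assert chain.depth == 1
        pred = chain.predict(table)
        assert (pred.depth == 1).all()

    def test_two_stage_beats_one_stage_on_split_signal(self):
        accs = {1: [], 2: []}
        for s in range(3):
            table, partition = two_block_cohort(n=2000, d1=0.7, d2=0.7, seed=s)
            train, test = split_cohort(table, split_seed=s)
            y = table.outcome.loc[test].to_numpy()
            for depth in (1, 2):
                chain = fit_chain(table.subset(train), partition.prefix(depth),
                                  families="logistic", seed=s)
                pred = chain.predict(table.subset(test))
                accs[depth].append(np.mean(pred.label == y))
        assert np.mean(accs[2]) > np.mean(accs[1])

    def test_six_blocks_gives_six_nested_stages(self):
        params = replace(default_params(n_samples=800, availability=0.8), nested=True)
        table, _ = generate(params, seed=0)
        chain = fit_chain(table, params.partition(), families="logistic", seed=0)
        assert chain.depth == 6
        sizes = [len(s.train_ids) for s in chain.stages]
        for a, b in zip(sizes, sizes[1:]):
            assert b <= a
        for t, stage in enumerate(chain.stages, 1):
            assert set(stage.train_ids) <= set(chain.stages[0].train_ids)
            if t > 1:
                assert stage.feature_columns[-1] == "prior_prediction"

    def test_truncates_on_empty_stage(self, caplog):
        params = default_params(n_samples=150, n_blocks=3)
        params = replace(params, availability={"block1": (1.0, 1.0),
                                               "block2": (1.0, 1.0),
                                               "block3": (0.0, 0.0)})
        table, _ = generate(params, seed=0)
        chain = fit_chain(table, params.partition(), families="logistic", seed=0)
        assert chain.depth == 2

    def test_determinism(self):
        table, partition = two_block_cohort(n=300)
        p1 = fit_chain(table, partition, families="gbt", seed=5).predict(table)
        p2 = fit_chain(table, partition, families="gbt", seed=5).predict(table)
        np.testing.assert_array_equal(p1.probability, p2.probability)
        np.testing.assert_array_equal(p1.trace, p2.trace)

    def test_probabilities_clipped_and_finite(self):
        table, partition = two_block_cohort(n=300, d1=3.0, d2=3.0)
        chain = fit_chain(table, partition, families="gbt", seed=0)
        pred = chain.predict(table)
        eps = chain.eps
        assert np.all(np.isfinite(pred.trace[~np.isnan(pred.trace)]))
        assert np.all(pred.probability >= eps)
        assert np.all(pred.probability <= 1 - eps)

    def test_bad_residual_mode_rejected(self):
        table, partition = two_block_cohort(n=100)
        with pytest.raises(ValueError):
            fit_chain(table, partition, residual_mode="magic")


class TestPredictDepth:
    @pytest.fixture
    def chain_and_table(self):
        params = default_params(n_samples=400, n_blocks=4, vars_per_block=1,
                                effect=1.0)
        table, _ = generate(params, seed=0)
        chain = fit_chain(table, params.partition(), families="logistic", seed=0)
        return chain, table, params

    def test_all_blocks_present_full_depth(self, chain_and_table):
        chain, table, _ = chain_and_table
        pred = chain.predict(table)
        assert (pred.depth == 4).all()
        np.testing.assert_array_equal(pred.probability, pred.trace[:, 3])

    def test_gap_stops_prefix(self, chain_and_table):
        chain, table, _ = chain_and_table
        t2 = table.subset(table.sample_ids[:5])
        t2.values.loc[:, "block3_v1"] = np.nan  # blocks {1,2,4} present
        pred = chain.predict(t2)
        assert (pred.depth == 2).all()
        np.testing.assert_array_equal(pred.probability, pred.trace[:, 1])
        assert np.isnan(pred.trace[:, 2]).all()

    def test_block1_missing_flagged_unpredictable(self, chain_and_table):
        chain, table, _ = chain_and_table
        t2 = table.subset(table.sample_ids[:3])
        t2.values.loc[t2.sample_ids[0], "block1_v1"] = np.nan
        pred = chain.predict(t2)
        assert pred.depth[0] == 0
        assert np.isnan(pred.probability[0])
        assert pred.label[0] == -1
        assert pred.depth[1] == 4

    def test_only_block1_gives_stage1_output(self, chain_and_table):
        chain, table, _ = chain_and_table
        t2 = table.subset(table.sample_ids[:4])
        for v in ["block2_v1", "block3_v1", "block4_v1"]:
            t2.values.loc[:, v] = np.nan
        pred = chain.predict(t2)
        assert (pred.depth == 1).all()
        np.testing.assert_array_equal(pred.probability, pred.trace[:, 0])

    def test_prediction_csv_roundtrip(self, chain_and_table, tmp_path):
        chain, table, _ = chain_and_table
        pred = chain.predict(table)
        path = tmp_path / "pred.csv"
        pred.to_csv(path)
        back = pd.read_csv(path, index_col="sample_id")
        assert list(back.columns) == ["depth", "probability", "label_at_0.5",
                                      "stage_1", "stage_2", "stage_3", "stage_4"]
        np.testing.assert_allclose(back["probability"].to_numpy(), pred.probability)


class TestSerialization:
    def test_roundtrip_reproduces_predictions_exactly(self, tmp_path):
        table, partition = two_block_cohort(n=250)
        chain = fit_chain(table, partition, families="gbt", seed=3)
        before = chain.predict(table)
        path = tmp_path / "chain.pkl"
        chain.save(path)
        after = FittedChain.load(path).predict(table)
        np.testing.assert_array_equal(before.trace, after.trace)
        np.testing.assert_array_equal(before.probability, after.probability)

    def test_load_rejects_other_objects(self, tmp_path):
        import pickle
        path = tmp_path / "junk.pkl"
        with open(path, "wb") as fh:
            pickle.dump({"not": "a chain"}, fh)
        with pytest.raises(TypeError):
            FittedChain.load(path)


class TestOrderModalities:
    def test_single_candidate_trivially_placed(self):
        table, partition = two_block_cohort(n=200)
        ordered = order_modalities(table, partition, families="logistic",
                                   inner_folds=3, seed=0)
        assert ordered.block_names == ["block1", "block2"]

    def test_informative_block_ordered_before_noise(self):
        wins = 0
        for s in range(10):
            params = default_params(n_samples=500, n_blocks=3, vars_per_block=2,
                                    effect=0.8)
            params = plant_signal(params, "block2", 0.0)   # noise candidate
            params = plant_signal(params, "block3", 1.5)   # signal candidate
            table, _ = generate(params, seed=s)
            ordered = order_modalities(table, params.partition(),
                                       families="logistic", inner_folds=3, seed=s)
            if ordered.block_names[1] == "block3":
                wins += 1
        assert wins >= 8

    def test_duplicate_blocks_keep_declaration_order(self):
        params = default_params(n_samples=300, n_blocks=3, vars_per_block=1,
                                effect=1.0)
        table, _ = generate(params, seed=0)
        # make block3 a byte-identical duplicate of block2
        table.values["block3_v1"] = table.values["block2_v1"]
        ordered = order_modalities(table, params.partition(), families="logistic",
                                   inner_folds=3, seed=0)
        assert ordered.block_names == ["block1", "block2", "block3"]

    def test_fixed_prefix_pinned(self):
        params = default_params(n_samples=300, n_blocks=4, vars_per_block=1,
                                effect=1.0)
        part = ModalityPartition(params.partition().blocks, fixed_prefix=2)
        table, _ = generate(params, seed=0)
        ordered = order_modalities(table, part, families="logistic",
                                   inner_folds=3, seed=0)
        assert ordered.block_names[:2] == ["block1", "block2"]

    def test_too_few_folds_rejected(self):
        table, partition = two_block_cohort(n=100)
        with pytest.raises(ValueError):
            order_modalities(table, partition, inner_folds=1)
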