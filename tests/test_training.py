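"""Epoch scheduling, the multi-task loop, fine-tuning, iteration plans."""
import numpy as np
import pytest

from clinsts.autodiff import tensor
from clinsts.core import SentenceExample, TaskSpec
from clinsts.evaluation import pearson_correlation
from clinsts.model import EncoderConfig, ModelState
from clinsts.synthetic import GeneratorConfig, corpus_sentences, generate_all
from clinsts.tokenizer import train_subword_vocab
from clinsts.training import (IterationPlan, TrainConfig, _SGD,
                              build_epoch_schedule, finetune_target,
                              mtl_train, predict_scores, run_iteration_plans)


def _examples(task, n, pair=True):
    return [SentenceExample(f"{task}-{i}", task, f"alpha beta {i % 5}",
                            f"beta gamma {i % 3}" if pair else None,
                            label=float(i % 6)) for i in range(n)]


class TestSchedule:
    def test_single_dataset_degenerate(self):
        ds = {"a": _examples("a", 4)}
        schedule = build_epoch_schedule(ds, batch_size=2, seed=0)
        assert len(schedule) == 2
        assert all(b.task == "a" and len(b.examples) == 2 for b in schedule)

    def test_batch_counts_proportional_to_size(self):
        ds = {"A": _examples("A", 8), "B": _examples("B", 4)}
        schedule = build_epoch_schedule(ds, batch_size=2, seed=1)
        assert len(schedule) == 6
        tasks = [b.task for b in schedule]
        assert tasks.count("A") == 4 and tasks.count("B") == 2

    def test_seeded_determinism_and_conservation(self):
        ds = {"A": _examples("A", 9), "B": _examples("B", 5)}
        one = build_epoch_schedule(ds, 2, seed=42)
        two = build_epoch_schedule(ds, 2, seed=42)
        other = build_epoch_schedule(ds, 2, seed=43)
        ids = lambda sched: [[e.id for e in b.examples] for b in sched]
        assert ids(one) == ids(two)
        assert ids(one) != ids(other)
        # conservation: every example exactly once, per dataset
        flat = lambda sched: sorted(e.id for b in sched for e in b.examples)
        expected = sorted(e.id for exs in ds.values() for e in exs)
        assert flat(one) == expected == flat(other)
        # short final batch rather than dropped remainder
        sizes = sorted(len(b.examples) for b in one if b.task == "B")
        assert sizes == [1, 2, 2]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_epoch_schedule({"a": []}, 2, 0)


class TestSGDOracle:
    def test_one_step_matches_hand_gradient(self):
        # 1-parameter linear model, MSE: theta' = theta - eta*2*(theta*x - y)*x
        theta = tensor([0.0], requires_grad=True)
        x, y, eta = 1.0, 1.0, 0.1
        loss = (theta * x - y) ** 2.0
        loss.backward()
        _SGD(eta).step("theta", theta, np.asarray(theta.grad))
        assert theta.data[0] == pytest.approx(0.2)


@pytest.fixture(scope="module")
def small_world():
    cfg = GeneratorConfig(seed=11, sizes={"sts": 48, "stsb": 48, "pairclass": 48,
                                          "topic": 48, "ner": 24, "noise": 48})
    datasets = generate_all(cfg)
    vocab = train_subword_vocab(corpus_sentences(datasets), 300)
    enc = EncoderConfig(vocab_size=len(vocab), width=16, layers=1, heads=2,
                        ffn_width=32, max_len=48)
    from clinsts.pipeline import TASK_SPECS
    state = ModelState(enc, [TASK_SPECS[n] for n in sorted(TASK_SPECS)], seed=11)
    return datasets, vocab, state


class TestMtlTrain:
    def test_zero_epochs_is_identity(self, small_world):
        datasets, vocab, state = small_world
        st = state.copy()
        cfg = TrainConfig(epochs=0, seed=0, max_len=48)
        log = mtl_train(st, {"pairclass": datasets["pairclass"]}, cfg, vocab)
        assert log.empty
        for name, p in st.params.items():
            np.testing.assert_array_equal(p.data, state.params[name].data)

    def test_reproducible_loss_log(self, small_world):
        datasets, vocab, state = small_world
        cfg = TrainConfig(epochs=2, batch_size=8, lr=1e-2, seed=5, max_len=48)
        ds = {"pairclass": datasets["pairclass"], "topic": datasets["topic"]}
        log1 = mtl_train(state.copy(), ds, cfg, vocab)
        log2 = mtl_train(state.copy(), ds, cfg, vocab)
        assert log1.equals(log2)

    def test_losses_decrease(self, small_world):
        datasets, vocab, state = small_world
        cfg = TrainConfig(epochs=8, batch_size=8, lr=1e-2, seed=3, max_len=48)
        ds = {"stsb": datasets["stsb"], "topic": datasets["topic"]}
        log = mtl_train(state.copy(), ds, cfg, vocab)
        for task in ds:
            curve = log[log.task == task].sort_values("epoch").mean_loss
            assert curve.iloc[-1] < curve.iloc[0]


class TestFinetune:
    def test_zero_epochs_identity(self, small_world):
        datasets, vocab, state = small_world
        st = state.copy()
        finetune_target(st, datasets["sts"], TrainConfig(epochs=0, max_len=48),
                        vocab)
        for name, p in st.params.items():
            np.testing.assert_array_equal(p.data, state.params[name].data)

    def test_only_shared_and_similarity_head_move(self, small_world):
        datasets, vocab, state = small_world
        st = state.copy()
        finetune_target(st, datasets["sts"][:16],
                        TrainConfig(epochs=1, batch_size=8, lr=1e-2, max_len=48),
                        vocab, task_name="sts")
        touched = set(st.trainable_for("sts"))
        for name, p in st.params.items():
            if name in touched:
                continue
            np.testing.assert_array_equal(p.data, state.params[name].data,
                                          err_msg=name)

    def test_reaches_high_training_correlation(self, small_world):
        datasets, vocab, state = small_world
        st = state.copy()
        train = datasets["sts"]
        finetune_target(st, train,
                        TrainConfig(epochs=25, batch_size=8, lr=5e-3, seed=12,
                                    max_len=48), vocab)
        gold = np.array([float(e.label) for e in train])
        preds = predict_scores(st, train, vocab, max_len=48)
        assert pearson_correlation(gold, preds) > 0.9

    def test_requires_similarity_head(self, small_world, tiny_vocab):
        datasets, vocab, _ = small_world
        enc = EncoderConfig(vocab_size=len(tiny_vocab), width=8, layers=1,
                            heads=2, ffn_width=16, max_len=32)
        state = ModelState(enc, [TaskSpec("t", "single_classification", ("a", "b"))])
        with pytest.raises(ValueError, match="pair_similarity"):
            finetune_target(state, datasets["sts"], TrainConfig(epochs=0),
                            tiny_vocab)


@pytest.fixture(scope="module")
def plan_run(small_world):
    datasets, vocab, state = small_world
    target = datasets["sts"]
    plans = [IterationPlan(1, ("stsb",)),
             IterationPlan(2, ("stsb", "noise"))]
    cfg = TrainConfig(epochs=1, batch_size=8, lr=5e-3, seed=2, max_len=48)
    aux = {n: datasets[n] for n in datasets if n != "sts"}
    return run_iteration_plans(state, plans, aux, target[:32], target[32:],
                               cfg, cfg, vocab)


class TestIterationPlans:
    def test_single_plan_is_best(self, small_world):
        datasets, vocab, state = small_world
        target = datasets["sts"]
        cfg = TrainConfig(epochs=1, batch_size=8, lr=5e-3, seed=2, max_len=48)
        plans, best, report = run_iteration_plans(
            state, [IterationPlan(1, ("topic",))],
            {"topic": datasets["topic"]}, target[:32], target[32:], cfg, cfg,
            vocab)
        assert best is plans[0]
        assert len(report) == 1 and report.best.iloc[0]

    def test_report_contains_all_plans_and_flags_argmax(self, plan_run):
        plans, best, report = plan_run
        assert len(report) == 2
        assert report.pcc.notna().all()
        assert report.loc[report.best, "iteration"].iloc[0] == best.index
        assert best.pcc == max(p.pcc for p in plans)

    def test_pcc_recomputable_from_saved_predictions(self, plan_run, small_world):
        datasets, _, _ = small_world
        target_eval = datasets["sts"][32:]
        gold = np.array([float(e.label) for e in target_eval])
        plans, _, _ = plan_run
        for plan in plans:
            again = pearson_correlation(gold, plan.predictions)
            assert abs(again - plan.pcc) < 1e-12

    def test_unknown_dataset_fails_fast(self, small_world):
        datasets, vocab, state = small_world
        cfg = TrainConfig(epochs=1, max_len=48)
        with pytest.raises(ValueError, match="unknown dataset"):
            run_iteration_plans(state, [IterationPlan(1, ("missing",))],
                                {}, datasets["sts"][:8], datasets["sts"][8:16],
                                cfg, cfg, vocab)
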