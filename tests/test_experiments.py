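"""Transfer-experiment orchestration: ordering, seeding, leakage, reproducibility."""

import numpy as np
import pytest

import simtransfer as st
from simtransfer.experiments import derive_seed


class TestDeriveSeed:
    def test_deterministic_and_context_sensitive(self):
        assert derive_seed(1, "a", 2) == derive_seed(1, "a", 2)
        assert derive_seed(1, "a", 2) != derive_seed(1, "a", 3)
        assert derive_seed(1, "a") != derive_seed(2, "a")

    def test_fits_in_31_bits(self):
        for master in (0, 1, 2**40, 123456789):
            assert 0 <= derive_seed(master, "x", 7) < 2**31


class TestOrderBySimilarity:
    def _simmat(self):
        names = ("A", "B", "C", "J")
        v = np.eye(4)
        v[3, 0] = v[0, 3] = 0.9
        v[3, 1] = v[1, 3] = 0.2
        v[3, 2] = v[2, 3] = 0.5
        v[0, 1] = v[1, 0] = 0.1
        v[0, 2] = v[2, 0] = 0.1
        v[1, 2] = v[2, 1] = 0.1
        return st.SimilarityMatrix(names, v)

    def test_descending_similarity(self):
        assert st.order_by_similarity(self._simmat(), "J") == ["A", "C", "B"]

    def test_ties_alphabetical(self):
        names = ("B", "A", "C", "J")
        v = np.eye(4)
        v[:3, 3] = v[3, :3] = 0.4
        v[0, 1] = v[1, 0] = v[0, 2] = v[2, 0] = v[1, 2] = v[2, 1] = 0.2
        mat = st.SimilarityMatrix(names, v)
        assert st.order_by_similarity(mat, "J") == ["A", "B", "C"]

    def test_target_excluded_and_unknown_rejected(self):
        mat = self._simmat()
        assert "J" not in st.order_by_similarity(mat, "J")
        with pytest.raises(KeyError):
            st.order_by_similarity(mat, "Z")


class TestRandomOrdering:
    def test_excludes_target_and_is_seeded(self):
        drugs = [f"d{i}" for i in range(8)]
        o1 = st.random_ordering(drugs, "d3", seed=5)
        o2 = st.random_ordering(drugs, "d3", seed=5)
        assert o1 == o2 and "d3" not in o1 and sorted(o1) == sorted(set(drugs) - {"d3"})
        assert st.random_ordering(drugs, "d3", seed=6) != o1


class _SpyTrainer:
    """Records every training/dev corpus it sees; predicts a constant label."""

    def __init__(self):
        self.seen = []

    def __call__(self, train, dev, config, cache=None):
        self.seen.append((train, dev))
        outer = self

        class _Model:
            def predict(self, docs, cache=None):
                return ["G-u"] * len(docs)

        return _Model()


class TestSingleTransfer:
    def test_self_transfer_on_separable_drug(self, coupled_world, fast_config):
        drugs, simmat, corpus = coupled_world
        names = [d.name for d in drugs]
        res = st.run_single_transfer(corpus, names, names[0], names[0], fast_config, seed=1)
        assert res.macro_f1 >= 0.95

    def test_identical_distributions_transfer_like_self(self, coupled_world, fast_config):
        drugs, simmat, corpus = coupled_world
        names = [d.name for d in drugs]
        same_class = [d.name for d in drugs if d.class_id == 0]
        res_self = st.run_single_transfer(
            corpus, names, same_class[0], same_class[0], fast_config, seed=1
        )
        res_cross = st.run_single_transfer(
            corpus, names, same_class[0], same_class[1], fast_config, seed=1
        )
        assert abs(res_cross.macro_f1 - res_self.macro_f1) < 0.15

    def test_disjoint_vocabulary_transfer_near_majority_level(self, fast_config):
        config = st.GeneratorConfig(
            n_drugs=4, n_classes=4, docs_per_drug=150, coupling=0.0, seed=7
        )
        drugs = st.generate_drug_set(config)
        corpus = st.generate_corpus(drugs, config)
        names = [d.name for d in drugs]
        res = st.run_single_transfer(corpus, names, names[0], names[1], fast_config, seed=2)
        # with no shared informative vocabulary, accuracy sits near the
        # majority-class rate (G-u: 0.38), far below the in-domain level
        assert res.accuracy < 0.6

    def test_unknown_drug_rejected(self, coupled_world, fast_config):
        drugs, _, corpus = coupled_world
        names = [d.name for d in drugs]
        with pytest.raises(ValueError):
            st.run_single_transfer(corpus, names, "nope", names[0], fast_config, seed=0)

    def test_no_target_document_in_training(self, coupled_world, fast_config):
        drugs, _, corpus = coupled_world
        names = [d.name for d in drugs]
        spy = _SpyTrainer()
        st.run_single_transfer(
            corpus, names, names[0], names[1], fast_config, seed=3, trainer=spy
        )
        target_ids = st.subcorpus(corpus, names[1]).doc_ids()
        for train, dev in spy.seen:
            assert not (train.source_ids() | dev.source_ids()) & target_ids


class TestTransferMatrix:
    def test_shape_range_and_reproducibility(self, coupled_world, fast_config):
        drugs, _, corpus = coupled_world
        names = [d.name for d in drugs][:3]
        tm1 = st.run_transfer_matrix(corpus, names, fast_config, seed=9)
        tm2 = st.run_transfer_matrix(corpus, names, fast_config, seed=9)
        assert tm1.f1.shape == (3, 3)
        assert tm1.f1.min() >= 0.0 and tm1.f1.max() <= 1.0
        assert np.array_equal(tm1.f1, tm2.f1) and np.array_equal(tm1.accuracy, tm2.accuracy)

    def test_diagonal_dominance_on_distinct_distributions(self, fast_config):
        config = st.GeneratorConfig(
            n_drugs=3, n_classes=3, docs_per_drug=200, coupling=0.0, seed=21
        )
        drugs = st.generate_drug_set(config)
        corpus = st.generate_corpus(drugs, config)
        tm = st.run_transfer_matrix(corpus, [d.name for d in drugs], fast_config, seed=4)
        assert tm.diagonal_mean() > tm.offdiagonal_mean()


class TestIncremental:
    def test_x_out_of_range_rejected(self, coupled_world, fast_config):
        drugs, simmat, corpus = coupled_world
        names = [d.name for d in drugs]
        ordering = st.order_by_similarity(simmat, names[0])
        for bad_x in (0, len(names)):
            with pytest.raises(ValueError):
                st.run_incremental(
                    corpus, names, names[0], ordering, bad_x, fast_config, seed=0
                )

    def test_ordering_containing_target_rejected(self, coupled_world, fast_config):
        drugs, _, corpus = coupled_world
        names = [d.name for d in drugs]
        with pytest.raises(ValueError, match="exclude"):
            st.run_incremental(
                corpus, names, names[0], names, 2, fast_config, seed=0
            )

    def test_full_x_identical_for_any_ordering(self, coupled_world, fast_config):
        """At X = n-1 both policies train on the same pooled corpus."""
        drugs, simmat, corpus = coupled_world
        names = [d.name for d in drugs]
        target = names[0]
        sim_order = st.order_by_similarity(simmat, target)
        rnd_order = st.random_ordering(names, target, seed=11)
        x = len(names) - 1
        r1 = st.run_incremental(corpus, names, target, sim_order, x, fast_config, seed=5)
        r2 = st.run_incremental(corpus, names, target, rnd_order, x, fast_config, seed=5)
        assert r1 == r2

    def test_target_never_in_training(self, coupled_world, fast_config):
        drugs, simmat, corpus = coupled_world
        names = [d.name for d in drugs]
        target = names[2]
        spy = _SpyTrainer()
        st.run_incremental(
            corpus, names, target, st.order_by_similarity(simmat, target), 3,
            fast_config, seed=1, trainer=spy,
        )
        target_ids = st.subcorpus(corpus, target).doc_ids()
        for train, dev in spy.seen:
            assert not (train.source_ids() | dev.source_ids()) & target_ids


class TestSimVsRnd:
    def test_table_is_byte_identical_under_master_seed(self, coupled_world, fast_config):
        drugs, simmat, corpus = coupled_world
        names = [d.name for d in drugs][:4]
        sub = st.subcorpus(corpus, names)
        simmat4 = st.SimilarityMatrix(
            tuple(names), simmat.values[np.ix_(range(4), range(4))]
        )
        kw = dict(x_list=[1, 2], config=fast_config, seed=77, n_rnd_reps=2)
        t1 = st.sim_vs_rnd(sub, names, simmat4, **kw)
        t2 = st.sim_vs_rnd(sub, names, simmat4, **kw)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_summary_shape_and_means(self, coupled_world, fast_config):
        drugs, simmat, corpus = coupled_world
        names = [d.name for d in drugs]
        table = st.sim_vs_rnd(
            corpus, names, simmat, x_list=[2], config=fast_config, seed=3, n_rnd_reps=2
        )
        summary = st.sim_vs_rnd_summary(table)
        assert set(summary["policy"]) == {"sim", "rnd"}
        assert all(0.0 <= v <= 1.0 for v in summary["mean_accuracy"])
        # per-target means aggregate to the reported mean
        sim_rows = table[(table.policy == "sim") & (table.x == 2)]
        want = sim_rows.groupby("target")["accuracy"].mean().mean()
        got = summary[(summary.policy == "sim")]["mean_accuracy"].iloc[0]
        assert got == pytest.approx(want)

    def test_rising_accuracy_with_more_source_drugs(self, coupled_world, fast_config):
        """Mean accuracy is non-decreasing in X up to noise on coupled data."""
        drugs, simmat, corpus = coupled_world
        names = [d.name for d in drugs]
        table = st.sim_vs_rnd(
            corpus, names, simmat, x_list=[1, 3, 5], config=fast_config,
            seed=13, n_rnd_reps=3,
        )
        summary = st.sim_vs_rnd_summary(table)
        rnd = summary[summary.policy == "rnd"].sort_values("x")
        slope = np.polyfit(rnd["x"], rnd["mean_accuracy"], 1)[0]
        assert slope >= -0.02
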