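"""Random-network nulls, shuffles, and the occurrence-vs-degree table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import songnet as sn
from songnet.measures import UndefinedMeasureError
from songnet.nulls import NullConfig, ensemble_summary

labels = st.sampled_from(list("abcdef"))
bout_lists = st.lists(st.lists(labels, min_size=1, max_size=10), min_size=1,
                      max_size=5)


class TestGenerateRun:
    def test_exact_edge_count_every_draw(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            net = sn.generate_run(30, 60, rng)
            assert net.n == 30 and net.n_edges == 60
            assert all(u != v for u, v in net.graph.edges())

    def test_forced_complete_graph(self):
        net = sn.generate_run(4, 6, seed=1)
        assert net.n_edges == 6 and sn.average_path_length(net) == 1.0

    def test_deterministic_for_fixed_seed(self):
        a = sn.generate_run(50, 100, seed=9)
        b = sn.generate_run(50, 100, seed=9)
        assert a.edges == b.edges

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sn.generate_run(4, 7, seed=0)

    def test_ensemble_clustering_matches_er_oracle(self):
        """Mean C of matched ER graphs ~ <k>/(n-1), the closed-form value."""
        n, m = 100, 300
        rng = np.random.default_rng(11)
        cs = [sn.clustering_coefficient(sn.generate_run(n, m, rng))
              for _ in range(150)]
        expected = 2 * m / (n * (n - 1))  # = p; degree>=2 correction is <2%
        assert np.mean(cs) == pytest.approx(expected, rel=0.12)

    def test_degree_distribution_near_binomial(self):
        """Degree histogram of pooled draws tracks Binomial(n-1, p)."""
        from scipy import stats

        n, m = 100, 300
        p = 2 * m / (n * (n - 1))
        rng = np.random.default_rng(12)
        degrees = np.concatenate([
            [d for _, d in sn.generate_run(n, m, rng).graph.degree()]
            for _ in range(60)
        ])
        ks = np.arange(0, 16)
        expected = stats.binom.pmf(ks, n - 1, p)
        observed = np.array([(degrees == k).mean() for k in ks])
        assert np.abs(observed - expected).max() < 0.03


class TestGenerateRdn:
    def test_exact_arc_count_and_no_self_arcs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = sn.generate_rdn(25, 80, rng)
            assert d.n_arcs == 80
            assert all(u != v for u, v in d.arcs)

    def test_unique_two_cycle(self):
        d = sn.generate_rdn(2, 2, seed=0)
        assert d.arcs == {(0, 1), (1, 0)}

    def test_mean_total_degree_convention(self):
        d = sn.generate_rdn(20, 50, seed=3)
        assert d.mean_total_degree == pytest.approx(2 * 50 / 20)

    def test_hourglass_proportion_matches_poisson_oracle(self):
        """In/out degrees are ~Poisson(arcs/n); Hourglass ~ P(Pois>=2)^2."""
        from scipy import stats

        n, arcs = 182, 682
        lam = arcs / n
        oracle = (1 - stats.poisson.cdf(1, lam)) ** 2
        rng = np.random.default_rng(4)
        props = [
            sn.motif_profile(sn.generate_rdn(n, arcs, rng)).proportions["Hourglass"]
            for _ in range(100)
        ]
        assert np.mean(props) == pytest.approx(oracle, abs=0.02)


class TestEnsembleSummary:
    def test_deterministic_rerun(self):
        cfg = NullConfig(n=30, target_edges=60, reps=5, seed=77)
        a = ensemble_summary(cfg, "run", ["L", "C"])
        b = ensemble_summary(cfg, "run", ["L", "C"])
        assert a == b

    def test_z_consistency(self):
        cfg = NullConfig(n=40, target_edges=90, reps=30, seed=5)
        (summary,) = ensemble_summary(cfg, "run", ["C"], observed={"C": 0.4})
        assert summary.z == pytest.approx(
            sn.z_score(0.4, summary.mean, summary.sd)
        )

    def test_constant_measure_gives_no_z(self):
        cfg = NullConfig(n=20, target_edges=40, reps=5, seed=6)
        (summary,) = ensemble_summary(
            cfg, "run", ["mean_degree"], observed={"mean_degree": 4.0}
        )
        assert summary.sd == 0 and summary.z is None

    def test_rdn_motif_measures(self):
        cfg = NullConfig(n=30, target_arcs=90, reps=10, seed=8)
        stats_ = ensemble_summary(
            cfg, "rdn", ["motif_prop:Hourglass", "motif_count:Margin"]
        )
        assert 0 <= stats_[0].mean <= 1
        assert stats_[1].mean >= 0


class TestShuffleCorpus:
    def test_single_phrase_type_identity(self):
        corpus = sn.corpus_from_bouts([["a", "a", "a"], ["a", "a"]])
        out = sn.shuffle_corpus(corpus, n_swaps=50, seed=0)
        assert [b.phrases for b in out.bouts] == [b.phrases for b in corpus.bouts]

    def test_zero_swaps_identity(self, walk_corpus):
        out = sn.shuffle_corpus(walk_corpus, n_swaps=0, seed=0)
        assert list(out.tokens()) == list(walk_corpus.tokens())

    @given(bout_lists, st.integers(0, 200))
    @settings(max_examples=40, derandomize=True)
    def test_label_multiset_preserved(self, bouts, n_swaps):
        corpus = sn.corpus_from_bouts(bouts)
        if corpus.n_tokens < 2:
            return
        out = sn.shuffle_corpus(corpus, n_swaps=n_swaps, seed=1)
        assert out.token_counts() == corpus.token_counts()
        assert [len(b) for b in out.bouts] == [len(b) for b in corpus.bouts]

    def test_destroys_transition_context(self, walk_corpus):
        out = sn.shuffle_corpus(walk_corpus, n_swaps=2000, seed=2)
        assert sn.build_sdn(out).arcs != sn.build_sdn(walk_corpus).arcs


class TestOccurrenceVsDegree:
    def test_hand_example(self):
        corpus = sn.corpus_from_bouts([["a", "b", "a", "c"]])
        table = sn.occurrence_vs_degree(corpus).set_index("phrase")
        # occurrences: a 2/4, b 1/4, c 1/4
        assert table.loc["a", "occurrence_frequency"] == pytest.approx(0.5)
        # arcs a->b, b->a, a->c; total degrees a=3, b=2, c=1, sum 6
        assert table.loc["a", "degree_frequency"] == pytest.approx(3 / 6)
        assert table.loc["b", "degree_frequency"] == pytest.approx(2 / 6)
        assert table.loc["c", "degree_frequency"] == pytest.approx(1 / 6)

    def test_columns_sum_to_one(self, walk_corpus):
        table = sn.occurrence_vs_degree(walk_corpus)
        assert table["occurrence_frequency"].sum() == pytest.approx(1.0)
        assert table["degree_frequency"].sum() == pytest.approx(1.0)

    def test_edgeless_rejected(self):
        with pytest.raises(UndefinedMeasureError):
            sn.occurrence_vs_degree(sn.corpus_from_bouts([["a"], ["b"]]))

    def test_shuffled_comparison_runs(self, walk_corpus):
        shuffled = sn.shuffle_corpus(walk_corpus, n_swaps=1000, seed=3)
        real = sn.occurrence_vs_degree(walk_corpus)
        shuf = sn.occurrence_vs_degree(shuffled)
        merged = real.merge(shuf, on="phrase", suffixes=("_real", "_shuf"))
        assert np.allclose(
            merged["occurrence_frequency_real"],
            merged["occurrence_frequency_shuf"],
        )
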