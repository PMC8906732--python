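"""Selection score, virtual loss, tree bookkeeping, and search-vs-oracle."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluoromcts as fm
from fluoromcts.errors import (
    ExpansionError,
    InputError,
    LedgerFormatError,
    SearchStateError,
)
from fluoromcts.mcts import SearchNode, SearchState
from fluoromcts.oracle import CachedEvaluator
from fluoromcts.prior import BEGIN_TOKEN, END_TOKEN, UniformPrior
import numpy as np


def node(reward_sum=0.0, visits=0, virtual=0, prior=1.0, token="C"):
    return SearchNode(token=token, prefix=(BEGIN_TOKEN, token), prior=prior,
                      reward_sum=reward_sum, visits=visits, virtual=virtual)


class TestSelectionScore:
    def test_hand_value_visited(self):
        n = node(reward_sum=1.0, visits=1, prior=0.5)
        assert fm.selection_score(n, v_p=1, w_p=0, c=4.0) == pytest.approx(
            2.0, abs=1e-9)

    def test_hand_value_with_virtual_loss(self):
        n = node(reward_sum=1.0, visits=1, virtual=1, prior=0.5)
        expected = 0.5 + 4 * 0.5 * math.sqrt(2) / 3
        assert fm.selection_score(n, v_p=1, w_p=1, c=4.0) == pytest.approx(
            expected, abs=1e-9)
        assert expected == pytest.approx(1.4428, abs=1e-4)

    def test_unvisited_convention(self):
        n = node(prior=0.3)
        assert fm.selection_score(n, v_p=9, w_p=0, c=4.0) == pytest.approx(
            4.0 * 0.3 * 3.0, abs=1e-12)

    @given(st.floats(0.0, 10.0), st.integers(0, 50), st.integers(0, 20),
           st.floats(0.01, 1.0), st.integers(1, 100), st.integers(0, 20))
    @settings(max_examples=200, derandomize=True)
    def test_strictly_decreasing_in_virtual_visits(self, r, v, w, p, vp, wp):
        lo = fm.selection_score(node(reward_sum=min(r, v), visits=v, virtual=w,
                                     prior=p), vp, wp, 4.0)
        hi = fm.selection_score(node(reward_sum=min(r, v), visits=v,
                                     virtual=w + 1, prior=p), vp, wp, 4.0)
        assert hi < lo


class TestSelectLeaf:
    def _tiny_tree(self):
        vocab = fm.TokenVocabulary(tokens=(BEGIN_TOKEN, END_TOKEN, "C", "O"))
        prior = UniformPrior(vocab)
        root = SearchNode(token=BEGIN_TOKEN, prefix=(BEGIN_TOKEN,))
        fm.expand(root, prior)
        return root, prior

    def test_argmax_child_selected_and_virtual_loss_applied(self):
        root, _ = self._tiny_tree()
        root.visits = 2
        root.children["C"].visits = 1
        root.children["C"].reward_sum = 1.0
        cfg = fm.SearchConfig(budget=1)
        path = fm.select_leaf(root, cfg)
        assert [n.token for n in path] == [BEGIN_TOKEN, "C"]
        assert all(n.virtual == 1 for n in path)

    def test_tie_breaks_to_first_vocabulary_child(self):
        root, _ = self._tiny_tree()
        root.visits = 1
        path = fm.select_leaf(root, fm.SearchConfig(budget=1))
        # all children tied (equal prior, unvisited): vocabulary order wins
        assert path[-1].token == "$"

    def test_virtual_loss_diverts_consecutive_selections(self):
        """Without any backpropagation in between, two selections from a
        symmetric root must pick two different children."""
        root, _ = self._tiny_tree()
        root.visits = 4
        for child in root.children.values():
            child.visits = 1
            child.reward_sum = 0.5
        cfg = fm.SearchConfig(budget=1)
        first = fm.select_leaf(root, cfg)[-1]
        second = fm.select_leaf(root, cfg)[-1]
        assert first.token != second.token


class TestExpand:
    def test_children_cover_prior_mass_and_renormalize(self, ngram_prior):
        root = SearchNode(token=BEGIN_TOKEN, prefix=(BEGIN_TOKEN,))
        fm.expand(root, ngram_prior)
        total = sum(c.prior for c in root.children.values())
        assert total == pytest.approx(1.0, abs=1e-9)
        assert BEGIN_TOKEN not in root.children
        assert all(c.prior > 0 for c in root.children.values())

    def test_terminal_node_rejected(self, ngram_prior):
        term = SearchNode(token=END_TOKEN, prefix=(BEGIN_TOKEN, "C", END_TOKEN))
        with pytest.raises(ExpansionError):
            fm.expand(term, ngram_prior)

    def test_degenerate_model_puts_mode_first(self):
        prior = fm.train_prior(["CCO"] * 50, model="ngram")
        root = SearchNode(token=BEGIN_TOKEN, prefix=(BEGIN_TOKEN,))
        fm.expand(root, prior)
        best = max(root.children.values(), key=lambda c: c.prior)
        assert best.token == "C"


class TestBackpropagate:
    def _path(self):
        nodes = [node(token=t) for t in ("a", "b", "c")]
        for n in nodes:
            n.virtual = 1
        return nodes

    def test_updates_and_virtual_release(self):
        path = self._path()
        fm.backpropagate(path, 0.5)
        for n in path:
            assert (n.reward_sum, n.visits, n.virtual) == (0.5, 1, 0)

    def test_underflow_detected(self):
        path = self._path()
        path[1].virtual = 0
        with pytest.raises(SearchStateError):
            fm.backpropagate(path, 0.5)

    @pytest.mark.parametrize("r", [-0.1, 1.5])
    def test_out_of_range_reward_rejected(self, r):
        with pytest.raises(InputError):
            fm.backpropagate(self._path(), r)


class TestRollout:
    def _state(self, prior, **cfg):
        return SearchState(
            model=prior, oracle=CachedEvaluator(fm.surrogate_evaluate),
            params=fm.RewardParams(),
            config=fm.SearchConfig(budget=10, seed=0, **cfg),
            rng=np.random.default_rng(0))

    def test_valid_completion_scores_like_composed_oracles(self):
        prior = fm.train_prior(["C=CC=C"] * 50, model="ngram")
        state = self._state(prior)
        leaf = SearchNode(token=BEGIN_TOKEN, prefix=(BEGIN_TOKEN,))
        rec, r = fm.rollout(leaf, state)
        assert rec is not None
        expected = fm.total_reward(
            fm.surrogate_evaluate(fm.parse_smiles(rec.molecule.smiles_canonical)),
            fm.RewardParams())
        assert r == pytest.approx(expected, rel=1e-12)

    def test_duplicate_gets_no_new_generation_index(self):
        prior = fm.train_prior(["CCO"] * 100, model="ngram")
        state = self._state(prior)
        # a terminal prefix always completes to the same molecule
        leaf = SearchNode(token=END_TOKEN,
                          prefix=(BEGIN_TOKEN, "C", "C", "O", END_TOKEN))
        rec1, r1 = fm.rollout(leaf, state)
        rec2, r2 = fm.rollout(leaf, state)
        assert rec1.generation_index == rec2.generation_index == 1
        assert len(state.records) == 1
        assert r1 == r2
        assert state.oracle.n_calls == 1

    def test_invalid_completion_scores_zero(self):
        # prefix that cannot terminate validly: unclosed ring at max_len
        vocab = fm.TokenVocabulary(tokens=(BEGIN_TOKEN, END_TOKEN, "C", "1"))
        state = self._state(UniformPrior(vocab), max_len=6)
        leaf = SearchNode(token="1", prefix=(BEGIN_TOKEN, "C", "1", "C", "C"))
        rec, r = fm.rollout(leaf, state)
        # either it drew "$" (unclosed ring -> invalid) or hit max_len
        assert rec is None and r == 0.0


class TestSearch:
    def test_budget_zero_rejected(self):
        with pytest.raises(InputError):
            fm.SearchConfig(budget=0)

    def test_single_worker_determinism(self, ngram_prior):
        def run():
            recs = fm.search(ngram_prior, fm.surrogate_evaluate,
                             fm.RewardParams(), fm.SearchConfig(budget=40, seed=5))
            return [(r.molecule.smiles_canonical, r.reward,
                     r.generation_index) for r in recs]

        assert run() == run()

    def test_ledger_invariants(self, ngram_prior):
        recs = fm.search(ngram_prior, fm.surrogate_evaluate, fm.RewardParams(),
                         fm.SearchConfig(budget=50, seed=1))
        smiles = [r.molecule.smiles_canonical for r in recs]
        assert len(set(smiles)) == len(smiles)  # dedup
        assert [r.generation_index for r in recs] == list(
            range(1, len(recs) + 1))  # contiguous
        assert all(0.0 <= r.reward <= 1.0 for r in recs)

    def test_cache_transparency(self, ngram_prior):
        """Search results are identical with and without a pre-wrapped
        cache (the wrapper only avoids repeated evaluator calls)."""
        cfg = fm.SearchConfig(budget=30, seed=2)
        a = fm.search(ngram_prior, fm.surrogate_evaluate, fm.RewardParams(), cfg)
        b = fm.search(ngram_prior, CachedEvaluator(fm.surrogate_evaluate),
                      fm.RewardParams(), cfg)
        assert ([r.molecule.smiles_canonical for r in a]
                == [r.molecule.smiles_canonical for r in b])

    def test_finds_toy_grammar_optimum(self, toy_grammar_vocab,
                                       toy_grammar_rewards):
        best_possible = max(toy_grammar_rewards.values())
        recs = fm.search(UniformPrior(toy_grammar_vocab), fm.surrogate_evaluate,
                         fm.RewardParams(),
                         fm.SearchConfig(budget=300, seed=0, max_len=8))
        assert max(r.reward for r in recs) == pytest.approx(best_possible,
                                                            abs=1e-12)

    def test_multiworker_ledger_invariants(self, toy_grammar_vocab):
        recs = fm.search(UniformPrior(toy_grammar_vocab), fm.surrogate_evaluate,
                         fm.RewardParams(),
                         fm.SearchConfig(budget=100, seed=0, max_len=8,
                                         n_workers=4))
        smiles = [r.molecule.smiles_canonical for r in recs]
        assert len(set(smiles)) == len(smiles)
        assert [r.generation_index for r in recs] == list(range(1, len(recs) + 1))

    def test_root_visit_conservation(self, ngram_prior):
        """After quiescence: root visits equal completed rollouts and no
        virtual visits remain anywhere in the tree."""
        from fluoromcts import mcts as m

        state = SearchState(
            model=ngram_prior, oracle=CachedEvaluator(fm.surrogate_evaluate),
            params=fm.RewardParams(), config=fm.SearchConfig(budget=25, seed=3),
            rng=np.random.default_rng(3))
        root = SearchNode(token=BEGIN_TOKEN, prefix=(BEGIN_TOKEN,))
        n_rollouts = 0
        while len(state.records) < 25 and n_rollouts < 500:
            path = m.select_leaf(root, state.config)
            leaf = path[-1]
            if not leaf.is_terminal(END_TOKEN) and not leaf.expanded:
                m.expand(leaf, ngram_prior)
            _, r = m.rollout(leaf, state)
            n_rollouts += 1
            m.backpropagate(path, r)
        assert root.visits == n_rollouts

        def no_virtual(nd):
            assert nd.virtual == 0
            for c in nd.children.values():
                no_virtual(c)

        no_virtual(root)


class TestLedgerIO:
    def test_round_trip(self, tmp_path, ngram_prior):
        recs = fm.search(ngram_prior, fm.surrogate_evaluate, fm.RewardParams(),
                         fm.SearchConfig(budget=20, seed=4))
        path = tmp_path / "ledger.csv"
        fm.write_ledger(recs, path)
        loaded = fm.read_ledger(path)
        assert len(loaded) == len(recs)
        for a, b in zip(recs, loaded):
            assert a.molecule.smiles_canonical == b.molecule.smiles_canonical
            assert a.generation_index == b.generation_index
            assert b.reward == pytest.approx(a.reward, rel=1e-9)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "generation_index,smiles_canonical,a_w_nm,a_i,f_w_nm,f_i,reward,status\n"
            "1,CCO,190,0.14,230,0.14,0.1,ok\n"
            "2,CCO,not_a_number,0.14,230,0.14,0.1,ok\n")
        with pytest.raises(LedgerFormatError, match="line 3"):
            fm.read_ledger(path)
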