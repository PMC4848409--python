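import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oncotrees as ot
from oncotrees.branching import (
    EdgeWeightMatrix,
    ErrorModel,
    OncoTree,
    edge_probabilities,
    exhaustive_branching,
    fit_error_model,
    optimal_branching,
    pair_weights,
    pattern_likelihood,
)
from oncotrees.data import FrequencyEstimates, estimate_probabilities
from oncotrees.exceptions import ValidationError

from .conftest import make_matrix, random_matrix


def freq_from(marginal: dict, joint: dict, n: int = 100) -> FrequencyEstimates:
    return FrequencyEstimates(
        n=n,
        events=tuple(marginal),
        marginal=dict(marginal),
        joint={frozenset(k): v for k, v in joint.items()},
        pseudo_floor=1.0 / (2 * n),
    )


class TestPairWeights:
    def test_independent_events(self):
        freq = freq_from({"A": 0.5, "B": 0.5}, {("A", "B"): 0.25})
        w = pair_weights(freq)
        assert w.w("A", "B") == pytest.approx(math.log(0.25), abs=1e-9)

    def test_identical_events_zero_weight(self):
        freq = freq_from({"A": 0.5, "B": 0.5}, {("A", "B"): 0.5})
        assert pair_weights(freq).w("A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_root_weight(self):
        freq = freq_from({"A": 0.5, "B": 0.5}, {("A", "B"): 0.25})
        w = pair_weights(freq)
        assert w.w("root", "B") == pytest.approx(math.log(1 / 3), abs=1e-9)

    def test_symmetry_between_events(self):
        freq = freq_from({"A": 0.7, "B": 0.3}, {("A", "B"): 0.2})
        w = pair_weights(freq)
        assert w.w("A", "B") == pytest.approx(w.w("B", "A"))


class TestOptimalBranching:
    def test_single_event(self):
        w = EdgeWeightMatrix(events=("A",), weights={("root", "A"): -1.0})
        tree = optimal_branching(w)
        assert tree.parent == {"A": "root"}

    def test_nested_pair_hangs_under_ancestor(self):
        freq = freq_from({"A": 0.8, "B": 0.4}, {("A", "B"): 0.4})
        w = pair_weights(freq)
        assert w.w("A", "B") == pytest.approx(math.log(0.4 / 0.96), abs=1e-4)
        assert w.w("root", "B") == pytest.approx(math.log(0.4 / 1.4), abs=1e-4)
        tree = optimal_branching(w)
        assert tree.parent == {"A": "root", "B": "A"}

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(5, 40))
            m = random_matrix(rng, n, k)
            w = pair_weights(estimate_probabilities(m))
            assert optimal_branching(w).canonical() == \
                exhaustive_branching(w).canonical()

    def test_tie_breaks_lexicographically(self):
        # p_A == p_B makes root->A / A->B and root->B / B->A exact ties
        freq = freq_from({"A": 0.5, "B": 0.5}, {("A", "B"): 0.4})
        tree = optimal_branching(pair_weights(freq))
        # lexicographically smallest assignment: A gets the smallest parent
        assert tree.parent == {"A": "B", "B": "root"}
        assert tree.canonical() == exhaustive_branching(
            pair_weights(freq)
        ).canonical()

    def test_attains_oracle_weight(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = random_matrix(rng, 25, 4)
            w = pair_weights(estimate_probabilities(m))
            assert optimal_branching(w).total_weight() == pytest.approx(
                exhaustive_branching(w).total_weight(), abs=1e-9
            )


class TestOncoTreeValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            OncoTree(events=("A", "B"), parent={"A": "B", "B": "A"})

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValidationError):
            OncoTree(events=("A",), parent={"A": "X"})


class TestEdgeProbabilities:
    def test_conditional_from_joint(self):
        freq = freq_from({"A": 0.8, "B": 0.4}, {("A", "B"): 0.4})
        tree = OncoTree(events=("A", "B"), parent={"A": "root", "B": "A"})
        fitted = edge_probabilities(tree, freq)
        assert fitted.cond_prob["B"] == pytest.approx(0.5)

    def test_root_child_gets_marginal(self):
        freq = freq_from({"A": 0.126, "B": 0.4}, {("A", "B"): 0.05})
        tree = OncoTree(events=("A", "B"), parent={"A": "root", "B": "root"})
        fitted = edge_probabilities(tree, freq)
        assert fitted.cond_prob["A"] == pytest.approx(0.126)

    def test_perfect_nesting_gives_one(self):
        freq = freq_from({"A": 0.3, "B": 0.3}, {("A", "B"): 0.3})
        tree = OncoTree(events=("A", "B"), parent={"A": "root", "B": "A"})
        assert edge_probabilities(tree, freq).cond_prob["B"] == pytest.approx(1.0)


def chain_tree(pi_a=0.5, pi_b=0.5) -> OncoTree:
    return OncoTree(
        events=("A", "B"),
        parent={"A": "root", "B": "A"},
        fire_prob={"A": pi_a, "B": pi_b},
    )


def oracle_pattern_likelihood(tree: OncoTree, err: ErrorModel, pattern) -> float:
    """Independent oracle: filter all subsets for downward closure directly."""
    events = tree.events
    total = 0.0
    for true_set in itertools.chain.from_iterable(
        itertools.combinations(events, r) for r in range(len(events) + 1)
    ):
        ts = set(true_set)
        if any(tree.parent[e] != "root" and tree.parent[e] not in ts for e in ts):
            continue
        p = 1.0
        for e in events:
            par = tree.parent[e]
            if par == "root" or par in ts:
                p *= tree.fire_prob[e] if e in ts else 1 - tree.fire_prob[e]
        for e, obs in zip(events, pattern):
            if e in ts:
                p *= (1 - err.eps_minus) if obs else err.eps_minus
            else:
                p *= err.eps_plus if obs else (1 - err.eps_plus)
        total += p
    return total


class TestPatternLikelihood:
    def test_deterministic_chain(self):
        tree = chain_tree(1.0, 1.0)
        assert pattern_likelihood(tree, ErrorModel(), [1, 1]) == pytest.approx(1.0)

    def test_child_without_ancestor_impossible(self):
        tree = chain_tree(0.5, 0.5)
        assert pattern_likelihood(tree, ErrorModel(), [0, 1]) == 0.0

    def test_hand_computed_error_case(self):
        tree = chain_tree(0.5, 0.5)
        lik = pattern_likelihood(tree, ErrorModel(0.1, 0.1), [0, 1])
        assert lik == pytest.approx(0.07, abs=1e-9)
        assert lik == pytest.approx(
            oracle_pattern_likelihood(tree, ErrorModel(0.1, 0.1), [0, 1]),
            abs=1e-12,
        )

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_sums_to_one_over_all_patterns(self, k):
        rng = np.random.default_rng(k)
        events = tuple(f"E{i}" for i in range(k))
        parent = {events[0]: "root"}
        for i in range(1, k):
            parent[events[i]] = rng.choice(["root", *events[:i]])
        tree = OncoTree(
            events=events,
            parent=parent,
            fire_prob={e: float(rng.uniform(0.1, 0.9)) for e in events},
        )
        err = ErrorModel(0.07, 0.12)
        total = sum(
            pattern_likelihood(tree, err, pat)
            for pat in itertools.product([0, 1], repeat=k)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_subset_oracle(self):
        rng = np.random.default_rng(10)
        events = ("A", "B", "C", "D")
        tree = OncoTree(
            events=events,
            parent={"A": "root", "B": "A", "C": "A", "D": "root"},
            fire_prob={e: float(rng.uniform(0.1, 0.9)) for e in events},
        )
        err = ErrorModel(0.05, 0.15)
        for pat in itertools.product([0, 1], repeat=4):
            assert pattern_likelihood(tree, err, pat) == pytest.approx(
                oracle_pattern_likelihood(tree, err, pat), abs=1e-12
            )

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        events = ("A", "B", "C")
        tree = OncoTree(
            events=events,
            parent={"A": "root", "B": "A", "C": "B"},
            fire_prob={e: float(rng.uniform(0.1, 0.9)) for e in events},
        )
        err = ErrorModel(0.05, 0.1)
        pattern = tuple(int(b) for b in rng.integers(0, 2, size=3))
        relabel = {"A": "X", "B": "Y", "C": "Z"}
        tree2 = OncoTree(
            events=tuple(relabel[e] for e in events),
            parent={relabel[c]: relabel.get(p, p) for c, p in tree.parent.items()},
            fire_prob={relabel[e]: tree.fire_prob[e] for e in events},
        )
        assert pattern_likelihood(tree, err, pattern) == pytest.approx(
            pattern_likelihood(tree2, err, pattern), abs=1e-12
        )


class TestFitErrorModel:
    def test_noise_free_chain_recovery(self):
        gen = chain_tree(0.6, 0.5)
        coh = ot.simulate_cohort(ot.GenerativeSpec(tree=gen, n=5000, seed=11))
        fit = fit_error_model(coh, gen)
        assert fit.fire_prob["A"] == pytest.approx(0.6, abs=0.05)
        assert fit.fire_prob["B"] == pytest.approx(0.5, abs=0.05)
        assert fit.error.eps_plus < 0.02
        assert fit.error.eps_minus < 0.02

    def test_all_zero_cohort_degenerate(self):
        m = make_matrix(np.zeros((50, 2), dtype=np.int8))
        topo = OncoTree(events=("A", "B"), parent={"A": "root", "B": "A"})
        fit = fit_error_model(m, topo)
        assert fit.fire_prob["A"] <= 1e-4
        assert fit.fire_prob["B"] <= 1e-4
        assert fit.error.eps_plus <= 1e-3

    def test_fixed_zero_error_matches_conditional_frequencies(self):
        gen = chain_tree(0.6, 0.5)
        coh = ot.simulate_cohort(ot.GenerativeSpec(tree=gen, n=2000, seed=3))
        fit = fit_error_model(coh, gen, fix_error=ErrorModel(0.0, 0.0))
        cond = edge_probabilities(gen, estimate_probabilities(coh))
        for e in gen.events:
            assert fit.fire_prob[e] == pytest.approx(cond.cond_prob[e], abs=1e-4)

    def test_objective_at_least_moment_start(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 200, 3)
        topo = ot.fit_branching_tree(m)
        fit = fit_error_model(m, topo)
        moment = edge_probabilities(topo, estimate_probabilities(m))
        start_ll = sum(
            math.log(
                pattern_likelihood(moment, ErrorModel(0.01, 0.01), row)
            )
            for row in m.values
        )
        assert fit.loglik >= start_ll - 1e-9


def test_branching_fit_consistency_50_runs():
    """Fitted topology equals the generating one in >= 95% of 50 runs."""
    gen = OncoTree(
        events=("A", "B", "C", "D"),
        parent={"A": "root", "B": "A", "C": "A", "D": "root"},
        fire_prob={"A": 0.7, "B": 0.5, "C": 0.35, "D": 0.25},
    )
    hits = 0
    for s in range(50):
        coh = ot.simulate_cohort(ot.GenerativeSpec(tree=gen, n=5000, seed=1000 + s))
        hits += ot.fit_branching_tree(coh).parent == gen.parent
    assert hits >= 48  # 95% of 50 rounds up to 48


class TestSerialization:
    def test_json_parent_map(self):
        tree = edge_probabilities(
            OncoTree(events=("A", "B"), parent={"A": "root", "B": "A"}),
            freq_from({"A": 0.8, "B": 0.4}, {("A", "B"): 0.4}),
        )
        d = tree.to_json_dict()
        assert d["B"]["parent"] == "A"
        assert d["B"]["cond_prob"] == pytest.approx(0.5)

    def test_dot_edges(self):
        tree = OncoTree(events=("A", "B"), parent={"A": "root", "B": "A"})
        dot = tree.to_dot()
        assert '"root" -> "A"' in dot
        assert '"A" -> "B"' in dot
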