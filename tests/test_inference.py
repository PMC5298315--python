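import numpy as np
import pytest

from mibni import (
    BooleanFunction,
    BooleanNetwork,
    Gate,
    Trajectory,
    entropy,
    gene_wise_consistency,
    infer_gene,
    infer_network,
    make_lagged_problem,
    mifs_select,
    mutual_information,
    predict_one_step,
    search_update_rule,
    simulate,
    swap_improve,
)
from mibni.inference import LaggedProblem, _rule_predictions


class TestLaggedProblem:
    def test_lagging(self, random_trajectory):
        traj = random_trajectory(4, 6, seed=0)
        prob = make_lagged_problem(traj, 2)
        assert prob.target.tolist() == traj.states[1:, 2].tolist()
        assert prob.candidates.shape == (4, 5)
        # self-candidate is the target's own one-step-earlier series
        assert prob.candidates[2].tolist() == traj.states[:-1, 2].tolist()

    def test_minimum_length(self):
        traj = Trajectory(np.array([[0, 1], [1, 0]]))
        prob = make_lagged_problem(traj, 0)
        assert prob.target.size == 1
        with pytest.raises(ValueError):
            make_lagged_problem(Trajectory(np.array([[0, 1]])), 0)


@pytest.mark.parametrize(
    "obs, pred, expected",
    [
        ([0, 1, 1, 0], [0, 1, 1, 0], 1.0),
        ([0, 1, 1, 0], [1, 0, 0, 1], 0.0),
        ([0, 1, 1, 0], [0, 1, 1, 1], 0.75),
    ],
)
def test_gene_wise_consistency(obs, pred, expected):
    assert gene_wise_consistency(obs, pred) == expected


def test_gene_wise_consistency_length_mismatch():
    with pytest.raises(ValueError):
        gene_wise_consistency([0, 1], [0, 1, 1])


class TestSearchUpdateRule:
    def test_enumerates_eight_rules_for_two_regulators(self):
        # all 2^(|S|+1) = 8 signed AND/OR rules over 2 regulators are distinct
        cand = np.array([[0, 0, 1, 1], [0, 1, 0, 1]], dtype=np.int8)
        preds = _rule_predictions(cand)
        assert preds.shape == (8, 4)
        assert len({tuple(p) for p in preds}) == 8

    def test_recovers_signed_and(self):
        # target(t) = a(t-1) AND NOT b(t-1), all four input patterns seen
        a = np.array([0, 0, 1, 1, 0, 1], dtype=np.int8)
        b = np.array([0, 1, 0, 1, 1, 0], dtype=np.int8)
        target = a & (1 - b)
        prob = LaggedProblem(target, np.vstack([a, b]), target_index=0)
        rule, c = search_update_rule(prob, [0, 1])
        assert c == 1.0
        assert rule.gate is Gate.AND
        assert rule.regulators == (0, 1) and rule.signs == (1, -1)

    def test_identity_candidate(self):
        t = np.array([0, 1, 1, 0], dtype=np.int8)
        prob = LaggedProblem(t, t[None, :], target_index=0)
        rule, c = search_update_rule(prob, [0])
        assert c == 1.0 and rule.signs == (1,)

    def test_empty_set_rejected(self, random_trajectory):
        prob = make_lagged_problem(random_trajectory(3, 5, seed=1), 0)
        with pytest.raises(ValueError):
            search_update_rule(prob, [])


def _greedy_mifs_reference(prob, k):
    """Step-by-step re-evaluation of the greedy selection criterion."""
    rel = [mutual_information(prob.target, c) for c in prob.candidates]
    S = [int(np.argmax(rel))]
    while len(S) < k:
        best_w, best_score = None, -np.inf
        for w in range(prob.n_candidates):
            if w in S:
                continue
            score = rel[w] - sum(
                mutual_information(prob.candidates[w], prob.candidates[s]) for s in S
            )
            if score > best_score:
                best_w, best_score = w, score
        S.append(best_w)
    return S


class TestMifsSelect:
    def test_k1_picks_max_mi_candidate(self, random_trajectory):
        prob = make_lagged_problem(random_trajectory(6, 12, seed=5), 0)
        (pick,) = mifs_select(prob, 1)
        mis = [mutual_information(prob.target, c) for c in prob.candidates]
        assert mis[pick] == max(mis)

    def test_identical_candidate_selected_first(self):
        t = np.array([0, 1, 0, 1, 1], dtype=np.int8)
        rng = np.random.default_rng(0)
        cands = rng.integers(0, 2, size=(4, 5)).astype(np.int8)
        cands[2] = t  # a perfect copy of the target
        prob = LaggedProblem(t, cands, target_index=0)
        assert mifs_select(prob, 1) == [2]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_greedy(self, seed, random_trajectory):
        prob = make_lagged_problem(random_trajectory(4, 9, seed=seed), 0)
        assert mifs_select(prob, 2) == _greedy_mifs_reference(prob, 2)

    def test_k_out_of_range(self, random_trajectory):
        prob = make_lagged_problem(random_trajectory(3, 5, seed=2), 0)
        with pytest.raises(ValueError):
            mifs_select(prob, 0)
        with pytest.raises(ValueError):
            mifs_select(prob, 4)


class TestSwapImprove:
    def test_perfect_set_returned_unchanged(self):
        t = np.array([0, 1, 1, 0, 1], dtype=np.int8)
        prob = LaggedProblem(t, np.vstack([t, 1 - t]), target_index=0)
        S, rule, c = swap_improve(prob, [0])
        assert S == [0] and c == 1.0

    def test_swaps_in_the_true_regulator(self):
        rng = np.random.default_rng(1)
        c_true = rng.integers(0, 2, size=12).astype(np.int8)
        unrelated = np.array([0] * 11 + [1], dtype=np.int8)
        target = 1 - c_true
        prob = LaggedProblem(target, np.vstack([unrelated, c_true]), target_index=0)
        S, rule, c = swap_improve(prob, [0])
        assert S == [1] and c == 1.0 and rule.signs == (-1,)

    def test_consistency_never_below_start(self, random_trajectory):
        for seed in range(10):
            prob = make_lagged_problem(random_trajectory(6, 10, seed=seed), 0)
            S0 = mifs_select(prob, 2)
            _, start = search_update_rule(prob, S0)
            _, _, final = swap_improve(prob, S0)
            assert final >= start


class TestInferGene:
    def test_constant_target_shortcut(self):
        states = np.array([[1, 0], [0, 1], [0, 1], [0, 1]])
        res = infer_gene(Trajectory(states), 1)
        assert res.rule.gate is Gate.CONSTANT and res.rule.constant_value == 1
        assert res.selected == () and res.consistency == 1.0 and res.k_used == 0

    def test_recovers_single_regulator_rule(self):
        net = BooleanNetwork(
            [
                BooleanFunction((0,), (-1,), Gate.OR),  # oscillator driver
                BooleanFunction((0,), (1,), Gate.OR),  # copies node 0
            ]
        )
        traj = simulate(net, [0, 1], 8)
        res = infer_gene(traj, 1)
        assert res.consistency == 1.0 and res.k_used == 1
        assert res.rule.regulators == (0,) and res.rule.signs == (1,)

    def test_reported_consistency_is_self_consistent(self, random_trajectory):
        for seed in range(8):
            traj = random_trajectory(5, 9, seed=seed)
            for g in range(5):
                res = infer_gene(traj, g)
                prob = make_lagged_problem(traj, g)
                if res.rule.gate is Gate.CONSTANT:
                    pred = np.full(prob.target.size, res.rule.constant_value)
                else:
                    _, recomputed = search_update_rule(prob, res.rule.regulators)
                    assert res.consistency == recomputed
                    continue
                assert res.consistency == gene_wise_consistency(prob.target, pred)


class TestInferNetwork:
    def test_all_constant_trajectory_gives_empty_network(self):
        traj = Trajectory(np.tile([1, 0, 1], (6, 1)))
        net, results = infer_network(traj)
        assert net.edges == set()
        assert all(r.rule.gate is Gate.CONSTANT for r in results)

    def test_one_rule_per_gene(self, random_trajectory):
        traj = random_trajectory(6, 8, seed=11)
        net, results = infer_network(traj)
        assert len(results) == 6 and net.n_nodes == 6

    def test_dynamics_accuracy_equals_mean_consistency(self, random_trajectory):
        from mibni import dynamics_accuracy

        traj = random_trajectory(5, 10, seed=4)
        net, results = infer_network(traj)
        per_gene, dyn = dynamics_accuracy(traj, predict_one_step(net, traj))
        assert dyn == pytest.approx(np.mean([r.consistency for r in results]))
        assert per_gene.tolist() == [r.consistency for r in results]
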