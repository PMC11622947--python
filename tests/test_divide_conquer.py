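import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emfi import (
    DemandPoint,
    PMedianInstance,
    EmFiConfig,
    apportion_facilities,
    brute_force_optimum,
    evaluate_solution,
    run_em_fi,
)
from emfi.divide_conquer import (
    SubSolver,
    SubproblemSpec,
    choose_subsolver,
    conquer_reassign,
    improve_global,
    solve_subproblems,
)


def two_blob_instance(n_per=10, gap=100.0, seed=0, p=2):
    rng = np.random.default_rng(seed)
    coords = np.vstack(
        [rng.normal(scale=1.0, size=(n_per, 2)), [gap, 0] + rng.normal(scale=1.0, size=(n_per, 2))]
    )
    return PMedianInstance(
        [DemandPoint(i, *c, float(w)) for i, (c, w) in enumerate(zip(coords, rng.uniform(1, 3, 2 * n_per)))],
        p=p,
    )


class TestApportionment:
    def test_leftover_goes_to_largest_demand(self):
        assert apportion_facilities([600, 300, 100], 7, [50, 50, 50]) == [5, 2, 0]

    def test_single_subregion_gets_everything(self):
        assert apportion_facilities([123.0], 9, [40]) == [9]

    def test_demand_tie_broken_by_index(self):
        assert apportion_facilities([100, 100], 5, [30, 30]) == [3, 2]

    def test_capacity_overflow_redistributed(self):
        # first subregion can host only 2 facilities
        result = apportion_facilities([900, 100], 6, [2, 20])
        assert result == [2, 4] and sum(result) == 6

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_conservation_property(self, data):
        q = data.draw(st.integers(1, 8))
        demands = data.draw(
            st.lists(st.floats(0.1, 1e6), min_size=q, max_size=q)
        )
        counts = data.draw(st.lists(st.integers(1, 50), min_size=q, max_size=q))
        p = data.draw(st.integers(1, sum(counts)))
        shares = apportion_facilities(demands, p, counts)
        assert sum(shares) == p
        assert all(0 <= s <= c for s, c in zip(shares, counts))


class TestChooseSubsolver:
    @pytest.mark.parametrize(
        "n_sub,p_sub,expected",
        [(100, 10, SubSolver.MILP), (301, 10, SubSolver.FI), (100, 31, SubSolver.FI), (5, 0, SubSolver.NONE)],
    )
    def test_threshold_rule(self, n_sub, p_sub, expected):
        assert choose_subsolver(n_sub, p_sub, EmFiConfig(milp_max_n=300, milp_max_p=30)) == expected


class TestSolveSubproblems:
    def test_separated_blobs_solved_per_blob(self):
        inst = two_blob_instance()
        specs = [
            SubproblemSpec(members=np.arange(10), p_sub=1, solver=SubSolver.MILP),
            SubproblemSpec(members=np.arange(10, 20), p_sub=1, solver=SubSolver.MILP),
        ]
        sets = solve_subproblems(inst, specs, seed=0)
        for members, fac in zip([np.arange(10), np.arange(10, 20)], sets):
            sub = inst.subinstance(members, 1)
            oracle = brute_force_optimum(sub)
            assert members[oracle.facilities].tolist() == fac.tolist()

    def test_worker_count_invariance(self):
        inst = two_blob_instance(n_per=15, p=4)
        specs = lambda: [
            SubproblemSpec(members=np.arange(15), p_sub=2, solver=SubSolver.FI),
            SubproblemSpec(members=np.arange(15, 30), p_sub=2, solver=SubSolver.FI),
        ]
        serial = solve_subproblems(inst, specs(), workers=1, seed=5)
        parallel = solve_subproblems(inst, specs(), workers=4, seed=5)
        assert [s.tolist() for s in serial] == [s.tolist() for s in parallel]

    def test_zero_budget_returns_empty(self):
        inst = two_blob_instance()
        specs = [
            SubproblemSpec(members=np.arange(10), p_sub=2, solver=SubSolver.MILP),
            SubproblemSpec(members=np.arange(10, 20), p_sub=0, solver=SubSolver.NONE),
        ]
        sets = solve_subproblems(inst, specs, seed=0)
        assert sets[1].size == 0


class TestConquer:
    def test_union_must_have_p_facilities(self):
        inst = two_blob_instance(p=3)
        with pytest.raises(ValueError, match="apportionment breach"):
            conquer_reassign(inst, [np.array([0]), np.array([10])])

    def test_reassignment_no_worse_than_sum_of_parts(self):
        inst = two_blob_instance(n_per=12, p=2)
        parts = [np.arange(12), np.arange(12, 24)]
        subtotal = 0.0
        sets = []
        for members in parts:
            sub = inst.subinstance(members, 1)
            sol = brute_force_optimum(sub)
            subtotal += sol.objective
            sets.append(members[sol.facilities])
        merged = conquer_reassign(inst, sets)
        assert merged.objective <= subtotal + 1e-9

    def test_separated_blobs_reach_global_optimum(self):
        inst = two_blob_instance(n_per=10, p=2)
        sets = []
        for members in [np.arange(10), np.arange(10, 20)]:
            sub = inst.subinstance(members, 1)
            sets.append(members[brute_force_optimum(sub).facilities])
        merged = conquer_reassign(inst, sets)
        assert merged.objective == pytest.approx(
            brute_force_optimum(inst).objective, rel=1e-12
        )


class TestImproveGlobal:
    def test_fixed_point_at_local_optimum(self, make_random_instance):
        inst = make_random_instance(np.random.default_rng(1), 20, 4)
        opt = brute_force_optimum(inst)
        improved = improve_global(inst, opt)
        assert improved.facility_set() == opt.facility_set()

    def test_never_increases_objective(self, make_random_instance):
        rng = np.random.default_rng(2)
        inst = make_random_instance(rng, 25, 5)
        start = evaluate_solution(inst, np.sort(rng.choice(25, 5, replace=False)))
        assert improve_global(inst, start).objective <= start.objective

    def test_usually_reaches_oracle(self, make_random_instance):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            inst = make_random_instance(rng, 12, 3)
            start = evaluate_solution(inst, np.sort(rng.choice(12, 3, replace=False)))
            improved = improve_global(inst, start)
            if improved.objective <= brute_force_optimum(inst).objective * (1 + 1e-9):
                hits += 1
        assert hits >= 8  # single-start warm interchange occasionally stalls short


class TestRunEmFi:
    def test_clustered_fixture_engages_decomposition(self, small_clustered):
        inst, labels = small_clustered
        sol, report, art = run_em_fi(inst, EmFiConfig(seed=0, improve_mode="none"))
        assert sol.facilities.size == inst.p
        assert art.q_subregions is not None and art.q_subregions >= 2

    def test_homogeneous_fixture_reports_fallback(self):
        rng = np.random.default_rng(10)
        coords = rng.uniform(0, 100, size=(60, 2))
        inst = PMedianInstance(
            [DemandPoint(i, *c, 1.0) for i, c in enumerate(coords)], p=15
        )
        sol, report, art = run_em_fi(inst, EmFiConfig(seed=1, improve_mode="none"))
        assert art.fallback is not None
        assert sol.facilities.size == 15

    def test_seeded_determinism(self, small_clustered):
        inst, _ = small_clustered
        cfg = EmFiConfig(seed=9, improve_mode="global_fi")
        a, _, _ = run_em_fi(inst, cfg)
        b, _, _ = run_em_fi(inst, cfg)
        assert a.facilities.tolist() == b.facilities.tolist()
        assert a.objective == b.objective

    def test_improvement_never_worse_than_reassignment(self, small_clustered):
        inst, _ = small_clustered
        sol, _, art = run_em_fi(inst, EmFiConfig(seed=2, improve_mode="global_fi"))
        assert sol.objective <= art.reassignment.objective + 1e-9

    def test_no_cross_blob_assignment_in_final_solution(self, small_clustered):
        inst, labels = small_clustered
        sol, _, _ = run_em_fi(inst, EmFiConfig(seed=3, improve_mode="global_fi"))
        assert np.array_equal(labels[sol.assignment], labels)
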