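"""Radial DEA solver: frontier properties, oracle equivalence, targets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import broilerdea as bd
from broilerdea.dea import EFFICIENT_TOL, ModelSpec

from conftest import make_table
from oracle import crs_input_score_oracle

ALL_SPECS = [
    ModelSpec("crs", "input"),
    ModelSpec("crs", "output"),
    ModelSpec("vrs", "input"),
    ModelSpec("vrs", "output"),
]


class TestModelSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"returns_to_scale": "nirs"},
            {"orientation": "sideways"},
            {"frontier_side": "upside-down"},
            {"epsilon": -1e-6},
            {"epsilon": 1e-3},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)

    def test_unknown_dmu(self, broiler):
        with pytest.raises(KeyError):
            bd.solve_dmu(broiler, ModelSpec(), 99)


class TestFrontierProperties:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
    def test_scores_in_unit_interval_and_frontier_nonempty(self, broiler, spec):
        values = bd.scores(broiler, spec)
        assert ((values > 0) & (values <= 1)).all()
        assert (values >= 1 - EFFICIENT_TOL).any()

    def test_crs_orientation_reciprocity(self, broiler, broiler_crs_input):
        out = bd.scores(broiler, ModelSpec("crs", "output"))
        assert np.allclose(broiler_crs_input, out, atol=1e-9)

    @pytest.mark.parametrize("orientation", ["input", "output"])
    def test_vrs_dominates_crs(self, broiler, orientation):
        crs = bd.scores(broiler, ModelSpec("crs", orientation))
        vrs = bd.scores(broiler, ModelSpec("vrs", orientation))
        assert (vrs >= crs - 1e-9).all()

    def test_units_invariance(self, broiler, broiler_crs_input):
        scaled = broiler.frame.copy()
        scaled["housing"] *= 1e-3
        scaled["cost"] *= 250.0
        table = bd.DMUTable(frame=scaled)
        rescored = bd.scores(table, ModelSpec("crs", "input"))
        assert np.abs(rescored - broiler_crs_input).max() < 1e-9

    @given(sx=st.floats(1e-3, 1e3), sy=st.floats(1e-3, 1e3))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_units_invariance_property(self, sx, sy):
        X = np.array([[2.0, 1.0], [4.0, 3.0], [3.0, 5.0], [6.0, 2.0]])
        Y = np.array([[4.0], [5.0], [6.0], [5.0]])
        base = bd.scores(make_table(X, Y), ModelSpec("crs", "input"))
        scaled = bd.scores(make_table(X * [sx, 1.0], Y * sy), ModelSpec("crs", "input"))
        assert np.abs(scaled - base).max() < 1e-8

    def test_dominated_dmu_changes_no_score(self, broiler, broiler_crs_input):
        frame = broiler.frame.copy()
        worst = frame.loc[31]
        dominated = worst.copy()
        dominated[["housing", "age", "feed", "mortality", "cost"]] *= 1.3
        dominated["total_weight"] *= 0.7
        frame.loc[99] = dominated
        grown = bd.scores(bd.DMUTable(frame=frame), ModelSpec("crs", "input"))
        assert np.abs(grown.drop(99) - broiler_crs_input).max() < 1e-9

    def test_two_identical_dmus_define_their_own_frontier(self):
        table = make_table([[2.0, 3.0], [2.0, 3.0]], [[5.0], [5.0]])
        for spec in ALL_SPECS:
            assert all(r.is_efficient for r in bd.solve_all(table, spec))

    def test_benchmarks_are_efficient(self, broiler):
        for spec in ALL_SPECS:
            results = {r.dmu_id: r for r in bd.solve_all(broiler, spec)}
            for r in results.values():
                for peer in r.benchmarks:
                    assert results[peer].is_efficient, (spec.label, r.dmu_id, peer)

    def test_vrs_intensities_sum_to_one(self, broiler):
        for r in bd.solve_all(broiler, ModelSpec("vrs", "input")):
            assert r.intensities.sum() == pytest.approx(1.0, abs=1e-6)


class TestOracleEquivalence:
    def test_random_instances_match_vertex_enumeration(self):
        rng = np.random.default_rng(20240)
        for _ in range(25):
            X = rng.uniform(0.5, 5.0, (3, 2))
            Y = rng.uniform(0.5, 5.0, (3, 1))
            table = make_table(X, Y)
            lp = bd.scores(table, ModelSpec("crs", "input"))
            for o in range(3):
                expected = crs_input_score_oracle(X, Y, o)
                assert lp.iloc[o] == pytest.approx(expected, abs=1e-6)

    def test_planted_contraction_recovered(self):
        # a frontier point with inputs inflated by 1/theta scores theta
        theta = 0.75
        X = np.array([[2.0, 1.0], [4.0, 3.0], [2.0 / theta, 1.0 / theta]])
        Y = np.array([[4.0], [5.0], [4.0]])
        lp = bd.scores(make_table(X, Y), ModelSpec("crs", "input"))
        assert lp.iloc[2] == pytest.approx(theta, abs=1e-6)


class TestSlacksAndTargets:
    def test_efficient_dmu_projects_onto_itself(self, broiler):
        r = bd.solve_dmu(broiler, ModelSpec("crs", "input"), 4)
        assert r.is_efficient
        assert np.allclose(r.target_inputs, broiler.inputs.loc[4], rtol=1e-7)
        assert np.allclose(r.target_outputs, broiler.outputs.loc[4], rtol=1e-7)

    def test_input_targets_contract(self, broiler):
        for r in bd.solve_all(broiler, ModelSpec("crs", "input")):
            observed = broiler.inputs.loc[r.dmu_id]
            assert (r.target_inputs <= observed * (1 + 1e-9)).all()
            assert (r.input_slacks >= -1e-9).all() and (r.output_slacks >= -1e-9).all()

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
    def test_targets_equal_peer_combination(self, broiler, spec):
        for dmu in (4, 17, 31):
            r = bd.solve_dmu(broiler, spec, dmu)
            lam = r.intensities.to_numpy()
            peer_in = lam @ broiler.inputs.to_numpy()
            peer_out = lam @ broiler.outputs.to_numpy()
            target = bd.projection_targets(r, broiler)
            combo = np.concatenate([peer_in, peer_out])
            assert np.allclose(target, combo, rtol=1e-6, atol=1e-6)

    def test_multiplier_weights_reproduce_score(self, broiler):
        # virtual output / virtual input = score at the optimal weights
        for dmu in (4, 12, 31):
            r = bd.solve_dmu(broiler, ModelSpec("crs", "input"), dmu)
            virtual_in = float(r.input_weights @ broiler.inputs.loc[dmu])
            virtual_out = float(r.output_weights @ broiler.outputs.loc[dmu])
            assert virtual_in == pytest.approx(1.0, abs=1e-6)
            assert virtual_out == pytest.approx(r.score, abs=1e-6)


class TestEpsilonPolicy:
    def test_explicit_epsilon_matches_two_phase(self, broiler):
        two_phase = bd.scores(broiler, ModelSpec("crs", "input"))
        explicit = bd.scores(broiler, ModelSpec("crs", "input", epsilon=1e-6))
        assert np.abs(two_phase - explicit).max() < 5e-6
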