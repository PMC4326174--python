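"""Orientation angles, loop-state classification and transition detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allostery import (OrientationDefinition, ReferenceState, Selection,
                       build_toy, classify_frames, generate_equilibration,
                       loop_rmsd_series, orientation_series, state_statistics,
                       transition_detect)
from allostery.conformation import UNASSIGNED, StateCall
from allostery.structio import Trajectory
from allostery.synthetic import SyntheticSpec, _rotation_about


@pytest.fixture(scope="module")
def system():
    return build_toy(seed=4)


def egf_odef(system):
    sel = system.selections
    return OrientationDefinition(
        hinge_sel=Selection(sel["hinge1"]), body_sel=Selection(sel["egf"]),
        align_sel=Selection(sel["lec_rigid"]), reference=system.structure)


class TestOrientationSeries:
    def test_reference_frame_gives_zero(self, system):
        traj = Trajectory(system.structure, [system.structure.coords], [0.0])
        angle = orientation_series(traj, egf_odef(system))[0]
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_constructed_rotation_recovered(self, system):
        """Body rotated 37° about an axis through the hinge center ⊥ v_ref."""
        coords = system.structure.coords
        idx = system.index_sets
        h = coords[idx["hinge1"]].mean(axis=0)
        v = coords[idx["egf"]].mean(axis=0) - h
        axis = np.cross(v, [1.0, 0.0, 0.0])
        axis /= np.linalg.norm(axis)
        R = _rotation_about(axis, 37.0)
        moved = coords.copy()
        moved[idx["egf"]] = (moved[idx["egf"]] - h) @ R.T + h
        traj = Trajectory(system.structure, [moved], [0.0])
        angle = orientation_series(traj, egf_odef(system))[0]
        assert angle == pytest.approx(37.0, abs=1e-6)

    def test_global_rigid_motion_invariance(self, system):
        rng = np.random.default_rng(0)
        coords = system.structure.coords
        frames = [coords]
        from allostery.synthetic import _random_rigid_motion
        for _ in range(30):
            Q, t = _random_rigid_motion(rng)
            frames.append(coords @ Q.T + t)
        traj = Trajectory(system.structure, frames)
        angles = orientation_series(traj, egf_odef(system))
        np.testing.assert_allclose(angles, angles[0], atol=1e-6)

    def test_programmed_schedule_recovered(self, system):
        spec = SyntheticSpec(seed=4, mode="equilibration",
                             theta_schedule=[(0, 20.0), (5, 150.0), (10, 60.0)])
        traj, truth = generate_equilibration(system, spec)
        angles = orientation_series(traj, egf_odef(system))
        np.testing.assert_allclose(angles, truth.theta_egf_deg, atol=1e-6)

    def test_hinge_body_overlap_rejected(self, system):
        sel = system.selections
        with pytest.raises(ValueError, match="overlap"):
            OrientationDefinition(Selection(sel["hinge1"]),
                                  Selection("chain A and resid 120-141"),
                                  Selection(sel["lec_rigid"]),
                                  system.structure)


class TestLoopRmsdSeries:
    def refs(self, system):
        sel = system.selections
        return [ReferenceState(lab, system.references[lab],
                               Selection(sel["lec_rigid"]), Selection(sel["loop"]))
                for lab in ("S1", "S1'", "S2")]

    def test_zero_against_own_reference(self, system):
        traj = Trajectory(system.structure,
                          [system.references["S1'"].coords], [0.0])
        series = loop_rmsd_series(traj, self.refs(system))
        assert series.loc[0, "S1'"] == pytest.approx(0.0, abs=1e-9)
        assert series.loc[0, "S1"] > 10.0

    def test_reference_order_permutes_columns_only(self, system):
        traj = Trajectory(system.structure, [system.structure.coords], [0.0])
        refs = self.refs(system)
        a = loop_rmsd_series(traj, refs)
        b = loop_rmsd_series(traj, refs[::-1])
        for lab in ("S1", "S1'", "S2"):
            assert a.loc[0, lab] == pytest.approx(b.loc[0, lab], abs=1e-12)

    def test_monotone_ramp_toward_target_state(self, system):
        spec = SyntheticSpec(seed=4, mode="equilibration",
                             theta_schedule=[(0, 0.0), (10, 0.0)],
                             loop_schedule=[(0, "S1"), (50, "S2")],
                             loop_blend_frames=100)
        traj, _ = generate_equilibration(system, spec)
        series = loop_rmsd_series(traj, self.refs(system))
        ramp = series["S2"].to_numpy()[50:150]
        assert np.all(np.diff(ramp) < 0)  # approaching S2 monotonically


class TestClassifyFrames:
    def frame(self, s1, s1p, s2):
        return pd.DataFrame({"S1": [s1], "S1'": [s1p], "S2": [s2]})

    @pytest.mark.parametrize("rmsds, expected", [
        ((3.0, 6.0, 7.0), "S1"),            # single qualifier
        ((3.5, 3.8, 9.0), "S1'"),           # S1/S1' dual qualifier → S1'
        ((4.0, 6.0, 7.0), "S1"),            # boundary inclusive
        ((5.0, 6.0, 7.0), UNASSIGNED),      # no qualifier
        ((9.0, 3.9, 3.2), "S2"),            # S2 + other → smaller RMSD
        ((3.0, 3.5, 2.0), "S2"),            # triple: S1 absorbed, S2 smallest
    ])
    def test_call_rules(self, rmsds, expected):
        calls = classify_frames(self.frame(*rmsds), threshold=4.0)
        assert calls[0].call == expected

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        series = pd.DataFrame({
            "S1": rng.uniform(0, 10, 200), "S1'": rng.uniform(0, 10, 200),
            "S2": rng.uniform(0, 10, 200)})
        lo = classify_frames(series, threshold=3.0)
        hi = classify_frames(series, threshold=6.0)
        for c_lo, c_hi in zip(lo, hi):
            if c_lo.call != UNASSIGNED:
                assert c_hi.call != UNASSIGNED

    def test_total_and_deterministic(self):
        rng = np.random.default_rng(2)
        series = pd.DataFrame({"S1": rng.uniform(0, 8, 50),
                               "S1'": rng.uniform(0, 8, 50),
                               "S2": rng.uniform(0, 8, 50)})
        a = [c.call for c in classify_frames(series)]
        b = [c.call for c in classify_frames(series)]
        assert a == b
        assert len(a) == 50

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_frames(self.frame(1, 2, 3), threshold=0.0)


class TestStateStatistics:
    def calls(self, labels):
        return [StateCall(i, {}, lab) for i, lab in enumerate(labels)]

    def test_constant_weights(self):
        calls = self.calls(["S1"] * 4)
        stats = state_statistics(calls, weights=np.full(4, -30.0))
        assert stats.loc["S1", "n"] == 4
        assert stats.loc["S1", "fraction"] == 1.0
        assert stats.loc["S1", "mean"] == pytest.approx(-30.0)
        assert stats.loc["S1", "sd"] == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        calls = self.calls(["S2", "S2"])
        stats = state_statistics(calls, weights=np.array([-10.0, -20.0]))
        assert stats.loc["S2", "mean"] == pytest.approx(-15.0)
        assert stats.loc["S2", "sd"] == pytest.approx(np.sqrt(50.0))  # ≈7.071

    def test_unassigned_excluded_and_fractions(self):
        calls = self.calls(["S1", UNASSIGNED, "S1", "S2"])
        stats = state_statistics(calls, weights=np.array([1.0, 99.0, 3.0, 5.0]))
        assert stats.loc["S1", "mean"] == pytest.approx(2.0)
        assert stats.loc["S1", "fraction"] == pytest.approx(0.5)
        assert stats.loc["S2", "n"] == 1
        assert np.isnan(stats.loc["S2", "sd"])  # single frame → SD absent

    def test_empty_state_reports_absent_not_zero(self):
        calls = [StateCall(0, {"S1": 1.0, "S2": 9.0}, "S1")]
        stats = state_statistics(calls, weights=np.array([-5.0]))
        assert stats.loc["S2", "n"] == 0
        assert np.isnan(stats.loc["S2", "mean"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            state_statistics(self.calls(["S1"]), weights=np.zeros(3))


class TestTransitionDetect:
    def calls(self, labels):
        return [StateCall(i, {}, lab) for i, lab in enumerate(labels)]

    def test_constant_sequence_has_no_transitions(self):
        assert transition_detect(self.calls(["S1"] * 30), min_dwell=5) == []

    def test_single_persistent_switch(self):
        labels = ["S1"] * 20 + ["S1'"] * 20
        assert transition_detect(self.calls(labels), min_dwell=10) == [("S1", "S1'", 20)]

    def test_blip_shorter_than_dwell_ignored(self):
        labels = ["S1"] * 10 + ["S2"] + ["S1"] * 10
        assert transition_detect(self.calls(labels), min_dwell=2) == []

    def test_unassigned_does_not_break_dwell(self):
        labels = (["S1"] * 10 + [UNASSIGNED] * 5 + ["S1'"] * 3
                  + [UNASSIGNED] * 4 + ["S1'"] * 3)
        got = transition_detect(self.calls(labels), min_dwell=5)
        assert got == [("S1", "S1'", 15)]

    def test_programmed_switch_recovered_from_generator(self, system):
        spec = SyntheticSpec(seed=4, mode="equilibration",
                             theta_schedule=[(0, 0.0), (10, 0.0)],
                             loop_schedule=[(0, "S1"), (60, "S1'")],
                             loop_blend_frames=1)
        traj, truth = generate_equilibration(system, spec)
        sel = system.selections
        refs = [ReferenceState(lab, system.references[lab],
                               Selection(sel["lec_rigid"]), Selection(sel["loop"]))
                for lab in ("S1", "S1'", "S2")]
        calls = classify_frames(loop_rmsd_series(traj, refs))
        got = transition_detect(calls, min_dwell=10)
        assert [list(t) for t in got] == truth.transitions
        assert got[0][2] == 60

    def test_min_dwell_validation(self):
        with pytest.raises(ValueError):
            transition_detect([], min_dwell=0)
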