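"""Per-step gait parameters: spatiotemporal, GRF, angles, moments, assembly."""

import numpy as np
import pandas as pd
import pytest

from cgam.errors import ParameterError
from cgam.events import GaitEventTable, SideEvents, build_step_sequence
from cgam.io import ForcePlate, Subject, TrialRecording
from cgam.parameters import (
    CANONICAL_PARAMS,
    SPATIOTEMPORAL_SUBSET,
    WINTER_ANTHROPOMETRY,
    angle_summary,
    compute_parameters,
    grf_features,
    inverse_dynamics_2d,
    joint_angles,
    moment_summary,
    step_lengths,
    step_times,
)
from cgam.pipeline import analyze_trial, detect_events

from conftest import match_truth


def _events(l_hs, l_to, r_hs, r_to):
    return build_step_sequence(
        SideEvents(hs=np.asarray(l_hs, float), to=np.asarray(l_to, float)),
        SideEvents(hs=np.asarray(r_hs, float), to=np.asarray(r_to, float)),
    )


def _static_trial(marker_pos, n=200, rate=100.0, force=None, cop=None,
                  mass=70.0):
    markers = {k: np.tile(np.asarray(v, float), (n, 1)) for k, v in marker_pos.items()}
    f = np.tile(force if force is not None else [0.0, 0.0, 0.0], (n, 1))
    c = np.tile(cop if cop is not None else [0.0, 0.0, 0.0], (n, 1))
    fp = {s: ForcePlate(force=f.copy(), cop=c.copy()) for s in ("left", "right")}
    return TrialRecording(markers=markers, marker_rate=rate, forces=fp,
                          force_rate=rate, subject=Subject(mass, 0.94, 0.9))


def _leg(p, x, hip=(0.0, 1.0), knee=(0.0, 0.55), ankle=(0.0, 0.10),
         heel=(-0.05, 0.05), toe=(0.15, 0.05)):
    return {
        f"{p}ASI": [x, *hip], f"{p}KNE": [x, *knee], f"{p}ANK": [x, *ankle],
        f"{p}HEE": [x, *heel], f"{p}TOE": [x, *toe],
    }


class TestSpatiotemporal:
    def test_periodic_symmetric_step_times(self):
        ev = _events([1.0, 2.2, 3.4], [1.7, 2.9, 4.1],
                     [1.6, 2.8, 4.0], [2.3, 3.5, 4.7])
        st = step_times(ev)
        np.testing.assert_allclose(st["value"], 0.6)

    def test_asymmetric_step_times_recovered(self, default_trial):
        trial, truth = default_trial
        ev = detect_events(trial)
        st = step_times(ev)
        for side, col in (("left", "ST_L"), ("right", "ST_R")):
            got = st[st["side"] == side]["value"].to_numpy()
            want = truth.steps[col].dropna().to_numpy()
            assert abs(np.mean(got) - np.mean(want)) < 1e-3

    def test_static_heels_step_length(self):
        pos = {**_leg("L", -0.1), **_leg("R", 0.1)}
        pos["LHEE"] = [-0.1, 0.5, 0.05]
        pos["RHEE"] = [0.1, 0.0, 0.05]
        trial = _static_trial(pos)
        ev = _events([0.5], [1.0], [1.1], [1.6])
        sl = step_lengths(trial, ev)
        # left heel 0.5 m ahead: left step +0.5, right step -0.5... the right
        # step length is the anterior distance of RHEE past LHEE, i.e. -0.5
        left = sl[sl["side"] == "left"]["value"].to_numpy()
        np.testing.assert_allclose(left, 0.5, atol=1e-12)

    def test_side_swap_exchanges_step_lengths(self, default_trial):
        trial, _ = default_trial
        ev = detect_events(trial)
        sl = step_lengths(trial, ev)
        swapped = TrialRecording(
            markers={("R" + k[1:]) if k.startswith("L") else
                     ("L" + k[1:]) if k.startswith("R") else k: v
                     for k, v in trial.markers.items()},
            marker_rate=trial.marker_rate,
            forces={"left": trial.forces["right"], "right": trial.forces["left"]},
            force_rate=trial.force_rate, subject=trial.subject)
        ev_sw = detect_events(swapped)
        sl_sw = step_lengths(swapped, ev_sw)
        for a, b in (("left", "right"), ("right", "left")):
            np.testing.assert_allclose(
                sl[sl["side"] == a]["value"].to_numpy(),
                sl_sw[sl_sw["side"] == b]["value"].to_numpy(), atol=1e-9)


class TestGrfFeatures:
    def test_analytic_stance_template(self):
        rate, mass = 1000.0, 70.0
        bw = mass * 9.81
        t = np.arange(0, 1.0, 1 / rate)
        tau = np.clip(t / 0.7, 0, 1)
        fz = 1.1 * bw * np.sin(np.pi * tau)
        fy = 0.2 * bw * -np.sin(2 * np.pi * tau)
        force = np.column_stack([np.zeros_like(t), fy, fz])
        out = grf_features(force, rate, [(0.0, 0.7)], body_mass=mass)
        np.testing.assert_allclose(out.loc[0, ["GRF", "BF", "PF"]],
                                   [1.1, 0.2, 0.2], atol=1e-3)

    def test_zero_ap_force_gives_zero_features(self):
        force = np.column_stack([np.zeros(100), np.zeros(100), np.full(100, 700.0)])
        out = grf_features(force, 100.0, [(0.0, 0.5)], body_mass=70.0)
        assert out.loc[0, "BF"] == 0.0 and out.loc[0, "PF"] == 0.0

    def test_body_weight_normalization_cancels_scale(self):
        rng = np.random.default_rng(3)
        force = np.column_stack([np.zeros(200), rng.normal(0, 50, 200),
                                 np.abs(rng.normal(700, 50, 200))])
        a = grf_features(force, 100.0, [(0.0, 1.0)], body_mass=70.0)
        b = grf_features(2 * force, 100.0, [(0.0, 1.0)], body_mass=140.0)
        pd.testing.assert_frame_equal(a, b)


class TestJointAngles:
    def test_collinear_leg_zero_knee(self):
        trial = _static_trial({**_leg("L", -0.1), **_leg("R", 0.1)})
        ang = joint_angles(trial)
        np.testing.assert_allclose(ang["left"]["knee"], 0.0, atol=1e-9)
        np.testing.assert_allclose(ang["left"]["hip"], 0.0, atol=1e-9)

    def test_thigh_vertical_shank_flexed_30(self):
        # knee flexion carries the ankle posteriorly: shank 30 deg from vertical
        ankle = (0.0 - 0.45 * np.sin(np.radians(30.0)),
                 0.55 - 0.45 * np.cos(np.radians(30.0)))
        trial = _static_trial({**_leg("L", -0.1, ankle=ankle), **_leg("R", 0.1)})
        ang = joint_angles(trial)
        np.testing.assert_allclose(ang["left"]["knee"], 30.0, atol=1e-9)

    def test_neutral_ankle_zero(self):
        # shank vertical, foot horizontal
        trial = _static_trial({**_leg("L", -0.1, heel=(-0.05, 0.05), toe=(0.15, 0.05)),
                               **_leg("R", 0.1)})
        ang = joint_angles(trial)
        np.testing.assert_allclose(ang["left"]["ankle"], 0.0, atol=1e-9)

    def test_mirror_and_side_swap_invariance(self, default_trial):
        """Negating X and swapping side labels leaves all angles invariant."""
        trial, _ = default_trial
        mirrored = TrialRecording(
            markers={("R" + k[1:]) if k.startswith("L") else
                     ("L" + k[1:]) if k.startswith("R") else k:
                     v * np.array([-1.0, 1.0, 1.0]) for k, v in trial.markers.items()},
            marker_rate=trial.marker_rate,
            forces={"left": trial.forces["right"], "right": trial.forces["left"]},
            force_rate=trial.force_rate, subject=trial.subject)
        a = joint_angles(trial)
        b = joint_angles(mirrored)
        for s1, s2 in (("left", "right"), ("right", "left")):
            pd.testing.assert_frame_equal(a[s1], b[s2])


class TestSummaries:
    def test_constant_series_zero_range(self):
        assert angle_summary(np.full(100, 12.0), 100.0, (0.0, 0.9)) == 0.0

    def test_sine_amplitude_range(self):
        t = np.arange(0, 1.2, 1e-3)
        series = 30.0 * np.sin(2 * np.pi * t / 1.2)
        assert abs(angle_summary(series, 1000.0, (0.0, 1.199)) - 60.0) < 0.01

    def test_triangular_pulse_moment_range(self):
        series = np.concatenate([np.linspace(0, 1.5, 50),
                                 np.linspace(1.5, 0, 50), np.zeros(60)])
        assert moment_summary(series, 100.0, (0.0, 1.59)) == pytest.approx(1.5)

    def test_programmed_asymmetric_moment_templates_recovered(self):
        # per-stride scaled templates: range recovered within 2 %
        t = np.arange(0, 2.4, 1e-2)
        amp = np.where(t < 1.2, 1.8, 1.2)
        series = amp * np.sin(2 * np.pi * t / 1.2) ** 2
        for window, want in (((0.0, 1.19), 1.8), ((1.2, 2.39), 1.2)):
            got = moment_summary(series, 100.0, window)
            assert abs(got - want) / want < 0.02


class TestInverseDynamics:
    def _static_events(self, n=200, rate=100.0):
        se = SideEvents(hs=np.array([0.0]), to=np.array([(n - 1) / rate]))
        return GaitEventTable(
            left=se, right=SideEvents(hs=np.array([0.0]),
                                      to=np.array([(n - 1) / rate])),
            sequence=[])

    def test_static_cop_under_ankle_zero_moment(self):
        # foot axis vertical so gravity has no lever about the ankle
        pos = {**_leg("L", -0.1, heel=(0.0, 0.15), toe=(0.0, 0.0)),
               **_leg("R", 0.1, heel=(0.0, 0.15), toe=(0.0, 0.0))}
        trial = _static_trial(pos, force=[0.0, 0.0, 700.0], cop=[0.0, 0.0, 0.0])
        mom = inverse_dynamics_2d(trial, self._static_events())
        assert abs(mom["left"]["ankle"].iloc[100]) < 1e-6

    def test_static_anterior_cop_closed_form(self):
        # 700 N at 0.1 m lever, 70 kg: |ankle moment| = 1.0 N*m/kg
        pos = {**_leg("L", -0.1, heel=(0.0, 0.15), toe=(0.0, 0.0)),
               **_leg("R", 0.1, heel=(0.0, 0.15), toe=(0.0, 0.0))}
        trial = _static_trial(pos, force=[0.0, 0.0, 700.0], cop=[0.0, 0.1, 0.0],
                              mass=70.0)
        mom = inverse_dynamics_2d(trial, self._static_events())
        assert abs(abs(mom["left"]["ankle"].iloc[100]) - 1.0) < 1e-6

    def test_swing_pendulum_matches_analytic_torque(self):
        """Shank+foot swinging rigidly about a fixed knee, no external force:
        the recursive knee moment matches the closed-form rigid-body torque."""
        n, rate = 400, 100.0
        t = np.arange(n) / rate
        th0, om = np.radians(25.0), 2 * np.pi * 0.8
        th = th0 * np.sin(om * t)
        thd = th0 * om * np.cos(om * t)
        thdd = -th0 * om ** 2 * np.sin(om * t)

        knee0 = np.array([0.08, 0.55])  # (y, z)
        Ls = 0.45
        rig = {"ankle": np.array([0.0, -Ls]),
               "heel": np.array([-0.05, -Ls - 0.05]),
               "toe": np.array([0.15, -Ls - 0.05])}

        def rot(v, a):
            c, s = np.cos(a), np.sin(a)
            return np.stack([c * v[0] + s * v[1], -s * v[0] + c * v[1]], axis=-1)

        markers = {}
        for p, x in (("L", -0.1), ("R", 0.1)):
            markers[f"{p}ASI"] = np.tile([x, 0.08, 1.0], (n, 1))
            markers[f"{p}KNE"] = np.tile([x, *knee0], (n, 1))
            for name, lab in (("ankle", "ANK"), ("heel", "HEE"), ("toe", "TOE")):
                yz = knee0 + rot(rig[name], th)
                markers[f"{p}{lab}"] = np.column_stack([np.full(n, x), yz])
        zero = np.zeros((n, 3))
        fp = {s: ForcePlate(force=zero.copy(), cop=zero.copy())
              for s in ("left", "right")}
        trial = TrialRecording(markers=markers, marker_rate=rate, forces=fp,
                               force_rate=rate, subject=Subject(70.0, 0.94, 0.9))
        empty = SideEvents(hs=np.empty(0), to=np.empty(0))
        events = GaitEventTable(left=empty, right=empty, sequence=[])
        got = inverse_dynamics_2d(trial, events)["left"]["knee"].to_numpy()

        # independent d'Alembert oracle with exact analytic accelerations
        M = 70.0
        g = np.array([0.0, -9.81])
        segs = []
        fr = WINTER_ANTHROPOMETRY
        com_s0 = rig["ankle"] * fr.shank.com
        com_f0 = rig["heel"] + fr.foot.com * (rig["toe"] - rig["heel"])
        lf = np.linalg.norm(rig["toe"] - rig["heel"])
        segs.append((fr.shank.mass * M, com_s0,
                     fr.shank.mass * M * (fr.shank.rog * Ls) ** 2))
        segs.append((fr.foot.mass * M, com_f0,
                     fr.foot.mass * M * (fr.foot.rog * lf) ** 2))
        want = np.zeros(n)
        for m_seg, c0, inertia in segs:
            r = rot(c0, th)  # com relative to knee
            acc = (np.stack([thdd, thdd], axis=-1) * rot(c0, th + np.pi / 2)
                   - np.stack([thd ** 2, thd ** 2], axis=-1) * rot(c0, th))
            want += (-inertia * thdd
                     + m_seg * (r[:, 0] * (acc - g)[:, 1]
                                - r[:, 1] * (acc - g)[:, 0]))
        want /= M  # implementation reports moments normalized by body mass
        mid = slice(50, 350)
        scale = np.abs(want[mid]).max()
        assert np.abs(got[mid] - want[mid]).max() < 0.02 * scale


class TestAssembly:
    def test_full_pipeline_record_count_and_shape(self, default_trial):
        trial, _ = default_trial
        table = compute_parameters(trial, detect_events(trial))
        complete = table.complete()
        assert len(complete) == 20
        for p in CANONICAL_PARAMS:
            assert f"{p}_L" in complete.columns and f"{p}_R" in complete.columns
            assert np.isfinite(complete[[f"{p}_L", f"{p}_R"]].to_numpy()).all()

    def test_five_parameter_subset(self, default_trial):
        trial, _ = default_trial
        table = compute_parameters(trial, detect_events(trial),
                                   active=SPATIOTEMPORAL_SUBSET)
        assert table.params == SPATIOTEMPORAL_SUBSET
        value_cols = [c for c in table.data.columns
                      if c.endswith(("_L", "_R")) and not c.startswith("t_hs")]
        assert len(value_cols) == 10

    def test_marker_dropout_flags_record(self, default_trial):
        trial, _ = default_trial
        broken = TrialRecording(
            markers={k: v.copy() for k, v in trial.markers.items()},
            marker_rate=trial.marker_rate, forces=trial.forces,
            force_rate=trial.force_rate, subject=trial.subject)
        ev = detect_events(broken)
        # NaN out the left heel around one mid-trial heel strike
        t_bad = ev.left.hs[10]
        i = int(round(t_bad * broken.marker_rate))
        broken.markers["LHEE"][i - 2:i + 3] = np.nan
        table = compute_parameters(broken, ev, active=("SL", "ST"),
                                   condition=False)
        flags = table.data["complete"]
        assert (~flags).sum() == 1
        assert flags.sum() >= 19

    def test_empty_active_set_rejected(self, default_trial):
        trial, _ = default_trial
        with pytest.raises(ParameterError, match="empty"):
            compute_parameters(trial, detect_events(trial), active=())

    def test_truth_recovery_all_parameters(self, default_trial):
        trial, truth = default_trial
        an = analyze_trial(trial)
        ext = an.table.complete()
        tol = {"ST": 1.001e-3, "SL": 5e-3, "GRF": 1e-3, "PF": 1e-3,
               "BF": 1e-3, "KA": 1.0, "AA": 1.0, "HA": 1.0}
        for suf in ("_L", "_R"):
            for p, lim in tol.items():
                err = match_truth(ext, truth.steps, p, suf)
                assert err.max() < lim, f"{p}{suf}: {err.max()}"
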