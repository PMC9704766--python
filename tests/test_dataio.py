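import numpy as np
import pandas as pd
import pytest

from latstep.dataio import (
    EXCLUSION_WINDOW,
    align_maneuvers,
    classify_strategy,
    estimate_epsilon,
    estimate_steady_goals,
    generate_synthetic_experiment,
    make_crossover_fixture,
    make_multistep_fixture,
    read_stepping_csv,
    stepping_errors,
    write_stepping_csv,
)


def _tiny_table():
    """Hand-built two-maneuver rightward table with obvious structure."""
    rows = []
    for mid in ("M1", "M2"):
        for i in range(-13, 19):
            if i <= 0:
                z_L, z_R = -0.36, -0.24
            else:
                z_L, z_R = 0.24, 0.36
            foot = "right" if i % 2 else "left"
            rows.append((mid, i, foot, z_L, z_R))
    return pd.DataFrame(rows, columns=["maneuver_id", "step_index", "moving_foot", "z_L_m", "z_R_m"])


class TestInterchange:
    def test_round_trip(self, tmp_path, synthetic_table):
        path = tmp_path / "steps.csv"
        write_stepping_csv(synthetic_table, path)
        back = read_stepping_csv(path)
        for col in ("maneuver_id", "step_index", "moving_foot"):
            assert (back[col] == synthetic_table[col]).all()
        for col in ("z_L_m", "z_R_m", "z_B_m", "w_m"):
            assert np.allclose(back[col], synthetic_table[col])

    def test_tab_delimited_autodetected(self, tmp_path):
        path = tmp_path / "steps.tsv"
        write_stepping_csv(_tiny_table(), path, sep="\t")
        back = read_stepping_csv(path)
        assert len(back) == len(_tiny_table())

    def test_derives_step_variables_when_absent(self, tmp_path):
        path = tmp_path / "feet_only.csv"
        _tiny_table().to_csv(path, index=False)
        table = read_stepping_csv(path)
        assert np.allclose(table["z_B_m"], 0.5 * (table["z_L_m"] + table["z_R_m"]))
        assert np.allclose(table["w_m"], table["z_R_m"] - table["z_L_m"])

    def test_missing_columns_listed(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"maneuver_id": ["a"], "z_L_m": [0.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="step_index"):
            read_stepping_csv(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "malformed.csv"
        t = _tiny_table().head(4).copy()
        t["z_L_m"] = t["z_L_m"].astype(object)
        t.loc[2, "z_L_m"] = "oops"
        t.to_csv(path, index=False)
        with pytest.raises(ValueError, match="line"):
            read_stepping_csv(path)

    def test_inconsistent_derived_columns_warn(self, tmp_path, caplog):
        path = tmp_path / "inconsistent.csv"
        t = _tiny_table().head(6).copy()
        t["w_m"] = 99.0
        t.to_csv(path, index=False)
        with caplog.at_level("WARNING", logger="latstep.dataio"):
            read_stepping_csv(path)
        assert any("inconsistent" in rec.message for rec in caplog.records)


class TestAlignment:
    def test_synthetic_rightward_unchanged(self, synthetic_table):
        aligned = align_maneuvers(synthetic_table)
        one = aligned[aligned["maneuver_id"] == "P01-M1"]
        orig = synthetic_table[synthetic_table["maneuver_id"] == "P01-M1"]
        assert sorted(one["step_index"]) == sorted(orig["step_index"])
        assert np.allclose(
            one.sort_values("step_index")["z_L_m"], orig.sort_values("step_index")["z_L_m"]
        )

    def test_mirrored_copy_aligns_to_same_records(self, synthetic_table):
        one = synthetic_table[synthetic_table["maneuver_id"] == "P01-M1"].copy()
        mirrored = one.copy()
        mirrored["z_L_m"], mirrored["z_R_m"] = -one["z_R_m"].to_numpy(), -one["z_L_m"].to_numpy()
        mirrored["moving_foot"] = one["moving_foot"].map({"left": "right", "right": "left"})
        mirrored["maneuver_id"] = "MIR"
        both = align_maneuvers(pd.concat([one, mirrored], ignore_index=True))
        a = both[both["maneuver_id"] == "P01-M1"].sort_values("step_index")
        b = both[both["maneuver_id"] == "MIR"].sort_values("step_index")
        assert np.allclose(a["z_L_m"].to_numpy(), b["z_L_m"].to_numpy(), atol=1e-12)
        assert (a["moving_foot"].to_numpy() == b["moving_foot"].to_numpy()).all()

    def test_idempotent(self, synthetic_table):
        once = align_maneuvers(synthetic_table)
        twice = align_maneuvers(once)
        pd.testing.assert_frame_equal(
            once.sort_values(["maneuver_id", "step_index"]).reset_index(drop=True),
            twice.sort_values(["maneuver_id", "step_index"]).reset_index(drop=True),
        )

    def test_no_crossing_excluded_with_log(self, caplog):
        t = _tiny_table()
        flat = t[t["maneuver_id"] == "M1"].copy()
        flat[["z_L_m", "z_R_m"]] = (-0.36, -0.24)  # never leaves the path
        flat["maneuver_id"] = "FLAT"
        with caplog.at_level("WARNING", logger="latstep.dataio"):
            aligned = align_maneuvers(pd.concat([t, flat], ignore_index=True))
        assert "FLAT" not in set(aligned["maneuver_id"])
        assert any("FLAT" in rec.message for rec in caplog.records)

    def test_midline_tie_assigned_to_new_path(self):
        t = _tiny_table()
        m1 = t[t["maneuver_id"] == "M1"].copy().reset_index(drop=True)
        # transition foot lands exactly on the midline (0.0)
        pos = m1.index[m1["step_index"] == 1][0]
        m1.loc[pos, ["z_L_m", "z_R_m"]] = (-0.36, 0.0)
        aligned = align_maneuvers(m1)
        # step 1 is still the crossing step, so step 0 stays at initiation
        assert set(aligned["step_index"]) == set(m1["step_index"])


class TestClassification:
    def test_default_maneuver_is_ipsilateral_single_step(self, synthetic_table):
        aligned = align_maneuvers(synthetic_table)
        one = aligned[aligned["maneuver_id"] == "P01-M1"]
        assert classify_strategy(one) == "ipsilateral_single_step"

    def test_crossover_fixture(self):
        fx = align_maneuvers(make_crossover_fixture("C1"))
        assert classify_strategy(fx) == "crossover"

    def test_multistep_fixture(self):
        fx = align_maneuvers(make_multistep_fixture("S1"))
        assert classify_strategy(fx) == "multi_step"


class TestSteadyGoals:
    def test_recovery_on_goal_tracking_generator(self, accurate_table):
        aligned = align_maneuvers(accurate_table)
        est = estimate_steady_goals(aligned)
        # steps are autocorrelated within a maneuver: cluster the SE at the
        # maneuver level
        pre = aligned[aligned["step_index"] < EXCLUSION_WINDOW[0]]
        post = aligned[aligned["step_index"] > EXCLUSION_WINDOW[1]]

        def cluster_se(groups):
            means = groups.mean()
            return means.std(ddof=1) / np.sqrt(len(means))

        se_pre = cluster_se(pre.groupby("maneuver_id")["z_B_m"])
        se_post = cluster_se(post.groupby("maneuver_id")["z_B_m"])
        se_w = cluster_se(pd.concat([pre, post]).groupby("maneuver_id")["w_m"])
        assert abs(est.z_B_star_left_path - (-0.3)) < 3 * se_pre
        assert abs(est.z_B_star_right_path - 0.3) < 3 * se_post
        assert abs(est.w_star - 0.12) < 3 * se_w

    def test_default_generator_recovers_goals_loosely(self, synthetic_table):
        """With gamma/alpha = 0.1 the post-transition window retains a small
        deterministic undershoot (partial error correction), so recovery is
        asserted only to 0.02 m here."""
        est = estimate_steady_goals(align_maneuvers(synthetic_table))
        assert est.z_B_star_left_path == pytest.approx(-0.3, abs=0.02)
        assert est.z_B_star_right_path == pytest.approx(0.3, abs=0.02)
        assert est.w_star == pytest.approx(0.12, abs=0.01)

    def test_exclusion_window_boundaries(self):
        t = _tiny_table()
        est_all = estimate_steady_goals(t)
        # moving step -6 into the window must change nothing; step -5 is excluded
        boundary = t[t["step_index"].isin([-5, 10])]
        included = t[~t["step_index"].isin(range(EXCLUSION_WINDOW[0], EXCLUSION_WINDOW[1] + 1))]
        assert est_all.n_steps == len(included)
        assert -6 in set(included["step_index"]) and -5 not in set(included["step_index"])
        assert 11 in set(included["step_index"]) and 10 not in set(included["step_index"])
        assert len(boundary) > 0

    def test_only_excluded_steps_errors(self):
        t = _tiny_table()
        window_only = t[t["step_index"].between(*EXCLUSION_WINDOW)]
        with pytest.raises(ValueError):
            estimate_steady_goals(window_only)


class TestSteppingErrors:
    def test_noiseless_perfect_walker_zero_errors(self, noiseless_regs):
        reg_zB, reg_w = noiseless_regs
        reg_zB = reg_zB.__class__(q_star=0.0, gamma=0.0, sigma_a=0.0)
        reg_w = reg_w.__class__(q_star=0.12, gamma=0.0, sigma_a=0.0)
        table = generate_synthetic_experiment(
            n_participants=2, n_maneuvers=2, seed=5, reg_zB=reg_zB, reg_w=reg_w
        )
        aligned = align_maneuvers(table)
        goals = estimate_steady_goals(aligned)
        per_step, summary = stepping_errors(aligned, goals)
        steady = per_step[~per_step["step_index"].between(-5, 10)]
        assert np.allclose(steady[["F_zB", "F_w"]], 0.0, atol=1e-9)

    def test_position_goal_switches_at_initiation(self):
        t = _tiny_table()
        goals = estimate_steady_goals(t)
        per_step, _ = stepping_errors(t, goals)
        at0 = per_step[per_step["step_index"] == 0].iloc[0]
        at1 = per_step[per_step["step_index"] == 1].iloc[0]
        assert at0["F_zB"] == pytest.approx(at0["z_B_m"] - goals.z_B_star_left_path)
        assert at1["F_zB"] == pytest.approx(at1["z_B_m"] - goals.z_B_star_right_path)

    def test_maneuver_width_error_sd_exceeds_steady(self, synthetic_table):
        """Doubling sigma_a at the preparatory/transition steps inflates the
        width-error SD well above steady state.  (The position-error SD is
        already large at steady state — position is only weakly regulated —
        so no comparable increase is expected there.)"""
        aligned = align_maneuvers(synthetic_table)
        goals = estimate_steady_goals(aligned)
        _, summary = stepping_errors(aligned, goals)
        steady_idx = [i for i in summary.index if i < -5 or i > 10]
        steady_sd_w = summary.loc[steady_idx, "sd_F_w"].mean()
        assert summary.loc[0, "sd_F_w"] > 1.5 * steady_sd_w
        assert summary.loc[1, "sd_F_w"] > 1.5 * steady_sd_w


class TestEpsilonEstimate:
    def test_noiseless_exact(self):
        from latstep.regulator import RegulatorParams

        table = generate_synthetic_experiment(
            n_participants=2,
            n_maneuvers=2,
            seed=6,
            reg_zB=RegulatorParams(0.0, gamma=0.0, sigma_a=0.0),
            reg_w=RegulatorParams(0.12, gamma=0.0, sigma_a=0.0),
        )
        aligned = align_maneuvers(table)
        assert estimate_epsilon(aligned) == pytest.approx(0.03, abs=1e-9)

    def test_recovery_within_three_se(self, accurate_table):
        aligned = align_maneuvers(accurate_table)
        # empirical SE of the estimator: signed offsets, one per maneuver per side
        pre = aligned[aligned["step_index"] < EXCLUSION_WINDOW[0]]
        post = aligned[aligned["step_index"] > EXCLUSION_WINDOW[1]]
        offs = np.concatenate(
            [
                aligned.loc[aligned["step_index"] == 0, "z_L_m"] - pre["z_L_m"].mean(),
                post["z_R_m"].mean() - aligned.loc[aligned["step_index"] == 2, "z_R_m"],
            ]
        )
        se = offs.std(ddof=1) / np.sqrt(len(offs))
        assert abs(estimate_epsilon(aligned) - 0.03) < 3 * se

    def test_zero_offset_table(self):
        t = _tiny_table()
        assert estimate_epsilon(t, prep_index=0, recovery_index=2) == pytest.approx(0.0)

    def test_missing_labeled_steps_error(self):
        t = _tiny_table()
        steady_only = t[~t["step_index"].isin([0, 2])]
        with pytest.raises(ValueError):
            estimate_epsilon(steady_only)


class TestGenerator:
    def test_pooled_steady_step_count(self, synthetic_table):
        steady = synthetic_table[
            (synthetic_table["step_index"] < EXCLUSION_WINDOW[0])
            | (synthetic_table["step_index"] > EXCLUSION_WINDOW[1])
        ]
        assert len(steady) == 20 * 4 * 16 == 1280

    def test_deterministic_under_seed(self):
        a = generate_synthetic_experiment(n_participants=2, n_maneuvers=2, seed=9)
        b = generate_synthetic_experiment(n_participants=2, n_maneuvers=2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_directions_alternate(self, synthetic_table):
        m1 = synthetic_table[synthetic_table["maneuver_id"] == "P01-M1"]
        m2 = synthetic_table[synthetic_table["maneuver_id"] == "P01-M2"]
        assert m1["z_B_m"].iloc[-1] > m1["z_B_m"].iloc[0]
        assert m2["z_B_m"].iloc[-1] < m2["z_B_m"].iloc[0]

    def test_one_cue_per_maneuver(self, synthetic_table):
        cues = synthetic_table.groupby("maneuver_id")["cue_flag"].sum()
        assert (cues == 1).all()
        cue_rows = synthetic_table[synthetic_table["cue_flag"]]
        assert cue_rows["step_index"].between(-3, 0).all()

    def test_fig5c_style_ordering_end_to_end(self, synthetic_table):
        """Generate -> align -> ellipses reproduces the qualitative pattern:
        aspect ratio minimal at the transition and below steady state at
        all three maneuver steps; area larger at preparatory/transition
        than at steady state."""
        from latstep.ellipse import fit_prediction_ellipse

        aligned = align_maneuvers(synthetic_table)

        def ellipse_at(idx):
            pts = aligned.loc[aligned["step_index"] == idx, ["z_L_m", "z_R_m"]].to_numpy()
            return fit_prediction_ellipse(pts)

        steady = aligned[aligned["step_index"] < EXCLUSION_WINDOW[0]]
        e_steady = fit_prediction_ellipse(steady[["z_L_m", "z_R_m"]].to_numpy())
        e_prep, e_trans, e_recov = ellipse_at(0), ellipse_at(1), ellipse_at(2)
        assert e_trans.aspect_ratio < e_prep.aspect_ratio < e_steady.aspect_ratio
        assert e_trans.aspect_ratio < e_recov.aspect_ratio < e_steady.aspect_ratio
        assert e_prep.area > e_steady.area
        assert e_trans.area > e_steady.area
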