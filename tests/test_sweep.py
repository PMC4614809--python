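"""Posture sweeps, classification, group statistics and mode differences."""

import math

import numpy as np
import pandas as pd
import pytest

from hipmoment import (
    MomentArmRecord,
    Posture,
    SweepProtocol,
    SynthSpec,
    ToySpec,
    classify_function,
    compare_cohorts,
    diff_modes,
    axis_frames,
    geometric_moment_arm,
    hinge_toy_moment_arm,
    make_hinge_toy,
    make_hip_model,
    records_to_frame,
    run_sweep,
    summarize_groups,
)
from hipmoment.sweep import summaries_to_frame


def _synthetic_records(values_by_muscle_dof, fe_grid, model="m", mode="corrected"):
    """Build records directly from prescribed normalized values."""
    records = []
    for (muscle, dof), values in values_by_muscle_dof.items():
        for fe, v in zip(fe_grid, values):
            records.append(
                MomentArmRecord(
                    model=model,
                    muscle=muscle,
                    dof=dof,
                    posture=Posture(fe, -10.0, 0.0),
                    mode=mode,
                    moment_arm=2.0 * v,
                    moment_arm_norm=v,
                )
            )
    return records


FE_GRID = list(range(-90, 91, 15))


def test_protocol_grid_arithmetic(default_protocol):
    grid = default_protocol.fe_grid()
    assert len(grid) == 13
    assert grid[0] == -90.0 and grid[-1] == 90.0
    assert np.allclose(np.diff(grid), 15.0)


def test_protocol_invalid():
    with pytest.raises(ValueError):
        SweepProtocol(fe_step_deg=0.0)
    with pytest.raises(ValueError):
        SweepProtocol(fe_min_deg=10, fe_max_deg=-10)
    with pytest.raises(ValueError):
        SweepProtocol(modes=("bogus",))


def test_sweep_record_count_and_offsets(small_hip_model):
    protocol = SweepProtocol(modes=("corrected", "legacy"))
    records = run_sweep(small_hip_model, protocol)
    n_muscles = len(small_hip_model.muscles)
    assert len(records) == n_muscles * 3 * 13 * 2
    for record in records:
        # 10 deg of abduction stored as -10 under positive-adduction signs
        assert record.posture.abd_deg == -10.0
        assert record.posture.lar_deg == 0.0
        assert record.moment_arm_norm * small_hip_model.femur_length == pytest.approx(
            record.moment_arm, rel=1e-12, abs=1e-15
        )


def test_single_muscle_three_dof_sweep_is_39_records():
    toy = make_hinge_toy(ToySpec(dof="FE"))
    records = run_sweep(toy, SweepProtocol(abd_offset_deg=0.0))
    assert len(records) == 39


def test_toy_sweep_matches_closed_form():
    toy = make_hinge_toy(ToySpec(dof="FE"))
    protocol = SweepProtocol(abd_offset_deg=0.0)
    records = run_sweep(toy, protocol, method="geometric")
    for record in records:
        if record.dof == "FE":
            assert record.moment_arm == pytest.approx(
                hinge_toy_moment_arm(1.0, 1.0, record.posture.fe_deg), abs=1e-12
            )


def test_sweep_requires_muscles(default_joint):
    from hipmoment import LimbModel

    empty = LimbModel("empty", default_joint, 1.0, ())
    with pytest.raises(ValueError, match="no muscles"):
        run_sweep(empty)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_switching_muscle_recovers_zero_crossing():
    values = [0.01 * math.sin(math.radians(fe)) for fe in FE_GRID]
    labels = classify_function(_synthetic_records({("s", "ABD"): values}, FE_GRID))
    (label,) = labels
    assert label.label == "switching"
    assert label.crossing_angle_deg == pytest.approx(0.0, abs=1.0)


def test_obligatory_and_negligible_labels():
    records = _synthetic_records(
        {
            ("pos", "ABD"): [0.1] * 13,
            ("neg", "ABD"): [-0.1] * 13,
            ("tiny", "ABD"): [0.001] * 13,
        },
        FE_GRID,
    )
    by_name = {l.muscle: l for l in classify_function(records)}
    assert by_name["pos"].label == "obligatory-positive"
    assert by_name["neg"].label == "obligatory-negative"
    assert by_name["tiny"].label == "negligible"
    assert by_name["pos"].crossing_angle_deg is None
    assert by_name["pos"].extremes == (0.1, 0.1)


def test_classification_needs_two_postures():
    records = _synthetic_records({("m1", "FE"): [0.1]}, [0.0])
    with pytest.raises(ValueError, match="2 sweep postures"):
        classify_function(records)


def test_classification_scale_invariant(small_hip_model):
    from hipmoment import scale_model

    protocol = SweepProtocol()
    labels = classify_function(run_sweep(small_hip_model, protocol))
    labels_scaled = classify_function(run_sweep(scale_model(small_hip_model, 10.0), protocol))
    assert [(l.muscle, l.dof, l.label) for l in labels] == [
        (l.muscle, l.dof, l.label) for l in labels_scaled
    ]


def test_crossing_angle_converges_with_grid_refinement():
    toy = make_hinge_toy(ToySpec(dof="FE"))
    crossings = []
    for step in (15.0, 5.0, 1.0):
        records = run_sweep(
            toy, SweepProtocol(fe_min_deg=-50, fe_max_deg=40, fe_step_deg=step, abd_offset_deg=0.0)
        )
        fe_labels = [l for l in classify_function(records) if l.dof == "FE"]
        crossings.append(fe_labels[0].crossing_angle_deg)
    errors = [abs(c - 0.0) for c in crossings]
    assert errors[-1] <= errors[0] + 1e-12
    assert errors[-1] < 0.1


# ---------------------------------------------------------------------------
# group summaries and cohorts
# ---------------------------------------------------------------------------

def test_signed_split_single_posture():
    records = _synthetic_records(
        {("a", "ABD"): [0.1, 0.1], ("b", "ABD"): [-0.2, -0.2]}, [0.0, 15.0]
    )
    summaries = summarize_groups(records)
    for s in summaries:
        assert s.summed_positive == pytest.approx(0.1)
        assert s.summed_negative_magnitude == pytest.approx(0.2)


def test_all_positive_muscle_has_zero_negative_sum():
    records = _synthetic_records({("a", "FE"): [0.3] * 13}, FE_GRID)
    for s in summarize_groups(records):
        assert s.summed_negative_magnitude == 0.0
        assert s.mean_negative_magnitude == 0.0
        assert s.mean_positive == pytest.approx(0.3)


def test_summary_conservation_against_recount(small_hip_model):
    """summed_positive - summed_negative_magnitude == sum of r_norm."""
    records = run_sweep(small_hip_model, SweepProtocol())
    summaries = summarize_groups(records)
    frame = records_to_frame(records)
    for s in summaries:
        cell = frame[
            (frame["dof"] == s.dof) & (frame["fe_deg"] == s.posture.fe_deg)
        ]["moment_arm_norm"]
        assert s.summed_positive - s.summed_negative_magnitude == pytest.approx(
            cell.sum(), abs=1e-12
        )
        # independent brute-force recount of each signed side
        assert s.summed_positive == pytest.approx(
            sum(v for v in cell if v > 0), abs=1e-12
        )
        assert s.summed_negative_magnitude == pytest.approx(
            sum(-v for v in cell if v < 0), abs=1e-12
        )


def test_identical_models_in_opposite_cohorts_contrast_to_zero():
    rec_a = _synthetic_records({("a", "LAR"): [0.1] * 13}, FE_GRID, model="A")
    rec_b = _synthetic_records({("a", "LAR"): [0.1] * 13}, FE_GRID, model="B")
    summaries = summarize_groups(rec_a) + summarize_groups(rec_b)
    table = compare_cohorts(summaries, {"A": "biped", "B": "quadruped"})
    per_posture = table[table["level"] == "per_posture"]
    pivot = per_posture.pivot_table(
        index=["dof", "fe_deg"], columns="cohort", values="summed_positive_mean"
    )
    assert np.allclose(pivot["biped"], pivot["quadruped"])


def test_known_cohort_offset_recovered():
    delta = 0.07
    rec_a = _synthetic_records({("a", "LAR"): [0.1] * 13}, FE_GRID, model="A")
    rec_b = _synthetic_records({("a", "LAR"): [0.1 + delta] * 13}, FE_GRID, model="B")
    summaries = summarize_groups(rec_a) + summarize_groups(rec_b)
    table = compare_cohorts(summaries, {"A": "biped", "B": "quadruped"})
    overall = table[table["level"] == "overall"].set_index("cohort")
    contrast = (
        overall.loc["quadruped", "mean_positive"] - overall.loc["biped", "mean_positive"]
    )
    assert contrast == pytest.approx(delta, abs=1e-12)


def test_single_model_cohort_mean_equals_model_summary():
    rec = _synthetic_records({("a", "FE"): [0.2] * 13}, FE_GRID, model="A")
    summaries = summarize_groups(rec)
    table = compare_cohorts(summaries, {"A": "biped"})
    row = table[(table["level"] == "per_posture") & (table["dof"] == "FE")].iloc[0]
    assert row["summed_positive_mean"] == pytest.approx(0.2)
    assert row["n_models"] == 1


def test_missing_cohort_assignment_names_model():
    rec = _synthetic_records({("a", "FE"): [0.2] * 13}, FE_GRID, model="Orphan")
    with pytest.raises(ValueError, match="Orphan"):
        compare_cohorts(summarize_groups(rec), {})


# ---------------------------------------------------------------------------
# mode differences
# ---------------------------------------------------------------------------

def test_diff_modes_fe_always_zero(small_hip_model):
    records = run_sweep(small_hip_model, SweepProtocol(modes=("corrected", "legacy")))
    diff, summary = diff_modes(records)
    fe_rows = diff[diff["dof"] == "FE"]
    assert fe_rows["delta"].abs().max() <= 1e-10
    assert summary.set_index("dof").loc["FE", "max_abs_delta_norm"] <= 1e-10


def test_diff_modes_zero_at_neutral(small_hip_model):
    protocol = SweepProtocol(abd_offset_deg=0.0, modes=("corrected", "legacy"))
    diff, _ = diff_modes(run_sweep(small_hip_model, protocol))
    neutral_rows = diff[diff["fe_deg"] == 0.0]
    assert neutral_rows["delta"].abs().max() <= 1e-10


def test_diff_modes_matches_independent_oracle(small_hip_model):
    protocol = SweepProtocol(modes=("corrected", "legacy"))
    diff, _ = diff_modes(run_sweep(small_hip_model, protocol, method="geometric"))
    muscle = small_hip_model.muscle_names[0]
    posture = Posture(60.0, -10.0, 0.0)
    expected = geometric_moment_arm(
        small_hip_model, muscle, "LAR", posture, "corrected"
    ) - geometric_moment_arm(small_hip_model, muscle, "LAR", posture, "legacy")
    row = diff[
        (diff["muscle"] == muscle) & (diff["dof"] == "LAR") & (diff["fe_deg"] == 60.0)
    ]
    assert row["delta"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_diff_modes_requires_both_modes(small_hip_model):
    records = run_sweep(small_hip_model, SweepProtocol(modes=("corrected",)))
    with pytest.raises(ValueError, match="both"):
        diff_modes(records)


def test_diff_modes_rejects_mismatched_grids(small_hip_model):
    a = run_sweep(small_hip_model, SweepProtocol(modes=("corrected",)))
    b = run_sweep(
        small_hip_model, SweepProtocol(modes=("legacy",), fe_max_deg=75.0)
    )
    with pytest.raises(ValueError, match="grid"):
        diff_modes(a + b)


def test_axis_frames_rows_and_unit_norms(small_hip_model, default_protocol):
    frame = axis_frames(small_hip_model, default_protocol, "corrected")
    assert len(frame) == 13 * 3
    norms = np.sqrt(frame.ux**2 + frame.uy**2 + frame.uz**2)
    assert np.allclose(norms, 1.0, atol=1e-12)
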