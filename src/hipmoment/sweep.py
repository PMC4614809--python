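"""Posture sweeps, muscle-function classification and group statistics.

The sweep protocol mirrors the standard comparative workflow: hold the hip
at a fixed abduction offset (10 deg of abduction by default), step
flexion-extension on a regular grid (15 deg by default), and at every grid
posture evaluate the moment arm of each muscle about each requested degree
of freedom under one or both axis conventions.

Downstream operations work on the resulting
:class:`~hipmoment.model.MomentArmRecord` lists or tables:

* :func:`classify_function` — obligatory / switching / negligible labels
  per muscle x dof, with interpolated sign-crossing angles;
* :func:`summarize_groups` — per-posture summed positive (extensor /
  adductor / lateral-rotator) and negative-magnitude (flexor / abductor /
  medial-rotator) normalized moment arms, plus sweep means;
* :func:`compare_cohorts` — biped-vs-quadruped style cohort contrasts;
* :func:`diff_modes` — corrected-minus-legacy difference tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import momentarm
from .kinematics import axis_set
from .model import (
    DOFS,
    MODES,
    LimbModel,
    MomentArmRecord,
    Posture,
    records_to_frame,
)
from .momentarm import DEFAULT_SETTINGS, ExcursionSettings

__all__ = [
    "SweepProtocol",
    "FunctionLabel",
    "GroupSummary",
    "run_sweep",
    "classify_function",
    "summarize_groups",
    "compare_cohorts",
    "diff_modes",
    "axis_frames",
]

#: Default threshold (in femur lengths) below which a moment arm is
#: considered negligible for classification.
NEGLIGIBLE_EPS = 0.005


@dataclass(frozen=True)
class SweepProtocol:
    """A flexion-extension sweep at fixed abduction/rotation offsets.

    ``abd_offset_deg`` is degrees of *abduction* (the conventional way the
    starting posture is stated); internally, under the positive-adduction
    sign semantics, it becomes ``abd_deg = -abd_offset_deg``.  The default
    10 deg abduction and 15 deg flexion-extension step follow the standard
    protocol; the range is model-specific and defaults to -90..+90 deg.
    """

    fe_min_deg: float = -90.0
    fe_max_deg: float = 90.0
    fe_step_deg: float = 15.0
    abd_offset_deg: float = 10.0
    lar_offset_deg: float = 0.0
    dofs: tuple[str, ...] = DOFS
    modes: tuple[str, ...] = ("corrected",)

    def __post_init__(self) -> None:
        if self.fe_step_deg <= 0:
            raise ValueError("fe_step_deg must be > 0")
        if self.fe_min_deg > self.fe_max_deg:
            raise ValueError("fe_min_deg must be <= fe_max_deg")
        if not self.dofs or any(d not in DOFS for d in self.dofs):
            raise ValueError(f"dofs must be a non-empty subset of {DOFS}")
        if not self.modes or any(m not in MODES for m in self.modes):
            raise ValueError(f"modes must be a non-empty subset of {MODES}")

    @property
    def abd_deg(self) -> float:
        """Fixed abduction-adduction angle under positive-adduction signs."""
        return -self.abd_offset_deg

    def fe_grid(self) -> np.ndarray:
        n = math.floor((self.fe_max_deg - self.fe_min_deg) / self.fe_step_deg + 1e-9) + 1
        return self.fe_min_deg + self.fe_step_deg * np.arange(n)

    def postures(self) -> list[Posture]:
        return [Posture(fe, self.abd_deg, self.lar_offset_deg) for fe in self.fe_grid()]


@dataclass(frozen=True)
class FunctionLabel:
    """Classification of one muscle about one dof over a sweep.

    ``label`` is one of ``obligatory-positive`` (always extensor / adductor
    / lateral rotator), ``obligatory-negative``, ``switching`` (sign
    crossing within the sweep, ``crossing_angle_deg`` interpolated between
    the bracketing grid postures) or ``negligible``.  ``extremes`` is the
    (min, max) of the normalized moment arm over the sweep.
    """

    muscle: str
    dof: str
    label: str
    extremes: tuple[float, float]
    crossing_angle_deg: float | None = None


@dataclass(frozen=True)
class GroupSummary:
    """Signed-group statistics of normalized moment arms at one posture."""

    model: str
    mode: str
    dof: str
    posture: Posture
    summed_positive: float
    summed_negative_magnitude: float
    mean_positive: float
    mean_negative_magnitude: float


def run_sweep(
    model: LimbModel,
    protocol: SweepProtocol = SweepProtocol(),
    settings: ExcursionSettings = DEFAULT_SETTINGS,
    method: str = "excursion",
) -> list[MomentArmRecord]:
    """Evaluate every muscle x dof x grid posture x mode of the protocol.

    ``method`` selects the tendon-excursion procedure (default) or the
    exact geometric lever ("geometric"); the two agree to discretization
    error.  Output order is deterministic: muscles in model order, then
    dofs, then postures, then modes.
    """
    if method not in ("excursion", "geometric"):
        raise ValueError(f"method must be 'excursion' or 'geometric', got {method!r}")
    if not model.muscles:
        raise ValueError(f"model {model.name!r} has no muscles to sweep")
    records = []
    for muscle in model.muscle_names:
        for dof in protocol.dofs:
            for posture in protocol.postures():
                for mode in protocol.modes:
                    if method == "excursion":
                        r = momentarm.excursion_moment_arm(
                            model, muscle, dof, posture, mode, settings
                        )
                    else:
                        r = momentarm.geometric_moment_arm(model, muscle, dof, posture, mode)
                    records.append(
                        MomentArmRecord(
                            model=model.name,
                            muscle=muscle,
                            dof=dof,
                            posture=posture,
                            mode=mode,
                            moment_arm=r,
                            moment_arm_norm=r / model.femur_length,
                        )
                    )
    return records


def _crossing(fe: np.ndarray, r: np.ndarray) -> float | None:
    """First sign crossing along the flexion-extension grid, or None."""
    for i in range(len(r) - 1):
        if r[i] == 0.0:
            return float(fe[i])
        if r[i] * r[i + 1] < 0.0:
            return float(fe[i] - r[i] * (fe[i + 1] - fe[i]) / (r[i + 1] - r[i]))
    if r[-1] == 0.0:
        return float(fe[-1])
    return None


def classify_function(
    records: Sequence[MomentArmRecord], epsilon: float = NEGLIGIBLE_EPS
) -> list[FunctionLabel]:
    """Label each muscle x dof of a single-model, single-mode sweep.

    Uses normalized moment arms so the labels are scale-invariant.  A
    muscle is negligible when max |r_norm| < epsilon; switching when the
    sign changes between adjacent flexion-extension grid postures (the
    crossing angle is linearly interpolated); otherwise obligatory with
    the sign it holds throughout.
    """
    frame = records_to_frame(records)
    if frame["model"].nunique() != 1 or frame["mode"].nunique() != 1:
        raise ValueError("classify_function expects records from one model and one mode")
    labels = []
    for (muscle, dof), grp in frame.groupby(["muscle", "dof"], sort=False):
        grp = grp.sort_values("fe_deg")
        if len(grp) < 2:
            raise ValueError(
                f"muscle {muscle!r} dof {dof}: need >= 2 sweep postures to classify"
            )
        fe = grp["fe_deg"].to_numpy()
        r = grp["moment_arm_norm"].to_numpy()
        extremes = (float(r.min()), float(r.max()))
        if np.abs(r).max() < epsilon:
            labels.append(FunctionLabel(muscle, dof, "negligible", extremes))
            continue
        crossing = _crossing(fe, r)
        if crossing is not None:
            labels.append(FunctionLabel(muscle, dof, "switching", extremes, crossing))
        elif r.min() > 0:
            labels.append(FunctionLabel(muscle, dof, "obligatory-positive", extremes))
        else:
            labels.append(FunctionLabel(muscle, dof, "obligatory-negative", extremes))
    return labels


def labels_to_frame(labels: Sequence[FunctionLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "muscle": l.muscle,
                "dof": l.dof,
                "label": l.label,
                "crossing_angle_deg": l.crossing_angle_deg,
                "min_norm": l.extremes[0],
                "max_norm": l.extremes[1],
            }
            for l in labels
        ]
    )


def summarize_groups(records: Sequence[MomentArmRecord]) -> list[GroupSummary]:
    """Signed-group sums and sweep means of normalized moment arms.

    At each posture and dof, muscles are split by the sign of their moment
    arm: ``summed_positive`` totals the extensor / adductor /
    lateral-rotator side and ``summed_negative_magnitude`` the magnitude of
    the flexor / abductor / medial-rotator side.  The split is per posture
    because functional-group membership is posture-dependent (muscles
    switch polarity).  ``mean_*`` are means of the same signed parts over
    all muscle x posture cells of the sweep, constant within model x dof.
    """
    frame = records_to_frame(records)
    if frame["model"].nunique() != 1 or frame["mode"].nunique() != 1:
        raise ValueError("summarize_groups expects records from one model and one mode")
    model = frame["model"].iloc[0]
    mode = frame["mode"].iloc[0]
    frame = frame.assign(
        pos=frame["moment_arm_norm"].clip(lower=0.0),
        neg=(-frame["moment_arm_norm"]).clip(lower=0.0),
    )
    means = frame.groupby("dof")[["pos", "neg"]].mean()
    out = []
    for (dof, fe, abd, lar), grp in frame.groupby(
        ["dof", "fe_deg", "abd_deg", "lar_deg"], sort=True
    ):
        out.append(
            GroupSummary(
                model=model,
                mode=mode,
                dof=dof,
                posture=Posture(fe, abd, lar),
                summed_positive=float(grp["pos"].sum()),
                summed_negative_magnitude=float(grp["neg"].sum()),
                mean_positive=float(means.loc[dof, "pos"]),
                mean_negative_magnitude=float(means.loc[dof, "neg"]),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": s.model,
                "mode": s.mode,
                "dof": s.dof,
                "fe_deg": s.posture.fe_deg,
                "abd_deg": s.posture.abd_deg,
                "lar_deg": s.posture.lar_deg,
                "summed_positive": s.summed_positive,
                "summed_negative_magnitude": s.summed_negative_magnitude,
                "mean_positive": s.mean_positive,
                "mean_negative_magnitude": s.mean_negative_magnitude,
            }
            for s in summaries
        ]
    )


def compare_cohorts(
    summaries: Sequence[GroupSummary] | pd.DataFrame,
    cohorts: Mapping[str, str],
) -> pd.DataFrame:
    """Cohort contrasts of group summaries (e.g., bipeds vs quadrupeds).

    ``cohorts`` maps model name -> cohort label (typically taken from the
    model metadata ``posture_class``).  Returns a tidy table with one row
    per cohort x dof x posture carrying the between-model mean and sample
    standard deviation of the summed statistics (``level`` =
    ``per_posture``), plus per cohort x dof rows with cohort means of the
    per-model sweep means (``level`` = ``overall``).
    """
    frame = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    missing = sorted(set(frame["model"]) - set(cohorts))
    if missing:
        raise ValueError(f"model(s) missing a cohort assignment: {missing}")
    frame = frame.assign(cohort=frame["model"].map(cohorts))
    per_posture = (
        frame.groupby(["cohort", "dof", "fe_deg", "abd_deg", "lar_deg"])
        .agg(
            n_models=("model", "nunique"),
            summed_positive_mean=("summed_positive", "mean"),
            summed_positive_sd=("summed_positive", "std"),
            summed_negative_magnitude_mean=("summed_negative_magnitude", "mean"),
            summed_negative_magnitude_sd=("summed_negative_magnitude", "std"),
        )
        .reset_index()
        .assign(level="per_posture")
    )
    # one mean per model x dof first, then average across cohort members
    per_model = frame.drop_duplicates(["model", "dof"])[
        ["cohort", "model", "dof", "mean_positive", "mean_negative_magnitude"]
    ]
    overall = (
        per_model.groupby(["cohort", "dof"])
        .agg(
            n_models=("model", "nunique"),
            mean_positive=("mean_positive", "mean"),
            mean_negative_magnitude=("mean_negative_magnitude", "mean"),
        )
        .reset_index()
        .assign(level="overall")
    )
    return pd.concat([per_posture, overall], ignore_index=True)


def diff_modes(records: Sequence[MomentArmRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrected-minus-legacy moment arm differences on a shared grid.

    Returns ``(diff, summary)``: ``diff`` has one row per muscle x dof x
    posture with ``delta = corrected - legacy`` (raw and normalized);
    ``summary`` gives, per dof, the maximum |delta_norm| and the posture
    attaining it.  Raises if the two modes do not cover identical grids.
    """
    frame = records_to_frame(records)
    if set(frame["mode"].unique()) != set(MODES):
        raise ValueError("diff_modes needs records for both 'corrected' and 'legacy'")
    keys = ["model", "muscle", "dof", "fe_deg", "abd_deg", "lar_deg"]
    corrected = frame[frame["mode"] == "corrected"].set_index(keys)
    legacy = frame[frame["mode"] == "legacy"].set_index(keys)
    if not corrected.index.equals(legacy.index):
        raise ValueError("corrected and legacy records cover different posture grids")
    diff = corrected[["moment_arm", "moment_arm_norm"]].sub(
        legacy[["moment_arm", "moment_arm_norm"]]
    )
    diff.columns = ["delta", "delta_norm"]
    diff = diff.reset_index()
    idx = diff.groupby("dof")["delta_norm"].apply(lambda s: s.abs().idxmax())
    summary = diff.loc[idx.to_numpy(), ["dof", "fe_deg", "abd_deg", "lar_deg", "delta_norm"]]
    summary = summary.assign(max_abs_delta_norm=summary["delta_norm"].abs()).drop(
        columns="delta_norm"
    ).reset_index(drop=True)
    return diff, summary


def axis_frames(
    model: LimbModel,
    protocol: SweepProtocol = SweepProtocol(),
    mode: str = "corrected",
) -> pd.DataFrame:
    """Per-posture instantaneous axis triads, one row per posture x dof.

    Intended for animating or inspecting the axis cascade; columns give
    the global components of each unit axis.
    """
    rows = []
    for posture in protocol.postures():
        axes = axis_set(posture, model.joint, mode)
        for dof in DOFS:
            u = axes.axis(dof)
            rows.append(
                {
                    "model": model.name,
                    "mode": mode,
                    "fe_deg": posture.fe_deg,
                    "abd_deg": posture.abd_deg,
                    "lar_deg": posture.lar_deg,
                    "dof": dof,
                    "ux": u[0],
                    "uy": u[1],
                    "uz": u[2],
                }
            )
    return pd.DataFrame(rows)
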