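"""Domain types and file I/O for two-segment (pelvis + femur) limb models.

A :class:`LimbModel` holds everything the moment-arm engine needs: the hip
joint (a pure three-degree-of-freedom ball joint), the femur length used for
normalization, and one or more muscles described as ordered polylines of
attachment/via points, each point rigidly owned by one segment.

Conventions
-----------
* The pelvis is static; its segment frame coincides with the global frame.
* Femur-owned coordinates are expressed in the femur's neutral-posture frame
  *relative to the hip joint center*, so posing the femur is a pure rotation
  about the joint center.
* Angles everywhere in files and public interfaces are degrees.
* Anatomical sign semantics: positive flexion-extension angle = extension,
  positive abduction-adduction = adduction, positive long-axis rotation =
  lateral rotation.  A moment arm is positive when the muscle acts toward
  the positive sense (extensor / adductor / lateral rotator) and negative
  toward the negative sense (flexor / abductor / medial rotator).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "DOFS",
    "MODES",
    "SEGMENTS",
    "SCHEMA_VERSION",
    "RECORD_COLUMNS",
    "ModelValidationError",
    "Posture",
    "AttachmentPoint",
    "MusclePath",
    "HipJoint",
    "LimbModel",
    "MomentArmRecord",
    "load_model",
    "save_model",
    "model_from_dict",
    "model_to_dict",
    "save_records",
    "load_records",
    "records_to_frame",
]

#: The three hip degrees of freedom, in cascade order.
DOFS = ("FE", "ABD", "LAR")
#: Axis conventions: "corrected" rotates the ABD/LAR axes with the femur,
#: "legacy" keeps all three axes pelvis-fixed (the historical error).
MODES = ("corrected", "legacy")
SEGMENTS = ("pelvis", "femur")
SCHEMA_VERSION = 1

#: Exact column set of a moment-arm record table.
RECORD_COLUMNS = [
    "model",
    "muscle",
    "dof",
    "fe_deg",
    "abd_deg",
    "lar_deg",
    "mode",
    "moment_arm",
    "moment_arm_norm",
]

_MODEL_KEYS = {"schema_version", "name", "femur_length", "joint", "muscles", "metadata"}
_JOINT_KEYS = {"center", "dof_senses"}
_MUSCLE_KEYS = {"name", "points"}
_POINT_KEYS = {"segment", "xyz"}


class ModelValidationError(ValueError):
    """A model file or in-memory model violates the schema or an invariant."""


def _check_finite(values: Iterable[float], what: str) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ModelValidationError(f"{what} must be finite, got {v!r}")


@dataclass(frozen=True)
class Posture:
    """Hip posture: the three joint angles in degrees, anatomical signs.

    ``fe_deg`` positive = extension (femoral retraction), ``abd_deg``
    positive = adduction, ``lar_deg`` positive = lateral rotation.  The
    neutral posture is (0, 0, 0): femur axes aligned with the global frame.
    """

    fe_deg: float
    abd_deg: float
    lar_deg: float

    def __post_init__(self) -> None:
        _check_finite((self.fe_deg, self.abd_deg, self.lar_deg), "posture angle")

    @classmethod
    def neutral(cls) -> "Posture":
        return cls(0.0, 0.0, 0.0)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fe_deg, self.abd_deg, self.lar_deg)

    def angle(self, dof: str) -> float:
        return {"FE": self.fe_deg, "ABD": self.abd_deg, "LAR": self.lar_deg}[dof]


@dataclass(frozen=True)
class AttachmentPoint:
    """A muscle path point rigidly owned by one segment.

    ``xyz`` is in the owner segment's neutral-posture frame; femur-owned
    coordinates are relative to the hip joint center.
    """

    segment: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ModelValidationError(
                f"attachment segment must be one of {SEGMENTS}, got {self.segment!r}"
            )
        object.__setattr__(self, "xyz", tuple(float(v) for v in self.xyz))
        if len(self.xyz) != 3:
            raise ModelValidationError("attachment xyz must have exactly 3 components")
        _check_finite(self.xyz, "attachment coordinate")


@dataclass(frozen=True)
class MusclePath:
    """An ordered polyline of >= 2 attachment points, pelvis origin to femur
    insertion; intermediate via points may belong to either segment."""

    name: str
    points: tuple[AttachmentPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if not self.name:
            raise ModelValidationError("muscle name must be non-empty")
        if len(self.points) < 2:
            raise ModelValidationError(
                f"muscle {self.name!r} needs >= 2 path points, got {len(self.points)}"
            )
        if self.points[0].segment != "pelvis":
            raise ModelValidationError(
                f"muscle {self.name!r}: first path point must be pelvis-owned"
            )
        if self.points[-1].segment != "femur":
            raise ModelValidationError(
                f"muscle {self.name!r}: last path point must be femur-owned"
            )


@dataclass(frozen=True)
class HipJoint:
    """The three-degree-of-freedom hip: joint center and per-dof senses.

    ``dof_senses`` maps each anatomical-positive angle to a right-handed
    rotation sense (+1/-1) about the stored axis direction, so left- and
    right-limb models can both use the anatomical sign semantics.  The
    default (+1, +1, +1) is the canonical synthetic right hindlimb.
    """

    center: tuple[float, float, float]
    dof_senses: Mapping[str, int] = field(
        default_factory=lambda: {"FE": 1, "ABD": 1, "LAR": 1}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        if len(self.center) != 3:
            raise ModelValidationError("joint center must have exactly 3 components")
        _check_finite(self.center, "joint center coordinate")
        senses = dict(self.dof_senses)
        if set(senses) != set(DOFS):
            raise ModelValidationError(
                f"dof_senses must define exactly {DOFS}, got {sorted(senses)}"
            )
        for dof, s in senses.items():
            if s not in (1, -1):
                raise ModelValidationError(
                    f"dof sense for {dof} must be +1 or -1, got {s!r}"
                )
        object.__setattr__(self, "dof_senses", senses)

    def sense(self, dof: str) -> int:
        return self.dof_senses[dof]


@dataclass(frozen=True)
class LimbModel:
    name: str
    joint: HipJoint
    femur_length: float
    muscles: tuple[MusclePath, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "muscles", tuple(self.muscles))
        object.__setattr__(self, "metadata", dict(self.metadata))
        object.__setattr__(self, "femur_length", float(self.femur_length))
        if not self.name:
            raise ModelValidationError("model name must be non-empty")
        if not math.isfinite(self.femur_length) or self.femur_length <= 0:
            raise ModelValidationError(
                f"femur_length must be a positive finite number, got {self.femur_length!r}"
            )
        names = [m.name for m in self.muscles]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"muscle names must be unique; repeated: {dupes}")
        for m in self.muscles:
            self._check_no_coincident(m)

    def _check_no_coincident(self, muscle: MusclePath) -> None:
        # Coincidence is judged at the neutral posture, where both segment
        # frames share the global frame (femur offset by the joint center).
        prev = None
        for pt in muscle.points:
            pos = pt.xyz
            if pt.segment == "femur":
                pos = tuple(c + v for c, v in zip(self.joint.center, pt.xyz))
            if prev is not None and all(abs(a - b) < 1e-12 for a, b in zip(pos, prev)):
                raise ModelValidationError(
                    f"muscle {muscle.name!r} has coincident consecutive path points"
                )
            prev = pos

    def muscle(self, name: str) -> MusclePath:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"model {self.name!r} has no muscle named {name!r}")

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)


@dataclass(frozen=True)
class MomentArmRecord:
    """One muscle x one degree of freedom x one posture x one axis mode."""

    model: str
    muscle: str
    dof: str
    posture: Posture
    mode: str
    moment_arm: float
    moment_arm_norm: float

    def __post_init__(self) -> None:
        if self.dof not in DOFS:
            raise ModelValidationError(f"dof must be one of {DOFS}, got {self.dof!r}")
        if self.mode not in MODES:
            raise ModelValidationError(f"mode must be one of {MODES}, got {self.mode!r}")


# ---------------------------------------------------------------------------
# Model file I/O
# ---------------------------------------------------------------------------

def _warn_unknown(keys: Iterable[str], allowed: set[str], where: str) -> None:
    unknown = sorted(set(keys) - allowed)
    if unknown:
        warnings.warn(
            f"ignoring unknown key(s) {unknown} in {where}", UserWarning, stacklevel=3
        )


def model_from_dict(data: Mapping[str, object]) -> LimbModel:
    """Build and validate a :class:`LimbModel` from a parsed model file."""
    if not isinstance(data, Mapping):
        raise ModelValidationError("model file must contain a mapping at top level")
    _warn_unknown(data.keys(), _MODEL_KEYS, "model")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ModelValidationError(
            f"unsupported schema_version {version!r}; this reader supports {SCHEMA_VERSION}"
        )
    for key in ("name", "femur_length", "joint", "muscles"):
        if key not in data:
            raise ModelValidationError(f"model is missing required key {key!r}")
    joint_data = data["joint"]
    if not isinstance(joint_data, Mapping) or "center" not in joint_data:
        raise ModelValidationError("joint must be a mapping with a 'center' key")
    _warn_unknown(joint_data.keys(), _JOINT_KEYS, "joint")
    joint = HipJoint(
        center=tuple(joint_data["center"]),
        dof_senses=dict(joint_data.get("dof_senses", {"FE": 1, "ABD": 1, "LAR": 1})),
    )
    muscles = []
    for mdata in data["muscles"]:
        _warn_unknown(mdata.keys(), _MUSCLE_KEYS, f"muscle {mdata.get('name', '?')!r}")
        points = []
        for pdata in mdata.get("points", []):
            _warn_unknown(pdata.keys(), _POINT_KEYS, f"point of muscle {mdata.get('name', '?')!r}")
            if "segment" not in pdata or "xyz" not in pdata:
                raise ModelValidationError(
                    f"muscle {mdata.get('name', '?')!r}: each point needs 'segment' and 'xyz'"
                )
            points.append(AttachmentPoint(segment=pdata["segment"], xyz=tuple(pdata["xyz"])))
        muscles.append(MusclePath(name=mdata.get("name", ""), points=tuple(points)))
    return LimbModel(
        name=str(data["name"]),
        joint=joint,
        femur_length=data["femur_length"],
        muscles=tuple(muscles),
        metadata=dict(data.get("metadata", {})),
    )


def model_to_dict(model: LimbModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "femur_length": model.femur_length,
        "joint": {
            "center": list(model.joint.center),
            "dof_senses": {d: model.joint.dof_senses[d] for d in DOFS},
        },
        "muscles": [
            {
                "name": m.name,
                "points": [
                    {"segment": p.segment, "xyz": list(p.xyz)} for p in m.points
                ],
            }
            for m in model.muscles
        ],
        "metadata": dict(model.metadata),
    }


def load_model(path: str | Path) -> LimbModel:
    """Read and validate a model file (JSON, or YAML by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"could not parse {path} as JSON: {exc}") from exc
    return model_from_dict(data)


def save_model(model: LimbModel, path: str | Path) -> None:
    """Write a model file; JSON unless the extension says YAML.

    Output is deterministic: same model, byte-identical file.
    """
    path = Path(path)
    data = model_to_dict(model)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Record table I/O
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[MomentArmRecord]) -> pd.DataFrame:
    """Tabulate records with the canonical column set and stable row order
    (model, muscle, dof, fe_deg)."""
    if not records:
        raise ValueError("record list is empty")
    rows = [
        {
            "model": r.model,
            "muscle": r.muscle,
            "dof": r.dof,
            "fe_deg": r.posture.fe_deg,
            "abd_deg": r.posture.abd_deg,
            "lar_deg": r.posture.lar_deg,
            "mode": r.mode,
            "moment_arm": r.moment_arm,
            "moment_arm_norm": r.moment_arm_norm,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return frame.sort_values(
        ["model", "muscle", "dof", "fe_deg", "mode"], kind="stable"
    ).reset_index(drop=True)


def save_records(records: Sequence[MomentArmRecord], path: str | Path) -> None:
    """Write a record table as CSV with full float precision."""
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.17g")


def load_records(path: str | Path) -> list[MomentArmRecord]:
    """Read a record table written by :func:`save_records`."""
    frame = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"record table {path} is missing column(s) {missing}")
    return [
        MomentArmRecord(
            model=row.model,
            muscle=row.muscle,
            dof=row.dof,
            posture=Posture(row.fe_deg, row.abd_deg, row.lar_deg),
            mode=row.mode,
            moment_arm=row.moment_arm,
            moment_arm_norm=row.moment_arm_norm,
        )
        for row in frame.itertuples()
    ]
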