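"""Synthetic limb models: analytic hinge toys and randomized hip models.

Two kinds of scaffolding, both first-class citizens of the package:

* :func:`make_hinge_toy` — a two-point straight muscle arranged in the
  plane normal to one dof's neutral axis so its moment arm about that dof
  has the closed form  a*b*sin(theta) / sqrt(a^2 + b^2 + 2*a*b*cos(theta)),
  the classical two-link lever.  Used to validate both moment-arm routes
  against an exact answer.
* :func:`make_hip_model` — a seeded random archosaur-hip-like model
  carrying the standard comparative muscle nomenclature (IF, CFB, CFL,
  PIFE1/2, PIFI1/2, ADD1/2, ISTR, ITBa/ITBp, FTE, FTI3, AMB, IFB,
  IFMa/IFMp, PIT).  Attachment sites are drawn in anatomically plausible
  regions around a right hip (x cranial, y dorsal, z lateral; femur long
  axis along -y at neutral); the names carry nomenclature only — the
  geometry is generated, not a reconstruction of any published taxon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import DOFS, AttachmentPoint, HipJoint, LimbModel, MusclePath
from . import momentarm
from .model import Posture

__all__ = [
    "MUSCLE_NAMES",
    "ToySpec",
    "SynthSpec",
    "make_hinge_toy",
    "make_hip_model",
    "scale_model",
    "hinge_toy_moment_arm",
    "hinge_toy_length",
]

#: The standard archosaur hip muscle set used by the comparative studies.
MUSCLE_NAMES = (
    "IF", "CFB", "CFL", "PIFE1", "PIFE2", "PIFI1", "PIFI2", "ADD1", "ADD2",
    "ISTR", "ITBa", "ITBp", "FTE", "FTI3", "AMB", "IFB", "IFMa", "IFMp", "PIT",
)

#: Generator algorithm identifier, bumped whenever sampling changes.
GENERATOR_VERSION = "hip-synth-1"


def hinge_toy_length(a: float, b: float, theta_deg: float) -> float:
    """Law-of-cosines length of the two-link toy at hinge angle theta."""
    th = math.radians(theta_deg)
    return math.sqrt(a * a + b * b + 2.0 * a * b * math.cos(th))


def hinge_toy_moment_arm(a: float, b: float, theta_deg: float) -> float:
    """Closed-form moment arm of the two-link toy: a*b*sin(theta)/L(theta)."""
    th = math.radians(theta_deg)
    return a * b * math.sin(th) / hinge_toy_length(a, b, theta_deg)


@dataclass(frozen=True)
class ToySpec:
    """Two-link hinge toy: origin offset ``a`` (pelvis) and insertion
    offset ``b`` (femur) from the joint center, straight-line muscle."""

    a: float = 1.0
    b: float = 1.0
    dof: str = "FE"
    femur_length: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("toy offsets a and b must be > 0")
        if self.dof not in DOFS:
            raise ValueError(f"dof must be one of {DOFS}, got {self.dof!r}")
        if self.femur_length <= 0:
            raise ValueError("femur_length must be > 0")


def make_hinge_toy(spec: ToySpec = ToySpec()) -> LimbModel:
    """Build the analytic toy for one dof.

    The two attachment points sit on opposite sides of the joint center in
    the plane normal to the tested dof's neutral axis, so rotation by the
    anatomical angle theta about that axis gives the exact moment arm
    ``a*b*sin(theta)/L(theta)`` (positive toward extension / adduction /
    lateral rotation), with the other two dofs held at zero.
    """
    a, b = spec.a, spec.b
    if spec.dof in ("FE", "ABD"):
        # plane normal to z (FE) also contains these; plane normal to x (ABD) too
        origin, insertion = (0.0, a, 0.0), (0.0, -b, 0.0)
    else:  # LAR: plane normal to y
        origin, insertion = (a, 0.0, 0.0), (-b, 0.0, 0.0)
    return LimbModel(
        name=f"hinge-toy-{spec.dof}",
        joint=HipJoint(center=(0.0, 0.0, 0.0)),
        femur_length=spec.femur_length,
        muscles=(
            MusclePath(
                name="toy",
                points=(
                    AttachmentPoint("pelvis", origin),
                    AttachmentPoint("femur", insertion),
                ),
            ),
        ),
        metadata={"kind": "hinge-toy", "a": a, "b": b, "dof": spec.dof},
    )


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the random hip-model generator.

    ``polarity_targets`` maps muscle name -> {dof: +1 or -1}; the generator
    then places the muscle so its moment arm at the neutral posture has the
    requested sign (posture-dependent switches away from neutral are free
    to emerge).  ``coordinate_scale`` multiplies every length in the model.
    """

    seed: int = 0
    n_muscles: int = len(MUSCLE_NAMES)
    coordinate_scale: float = 1.0
    posture_class: str = "biped"
    polarity_targets: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.n_muscles <= len(MUSCLE_NAMES)):
            raise ValueError(
                f"n_muscles must be in 1..{len(MUSCLE_NAMES)}, got {self.n_muscles}"
            )
        if self.coordinate_scale <= 0:
            raise ValueError("coordinate_scale must be > 0")
        if self.posture_class not in ("biped", "quadruped"):
            raise ValueError("posture_class must be 'biped' or 'quadruped'")
        for name, dofs in self.polarity_targets.items():
            if name not in MUSCLE_NAMES[: self.n_muscles]:
                raise ValueError(f"polarity target for unknown muscle {name!r}")
            for dof, sign in dofs.items():
                if dof not in DOFS or sign not in (1, -1):
                    raise ValueError(
                        f"polarity target {name}/{dof} must map a dof to +1 or -1"
                    )


# Nominal attachment regions (units of femur length, right hindlimb):
# pelvis origin, femur insertion (relative to joint center), optional via
# point (segment, xyz).  Chosen for anatomical plausibility: iliofemoral
# muscles arise dorsally, caudofemoral caudally, puboischiofemoral
# cranio-/caudoventrally; insertions sit on the proximal half of the shaft.
_REGIONS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float], tuple[str, tuple[float, float, float]] | None]] = {
    "IF":    ((0.15, 0.35, 0.05), (0.02, -0.18, 0.10), None),
    "CFB":   ((-0.45, 0.05, -0.04), (-0.03, -0.28, 0.05), None),
    "CFL":   ((-0.70, -0.05, -0.04), (-0.03, -0.35, 0.02), None),
    "PIFE1": ((0.30, -0.25, -0.06), (0.01, -0.12, 0.06), None),
    "PIFE2": ((0.20, -0.32, -0.08), (0.01, -0.14, 0.06), None),
    "PIFI1": ((0.30, 0.12, -0.10), (0.04, -0.16, 0.05), None),
    "PIFI2": ((0.35, 0.15, -0.05), (0.05, -0.20, 0.07), None),
    "ADD1":  ((-0.18, -0.30, -0.05), (-0.01, -0.58, -0.02), None),
    "ADD2":  ((-0.16, -0.18, -0.10), (-0.01, -0.65, -0.01), ("femur", (-0.02, -0.45, -0.03))),
    "ISTR":  ((-0.18, -0.15, -0.12), (0.00, -0.12, 0.09), None),
    "ITBa":  ((0.30, 0.32, 0.10), (0.02, -0.80, 0.08), ("pelvis", (0.15, 0.25, 0.14))),
    "ITBp":  ((-0.22, 0.30, 0.10), (-0.01, -0.80, 0.08), ("pelvis", (-0.10, 0.22, 0.14))),
    "FTE":   ((-0.05, 0.15, 0.12), (0.00, -0.70, 0.09), None),
    "FTI3":  ((-0.25, -0.18, -0.04), (-0.02, -0.75, -0.04), None),
    "AMB":   ((0.38, -0.05, -0.02), (0.03, -0.60, 0.02), None),
    "IFB":   ((0.05, 0.30, 0.08), (0.01, -0.25, 0.09), None),
    "IFMa":  ((0.20, 0.28, 0.06), (0.02, -0.22, 0.08), None),
    "IFMp":  ((-0.05, 0.28, 0.06), (0.00, -0.24, 0.08), None),
    "PIT":   ((-0.15, -0.35, -0.08), (-0.02, -0.70, -0.03), None),
}

_JITTER = 0.05       # uniform half-width, femur lengths
_MIN_CLEARANCE = 0.20  # smallest allowed pelvis->femur segment length over the
                       # working range, femur lengths; keeps paths clear of the
                       # joint region (short grazing segments are unanatomical
                       # stand-ins for wrapping, which the engine excludes)
_MAX_ATTEMPTS = 64


def _neutral_sign(model: LimbModel, muscle: str, dof: str) -> float:
    return momentarm.geometric_moment_arm(model, muscle, dof, Posture.neutral())


def _min_mixed_segment(path: MusclePath, scale: float) -> float:
    """Smallest pelvis->femur segment length over the working posture range."""
    from .kinematics import femur_orientation
    from .momentarm import _path_arrays, _world_points

    joint = HipJoint(center=(0.0, 0.0, 0.0))
    pts, femur = _path_arrays(path)
    mixed = [i for i in range(len(pts) - 1) if femur[i] != femur[i + 1]]
    smallest = math.inf
    for fe in np.arange(-90.0, 90.1, 7.5):
        for abd in (0.0, -10.0):
            rot = femur_orientation(Posture(fe, abd, 0.0), joint)
            world = _world_points(pts, femur, rot, np.zeros(3))
            for i in mixed:
                smallest = min(smallest, float(np.linalg.norm(world[i + 1] - world[i])))
    return smallest / scale


def _with_flips(points: list[AttachmentPoint], flips: tuple[tuple[int, int], ...]) -> list[AttachmentPoint]:
    out = list(points)
    for idx, axis in flips:
        p = out[idx]
        xyz = list(p.xyz)
        xyz[axis] = -xyz[axis]
        out[idx] = AttachmentPoint(p.segment, tuple(xyz))
    return out


def _enforce_polarity(
    muscle: MusclePath,
    targets: Mapping[str, int],
    femur_length: float,
) -> MusclePath:
    """Mirror the origin/insertion across coordinate planes through the
    joint center until every targeted dof has the requested sign at the
    neutral posture (with a small magnitude margin)."""
    margin = 1e-3 * femur_length

    def satisfied(path: MusclePath) -> bool:
        from .model import ModelValidationError

        try:
            probe = LimbModel(
                name="probe",
                joint=HipJoint(center=(0.0, 0.0, 0.0)),
                femur_length=femur_length,
                muscles=(path,),
            )
        except ModelValidationError:
            return False  # a mirrored candidate may degenerate; just reject it
        for dof, sign in targets.items():
            r = _neutral_sign(probe, path.name, dof)
            if sign * r < margin:
                return False
        return True

    if satisfied(muscle):
        return muscle
    toggles = [(i, axis) for i in (0, len(muscle.points) - 1) for axis in (2, 0, 1)]
    for k in range(1, len(toggles) + 1):
        for combo in _combinations(toggles, k):
            candidate = MusclePath(muscle.name, tuple(_with_flips(list(muscle.points), combo)))
            if satisfied(candidate):
                return candidate
    dofs = ",".join(sorted(targets))
    raise ValueError(
        f"cannot satisfy polarity target(s) for muscle {muscle.name!r} dof(s) {dofs}"
    )


def _combinations(items, k):
    from itertools import combinations

    return combinations(items, k)


def make_hip_model(spec: SynthSpec = SynthSpec()) -> LimbModel:
    """Generate a seeded random archosaur-hip-like model.

    Deterministic: the same spec yields a byte-identical model file.
    Femur length is ``coordinate_scale`` model units; attachments are the
    nominal regions jittered uniformly by +/-0.05 femur lengths.
    """
    rng = np.random.default_rng(spec.seed)
    scale = spec.coordinate_scale
    muscles = []
    for name in MUSCLE_NAMES[: spec.n_muscles]:
        origin, insertion, via = _REGIONS[name]
        path = None
        for _ in range(_MAX_ATTEMPTS):
            o = np.asarray(origin) + rng.uniform(-_JITTER, _JITTER, 3)
            i = np.asarray(insertion) + rng.uniform(-_JITTER, _JITTER, 3)
            points = [AttachmentPoint("pelvis", tuple(o * scale))]
            if via is not None:
                seg, xyz = via
                v = np.asarray(xyz) + rng.uniform(-_JITTER, _JITTER, 3)
                points.append(AttachmentPoint(seg, tuple(v * scale)))
            points.append(AttachmentPoint("femur", tuple(i * scale)))
            candidate = MusclePath(name, tuple(points))
            targets = spec.polarity_targets.get(name)
            if targets:
                candidate = _enforce_polarity(candidate, targets, femur_length=scale)
            if _min_mixed_segment(candidate, scale) >= _MIN_CLEARANCE:
                path = candidate
                break
        if path is None:  # pragma: no cover - regions are sized to avoid this
            raise ValueError(
                f"could not place muscle {name!r} clear of the joint region"
            )
        muscles.append(path)
    return LimbModel(
        name=f"synth-hip-{spec.seed}",
        joint=HipJoint(center=(0.0, 0.0, 0.0)),
        femur_length=1.0 * scale,
        muscles=tuple(muscles),
        metadata={
            "kind": "synthetic-hip",
            "generator": GENERATOR_VERSION,
            "seed": spec.seed,
            "posture_class": spec.posture_class,
        },
    )


def scale_model(model: LimbModel, k: float) -> LimbModel:
    """Uniformly scale every coordinate and the femur length by k > 0."""
    if not (k > 0):
        raise ValueError(f"scale factor must be > 0, got {k!r}")
    return LimbModel(
        name=model.name,
        joint=HipJoint(
            center=tuple(k * c for c in model.joint.center),
            dof_senses=dict(model.joint.dof_senses),
        ),
        femur_length=k * model.femur_length,
        muscles=tuple(
            MusclePath(
                m.name,
                tuple(
                    AttachmentPoint(p.segment, tuple(k * v for v in p.xyz))
                    for p in m.points
                ),
            )
            for m in model.muscles
        ),
        metadata=dict(model.metadata),
    )
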