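"""Whole-body centre of mass, bipedal-feasibility statics, limb lengths,
and allometric body-mass estimation.

The whole-body COM is the mass-weighted composite of the posed segment
solids; its position is reported as craniad (+X) and ventrad (−Z) offsets
from the posed acetabular midpoint, and dimensionless by the
gleno-acetabular (GA) distance.  Static bipedal feasibility asks whether
the COM's craniad offset falls within the feet's craniocaudal support
interval (sagittal statics only).

Body mass can also be estimated from humeral + femoral minimal diaphyseal
circumferences with the stylopodial-circumference regression for
quadrupeds, log10(BM [g]) = 2.749 · log10(C_h + C_f [mm]) − 1.104, with a
±25.6% prediction-error band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .kinematics import forward_kinematics
from .meshmass import composite_properties
from .model import BodyModel, Pose

__all__ = [
    "ComReport",
    "whole_body_com",
    "bipedal_feasibility",
    "allometric_mass",
    "allometric_circumference",
    "limb_lengths",
    "ADJUSTED_STANDING_POSE",
]

#: Preset pose used for the COM analysis: −10° flexion of hip, knee, ankle,
#: and elbow; +10° flexion of shoulder and wrist (flexion is negative about
#: the JCS z-axis, so flexing the shoulder/wrist by 10° sets z = +10 under
#: the convention that their flexion sense is opposite).
ADJUSTED_STANDING_POSE = Pose(
    {
        "hip": {"z": -10.0},
        "knee": {"z": -10.0},
        "ankle": {"z": -10.0},
        "elbow": {"z": -10.0},
        "shoulder": {"z": 10.0},
        "wrist": {"z": 10.0},
    }
)


@dataclass
class ComReport:
    """Whole-body COM and its anatomical offsets from the acetabula."""

    com: np.ndarray
    craniad_offset_m: float
    ventrad_offset_m: float
    com_dimensionless: float
    body_mass_kg: float
    ga_distance_m: float

    def to_dict(self) -> dict:
        return {
            "com_m": np.asarray(self.com).tolist(),
            "craniad_offset_m": self.craniad_offset_m,
            "ventrad_offset_m": self.ventrad_offset_m,
            "com_dimensionless": self.com_dimensionless,
            "body_mass_kg": self.body_mass_kg,
            "ga_distance_m": self.ga_distance_m,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def whole_body_com(model: BodyModel, pose: Pose | dict | None = None) -> ComReport:
    """Whole-body COM in *pose*, with offsets from the acetabular midpoint.

    Every segment must carry mass properties.  The craniad offset is the
    +X distance from the posed acetabular midpoint to the COM; the ventrad
    offset is the −Z distance.  The dimensionless COM divides the craniad
    offset by the GA distance.
    """
    pose = Pose(pose or {})
    transforms = forward_kinematics(model, pose)
    parts = []
    for name, seg in model.segments.items():
        if seg.mass_props is None:
            raise ValueError(f"segment {name!r} has no mass properties")
        parts.append((seg.mass_props, transforms[name]))
    total = composite_properties(parts)

    ac = model.landmarks.get("acetabular_midpoint")
    if ac is None:
        raise ValueError("model lacks landmark 'acetabular_midpoint'")
    Ta = transforms[ac.segment]
    acet = Ta[:3, :3] @ ac.point + Ta[:3, 3]
    craniad = float(total.com[0] - acet[0])
    ventrad = float(acet[2] - total.com[2])
    ga = model.gleno_acetabular_distance()
    return ComReport(
        com=total.com,
        craniad_offset_m=craniad,
        ventrad_offset_m=ventrad,
        com_dimensionless=craniad / ga,
        body_mass_kg=total.mass,
        ga_distance_m=ga,
    )


def bipedal_feasibility(report: ComReport, support: tuple) -> dict:
    """Static test: can the COM be placed over the feet?

    *support* is the feet's craniocaudal interval [x_min, x_max] in metres
    relative to the acetabula.  Feasible iff x_min ≤ craniad offset ≤ x_max
    (inclusive); the margin is the distance to the nearest support
    boundary, negative (the shortfall) when infeasible.
    """
    x_min, x_max = float(support[0]), float(support[1])
    if not x_min < x_max:
        raise ValueError(f"degenerate support interval [{x_min}, {x_max}]")
    x = report.craniad_offset_m
    feasible = x_min <= x <= x_max
    if feasible:
        margin = min(x - x_min, x_max - x)
    else:
        margin = -(x_min - x) if x < x_min else -(x - x_max)
    return {"feasible": feasible, "margin_m": float(margin),
            "craniad_offset_m": x, "support_m": [x_min, x_max]}


_SLOPE, _INTERCEPT, _PE = 2.749, -1.104, 0.256


def allometric_mass(c_humerus_mm: float, c_femur_mm: float) -> dict:
    """Body mass (kg) from stylopodial circumferences (mm).

    Applies log10(BM [g]) = 2.749 · log10(C_h + C_f) − 1.104 and a ±25.6%
    prediction-error band.  Rounding happens only at presentation.
    """
    if c_humerus_mm <= 0 or c_femur_mm <= 0:
        raise ValueError("circumferences must be positive")
    total = c_humerus_mm + c_femur_mm
    mass_g = 10.0 ** (_SLOPE * np.log10(total) + _INTERCEPT)
    mass_kg = float(mass_g / 1000.0)
    return {
        "mass_kg": mass_kg,
        "band_kg": (mass_kg * (1 - _PE), mass_kg * (1 + _PE)),
        "prediction_error": _PE,
    }


def allometric_circumference(mass_kg: float) -> float:
    """Combined circumference (mm) producing *mass_kg* — inverse regression."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    return float(10.0 ** ((np.log10(mass_kg * 1000.0) - _INTERCEPT) / _SLOPE))


def limb_lengths(model: BodyModel) -> dict:
    """Forelimb length, hindlimb length, and GA distance (m), reference pose.

    Limb chains are declared on the model as ordered lists of point specs
    (joint names or landmark names); the length is the sum of consecutive
    point-to-point distances at the reference pose.
    """
    if not model.chains:
        raise ValueError("model declares no limb chains")

    def world_point(spec) -> np.ndarray:
        if spec in model.joints:
            return model.joints[spec].jcs.origin
        if spec in model.landmarks:
            lm = model.landmarks[spec]
            T = model.reference_placements[lm.segment]
            return T[:3, :3] @ lm.point + T[:3, 3]
        raise ValueError(f"chain point {spec!r} is neither a joint nor a landmark")

    out = {}
    for name, specs in model.chains.items():
        pts = [world_point(s) for s in specs]
        out[f"{name}_m"] = float(
            sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:]))
        )
    out["ga_distance_m"] = model.gleno_acetabular_distance()
    return out
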