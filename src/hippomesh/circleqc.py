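"""Full-circle registration-consistency quality control.

When scans are registered in a closed cycle (e.g. BL-A -> M12-A -> M12-B ->
BL-A), the product of the cycle's transforms should be the identity; its
deviation — the residual matrix RM — quantifies registration inconsistency.
Three summaries are derived from RM:

* ``translation_total``: the Euclidean norm of RM's translation (mm),
* ``rotation_total``: the rotation angle arccos((trace(R) - 1) / 2) in
  degrees, where R is RM's 3x3 rotation block,
* ``consistency``: the Jaccard index between a structure's surface and its
  RM-transformed copy; 1 - consistency is the registration error.

A standard four-circle preset over a back-to-back longitudinal session
(BL-A, BL-B, M12-A, M12-B) is provided, but arbitrary chains compose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inside import build_grid
from .overlap import jaccard
from .surfaces import TriSurface
from .transforms import InvalidTransformError, RigidTransform

__all__ = [
    "CircleReport",
    "compose_circle",
    "translation_total",
    "rotation_total",
    "consistency",
    "circle_report",
    "session_circles",
]

# the four named circles of a BL/M12 back-to-back session, as chains of
# (from, to) scan labels whose transforms are multiplied left to right
SESSION_CIRCLES = {
    "circle1": [("M12B", "BLA"), ("M12A", "M12B"), ("BLA", "M12A")],
    "circle2": [("M12A", "BLA"), ("BLB", "M12A"), ("BLA", "BLB")],
    "circle3": [("M12B", "BLA"), ("BLB", "M12B"), ("BLA", "BLB")],
    "circle4": [("M12A", "M12B"), ("BLB", "M12A"), ("M12B", "BLB")],
}


@dataclass
class CircleReport:
    """Residual matrix of one full circle and its summary statistics."""

    circle_id: str
    residual: RigidTransform
    translation_total_mm: float
    rotation_total_deg: float
    consistency: float | None = None

    @property
    def registration_error(self) -> float | None:
        return None if self.consistency is None else 1.0 - self.consistency

    def to_row(self) -> dict:
        return {
            "circle_id": self.circle_id,
            "translation_total_mm": self.translation_total_mm,
            "rotation_total_deg": self.rotation_total_deg,
            "consistency": self.consistency,
            "registration_error": self.registration_error,
        }


def compose_circle(transforms) -> RigidTransform:
    """Matrix product of a chain of rigid transforms, in the given order.

    The first list element is the leftmost factor.  The product is
    re-validated as rigid; an invalid input names its position.
    """
    transforms = list(transforms)
    if len(transforms) < 2:
        raise ValueError("a circle needs at least 2 transforms")
    mats = []
    for i, t in enumerate(transforms):
        if isinstance(t, RigidTransform):
            mats.append(t.matrix)
        else:
            try:
                mats.append(RigidTransform(t).matrix)
            except InvalidTransformError as exc:
                raise InvalidTransformError(f"transform at index {i} is not rigid: {exc}") from exc
    out = mats[0]
    for m in mats[1:]:
        out = out @ m
    return RigidTransform(out)


def translation_total(rm: RigidTransform) -> float:
    """Euclidean norm (mm) of the residual translation."""
    return float(np.linalg.norm(rm.translation))


def rotation_total(rm: RigidTransform) -> float:
    """Residual rotation angle in degrees from the rotation block's trace.

    Mathematically arccos((trace(R) - 1) / 2) with the argument clamped to
    [-1, 1]; evaluated as atan2(|skew(R)|, (trace(R) - 1) / 2), which is the
    same angle for any rotation but stays accurate to machine precision for
    the near-identity residuals of consistent circles (plain arccos loses
    half the significant digits next to 1).
    """
    cos_th = np.clip((float(np.trace(rm.rotation)) - 1.0) / 2.0, -1.0, 1.0)
    skew = 0.5 * (rm.rotation - rm.rotation.T)
    sin_th = np.sqrt(skew[2, 1] ** 2 + skew[0, 2] ** 2 + skew[1, 0] ** 2)
    return float(np.degrees(np.arctan2(sin_th, cos_th)))


def consistency(surface: TriSurface, rm: RigidTransform, spacing: float = 0.5,
                margin: float = 2.0) -> float:
    """Jaccard between a surface and its residual-transformed copy.

    1 for a perfectly consistent cycle; note that rotations about a
    symmetry axis of the surface are invisible to this measure (a perfect
    sphere scores 1 under any rotation about its centre).
    """
    from .surfaces import transform_surface

    moved = transform_surface(surface, rm)
    grid = build_grid([surface, moved], spacing=spacing, margin=margin)
    return jaccard(surface, moved, grid)


def circle_report(circle_id: str, transforms, surface: TriSurface | None = None,
                  spacing: float = 0.5) -> CircleReport:
    """Compose one circle and summarise its residual (optionally with consistency)."""
    rm = compose_circle(transforms)
    cons = None if surface is None else consistency(surface, rm, spacing=spacing)
    return CircleReport(
        circle_id=circle_id,
        residual=rm,
        translation_total_mm=translation_total(rm),
        rotation_total_deg=rotation_total(rm),
        consistency=cons,
    )


def session_circles(transforms: dict[tuple[str, str], RigidTransform]):
    """Yield the chains of the four preset circles from a (from, to) -> T map.

    Missing directions are filled by inverting the stored opposite
    direction when available.
    """
    def get(pair):
        if pair in transforms:
            return transforms[pair]
        rev = (pair[1], pair[0])
        if rev in transforms:
            return transforms[rev].inverse()
        raise KeyError(f"no transform for {pair[0]} -> {pair[1]} (or its inverse)")

    for name, chain in SESSION_CIRCLES.items():
        yield name, [get(p) for p in chain]
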