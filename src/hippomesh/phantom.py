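"""Synthetic phantoms with known ground truth.

Every downstream stage (surface extraction, grid overlap, regional splits,
circle QC, mixed-model selection) is exercised on synthetic data for which
the right answer is known analytically:

* label-volume phantoms — spheres, ellipsoids, and a bent tube (a sphere
  swept along a circular arc, an asymmetric elongated stand-in for a
  hippocampus) with closed-form volumes;
* back-to-back pairs — the same shape re-rasterized after a known small
  rigid transform, with optional boundary-voxel noise emulating outline
  variability between repeated segmentations;
* factorial observation tables drawn from a Gaussian linear mixed model
  with chosen fixed effects, subject random intercepts and residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surfaces import LabelVolume
from .transforms import RigidTransform

__all__ = [
    "ShapeSpec",
    "DesignSpec",
    "DEFAULT_LEVELS",
    "analytic_volume",
    "rasterize",
    "make_pair",
    "simulate_observations",
]


@dataclass(frozen=True)
class ShapeSpec:
    """An analytic solid in world mm.

    kinds:
      ``sphere``     — radius ``radii[0]`` around ``center``;
      ``ellipsoid``  — axis-aligned semi-axes ``radii``;
      ``bent_tube``  — a sphere of radius ``radii[0]`` (tube radius) swept
                       along a circular arc of radius ``radii[1]`` spanning
                       ``bend_angle`` degrees, arc in the x-y plane and
                       symmetric about the y axis through ``center``.
    """

    kind: str
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii: tuple[float, float, float] = (10.0, 10.0, 10.0)
    bend_angle: float = 0.0
    label: int = 1

    def __post_init__(self):
        if self.kind not in ("sphere", "ellipsoid", "bent_tube"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if any(r <= 0 for r in self.radii[: (1 if self.kind == 'sphere' else 2 if self.kind == 'bent_tube' else 3)]):
            raise ValueError("radii must be positive")
        if not 0.0 <= self.bend_angle <= 90.0:
            raise ValueError("bend_angle must be in [0, 90] degrees")
        if self.label <= 0:
            raise ValueError("label must be a positive integer")
        if self.kind == "bent_tube" and self.radii[1] <= self.radii[0]:
            raise ValueError("bent_tube arc radius (radii[1]) must exceed tube radius (radii[0])")


def _inside_points(shape: ShapeSpec, pts: np.ndarray) -> np.ndarray:
    """Strict-interior membership of (n, 3) world points in the analytic shape."""
    p = pts - np.asarray(shape.center)
    if shape.kind == "sphere":
        r = shape.radii[0]
        return np.einsum("ij,ij->i", p, p) < r * r
    if shape.kind == "ellipsoid":
        rx, ry, rz = shape.radii
        return (p[:, 0] / rx) ** 2 + (p[:, 1] / ry) ** 2 + (p[:, 2] / rz) ** 2 < 1.0
    # bent tube: arc centre sits arc_R below `center` on the y axis; the arc
    # passes through `center` at its apex and spans bend_angle degrees
    tube_r, arc_r = shape.radii[0], shape.radii[1]
    half = np.deg2rad(shape.bend_angle) / 2.0 if shape.bend_angle > 0 else 0.0
    q = p + np.array([0.0, arc_r, 0.0])
    ang = np.arctan2(q[:, 1], q[:, 0])  # apex at pi/2
    ang = np.clip(ang, np.pi / 2 - half, np.pi / 2 + half)
    nearest = arc_r * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(len(q))])
    d = q - nearest
    return np.einsum("ij,ij->i", d, d) < tube_r * tube_r


def analytic_volume(shape: ShapeSpec) -> float:
    """Closed-form volume (mm³) of the shape."""
    if shape.kind == "sphere":
        return 4.0 / 3.0 * np.pi * shape.radii[0] ** 3
    if shape.kind == "ellipsoid":
        rx, ry, rz = shape.radii
        return 4.0 / 3.0 * np.pi * rx * ry * rz
    # Pappus: torus-segment volume pi r^2 * arc length, plus two hemispherical caps
    tube_r, arc_r = shape.radii[0], shape.radii[1]
    arc_len = arc_r * np.deg2rad(shape.bend_angle)
    return float(np.pi * tube_r**2 * arc_len + 4.0 / 3.0 * np.pi * tube_r**3)


def _shape_bounds(shape: ShapeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Conservative world-space bounding box of the shape."""
    c = np.asarray(shape.center)
    if shape.kind == "sphere":
        r = np.full(3, shape.radii[0])
    elif shape.kind == "ellipsoid":
        r = np.asarray(shape.radii)
    else:
        tube_r, arc_r = shape.radii[0], shape.radii[1]
        r = np.array([arc_r + tube_r, arc_r + tube_r, tube_r])
    return c - r, c + r


def rasterize(shape: ShapeSpec, dims, voxel_size, origin=None,
              transform: RigidTransform | None = None) -> LabelVolume:
    """Binary rasterization of an analytic shape onto a voxel grid.

    A voxel carries the shape's label iff its world-space *centre* lies
    inside the (optionally rigidly transformed) analytic shape.  The affine
    maps 0-based voxel indices to world mm; by default the grid is centred
    on the shape centre.  The shape plus a 2-voxel margin must fit inside
    the grid, otherwise the overflowing axis is named.
    """
    dims = tuple(int(d) for d in dims)
    vs = np.asarray(voxel_size, dtype=float)
    if vs.ndim == 0:
        vs = np.repeat(vs, 3)
    if origin is None:
        centre = np.asarray(shape.center, dtype=float)
        if transform is not None:
            centre = transform.apply(centre)[0]
        origin = centre - vs * (np.asarray(dims) - 1) / 2.0
    origin = np.asarray(origin, dtype=float)
    lo, hi = _shape_bounds(shape)
    if transform is not None:
        corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
        tc = transform.apply(corners)
        lo, hi = tc.min(axis=0), tc.max(axis=0)
    glo = origin + 2 * vs
    ghi = origin + vs * (np.asarray(dims) - 1) - 2 * vs
    for a, name in enumerate("xyz"):
        if lo[a] < glo[a] - 1e-9 or hi[a] > ghi[a] + 1e-9:
            raise ValueError(
                f"shape (with 2-voxel margin) exceeds the grid bounds along axis {name}: "
                f"shape spans [{lo[a]:.2f}, {hi[a]:.2f}] mm, grid allows "
                f"[{glo[a]:.2f}, {ghi[a]:.2f}] mm"
            )
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    centres = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * vs + origin
    if transform is not None:
        centres = transform.inverse().apply(centres)
    flags = _inside_points(shape, centres).reshape(dims)
    voxels = np.where(flags, shape.label, 0).astype(np.int16)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = origin
    return LabelVolume(voxels, affine)


def make_pair(shape: ShapeSpec, perturbation: RigidTransform,
              boundary_flip_rate: float = 0.0, seed: int = 0,
              dims=(64, 64, 64), voxel_size=1.0) -> tuple[LabelVolume, LabelVolume, RigidTransform]:
    """A back-to-back pair: the shape, and the shape moved by a known transform.

    Both volumes share one grid (centred on the unmoved shape).  The second
    volume is the analytic shape under ``perturbation``, re-rasterized, with
    boundary voxels — those with at least one opposite-valued 6-neighbour —
    flipped independently at ``boundary_flip_rate``.  Returns the pair and
    the ground-truth transform.
    """
    if not 0.0 <= boundary_flip_rate < 0.5:
        raise ValueError("boundary_flip_rate must be in [0, 0.5)")
    vol1 = rasterize(shape, dims, voxel_size)
    origin = vol1.affine[:3, 3]
    vol2 = rasterize(shape, dims, voxel_size, origin=origin, transform=perturbation)
    if boundary_flip_rate > 0.0:
        fg = vol2.voxels > 0
        boundary = np.zeros_like(fg)
        for axis in range(3):
            for shift in (1, -1):
                neigh = np.roll(fg, shift, axis=axis)
                # roll wraps; wrapped faces are interior-margin by construction
                boundary |= fg != neigh
        rng = np.random.default_rng(seed)
        flips = boundary & (rng.random(fg.shape) < boundary_flip_rate)
        new = np.where(flips, ~fg, fg)
        vol2 = LabelVolume(np.where(new, shape.label, 0).astype(np.int16), vol2.affine)
    return vol1, vol2, perturbation


# ---------------------------------------------------------------------------
# factorial observation tables
# ---------------------------------------------------------------------------

DEFAULT_LEVELS = {
    "G": ("CTRL", "MCIN", "MCIP", "AD"),
    "M": ("Manual", "FIRST", "FreeSurfer"),
    "H": ("Left", "Right"),
    "T": ("BL", "M12"),
    "R": ("Anterior", "Middle", "Posterior"),
}

_FACTOR_COLUMNS = {"G": "group", "M": "method", "H": "hemisphere", "T": "timepoint", "R": "region"}


@dataclass
class DesignSpec:
    """A factorial design with known mixed-model ground truth.

    ``coefficients`` maps term names to effects: ``"intercept"`` to a float;
    a main effect like ``"G"`` to {level: coefficient}; an interaction like
    ``"G:R"`` to {(level_G, level_R): coefficient}.  Levels omitted from a
    term's dict contribute 0, so supplying only non-reference levels
    reproduces treatment-coded coefficients exactly.  Responses are

        intercept + sum of matching fixed effects
        + subject intercept ~ N(0, sd_subject²) + N(0, sd_residual²).
    """

    n_subjects_per_group: int = 20
    levels: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    coefficients: dict = field(default_factory=dict)
    sd_subject: float = 0.0
    sd_residual: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd_subject < 0 or self.sd_residual < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        valid = set(self.levels)
        for term in self.coefficients:
            if term == "intercept":
                continue
            parts = term.split(":")
            if len(set(parts)) != len(parts) or not set(parts) <= valid:
                raise ValueError(
                    f"unknown term {term!r}; valid terms are 'intercept' and "
                    f"colon-joined combinations of {sorted(valid)}"
                )
            effects = self.coefficients[term]
            for key in effects:
                combo = (key,) if isinstance(key, str) else tuple(key)
                if len(combo) != len(parts):
                    raise ValueError(f"coefficient key {key!r} does not match term {term!r}")
                for f, lev in zip(parts, combo):
                    if lev not in self.levels[f]:
                        raise ValueError(f"unknown level {lev!r} for factor {f} in term {term!r}")


def simulate_observations(design: DesignSpec) -> pd.DataFrame:
    """One record per subject x method x hemisphere x timepoint (x region) cell.

    Deterministic under ``design.seed``; columns are subject, group, method,
    hemisphere, timepoint, region (if the design has factor R) and response.
    """
    rng = np.random.default_rng(design.seed)
    lv = design.levels
    within = [f for f in ("M", "H", "T", "R") if f in lv]
    rows = []
    subj_effects = {}
    for g in lv["G"]:
        for s in range(design.n_subjects_per_group):
            sid = f"{g}_{s + 1:03d}"
            subj_effects[sid] = rng.normal(0.0, design.sd_subject) if design.sd_subject > 0 else 0.0
            cells = [()]
            for f in within:
                cells = [c + (levq,) for c in cells for levq in lv[f]]
            for cell in cells:
                rec = {"subject": sid, "group": g}
                fac_levels = {"G": g}
                for f, levq in zip(within, cell):
                    rec[_FACTOR_COLUMNS[f]] = levq
                    fac_levels[f] = levq
                resp = float(design.coefficients.get("intercept", 0.0))
                for term, effects in design.coefficients.items():
                    if term == "intercept":
                        continue
                    parts = term.split(":")
                    key = tuple(fac_levels[f] for f in parts)
                    lookup = key[0] if len(key) == 1 else key
                    if lookup in effects:
                        resp += float(effects[lookup])
                rec["response"] = resp + subj_effects[sid]
                rows.append(rec)
    df = pd.DataFrame(rows)
    if design.sd_residual > 0:
        df["response"] = df["response"] + rng.normal(0.0, design.sd_residual, len(df))
    return df
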