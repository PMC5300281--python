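"""Readers and writers for the standard on-disk formats.

Label maps travel as NIfTI (.nii / .nii.gz); transforms as FLIRT-style 4x4
whitespace-separated ASCII; meshes as PLY/STL; tables as CSV.  Voxel
indices are 0-based and world coordinates follow the NIfTI affine exactly.
Transform matrices are applied in world-mm space as given — supply
world-space matrices (FLIRT's internal scaled-voxel convention is not
reinterpreted here).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .surfaces import LabelVolume
from .transforms import RigidTransform

__all__ = [
    "RunConfig",
    "read_label_volume",
    "write_label_volume",
    "read_flirt_matrix",
    "write_flirt_matrix",
    "write_table",
    "read_table",
    "tool_version",
]


def tool_version() -> str:
    try:
        return version("hippomesh")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """Run-wide knobs shared by the CLI subcommands."""

    spacing: float = 0.5          # sample-grid spacing, mm
    margin: float = 2.0           # sample-grid margin around surfaces, mm
    fractions: tuple[float, float, float] = (0.35, 0.45, 0.20)
    seed: int = 0
    outdir: Path = field(default_factory=lambda: Path("."))
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")
        self.outdir = Path(self.outdir)

    def hash(self) -> str:
        payload = json.dumps(
            {
                "spacing": self.spacing,
                "margin": self.margin,
                "fractions": list(self.fractions),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_label_volume(path) -> LabelVolume:
    """Load a NIfTI label map; must be 3D, integer-valued, invertible affine.

    Float voxel values within 1e-6 of integers are rounded; anything else is
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got {data.ndim}D in {path}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded)) > 1e-6:
            raise ValueError(f"non-integer label values in {path} (beyond 1e-6 tolerance)")
        data = rounded.astype(np.int32)
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"non-invertible affine in {path}")
    return LabelVolume(data.astype(np.int32), affine)


def write_label_volume(volume: LabelVolume, path) -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.int32), volume.affine)
    nib.save(img, str(path))


def read_flirt_matrix(path, require_rigid: bool = False):
    """Parse a FLIRT-style 4x4 ASCII matrix.

    Returns a :class:`RigidTransform` when ``require_rigid`` (or when the
    matrix happens to validate as rigid), else the raw 4x4 array.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such transform file: {path}")
    rows = []
    for line in path.read_text().splitlines():
        if line.strip():
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ValueError(f"non-numeric token in {path}: {exc}") from exc
    m = np.asarray(rows, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected 4 rows x 4 columns in {path}, got shape {m.shape}")
    if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-6):
        raise ValueError(f"last row of {path} must be (0, 0, 0, 1), got {m[3]}")
    if require_rigid:
        return RigidTransform(m)
    try:
        return RigidTransform(m)
    except ValueError:
        return m


def write_flirt_matrix(matrix, path) -> None:
    m = np.asarray(getattr(matrix, "matrix", matrix), dtype=float)
    lines = ["  ".join(f"{v: .12e}" for v in row) for row in m]
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """CSV with a provenance header (tool version, config hash, seed)."""
    path = Path(path)
    header = [f"# hippomesh {tool_version()}"]
    if config is not None:
        header.append(f"# config_hash {config.hash()} seed {config.seed}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
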