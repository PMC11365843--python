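"""Core image containers and NIfTI plumbing.

:class:`Volume3D` is the unit of exchange between all pipeline stages: a 3D
scalar grid plus the grid-to-world affine.  It is a thin, explicit wrapper
around what a :class:`nibabel.Nifti1Image` carries, kept separate so that
in-memory stages never touch disk formats.

:class:`RigidTransform` is a proper rigid motion (rotation + translation in
world mm) with exact composition, inversion and matrix square root -- the
square root is what the halfway-space construction needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.spatial.transform import Rotation


class MetadataError(ValueError):
    """Raised for invalid or degenerate image metadata (e.g. singular affine)."""


@dataclass
class Volume3D:
    """A 3D scalar image with voxel-to-world geometry.

    Parameters
    ----------
    data
        3D array of intensities (any float/int dtype; converted lazily).
    affine
        4x4 voxel-index -> world-mm transform (NIfTI convention, RAS+ world).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise MetadataError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise MetadataError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def orientation_code(self) -> str:
        """Axis-orientation label such as ``RAS`` (nibabel axcodes)."""
        return "".join(nib.aff2axcodes(self.affine))

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy(), affine=self.affine.copy())

    # --- NIfTI round trip ---------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "Volume3D":
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        return cls(data=data, affine=np.asarray(img.affine))

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume3D":
        return cls.from_nifti(nib.load(str(path)))


def as_float32(vol: Volume3D) -> Volume3D:
    return Volume3D(vol.data.astype(np.float32, copy=False), vol.affine)


@dataclass
class RigidTransform:
    """A rigid world-space motion ``x -> R x + t`` (rotation in SO(3), t in mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of world points."""
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply *other* first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def sqrt(self) -> "RigidTransform":
        """The halfway motion ``H`` with ``H o H == self`` exactly.

        Rotation: half the rotation vector.  Translation: solves
        ``(I + R_half) t_half = t``, which reproduces the full motion on
        composition (the screw-decomposition midpoint).
        """
        r_half = Rotation.from_matrix(self.rotation)
        r_half = Rotation.from_rotvec(r_half.as_rotvec() * 0.5).as_matrix()
        t_half = np.linalg.solve(np.eye(3) + r_half, self.translation)
        return RigidTransform(rotation=r_half, translation=t_half)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(rotation=m[:3, :3], translation=m[:3, 3])

    def rotation_angle_deg(self) -> float:
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))
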