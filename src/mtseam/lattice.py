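"""Microtubule lattice geometry.

A microtubule is modelled as an N-protofilament, S-start pseudo-helix of
tubulin monomers with axial monomer repeat ``a`` (41 Å in the standard
B-lattice).  One step of the generating helical operator relates laterally
adjacent subunits: it advances ``rise = S*a/N`` ångström along the helix
axis and rotates ``twist = -360/N`` degrees about it (left-handed sign
convention).  Applying the operator N times closes the ring and climbs
exactly S monomers.

Euler angles follow the single-particle-analysis convention used by the
rest of the package: intrinsic ZYZ, degrees, with ``rot`` (phi) the
rotation about the reference/helix Z axis, ``tilt`` (theta) the
out-of-plane tilt and ``psi`` the in-plane rotation applied last in the
image plane.  The matrix returned by :func:`euler_to_matrix` maps
reference-frame vectors to image-frame vectors:

    R(rot, tilt, psi) = Rz(psi) @ Ry(tilt) @ Rz(rot)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "HelicalArchitecture",
    "HelicalSymmetry",
    "EulerTriplet",
    "RigidTransform",
    "derive_symmetry",
    "helical_operator",
    "euler_to_matrix",
    "matrix_to_euler",
    "wrap_angle",
    "circular_difference",
]

MONOMER_REPEAT_A = 41.0  # axial length of one tubulin monomer, Å


class LatticeValidationError(ValueError):
    """An architecture or symmetry descriptor violates its invariants."""


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    if np.ndim(angle) == 0:
        return float(a)
    return a


def circular_difference(a, b):
    """Smallest signed difference a - b on the circle, in (-180, 180] deg."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class HelicalArchitecture:
    """Lattice descriptor: N protofilaments, S helix starts, monomer repeat (Å)."""

    n_protofilaments: int
    n_starts: int
    monomer_repeat: float = MONOMER_REPEAT_A

    def __post_init__(self) -> None:
        if not (8 <= int(self.n_protofilaments) <= 18):
            raise LatticeValidationError(
                f"n_protofilaments must be in 8..18, got {self.n_protofilaments}"
            )
        if int(self.n_starts) not in (2, 3, 4):
            raise LatticeValidationError(
                f"n_starts must be one of 2, 3, 4, got {self.n_starts}"
            )
        if not self.monomer_repeat > 0:
            raise LatticeValidationError(
                f"monomer_repeat must be positive, got {self.monomer_repeat}"
            )

    @classmethod
    def from_string(cls, text: str, monomer_repeat: float = MONOMER_REPEAT_A
                    ) -> "HelicalArchitecture":
        """Parse an 'N-S' label such as '14-3' (en dashes tolerated)."""
        cleaned = text.strip().replace("–", "-").replace("−", "-")
        try:
            n_str, s_str = cleaned.split("-")
            return cls(int(n_str), int(s_str), monomer_repeat)
        except ValueError as exc:
            raise LatticeValidationError(
                f"cannot parse architecture label {text!r}; expected 'N-S'"
            ) from exc

    def __str__(self) -> str:
        return f"{self.n_protofilaments}-{self.n_starts}"


@dataclass(frozen=True)
class HelicalSymmetry:
    """Per-subunit helical operator parameters: rise (Å) and twist (deg).

    Twist is negative by convention (left-handed lateral helix).
    """

    rise: float
    twist: float

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise LatticeValidationError(f"rise must be positive, got {self.rise}")
        if not (-360.0 < self.twist < 0.0):
            raise LatticeValidationError(
                f"twist must lie in (-360, 0), got {self.twist}"
            )


@dataclass(frozen=True)
class EulerTriplet:
    """ZYZ Euler angles in degrees: rot (phi), tilt (theta), psi."""

    rot: float
    tilt: float
    psi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rot", wrap_angle(self.rot))
        object.__setattr__(self, "psi", wrap_angle(self.psi))
        if not (0.0 <= self.tilt <= 180.0):
            raise LatticeValidationError(
                f"tilt must lie in [0, 180], got {self.tilt}"
            )


@dataclass(frozen=True)
class RigidTransform:
    """Rotation followed by translation: x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)


def derive_symmetry(arch: HelicalArchitecture) -> HelicalSymmetry:
    """Theoretical per-subunit helical parameters of an N-S lattice.

    rise = S*a/N and twist = -360/N, so that N operator steps close the
    ring (rotation -360°) while climbing S monomer repeats.  For the
    canonical 14-3 lattice with a = 41 Å this gives rise 8.79 Å and twist
    -25.7° (display-rounded); values are never rounded internally.
    """
    n = arch.n_protofilaments
    s = arch.n_starts
    return HelicalSymmetry(rise=s * arch.monomer_repeat / n, twist=-360.0 / n)


def _rot_z(angle_deg: float) -> np.ndarray:
    c = np.cos(np.deg2rad(angle_deg))
    s = np.sin(np.deg2rad(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def helical_operator(sym: HelicalSymmetry, k: int) -> RigidTransform:
    """k-th power of the helical symmetry operator.

    Rotation about Z by k*twist and translation along Z by k*rise; forms a
    group: operator(k1) ∘ operator(k2) == operator(k1 + k2).
    """
    return RigidTransform(
        rotation=_rot_z(k * sym.twist),
        translation=np.array([0.0, 0.0, k * sym.rise]),
    )


def euler_to_matrix(e: EulerTriplet) -> np.ndarray:
    """Rotation matrix mapping reference-frame to image-frame vectors."""
    return Rotation.from_euler(
        "ZYZ", [e.psi, e.tilt, e.rot], degrees=True
    ).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> EulerTriplet:
    """Inverse of :func:`euler_to_matrix` (up to gimbal degeneracy at tilt 0/180)."""
    psi, tilt, rot = Rotation.from_matrix(np.asarray(matrix, dtype=float)).as_euler(
        "ZYZ", degrees=True
    )
    # scipy may return a tiny negative tilt from rounding; clamp into range
    tilt = min(max(tilt, 0.0), 180.0)
    return EulerTriplet(rot=rot, tilt=tilt, psi=psi)
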