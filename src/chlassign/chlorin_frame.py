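"""Chlorin geometry engine: rigid superposition and formyl-cone generation.

The cone scan asks: if a formyl group sat on a ring substituent carbon
(C2\N{SUPERSCRIPT ONE}, C3\N{SUPERSCRIPT ONE} or C7\N{SUPERSCRIPT ONE}),
where could its oxygen be?  With the C=O bond length and the C-C=O angle
fixed, the oxygen locus is a circle — a cone around the ring-carbon ->
substituent-carbon bond — parameterized by the dihedral angle, swept here
in fixed steps (5 degrees by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import place_atom
from .structure_io import ChlSite, MACROCYCLE_LABELS

__all__ = [
    "GeometryError",
    "RigidTransform",
    "ConeGeometry",
    "CONE_FRAME_ATOMS",
    "superpose_ring",
    "cone_positions",
]


class GeometryError(RuntimeError):
    pass


#: per probed substituent carbon: (dihedral zero-reference ring atom, ring carbon)
#: The zero reference fixes the angular origin of a scan; the physically
#: meaningful output (the peak direction in the protein frame) does not
#: depend on this choice.
CONE_FRAME_ATOMS: dict[str, tuple[str, str]] = {
    "C21": ("C1", "C2"),
    "C31": ("C2", "C3"),
    "C71": ("C8", "C7"),
}


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t with its post-fit RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise GeometryError("rotation matrix is not proper (det != +1)")
        if self.rmsd < 0:
            raise GeometryError("negative rmsd")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation, self.rmsd)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            0.0,
        )


@dataclass
class ConeGeometry:
    """Idealized formyl-oxygen placement geometry.

    bond_len_CO (1.22 A) and angle_CCO_deg (120 deg) are standard sp2
    carbonyl stereochemistry; step_deg controls angular sampling density.
    """

    position: str = "C21"  # C21 | C31 | C71
    step_deg: float = 5.0
    bond_len_CO: float = 1.22
    angle_CCO_deg: float = 120.0

    def __post_init__(self) -> None:
        if self.position not in CONE_FRAME_ATOMS:
            raise GeometryError(f"unsupported cone position {self.position!r}")
        if self.step_deg <= 0 or abs(360.0 % self.step_deg) > 1e-9:
            raise GeometryError("step_deg must divide 360")
        if self.bond_len_CO <= 0:
            raise GeometryError("bond_len_CO must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(360.0 / self.step_deg))


def superpose_ring(
    site: ChlSite,
    reference: ChlSite,
    labels: Optional[Sequence[str]] = None,
) -> RigidTransform:
    """Least-squares rigid superposition (Kabsch) of a site onto a reference.

    Uses the shared macrocycle atoms (default: the 20 carbons + 4 nitrogens).
    Returns the transform mapping `site` coordinates onto `reference`.
    """
    if labels is None:
        labels = [
            lbl for lbl in MACROCYCLE_LABELS if lbl in site.atoms and lbl in reference.atoms
        ]
    if len(labels) < 4:
        raise GeometryError(
            f"need >= 4 shared macrocycle atoms, have {len(labels)} "
            f"({site.site_id} vs {reference.site_id})"
        )
    mobile = np.array([site.atoms[lbl] for lbl in labels])
    target = np.array([reference.atoms[lbl] for lbl in labels])
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    p = mobile - mob_c
    q = target - tgt_c
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    # collinear/coincident point sets leave the rotation under-determined
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("degenerate (collinear or coincident) atom set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = tgt_c - rot @ mob_c
    fitted = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return RigidTransform(rot, translation, rmsd)


def cone_positions(
    site: ChlSite, geom: ConeGeometry
) -> list[tuple[float, np.ndarray]]:
    """Idealized formyl-oxygen positions around one substituent carbon.

    Returns n_samples pairs (dihedral_deg, xyz); pair k has dihedral
    k * step_deg measured from the fixed in-ring reference atom
    (C1 for C21, C2 for C31, C8 for C71).
    """
    ref_label, ring_label = CONE_FRAME_ATOMS[geom.position]
    for lbl in (ref_label, ring_label, geom.position):
        if lbl not in site.atoms:
            raise GeometryError(
                f"site {site.site_id}: atom {lbl} required for a {geom.position} cone is missing"
            )
    a = site.atoms[ref_label]
    b = site.atoms[ring_label]
    c = site.atoms[geom.position]
    out = []
    for k in range(geom.n_samples):
        phi = k * geom.step_deg
        point = place_atom(a, b, c, geom.bond_len_CO, geom.angle_CCO_deg, phi)
        out.append((phi, point))
    return out
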