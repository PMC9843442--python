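"""Synthetic ground-truth fixtures: chlorins, donor environments, density maps.

Everything the package detects can be generated here with known truth:
an idealized planar chlorin macrocycle carrying methyl or formyl
substituents at C2/C3/C7, protein donor atoms at controlled distances from
the probe carbons, and density maps rendered as sums of atom-centered
Gaussians with optional seeded noise.

This is deliberately not a physical cryo-EM simulator — no CTF, solvent,
or anisotropy — but it reproduces the features the detectors key on:
a resolvable formyl-oxygen density lobe at a known dihedral, and donor
atoms at exact distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .density import DensityGrid, write_map
from .geometry import place_atom, unit
from .chlorin_frame import CONE_FRAME_ATOMS
from .structure_io import (
    AtomRecord,
    ChlSite,
    FORMYL_POSITION_FOR_TYPE,
    builtin_atom_map,
    find_chl_sites,
    write_structure,
)

__all__ = [
    "PlacementError",
    "DonorSpec",
    "FixtureSpec",
    "SiteBundle",
    "chlorin_template",
    "make_chl_site",
    "make_environment",
    "make_density_map",
    "build_fixture",
    "write_fixture",
    "reference_chlorin",
    "oxygen_peak_height",
    "noise_sd_for_snr",
]


class PlacementError(RuntimeError):
    pass


_TYPE_TO_CODE = {"a": "CLA", "b": "CHL", "d": "CL7", "f": "F6C"}
_FORMYL_OXYGEN_LABEL = {"C21": "O21", "C31": "O31", "C71": "O71"}

# idealized bond lengths (A) used to solve the planar template
_BOND_N_CA = 1.38
_BOND_CA_CB = 1.44
_BOND_CB_CB = 1.36
_BOND_CA_MESO = 1.39
_RADIUS_N = 2.05
_RADIUS_MESO = 3.45
_BOND_C_SUBST = 1.50
_BOND_C_O = 1.22
_ANGLE_CCO = 120.0


def _solve_ring_params() -> tuple[float, float, float, float]:
    """Radii/azimuths (r_alpha, th_alpha, r_beta, th_beta) of the D4h template.

    Found once by least squares against the idealized bond lengths; the
    geometry is fourfold symmetric so four scalars determine every ring.
    """

    def residuals(p):
        r_a, th_a, r_b, th_b = p
        n = np.array([_RADIUS_N, 0.0])
        ca = r_a * np.array([np.cos(th_a), np.sin(th_a)])
        cb = r_b * np.array([np.cos(th_b), np.sin(th_b)])
        meso = _RADIUS_MESO * np.array([np.cos(np.pi / 4), np.sin(np.pi / 4)])
        return [
            np.linalg.norm(ca - n) - _BOND_N_CA,
            np.linalg.norm(ca - cb) - _BOND_CA_CB,
            2 * r_b * np.sin(th_b) - _BOND_CB_CB,
            np.linalg.norm(meso - ca) - _BOND_CA_MESO,
        ]

    x0 = [3.08, np.radians(22.5), 4.28, np.radians(9.1)]
    sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15)
    return tuple(sol.x)  # type: ignore[return-value]


_RING_PARAMS: Optional[tuple[float, float, float, float]] = None


def _polar(radius: float, azimuth_rad: float) -> np.ndarray:
    return np.array([radius * np.cos(azimuth_rad), radius * np.sin(azimuth_rad), 0.0])


def chlorin_template() -> dict[str, np.ndarray]:
    """Idealized planar macrocycle, IUPAC labels -> xyz (z = 0), Mg at origin.

    Ring A is centered on the +x axis and the numbering runs
    counter-clockwise; substituent carbons C21/C31/C71/C81 point radially
    outward in the plane.
    """
    global _RING_PARAMS
    if _RING_PARAMS is None:
        _RING_PARAMS = _solve_ring_params()
    r_a, th_a, r_b, th_b = _RING_PARAMS
    atoms: dict[str, np.ndarray] = {"MG": np.zeros(3)}
    nitrogens = ["NA", "NB", "NC", "ND"]
    for ring in range(4):
        base = ring * np.pi / 2
        c = 5 * ring  # C1, C6, C11, C16 are the first alpha carbons of rings A-D
        atoms[f"C{c + 1}"] = _polar(r_a, base - th_a)
        atoms[f"C{c + 2}"] = _polar(r_b, base - th_b)
        atoms[f"C{c + 3}"] = _polar(r_b, base + th_b)
        atoms[f"C{c + 4}"] = _polar(r_a, base + th_a)
        atoms[f"C{c + 5}"] = _polar(_RADIUS_MESO, base + np.pi / 4)  # meso
        atoms[nitrogens[ring]] = _polar(_RADIUS_N, base)
    # in-plane substituent carbons, radially outward from the beta carbons
    for sub, ring_c, n1, n2 in (
        ("C21", "C2", "C1", "C3"),
        ("C31", "C3", "C2", "C4"),
        ("C71", "C7", "C6", "C8"),
        ("C81", "C8", "C7", "C9"),
    ):
        out_dir = unit(atoms[ring_c] - 0.5 * (atoms[n1] + atoms[n2]))
        atoms[sub] = atoms[ring_c] + _BOND_C_SUBST * out_dir
    return atoms


@dataclass(frozen=True)
class DonorSpec:
    """One environment atom (or Phe ring) placed relative to a probe carbon.

    kind: hydroxyl | sidechain_N | backbone_N | water | phe_ring
    distance: A from the probe atom (for phe_ring: see orientation)
    direction: unit 3-vector from the probe, or None for in-plane outward
    orientation: for phe_ring, "in_plane" (CH-O geometry) or "axial"
        (CHO-pi geometry, distance is probe height above the centroid)
    """

    kind: str
    distance: float
    probe: str = "C21"
    direction: Optional[tuple[float, float, float]] = None
    orientation: str = "in_plane"


@dataclass(frozen=True)
class FixtureSpec:
    """Complete recipe for one synthetic site; the seed fixes all randomness."""

    chl_type: str = "a"
    formyl_dihedral_deg: float = 90.0
    donors: tuple[DonorSpec, ...] = ()
    chain_id: str = "X"
    residue_seq: int = 601
    voxel_size: float = 0.5
    margin: float = 5.0
    b_factor: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0
    random_pose: bool = False  # apply a seeded rigid motion to everything
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # scene placement

    def __post_init__(self) -> None:
        if self.chl_type not in _TYPE_TO_CODE:
            raise PlacementError(f"unknown chl type {self.chl_type!r}")
        if self.voxel_size <= 0:
            raise PlacementError("voxel_size must be positive")
        if self.margin < 5.0:
            raise PlacementError("map margin must be >= 5 A")


@dataclass
class SiteBundle:
    """A generated site with its environment, map, and ground-truth manifest."""

    site: ChlSite
    atoms: list  # chlorophyll + environment AtomRecords
    grid: Optional[DensityGrid]
    manifest: dict


def _dialect_name(code: str, label: str) -> str:
    name = builtin_atom_map([code]).dialect_name(code, label)
    if name is None:
        raise KeyError(f"{code}: no dialect name for {label}")
    return name


def _element_of(label: str) -> str:
    if label == "MG":
        return "MG"
    return label[0]


def make_chl_site(spec: FixtureSpec) -> tuple[ChlSite, list[AtomRecord], dict]:
    """Idealized chlorophyll of the requested type, plus records and manifest."""
    code = _TYPE_TO_CODE[spec.chl_type]
    coords = {k: v.copy() for k, v in chlorin_template().items()}
    formyl_pos = FORMYL_POSITION_FOR_TYPE.get(spec.chl_type)
    if formyl_pos is not None:
        ref_label, ring_label = CONE_FRAME_ATOMS[formyl_pos]
        oxy = place_atom(
            coords[ref_label],
            coords[ring_label],
            coords[formyl_pos],
            _BOND_C_O,
            _ANGLE_CCO,
            spec.formyl_dihedral_deg,
        )
        coords[_FORMYL_OXYGEN_LABEL[formyl_pos]] = oxy
    if spec.random_pose:
        rng = np.random.default_rng(spec.seed)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-3.0, 3.0, size=3)
        coords = {k: rot @ v + shift for k, v in coords.items()}
    if any(spec.offset):
        coords = {k: v + np.asarray(spec.offset, dtype=float) for k, v in coords.items()}
    records = [
        AtomRecord(
            atom_name=_dialect_name(code, label),
            element=_element_of(label),
            residue_name=code,
            residue_seq=spec.residue_seq,
            chain_id=spec.chain_id,
            position=xyz,
            b_factor=spec.b_factor,
            is_hetero=True,
        )
        for label, xyz in coords.items()
    ]
    site = ChlSite(
        site_id=f"{spec.chain_id}:{spec.residue_seq}",
        ligand_code=code,
        annotated_type=spec.chl_type,
        atoms=coords,
        chain_id=spec.chain_id,
        residue_seq=spec.residue_seq,
    )
    manifest = {
        "site_id": site.site_id,
        "chl_type": spec.chl_type,
        "ligand_code": code,
        "formyl_position": formyl_pos,
        "formyl_dihedral_deg": spec.formyl_dihedral_deg if formyl_pos else None,
        "n_chl_atoms": len(records),
        "seed": spec.seed,
    }
    return site, records, manifest


_DONOR_TEMPLATES = {
    # kind -> (residue_name, donor atom name, element, trailing companion atom)
    "hydroxyl": ("THR", "OG1", "O", ("CB", "C", 1.43)),
    "sidechain_N": ("ASN", "ND2", "N", ("CG", "C", 1.33)),
    "backbone_N": ("GLY", "N", "N", ("CA", "C", 1.46)),
    "water": ("HOH", "O", "O", None),
}


def _default_direction(site: ChlSite, probe: str) -> np.ndarray:
    ring_label = CONE_FRAME_ATOMS[probe][1]
    return unit(site.atoms[probe] - site.atoms[ring_label])


def _phe_ring_records(
    site: ChlSite, d: DonorSpec, seq: int, direction: np.ndarray
) -> list[AtomRecord]:
    probe = site.atoms[d.probe]
    u = direction
    # any vector perpendicular to u
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    w = unit(np.cross(u, helper))
    ring_r = 1.39
    if d.orientation == "in_plane":
        centroid = probe + (d.distance + ring_r) * u
        e1, e2 = u, w  # ring plane contains the probe
    elif d.orientation == "axial":
        centroid = probe + d.distance * u
        e1, e2 = w, unit(np.cross(u, w))  # ring plane perpendicular to u
    else:
        raise PlacementError(f"unknown ring orientation {d.orientation!r}")
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    records = []
    for i, name in enumerate(names):
        ang = np.pi + i * np.pi / 3 if d.orientation == "in_plane" else i * np.pi / 3
        pos = centroid + ring_r * (np.cos(ang) * e1 + np.sin(ang) * e2)
        records.append(
            AtomRecord(
                atom_name=name,
                element="C",
                residue_name="PHE",
                residue_seq=seq,
                chain_id="P",
                position=pos,
                is_hetero=False,
            )
        )
    return records


def make_environment(site: ChlSite, spec: FixtureSpec) -> list[AtomRecord]:
    """Place the requested donor atoms / rings around the site.

    Requested probe-to-donor distances are realized exactly; any placement
    closer than 2.0 A to a site atom raises PlacementError.
    """
    records: list[AtomRecord] = []
    site_coords = np.array(list(site.atoms.values()))
    seq = 101
    for d in spec.donors:
        if d.probe not in site.atoms:
            raise PlacementError(f"probe atom {d.probe} absent from site")
        direction = (
            unit(np.asarray(d.direction, dtype=float))
            if d.direction is not None
            else _default_direction(site, d.probe)
        )
        if d.kind == "phe_ring":
            new = _phe_ring_records(site, d, seq, direction)
        elif d.kind in _DONOR_TEMPLATES:
            resname, atom_name, element, companion = _DONOR_TEMPLATES[d.kind]
            pos = site.atoms[d.probe] + d.distance * direction
            new = [
                AtomRecord(
                    atom_name=atom_name,
                    element=element,
                    residue_name=resname,
                    residue_seq=seq,
                    chain_id="P",
                    position=pos,
                    is_hetero=resname == "HOH",
                )
            ]
            if companion is not None:
                cname, celem, clen = companion
                new.append(
                    AtomRecord(
                        atom_name=cname,
                        element=celem,
                        residue_name=resname,
                        residue_seq=seq,
                        chain_id="P",
                        position=pos + clen * direction,
                        is_hetero=False,
                    )
                )
        else:
            raise PlacementError(f"unknown donor kind {d.kind!r}")
        for rec in new:
            dmin = float(np.min(np.linalg.norm(site_coords - rec.position, axis=1)))
            if dmin < 2.0:
                raise PlacementError(
                    f"{d.kind} placement clashes with the site ({dmin:.2f} A)"
                )
        records.extend(new)
        seq += 1
    return records


def make_density_map(atoms: Sequence[AtomRecord], spec: FixtureSpec) -> DensityGrid:
    """Render atoms as normalized Gaussians on an orthogonal grid.

    Per atom: weight = atomic number, variance = B/(8 pi^2) plus half a
    voxel in quadrature, so the voxel integral of each atom is its weight
    regardless of B.  Seeded Gaussian noise of SD noise_sd is added last.
    """
    if spec.voxel_size <= 0:
        raise PlacementError("voxel_size must be positive")
    pos = np.array([a.position for a in atoms])
    lo = pos.min(axis=0) - spec.margin
    hi = pos.max(axis=0) + spec.margin
    v = spec.voxel_size
    shape = np.maximum(np.ceil((hi - lo) / v).astype(int) + 1, 2)
    values = np.zeros(shape, dtype=np.float64)
    axes = [lo[i] + v * np.arange(shape[i]) for i in range(3)]
    for a in atoms:
        weight = float(gemmi.Element(a.element).atomic_number)
        sigma2 = a.b_factor / (8.0 * np.pi**2) + (v / 2.0) ** 2
        sigma = float(np.sqrt(sigma2))
        amp = weight / ((2.0 * np.pi) ** 1.5 * sigma**3) * v**3
        cut = 5.0 * sigma
        sl = []
        dist1d = []
        inside = True
        for i in range(3):
            j0 = max(int(np.floor((a.position[i] - cut - lo[i]) / v)), 0)
            j1 = min(int(np.ceil((a.position[i] + cut - lo[i]) / v)) + 1, shape[i])
            if j0 >= j1:
                inside = False
                break
            sl.append(slice(j0, j1))
            dist1d.append(axes[i][j0:j1] - a.position[i])
        if not inside:
            continue
        gx = np.exp(-(dist1d[0] ** 2) / (2 * sigma2))
        gy = np.exp(-(dist1d[1] ** 2) / (2 * sigma2))
        gz = np.exp(-(dist1d[2] ** 2) / (2 * sigma2))
        values[sl[0], sl[1], sl[2]] += amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    cell = (v * shape[0], v * shape[1], v * shape[2], 90.0, 90.0, 90.0)
    return DensityGrid(
        values=values.astype(np.float32),
        cell=cell,
        origin=lo,
        basis=np.diag([v, v, v]),
    )


def oxygen_peak_height(spec: FixtureSpec) -> float:
    """Peak (voxel-scale) density of a formyl oxygen rendered under spec."""
    sigma2 = spec.b_factor / (8.0 * np.pi**2) + (spec.voxel_size / 2.0) ** 2
    return 8.0 / ((2.0 * np.pi) ** 1.5 * sigma2**1.5) * spec.voxel_size**3


def noise_sd_for_snr(spec: FixtureSpec, snr: float) -> float:
    """Noise SD making (formyl-oxygen peak)/(noise SD) equal the given SNR."""
    return oxygen_peak_height(spec) / snr


def build_fixture(spec: FixtureSpec, with_map: bool = True) -> SiteBundle:
    """Site + environment + (optionally) map, with the ground-truth manifest."""
    site, chl_records, manifest = make_chl_site(spec)
    env = make_environment(site, spec)
    atoms = chl_records + env
    grid = make_density_map(atoms, spec) if with_map else None
    manifest = dict(manifest)
    manifest["n_atoms"] = len(atoms)
    manifest["donors"] = [
        {"kind": d.kind, "probe": d.probe, "distance": d.distance} for d in spec.donors
    ]
    for probe, formyl_type in (("C21", "f"), ("C31", "d"), ("C71", "b")):
        has_donor = any(
            d.probe == probe and d.kind in _DONOR_TEMPLATES for d in spec.donors
        )
        manifest[f"expected_hbond_{probe}"] = (
            "formyl_positive" if has_donor else "formyl_negative"
        )
    manifest["expected_conescan_C21"] = (
        "formyl_positive" if spec.chl_type == "f" else "formyl_negative"
    )
    return SiteBundle(site=site, atoms=atoms, grid=grid, manifest=manifest)


def reference_chlorin() -> ChlSite:
    """The idealized template as a ChlSite (superposition reference)."""
    site, _, _ = make_chl_site(FixtureSpec(chl_type="a", residue_seq=1, chain_id="R"))
    return site


def write_fixture(bundle: SiteBundle, out_dir: str | Path, stem: str = "fixture") -> dict:
    """Write mmCIF + MRC + manifest; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"structure": out_dir / f"{stem}.cif"}
    write_structure(bundle.atoms, paths["structure"])
    if bundle.grid is not None:
        paths["map"] = out_dir / f"{stem}.mrc"
        write_map(bundle.grid, paths["map"])
    import json

    paths["manifest"] = out_dir / f"{stem}_manifest.json"
    paths["manifest"].write_text(json.dumps(bundle.manifest, indent=1))
    return {k: str(v) for k, v in paths.items()}
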