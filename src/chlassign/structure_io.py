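"""Coordinate I/O and chlorophyll-site extraction.

Reads mmCIF / PDB files (via gemmi), locates chlorophyll ligand residues,
and renames their atoms from the deposited ligand dialect (``C2B``, ``CMB``,
``CHC`` ...) onto IUPAC chlorin positions (``C1``..``C20``, ``NA``..``ND``,
``C21`` for C2\N{SUPERSCRIPT ONE}, etc.), which is the coordinate language
the cone-scan and H-bond modules speak.

IUPAC position labels used throughout the package
-------------------------------------------------
``C1``..``C20``   the 20 macrocycle carbons (meso carbons C5/C10/C15/C20)
``NA``..``ND``    the four pyrrole nitrogens of rings A-D (IUPAC N21-N24)
``MG``            the central magnesium
``C21 C31 C71 C81``  first substituent carbons at ring positions 2, 3, 7, 8
``O21 O31 O71``   the formyl oxygen of Chl f, Chl d, Chl b respectively
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

try:  # tomllib is stdlib from 3.11
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None

import gemmi

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ChlSite",
    "LigandAtomMap",
    "SiteVerdict",
    "ParseError",
    "FormatError",
    "MACROCYCLE_CARBONS",
    "PYRROLE_NITROGENS",
    "MACROCYCLE_LABELS",
    "SUBSTITUENT_CARBONS",
    "FORMYL_POSITION_FOR_TYPE",
    "TYPE_FOR_PROBE",
    "default_atom_map",
    "builtin_atom_map",
    "load_atom_map",
    "read_structure",
    "write_structure",
    "find_chl_sites",
    "write_report",
    "read_report",
]


class ParseError(RuntimeError):
    """A coordinate file could not be parsed."""


class FormatError(RuntimeError):
    """A coordinate file has an unrecognized format."""


MACROCYCLE_CARBONS: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 21))
PYRROLE_NITROGENS: tuple[str, ...] = ("NA", "NB", "NC", "ND")
MACROCYCLE_LABELS: tuple[str, ...] = MACROCYCLE_CARBONS + PYRROLE_NITROGENS
SUBSTITUENT_CARBONS: tuple[str, ...] = ("C21", "C31", "C71", "C81")

#: which formylated chlorophyll corresponds to a formyl at each probe position
TYPE_FOR_PROBE: dict[str, str] = {"C21": "f", "C31": "d", "C71": "b"}
FORMYL_POSITION_FOR_TYPE: dict[str, str] = {"b": "C71", "d": "C31", "f": "C21"}


@dataclass
class AtomRecord:
    """One atom from a coordinate file, in the author's numbering."""

    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    b_factor: float = 20.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"bad position for atom {self.atom_name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError("element symbol must be non-empty")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)

    def is_water(self) -> bool:
        return self.residue_name in ("HOH", "WAT", "DOD", "H2O")


@dataclass
class ChlSite:
    """One chlorophyll ligand with atoms keyed by IUPAC position label."""

    site_id: str  # "chain:residue_seq", author numbering
    ligand_code: str
    annotated_type: str  # one of a, b, d, f, unknown
    atoms: dict[str, np.ndarray]
    complete: bool = False
    chain_id: str = ""
    residue_seq: int = 0

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        self.complete = all(lbl in self.atoms for lbl in MACROCYCLE_LABELS)

    def macrocycle_coords(self, labels: Sequence[str] = MACROCYCLE_LABELS) -> np.ndarray:
        missing = [lbl for lbl in labels if lbl not in self.atoms]
        if missing:
            raise KeyError(f"site {self.site_id} missing macrocycle atoms {missing}")
        return np.array([self.atoms[lbl] for lbl in labels])

    def geometry_issues(self) -> list[str]:
        """Sanity checks on bonded distances; non-empty list flags a bad site."""
        issues = []
        for ring_c, sub_c in (("C2", "C21"), ("C3", "C31"), ("C7", "C71")):
            if ring_c in self.atoms and sub_c in self.atoms:
                d = float(np.linalg.norm(self.atoms[ring_c] - self.atoms[sub_c]))
                if not (1.3 <= d <= 1.7):
                    issues.append(f"{ring_c}-{sub_c} bond {d:.2f} A outside [1.3, 1.7]")
        return issues

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChlSite":
        """Copy of the site with every atom mapped through x -> R x + t."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return ChlSite(
            site_id=self.site_id,
            ligand_code=self.ligand_code,
            annotated_type=self.annotated_type,
            atoms={k: rot @ v + t for k, v in self.atoms.items()},
            chain_id=self.chain_id,
            residue_seq=self.residue_seq,
        )


@dataclass
class SiteVerdict:
    """One formyl-vs-methyl call for a site, from one evidence channel."""

    site_id: str
    method: str  # hbond | conescan | combined
    position_probed: str  # C21 | C31 | C71
    call: str  # formyl_positive | formyl_negative | indeterminate
    evidence: list = field(default_factory=list)
    annotated_type: str = "unknown"
    ligand_code: str = ""
    n_hits: Optional[int] = None
    min_distance_A: Optional[float] = None
    peak_angle_deg: Optional[float] = None
    peak_value: Optional[float] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method == "hbond" and self.call == "formyl_positive" and not self.evidence:
            raise ValueError("formyl_positive H-bond verdict requires evidence")


# ---------------------------------------------------------------------------
# Ligand atom-name dialects
# ---------------------------------------------------------------------------

# The wwPDB chemical components for chlorophylls (CLA, CHL, CL7, F6C ...) share
# one naming dialect in which the ring lettering is rotated by one quadrant
# relative to IUPAC numbering: the ring carrying the C2 methyl / C3 vinyl
# (IUPAC ring A) is the dialect's "B" ring, and so on around the macrocycle.
# Meso carbons CHA..CHD bridge C4x-C1y of adjacent dialect rings.
_CHLORIN_DIALECT: dict[str, str] = {
    "C1": "C1B", "C2": "C2B", "C3": "C3B", "C4": "C4B", "C5": "CHC",
    "C6": "C1C", "C7": "C2C", "C8": "C3C", "C9": "C4C", "C10": "CHD",
    "C11": "C1D", "C12": "C2D", "C13": "C3D", "C14": "C4D", "C15": "CHA",
    "C16": "C1A", "C17": "C2A", "C18": "C3A", "C19": "C4A", "C20": "CHB",
    "NA": "NB", "NB": "NC", "NC": "ND", "ND": "NA",
    "MG": "MG",
    "C21": "CMB", "C31": "CAB", "C71": "CMC", "C81": "CAC",
}

_FORMYL_OXYGEN_DIALECT: dict[str, dict[str, str]] = {
    # chl type -> {IUPAC oxygen label: dialect name}
    "b": {"O71": "OMC"},
    "d": {"O31": "OBB"},
    "f": {"O21": "OMB"},
}

#: chemical identity implied by each known component code
LIGAND_DEFAULT_TYPE: dict[str, str] = {
    "CLA": "a",
    "CHL": "b",
    "CL7": "d",
    "G9R": "d",
    "F6C": "f",
}


@dataclass
class LigandAtomMap:
    """Mapping (ligand_code, IUPAC label) -> dialect atom name."""

    entries: dict[str, dict[str, str]]
    source: str = ""
    default_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, table in self.entries.items():
            if "C21" not in table or "C71" not in table:
                raise ValueError(f"ligand {code}: map must define C21 and C71")
            names = list(table.values())
            if len(names) != len(set(names)):
                raise ValueError(f"ligand {code}: dialect names are not unique")

    @property
    def ligand_codes(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def dialect_name(self, code: str, label: str) -> Optional[str]:
        return self.entries.get(code, {}).get(label)

    def default_type(self, code: str) -> str:
        return self.default_types.get(code, "unknown")

    def merged_with(self, other: "LigandAtomMap") -> "LigandAtomMap":
        entries = {c: dict(t) for c, t in self.entries.items()}
        entries.update({c: dict(t) for c, t in other.entries.items()})
        types = dict(self.default_types)
        types.update(other.default_types)
        return LigandAtomMap(entries, f"{self.source}+{other.source}", types)


def _dialect_for(chl_type: str) -> dict[str, str]:
    table = dict(_CHLORIN_DIALECT)
    table.update(_FORMYL_OXYGEN_DIALECT.get(chl_type, {}))
    return table


def builtin_atom_map(codes: Optional[Iterable[str]] = None) -> LigandAtomMap:
    """Atom map covering the given component codes (default: all known)."""
    wanted = tuple(codes) if codes is not None else tuple(LIGAND_DEFAULT_TYPE)
    unknown = [c for c in wanted if c not in LIGAND_DEFAULT_TYPE]
    if unknown:
        raise KeyError(f"no built-in dialect for component codes {unknown}")
    entries = {c: _dialect_for(LIGAND_DEFAULT_TYPE[c]) for c in wanted}
    types = {c: LIGAND_DEFAULT_TYPE[c] for c in wanted}
    return LigandAtomMap(entries, source="builtin", default_types=types)


def default_atom_map() -> LigandAtomMap:
    """The out-of-the-box map: standard Chl a (CLA) and Chl b (CHL) codes.

    Chl d / Chl f component codes vary between depositions, so they are
    opt-in: extend with ``builtin_atom_map(["CL7", "F6C"])`` or a user file
    via :func:`load_atom_map`.
    """
    return builtin_atom_map(["CLA", "CHL"])


def load_atom_map(path: str | Path) -> LigandAtomMap:
    """Load a user override map from JSON or TOML.

    Schema: ``{"ligands": {CODE: {IUPAC_LABEL: dialect_name, ...}, ...},
    "types": {CODE: "a|b|d|f"}}``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        if tomllib is None:  # pragma: no cover
            raise RuntimeError("TOML support requires Python >= 3.11")
        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    return LigandAtomMap(
        entries={c: dict(t) for c, t in data["ligands"].items()},
        source=str(path),
        default_types=dict(data.get("types", {})),
    )


# ---------------------------------------------------------------------------
# Reading and writing coordinates
# ---------------------------------------------------------------------------


def _detect_format(path: Path, format_hint: Optional[str]) -> gemmi.CoorFormat:
    if format_hint is not None:
        try:
            return {"mmcif": gemmi.CoorFormat.Mmcif, "pdb": gemmi.CoorFormat.Pdb}[format_hint]
        except KeyError:
            raise FormatError(f"unknown format hint {format_hint!r}") from None
    return gemmi.CoorFormat.Detect


def read_structure(
    path: str | Path,
    format_hint: Optional[str] = None,
    keep_waters: bool = True,
) -> list[AtomRecord]:
    """Read every atom of a mmCIF or PDB file into AtomRecords.

    Author chain/residue numbering is preserved (the numbering the field
    uses to name chlorophyll sites, e.g. "605").  Alternate conformers are
    collapsed to the highest-occupancy one (ties broken by altloc letter).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_detect_format(path, format_hint))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no model")
    st.setup_entities()
    records: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if not keep_waters and residue.is_water():
                continue
            het = residue.het_flag == "H"
            # altloc resolution: per atom name keep max occupancy, tie -> first letter
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = by_name.get(atom.name)
                if (
                    prev is None
                    or atom.occ > prev.occ
                    or (atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~"))
                ):
                    by_name[atom.name] = atom
            for name, atom in by_name.items():
                records.append(
                    AtomRecord(
                        atom_name=name,
                        element=atom.element.name,
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                        is_hetero=het,
                    )
                )
    if not records:
        raise ParseError(f"{path}: no atom records found")
    return records


def write_structure(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write AtomRecords as mmCIF (or PDB if the suffix is .pdb)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rec in atoms:
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = chain
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid.num == rec.residue_seq and last.name == rec.residue_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = rec.residue_name
            res.seqid = gemmi.SeqId(rec.residue_seq, " ")
            res.het_flag = "H" if rec.is_hetero else "A"
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element)
        atom.pos = gemmi.Position(*rec.position)
        atom.occ = rec.occupancy
        atom.b_iso = rec.b_factor
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() == ".pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))


def find_chl_sites(
    atoms: Sequence[AtomRecord],
    atom_map: Optional[LigandAtomMap] = None,
    annotation: Optional[Mapping[str, str]] = None,
    chains: Optional[Iterable[str]] = None,
) -> list[ChlSite]:
    """Locate chlorophyll ligand residues and express them as ChlSites.

    annotation: optional truth table {site_id: chl type} overriding the
    chemical identity implied by the component code.
    chains: restrict to these chain ids (e.g. one monomer of a dimer).
    """
    if atom_map is None:
        atom_map = default_atom_map()
    chain_filter = set(chains) if chains is not None else None
    residues: dict[tuple[str, int, str], dict[str, np.ndarray]] = {}
    order: list[tuple[str, int, str]] = []
    chl_codes = set(atom_map.ligand_codes)
    seen_codes: set[str] = set()
    for rec in atoms:
        if rec.is_hetero and not rec.is_water():
            seen_codes.add(rec.residue_name)
        if rec.residue_name not in chl_codes:
            continue
        if chain_filter is not None and rec.chain_id not in chain_filter:
            continue
        key = rec.residue_key
        if key not in residues:
            residues[key] = {}
            order.append(key)
        residues[key][rec.atom_name] = rec.position
    unmapped = {
        code
        for code in seen_codes - chl_codes
        if code in LIGAND_DEFAULT_TYPE
    }
    for code in sorted(unmapped):
        logger.warning(
            "chlorophyll-like ligand %s present but absent from the atom map; skipped", code
        )
    sites: list[ChlSite] = []
    all_labels = MACROCYCLE_LABELS + ("MG",) + SUBSTITUENT_CARBONS + ("O21", "O31", "O71")
    for chain_id, seq, code in order:
        dialect_atoms = residues[(chain_id, seq, code)]
        site_atoms: dict[str, np.ndarray] = {}
        for label in all_labels:
            dialect = atom_map.dialect_name(code, label)
            if dialect is not None and dialect in dialect_atoms:
                site_atoms[label] = dialect_atoms[dialect]
        site_id = f"{chain_id}:{seq}"
        annotated = atom_map.default_type(code)
        if annotation and site_id in annotation:
            annotated = annotation[site_id]
        site = ChlSite(
            site_id=site_id,
            ligand_code=code,
            annotated_type=annotated,
            atoms=site_atoms,
            chain_id=chain_id,
            residue_seq=seq,
        )
        issues = site.geometry_issues()
        if issues:
            logger.warning("site %s geometry issues: %s", site_id, "; ".join(issues))
        sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# Verdict reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "site_id",
    "ligand_code",
    "annotated_type",
    "method",
    "position",
    "call",
    "n_hits",
    "min_distance_A",
    "peak_angle_deg",
    "peak_value",
    "threshold",
]


def verdicts_to_frame(verdicts: Sequence[SiteVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append(
            {
                "site_id": v.site_id,
                "ligand_code": v.ligand_code,
                "annotated_type": v.annotated_type,
                "method": v.method,
                "position": v.position_probed,
                "call": v.call,
                "n_hits": v.n_hits,
                "min_distance_A": v.min_distance_A,
                "peak_angle_deg": v.peak_angle_deg,
                "peak_value": v.peak_value,
                "threshold": v.threshold,
            }
        )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_report(verdicts: Sequence[SiteVerdict], path: str | Path, format: str = "tsv") -> None:
    """Write verdicts as TSV (one row per site/method/position) or JSON."""
    if not verdicts:
        raise ValueError("no verdicts to write")
    path = Path(path)
    frame = verdicts_to_frame(verdicts)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        records = frame.to_dict(orient="records")
        clean = [
            {k: (None if pd.isna(v) else v) if not isinstance(v, str) else v for k, v in r.items()}
            for r in records
        ]
        path.write_text(json.dumps(clean, indent=1))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text()), columns=_REPORT_COLUMNS)
    raise ValueError(f"unknown report format {format!r}")
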