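"""Low-level vector geometry shared by the chlorin frame and the fixture builder.

All routines operate on plain numpy arrays of shape (3,) in Angstroms and
degrees.  Dihedral sign follows the IUPAC convention: looking down the B->C
bond, a positive angle rotates the A->B projection counter-clockwise onto
C->D.
"""

from __future__ import annotations

import numpy as np

__all__ = ["unit", "angle_deg", "dihedral_deg", "place_atom", "fit_plane"]


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the triangle a-b-c, in degrees."""
    u, v = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion angle a-b-c-d in degrees, in (-180, 180]."""
    b0 = a - b
    b1 = unit(c - b)
    b2 = d - c
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle_deg: float,
    dihedral: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to the chain a-b-c.

    The returned point satisfies |c-D| = bond_length, angle(b, c, D) =
    bond_angle_deg and dihedral(a, b, c, D) = dihedral (degrees).
    """
    theta = np.radians(bond_angle_deg)
    phi = np.radians(dihedral)
    bc = unit(c - b)
    n = np.cross(b - a, bc)
    nn = float(np.linalg.norm(n))
    if nn < 1e-10:
        raise ValueError("reference atoms a, b, c are collinear")
    n = n / nn
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through >= 3 points; returns (centroid, unit normal)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]
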