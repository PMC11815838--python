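"""Internal-coordinate geometry: atom placement, torsions, side-chain rotation.

All coordinates are in Å, all angles in degrees unless noted. The placement
primitive is the standard natural-extension-reference-frame (NeRF)
construction: an atom D is positioned from three reference atoms (C, B, A)
given the bond length |DC|, the angle D-C-B and the torsion D-C-B-A.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom", "dihedral", "bond_angle", "rotation_about_axis",
    "rotate_points_about_bond", "sp2_bisector_h",
]


def place_atom(c: np.ndarray, b: np.ndarray, a: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position a new atom D bonded to ``c`` using NeRF.

    ``angle_deg`` is the D-c-b angle, ``torsion_deg`` the D-c-b-a dihedral.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-8:  # collinear references: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(tor),
        -length * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.rad2deg(np.arctan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1) - np.asarray(p2)
    v2 = np.asarray(p3) - np.asarray(p2)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalized internally) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def rotate_points_about_bond(points: np.ndarray, origin: np.ndarray,
                             axis_end: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate ``points`` about the bond origin->axis_end by angle_deg."""
    rot = rotation_about_axis(np.asarray(axis_end) - np.asarray(origin), angle_deg)
    return (np.asarray(points) - origin) @ rot.T + origin


def sp2_bisector_h(parent: np.ndarray, nbr1: np.ndarray, nbr2: np.ndarray,
                   length: float) -> np.ndarray:
    """In-plane hydrogen anti to the bisector of the parent's two neighbours.

    Used for backbone amide H and ring N-H, where the proton lies in the sp2
    plane opposite the two heavy-atom substituents.
    """
    u1 = (np.asarray(nbr1) - parent)
    u1 /= np.linalg.norm(u1)
    u2 = (np.asarray(nbr2) - parent)
    u2 /= np.linalg.norm(u2)
    d = -(u1 + u2)
    n = np.linalg.norm(d)
    if n < 1e-8:
        # neighbours are antipodal; fall back to any perpendicular direction
        d = np.cross(u1, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(d) < 1e-8:
            d = np.cross(u1, np.array([0.0, 1.0, 0.0]))
        n = np.linalg.norm(d)
    return parent + d / n * length
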