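"""Internal-coordinate construction and measurement.

The builder places one atom at a time from a bond length, a bond angle and a
torsion relative to three already-placed atoms (the NeRF construction).  The
measurement functions invert it, so build-then-measure is an identity up to
floating point.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["place_atom", "dihedral", "bond_angle"]


def place_atom(
    a1: np.ndarray,
    a2: np.ndarray,
    a3: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom X bonded to ``a1`` with angle X-a1-a2 and torsion
    X-a1-a2-a3.

    Parameters are in Angstrom and degrees.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    a3 = np.asarray(a3, dtype=float)
    bc = a1 - a2
    nbc = np.linalg.norm(bc)
    if nbc < 1e-9:
        raise DegenerateGeometryError("reference atoms a1/a2 coincide")
    bc = bc / nbc
    ab = a2 - a3
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise DegenerateGeometryError("reference atoms are collinear")
    n = n / nn
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    # local frame: x along a2->a1, y in the a3-a2-a1 plane, z = x cross y
    return a1 + d[0] * bc + d[1] * m + d[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9:
        raise DegenerateGeometryError("central dihedral atoms coincide")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    a = p0 - p1
    b = p2 - p1
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise DegenerateGeometryError("angle atoms coincide")
    c = np.dot(a, b) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
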