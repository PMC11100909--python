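"""Low-level angular and Cartesian geometry.

All torsions in the package are degrees on the half-open interval
[-180, 180); every wrap goes through :func:`wrap_angle` so that bin
boundaries behave identically everywhere.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "circular_distance",
    "compute_dihedral",
    "bond_angle",
    "place_atom",
]


class DihedralError(ValueError):
    """Raised when a dihedral is undefined (collinear points)."""


def wrap_angle(angle):
    """Wrap degrees into the canonical half-open interval [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


def circular_distance(a, b, period: float = 360.0):
    """Shortest angular separation |a - b| on a circle of the given period."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % period
    return np.minimum(d, period - d)


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in [-180, 180).

    IUPAC convention: looking from p2 toward p3, a clockwise rotation of
    the far bond relative to the near bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DihedralError("dihedral undefined: three consecutive points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    return float(wrap_angle(angle))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 at the central point, degrees in [0, 180]."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom ``d`` from internal coordinates (natural extension).

    ``d`` is bonded to ``c`` at distance ``bond`` (A), with bond angle
    b-c-d equal to ``angle`` (degrees) and dihedral a-b-c-d equal to
    ``torsion`` (degrees).  Inverse of :func:`compute_dihedral`:
    ``compute_dihedral(a, b, c, place_atom(a, b, c, r, theta, chi)) == chi``.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise DihedralError("cannot place atom: reference points are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
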