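"""Small vector-geometry helpers shared by the fixture builder and terminus capping.

All coordinates are in Angstrom, angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

TETRAHEDRAL = 109.47122063449069  # arccos(-1/3)


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u = unit(np.asarray(a, float) - np.asarray(b, float))
    v = unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, IUPAC sign convention."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b0, b1, b2 = b - a, c - b, d - c
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def place_internal(a, b, c, r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom D from internal coordinates against the frame (a, b, c).

    D is bonded to c with bond length ``r``, angle(b, c, D) = ``theta`` and
    dihedral(a, b, c, D) = ``phi`` (natural extension reference frame).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    th = np.radians(theta)
    ph = np.radians(phi)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph)]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def complete_hydrogens(
    x: np.ndarray, neighbors: list[np.ndarray], n_h: int, r: float = 1.090
) -> list[np.ndarray]:
    """Positions for ``n_h`` hydrogens completing the valence of atom at ``x``.

    Supported patterns: CH3/NH3 (one heavy neighbor, 3 H), CH2 (two neighbors,
    2 H), CH (three neighbors, 1 H) and a lone substituent on a one-neighbor
    atom (1 H, staggered).
    """
    x = np.asarray(x, float)
    nbrs = [np.asarray(p, float) for p in neighbors]
    if n_h == 0:
        return []
    if len(nbrs) == 1:
        p = nbrs[0]
        # need an arbitrary but deterministic reference for the dihedral
        ref = p + _any_perpendicular(x - p)
        phis = {1: [180.0], 2: [90.0, 270.0], 3: [60.0, 180.0, 300.0]}[n_h]
        return [place_internal(ref, p, x, r, TETRAHEDRAL, phi) for phi in phis]
    if len(nbrs) == 2:
        n1, n2 = unit(nbrs[0] - x), unit(nbrs[1] - x)
        bis = -unit(n1 + n2)
        perp = unit(np.cross(n1, n2))
        half = np.radians(TETRAHEDRAL / 2.0)
        out = []
        for sgn in ([+1.0, -1.0] if n_h == 2 else [+1.0]):
            d = unit(bis * np.cos(half) + sgn * perp * np.sin(half))
            out.append(x + r * d)
        return out
    if len(nbrs) >= 3:
        s = np.sum([unit(p - x) for p in nbrs[:3]], axis=0)
        return [x + r * -unit(s)]
    raise ValueError("unsupported hydrogen-completion pattern")


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    v = unit(v)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, v)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, trial))
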