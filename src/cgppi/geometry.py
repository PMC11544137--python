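"""Small geometry helpers: interior angles and IUPAC torsions in degrees."""

from __future__ import annotations

import numpy as np


def interior_angle(a, b, c) -> float:
    """Interior angle at ``b`` of the triple (a, b, c), degrees in [0, 180].

    Raises ``ValueError`` if either arm has zero length (coincident points),
    which makes the angle undefined.
    """
    u = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    v = np.asarray(c, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle undefined: coincident points in triple")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def torsion_angle(a, b, c, d) -> float:
    """Signed torsion of (a, b, c, d), IUPAC sign, degrees in (-180, 180].

    Zero for a cis (eclipsed) planar arrangement.
    """
    p = [np.asarray(x, dtype=np.float64) for x in (a, b, c, d)]
    b0, b1, b2 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise ValueError("torsion undefined: collinear points in quadruple")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang
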