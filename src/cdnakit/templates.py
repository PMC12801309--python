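"""Idealized nucleotide building blocks.

Bases are embedded as planar coordinates in the standard base reference
frame (origin at the pairing centre, x toward the major groove, y toward the
strand-1 sugar, z along the stack).  A reduced backbone (P, O5', C5', sugar
ring, O3') is attached with an anti glycosidic torsion and a C2'-endo sugar.
The synthetic generator and the helix analyzer share these templates, which
makes parameter round-trips exact by construction.

All returned coordinates are in nm.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .geometry import dihedral, rotation_about

__all__ = [
    "BASE_ATOMS",
    "RING_NAMES",
    "COMPLEMENT",
    "ring_pucker",
    "ribose_ring",
    "nucleotide_template",
    "frame_fit_names",
]

# planar base coordinates (x, y) in Angstrom, standard reference frame
_BASE_XY: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124), "C1'": (-2.479, 5.346),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.848, 0.193),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177), "C1'": (-2.477, 5.399),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068), "C1'": (-2.477, 5.402),
    },
    "T": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.135), "O2": (-2.562, 2.608),
        "N3": (-0.298, 2.407), "C4": (0.994, 2.897), "O4": (1.944, 2.119),
        "C5": (1.106, 4.338), "C7": (2.466, 4.961), "C6": (-0.024, 5.057),
        "C1'": (-2.481, 5.354),
    },
    "U": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.131), "O2": (-2.563, 2.608),
        "N3": (-0.302, 2.397), "C4": (0.989, 2.884), "O4": (1.935, 2.094),
        "C5": (1.089, 4.311), "C6": (-0.024, 5.053), "C1'": (-2.481, 5.354),
    },
}

# the sugar/backbone is attached as one canonical, letter-independent unit so
# that backbone geometry (and hence groove widths) is exactly sequence
# uniform; C1' is unified accordingly
_C1P_CANONICAL = (-2.478, 5.375)
for _tbl in _BASE_XY.values():
    _tbl["C1'"] = _C1P_CANONICAL
_N_CANONICAL = np.array([-0.1287, 0.4525, 0.0])  # nm, virtual glycosidic N
_CHIREF_CANONICAL = np.array([-0.137, 0.314, 0.0])  # nm, virtual chi reference
_P_CANONICAL = np.array([0.246, 0.918, 0.0])  # nm, B-like phosphate position

RING_NAMES: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}
# chi is O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines)
CHI_REF = {"A": "C4", "G": "C4", "C": "C2", "T": "C2", "U": "C2"}

SUGAR_RING_ORDER = ("C1'", "C2'", "C3'", "C4'", "O4'")


def BASE_ATOMS(letter: str) -> dict[str, np.ndarray]:
    """Base (+C1') template coordinates in nm, z = 0."""
    table = _BASE_XY[letter]
    return {n: np.array([x, y, 0.0]) * 0.1 for n, (x, y) in table.items()}


def ring_pucker(coords: np.ndarray) -> tuple[float, float]:
    """Altona-Sundaralingam pseudorotation (phase deg in [0,360), amplitude deg).

    ``coords`` are the five ring atoms in the order C1',C2',C3',C4',O4'.
    """
    c = np.asarray(coords, float)
    if c.shape != (5, 3):
        raise ValueError("ring_pucker expects five ring atoms")
    idx = {"C1'": 0, "C2'": 1, "C3'": 2, "C4'": 3, "O4'": 4}
    # nu_j is the torsion about the bond opposite atom j+2 (standard numbering)
    quads = [
        ("C4'", "O4'", "C1'", "C2'"),  # nu0
        ("O4'", "C1'", "C2'", "C3'"),  # nu1
        ("C1'", "C2'", "C3'", "C4'"),  # nu2
        ("C2'", "C3'", "C4'", "O4'"),  # nu3
        ("C3'", "C4'", "O4'", "C1'"),  # nu4
    ]
    nu = [dihedral(*(c[idx[n]] for n in q)) for q in quads]
    denom = 2.0 * nu[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    numer = (nu[4] + nu[1]) - (nu[3] + nu[0])
    phase = np.degrees(np.arctan2(numer, denom))
    if phase < 0:
        phase += 360.0
    amplitude = nu[2] / np.cos(np.radians(phase))
    return float(phase), float(abs(amplitude))


def _ring_coords(q_nm: float, phi_deg: float, radius: float = 0.1301) -> np.ndarray:
    """Pentagon + out-of-plane displacements; atoms in SUGAR_RING_ORDER."""
    out = np.zeros((5, 3))
    for j in range(5):
        theta = np.radians(90.0 - 72.0 * j)
        out[j, 0] = radius * np.cos(theta)
        out[j, 1] = radius * np.sin(theta)
        out[j, 2] = np.sqrt(2.0 / 5.0) * q_nm * np.cos(
            np.radians(phi_deg) + 4.0 * np.pi * j / 5.0
        )
    return out


def ribose_ring(phase_deg: float, amplitude_deg: float = 36.0) -> np.ndarray:
    """Five-membered sugar ring with a prescribed pseudorotation state.

    Solves for the out-of-plane displacement pattern whose measured
    Altona-Sundaralingam (phase, amplitude) equals the request; returns ring
    coordinates (nm) in the order C1',C2',C3',C4',O4'.
    """

    def residual(x):
        q, phi = x
        p, amp = ring_pucker(_ring_coords(q, phi))
        dp = (p - phase_deg + 180.0) % 360.0 - 180.0
        return [dp, amp - amplitude_deg]

    sol = least_squares(residual, x0=[0.040, phase_deg + 90.0], xtol=1e-14,
                        ftol=1e-14)
    return _ring_coords(sol.x[0], sol.x[1])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@lru_cache(maxsize=None)
def _canonical_sugar(chi_deg: float, pucker_deg: float) -> dict[str, np.ndarray]:
    """Letter-independent sugar + reduced backbone in the standard frame.

    Built against a virtual glycosidic nitrogen / chi reference so the same
    coordinates serve every base, making backbone geometry exactly sequence
    uniform.  The phosphate is pinned to a B-like cylindrical position.
    """
    c1p = np.array([_C1P_CANONICAL[0], _C1P_CANONICAL[1], 0.0]) * 0.1
    g = _unit(c1p - _N_CANONICAL)  # glycosidic direction, away from base

    ring = ribose_ring(pucker_deg)
    ring = ring - ring[0]
    centroid_dir = _unit(ring.mean(axis=0) - ring[0])
    axis = np.cross(centroid_dir, g)
    if np.linalg.norm(axis) < 1e-10:
        R = np.eye(3)
    else:
        ang = np.degrees(np.arccos(np.clip(centroid_dir @ g, -1.0, 1.0)))
        R = rotation_about(axis, ang)
    ring = ring @ R.T + c1p

    atoms = {name: pos for name, pos in zip(SUGAR_RING_ORDER, ring)}

    # set chi (vs the virtual reference) by rotating about the glycosidic
    # bond; probe the rotation sense empirically so wrapping cannot bite
    def _chi(a):
        return dihedral(a["O4'"], a["C1'"], _N_CANONICAL, _CHIREF_CANONICAL)

    def _rotated(a, ang):
        R = rotation_about(g, ang)
        return {
            n: ((R @ (p - c1p)) + c1p if n != "C1'" else p)
            for n, p in a.items()
        }

    chi_now = _chi(atoms)
    sense = np.sign(((_chi(_rotated(atoms, 1.0)) - chi_now + 180.0) % 360.0) - 180.0)
    delta = ((chi_deg - chi_now + 180.0) % 360.0) - 180.0
    atoms = _rotated(atoms, sense * delta)

    # exocyclic backbone: C5'/O5' bridge C4' to the pinned phosphate, O3'
    # points to the 3' side (+z, the direction the strand is grown)
    z = np.array([0.0, 0.0, 1.0])
    c4, c3, c2 = atoms["C4'"], atoms["C3'"], atoms["C2'"]
    u = _P_CANONICAL - c4
    perp = np.cross(z, u)
    perp /= np.linalg.norm(perp)
    atoms["C5'"] = c4 + 0.25 * u + 0.035 * perp - 0.03 * z
    atoms["O5'"] = c4 + 0.65 * u + 0.035 * perp - 0.02 * z
    atoms["P"] = _P_CANONICAL.copy()
    d3 = _unit(_unit(c3 - c2) + _unit(c3 - c4))
    atoms["O3'"] = c3 + 0.142 * _unit(d3 + 1.2 * z)
    return atoms


@lru_cache(maxsize=None)
def _nucleotide_template_cached(letter: str, chi_deg: float, pucker_deg: float):
    atoms = dict(BASE_ATOMS(letter))
    atoms.update(_canonical_sugar(chi_deg, pucker_deg))
    return {k: v.copy() for k, v in atoms.items()}


def nucleotide_template(
    letter: str, chi_deg: float = -105.0, pucker_deg: float = 162.0
) -> dict[str, np.ndarray]:
    """Full reduced-atom nucleotide template in the standard base frame (nm).

    Defaults give an anti glycosidic torsion and a C2'-endo (B-like) sugar.
    """
    if letter not in _BASE_XY:
        raise ValueError(f"unknown base {letter!r}")
    tpl = _nucleotide_template_cached(letter, float(chi_deg), float(pucker_deg))
    return {k: v.copy() for k, v in tpl.items()}


def frame_fit_names(letter: str) -> tuple[str, ...]:
    """Atom names used to fit a base reference frame (ring atoms + C1')."""
    return RING_NAMES[letter] + ("C1'",)
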