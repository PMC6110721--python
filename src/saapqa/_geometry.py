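"""Internal-coordinate peptide geometry.

Builds idealized all-heavy-atom peptides from torsion angles (NeRF chain
extension), extracts internal coordinates back from Cartesian backbones, and
attaches template side chains in the local residue frame.  Shared by the
solvent-accessibility reference state (extended Ala-X-Ala tripeptides) and
the synthetic decoy generator.  Geometry is idealized, not energy-minimized:
bond lengths/angles are canonical values and side-chain rotamers are
extended, which is sufficient for surface-area and backbone H-bond work.
"""

from __future__ import annotations

import math

import numpy as np

# Canonical backbone internal coordinates (Å, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.5

# Torsions of ideal secondary-structure elements (phi, psi).
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)
EXTENDED_PHI_PSI = (-120.0, 140.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural extension reference frame (NeRF) placement.

    Returns the position ``d`` with ``|d-c| = bond``, ``angle(b,c,d) = angle``
    and ``torsion(a,b,c,d) = torsion`` (degrees).
    """
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        # Collinear reference frame: pick any perpendicular.
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        n_norm = np.linalg.norm(n)
    n /= n_norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion angle a-b-c-d in degrees, in (-180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def build_backbone(phi_psi: list[tuple[float, float]]) -> np.ndarray:
    """Build an N/CA/C backbone from per-residue (phi, psi), omega fixed 180.

    Returns an array of shape (3 * n_res, 3) ordered N, CA, C per residue.
    phi of the first residue is unused (no preceding carbonyl).
    """
    n_res = len(phi_psi)
    coords = np.zeros((3 * n_res, 3))
    # Seed residue in the xy-plane.
    coords[0] = [0.0, 0.0, 0.0]                                   # N
    coords[1] = [BOND_N_CA, 0.0, 0.0]                             # CA
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    coords[2] = coords[1] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords[3 * i] = n_i
        coords[3 * i + 1] = ca_i
        coords[3 * i + 2] = c_i
    return coords


def carbonyl_oxygens(backbone: np.ndarray) -> np.ndarray:
    """Place one carbonyl O per residue, anti to the following amide N.

    ``backbone`` is the flat (3n, 3) N/CA/C array; returns (n, 3) O positions.
    """
    n_res = backbone.shape[0] // 3
    oxy = np.zeros((n_res, 3))
    for i in range(n_res):
        n_i, ca_i, c_i = backbone[3 * i], backbone[3 * i + 1], backbone[3 * i + 2]
        if i + 1 < n_res:
            psi = dihedral(n_i, ca_i, c_i, backbone[3 * i + 3])
        else:
            psi = EXTENDED_PHI_PSI[1]
        oxy[i] = place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return oxy


# ---------------------------------------------------------------------------
# Internal-coordinate round trip (used to re-embed perturbed chains)
# ---------------------------------------------------------------------------

def extract_internal(backbone: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (bond, angle, torsion) for every backbone atom after the third.

    Rebuilding with :func:`rebuild_backbone` from the same internal
    coordinates and the original first three atoms reproduces the chain
    exactly, so torsion edits re-embed the chain without touching local
    geometry.
    """
    n = backbone.shape[0]
    bonds = np.zeros(n)
    angles = np.zeros(n)
    torsions = np.zeros(n)
    for i in range(3, n):
        a, b, c, d = backbone[i - 3], backbone[i - 2], backbone[i - 1], backbone[i]
        bonds[i] = float(np.linalg.norm(d - c))
        angles[i] = bond_angle(b, c, d)
        torsions[i] = dihedral(a, b, c, d)
    return bonds, angles, torsions


def rebuild_backbone(seed: np.ndarray, bonds: np.ndarray, angles: np.ndarray,
                     torsions: np.ndarray) -> np.ndarray:
    """Rebuild a flat backbone from internal coordinates and the seed triad."""
    n = bonds.shape[0]
    coords = np.zeros((n, 3))
    coords[:3] = seed
    for i in range(3, n):
        coords[i] = place_atom(coords[i - 3], coords[i - 2], coords[i - 1],
                               bonds[i], angles[i], torsions[i])
    return coords


def phi_atom_index(res_index: int) -> int:
    """Flat-array index of the atom whose torsion is phi(res_index): its C."""
    return 3 * res_index + 2


def psi_atom_index(res_index: int) -> int:
    """Flat-array index of the atom whose torsion is psi(res_index): N of the next residue."""
    return 3 * res_index + 3


# ---------------------------------------------------------------------------
# Side-chain templates
# ---------------------------------------------------------------------------

# Each entry: atom name -> (ref_a, ref_b, ref_c, bond, angle, torsion).
# References are names of previously placed atoms of the same residue
# (backbone N/CA/C included).  Rotamers are extended (trans chi) so the
# reference tripeptide state is maximally exposed; rings are near-planar.
_CB = ("C", "N", "CA", 1.53, 110.4, -122.0)

SIDE_CHAIN_TEMPLATES: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", *_CB)],
    "SER": [("CB", *_CB), ("OG", "N", "CA", "CB", 1.42, 110.5, 180.0)],
    "CYS": [("CB", *_CB), ("SG", "N", "CA", "CB", 1.81, 114.0, 180.0)],
    "THR": [("CB", *_CB),
            ("OG1", "N", "CA", "CB", 1.43, 109.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, -60.0)],
    "VAL": [("CB", *_CB),
            ("CG1", "N", "CA", "CB", 1.52, 110.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, 60.0)],
    "ILE": [("CB", *_CB),
            ("CG1", "N", "CA", "CB", 1.52, 110.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, -60.0),
            ("CD1", "CA", "CB", "CG1", 1.52, 113.0, 180.0)],
    "LEU": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.52, 116.0, 180.0),
            ("CD1", "CA", "CB", "CG", 1.52, 110.5, 180.0),
            ("CD2", "CA", "CB", "CG", 1.52, 110.5, 60.0)],
    "ASP": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.52, 112.6, 180.0),
            ("OD1", "CA", "CB", "CG", 1.25, 118.4, 0.0),
            ("OD2", "CA", "CB", "CG", 1.25, 118.4, 180.0)],
    "ASN": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.52, 112.6, 180.0),
            ("OD1", "CA", "CB", "CG", 1.23, 120.8, 0.0),
            ("ND2", "CA", "CB", "CG", 1.33, 116.4, 180.0)],
    "GLU": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 112.6, 180.0),
            ("OE1", "CB", "CG", "CD", 1.25, 118.4, 0.0),
            ("OE2", "CB", "CG", "CD", 1.25, 118.4, 180.0)],
    "GLN": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 112.6, 180.0),
            ("OE1", "CB", "CG", "CD", 1.23, 120.8, 0.0),
            ("NE2", "CB", "CG", "CD", 1.33, 116.4, 180.0)],
    "MET": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
            ("SD", "CA", "CB", "CG", 1.81, 112.7, 180.0),
            ("CE", "CB", "CG", "SD", 1.79, 100.9, 180.0)],
    "LYS": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 111.3, 180.0),
            ("CE", "CB", "CG", "CD", 1.52, 111.3, 180.0),
            ("NZ", "CG", "CD", "CE", 1.49, 111.9, 180.0)],
    "ARG": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 111.3, 180.0),
            ("NE", "CB", "CG", "CD", 1.46, 112.0, 180.0),
            ("CZ", "CG", "CD", "NE", 1.33, 124.2, 180.0),
            ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0)],
    "HIS": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("ND1", "CA", "CB", "CG", 1.38, 122.7, 90.0),
            ("CD2", "CA", "CB", "CG", 1.36, 131.2, -90.0),
            ("CE1", "CB", "CG", "ND1", 1.32, 109.3, 180.0),
            ("NE2", "CB", "CG", "CD2", 1.37, 107.2, 180.0)],
    "PHE": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("CD1", "CA", "CB", "CG", 1.39, 120.7, 90.0),
            ("CD2", "CA", "CB", "CG", 1.39, 120.7, -90.0),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0)],
    "TYR": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("CD1", "CA", "CB", "CG", 1.39, 120.7, 90.0),
            ("CD2", "CA", "CB", "CG", 1.39, 120.7, -90.0),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.38, 119.9, 180.0)],
    "TRP": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("CD1", "CA", "CB", "CG", 1.37, 127.0, 90.0),
            ("CD2", "CA", "CB", "CG", 1.43, 126.6, -90.0),
            ("NE1", "CB", "CG", "CD1", 1.38, 110.1, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.41, 107.2, 180.0),
            ("CE3", "CB", "CG", "CD2", 1.40, 133.9, 0.0),
            ("CZ2", "CG", "CD2", "CE2", 1.40, 122.4, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.39, 118.6, 180.0),
            ("CH2", "CD2", "CE2", "CZ2", 1.37, 117.5, 0.0)],
    "PRO": [("CB", *_CB),
            ("CG", "N", "CA", "CB", 1.50, 104.5, 30.0),
            ("CD", "CA", "CB", "CG", 1.51, 106.0, -35.0)],
}

#: Heavy side-chain atom names per residue type (Gly side chain: its CA,
#: by the naccess convention — handled downstream, not listed here).
SIDE_CHAIN_ATOM_NAMES: dict[str, tuple[str, ...]] = {
    res: tuple(entry[0] for entry in tmpl) for res, tmpl in SIDE_CHAIN_TEMPLATES.items()
}


def build_side_chain(res_name: str, n: np.ndarray, ca: np.ndarray,
                     c: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Place template side-chain heavy atoms in the frame of one residue."""
    placed: dict[str, np.ndarray] = {"N": n, "CA": ca, "C": c}
    out: list[tuple[str, np.ndarray]] = []
    for name, ra, rb, rc, bond, angle, torsion in SIDE_CHAIN_TEMPLATES[res_name]:
        pos = place_atom(placed[ra], placed[rb], placed[rc], bond, angle, torsion)
        placed[name] = pos
        out.append((name, pos))
    return out


def element_of(atom_name: str) -> str:
    """Element symbol from a (heavy-atom) PDB atom name."""
    stripped = atom_name.strip()
    if stripped[:1].isdigit():
        stripped = stripped[1:]
    return stripped[0].upper()
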