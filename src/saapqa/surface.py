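"""Solvent accessible surface area and relative side-chain accessibility.

Per-atom SASA is computed by Shrake-Rupley point sampling (delegated to
biotite's C implementation) with Chothia-style van der Waals radii and a
1.4 Å water probe, the naccess conventions.  Side-chain SASA per residue is
the sum over side-chain heavy atoms (for glycine the Cα counts as the side
chain); relative accessibility divides by the same residue type's
side-chain SASA in an extended Ala-X-Ala tripeptide built with this
package's own ideal geometry, computed once and cached — so a fully
extended side chain scores 100% by construction.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from . import config, _geometry
from .core import ONE_TO_THREE, Residue, Structure, to_atom_array

logger = logging.getLogger(__name__)

# Chothia (1976) van der Waals radii as used by naccess, in Å.
_RADIUS_BY_ELEMENT = {"N": 1.65, "O": 1.40, "S": 1.85, "C": 1.87}
_DEFAULT_RADIUS = 1.80

# sp2/trigonal carbons get the smaller carbonyl/aromatic radius 1.76.
_TRIGONAL_CARBONS: set[tuple[str, str]] = {("*", "C")}
for _res, _names in {
    "ASP": ("CG",), "GLU": ("CD",), "ASN": ("CG",), "GLN": ("CD",),
    "ARG": ("CZ",),
    "HIS": ("CG", "CD2", "CE1"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}.items():
    for _n in _names:
        _TRIGONAL_CARBONS.add((_res, _n))


def atom_radius(res_name: str, atom_name: str, element: str) -> float:
    """Van der Waals radius of one heavy atom (Chothia/naccess set)."""
    el = element.upper()
    if el == "C":
        if ("*", atom_name) in _TRIGONAL_CARBONS or (res_name, atom_name) in _TRIGONAL_CARBONS:
            return 1.76
        return 1.87
    return _RADIUS_BY_ELEMENT.get(el, _DEFAULT_RADIUS)


@dataclass
class ResidueAccessibility:
    seq_number: int
    insertion_code: str
    res_name: str
    abs_sidechain_sasa: float       # Å²
    rel_sidechain_sasa: float       # % of extended-tripeptide reference; nan if undefined
    abs_total_sasa: float           # Å²
    sidechain_complete: bool        # False if expected side-chain atoms are missing

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_number, self.insertion_code)


@dataclass
class AccessibilityProfile:
    """Per-residue absolute and relative side-chain SASA for one structure."""

    structure_id: str
    per_residue: list[ResidueAccessibility]
    probe_radius: float
    n_points: int
    radii_set_name: str = config.RADII_SET_NAME

    def rel_by_key(self) -> dict[tuple[int, str], float]:
        return {r.key: r.rel_sidechain_sasa for r in self.per_residue}

    def total_sasa(self) -> float:
        return float(sum(r.abs_total_sasa for r in self.per_residue))


def _is_sidechain_atom(res_name: str, atom_name: str) -> bool:
    if res_name == "GLY":
        return atom_name == "CA"
    return atom_name not in ("N", "CA", "C", "O", "OXT")


def atom_sasa(coords: np.ndarray, radii: np.ndarray,
              probe: float = config.PROBE_RADIUS,
              n_points: int = config.SASA_POINTS) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA for an arbitrary sphere set (Å²)."""
    n = coords.shape[0]
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.element[:] = "C"
    arr.atom_name[:] = "C"
    arr.res_name[:] = "UNK"
    arr.res_id[:] = np.arange(1, n + 1)
    arr.chain_id[:] = "A"
    return np.asarray(struc.sasa(arr, probe_radius=probe, point_number=n_points,
                                 vdw_radii=np.asarray(radii, dtype=float),
                                 ignore_ions=False), dtype=float)


def compute_sasa(s: Structure, probe: float = config.PROBE_RADIUS,
                 n_points: int = config.SASA_POINTS) -> AccessibilityProfile:
    """Residue-level accessibility profile of a single-chain structure.

    Residues with missing side-chain atoms (frequent in predicted models)
    are computed from the available atoms and flagged, not dropped.
    Residue types without a reference value get ``rel = nan``.
    """
    arr = to_atom_array(s)
    radii = np.array([
        atom_radius(arr.res_name[i], arr.atom_name[i], arr.element[i])
        for i in range(arr.array_length())
    ])
    per_atom = np.asarray(struc.sasa(arr, probe_radius=probe, point_number=n_points,
                                     vdw_radii=radii, ignore_ions=False), dtype=float)
    reference = sidechain_reference(probe, n_points)
    out: list[ResidueAccessibility] = []
    i = 0
    for r in s.residues:
        n_atoms = len(r.atoms)
        sasa_slice = per_atom[i:i + n_atoms]
        sc = sum(
            sasa_slice[k] for k, (name, _, *_xyz) in enumerate(r.atoms)
            if _is_sidechain_atom(r.name, name)
        )
        total = float(np.nansum(sasa_slice))
        ref = reference.get(r.name)
        if ref is None:
            logger.warning("%s: residue type %s has no reference accessibility",
                           s.id, r.name)
            rel = float("nan")
        else:
            rel = 100.0 * sc / ref
        expected = _geometry.SIDE_CHAIN_ATOM_NAMES.get(r.name, ())
        present = {name for name, *_ in r.atoms}
        complete = all(a in present for a in expected)
        if not complete:
            logger.debug("%s: residue %s%d missing side-chain atoms",
                         s.id, r.name, r.seq_number)
        out.append(ResidueAccessibility(
            seq_number=r.seq_number, insertion_code=r.insertion_code,
            res_name=r.name, abs_sidechain_sasa=float(sc),
            rel_sidechain_sasa=rel, abs_total_sasa=total,
            sidechain_complete=complete,
        ))
        i += n_atoms
    return AccessibilityProfile(structure_id=s.id, per_residue=out,
                                probe_radius=probe, n_points=n_points)


def accessible_mask(profile: AccessibilityProfile,
                    cutoff_percent: float = config.EXPOSURE_CUTOFF_PERCENT) -> np.ndarray:
    """Surface-exposure mask: strictly greater than the cutoff (50% default)."""
    rel = np.array([r.rel_sidechain_sasa for r in profile.per_residue])
    with np.errstate(invalid="ignore"):
        return rel > cutoff_percent


@functools.lru_cache(maxsize=8)
def sidechain_reference(probe: float = config.PROBE_RADIUS,
                        n_points: int = config.SASA_POINTS) -> dict[str, float]:
    """Maximum side-chain SASA per residue type (Å²).

    Computed from extended Ala-X-Ala tripeptides built with the package's
    ideal geometry and scored with the same SASA routine, following the
    naccess reference-state convention.
    """
    ref: dict[str, float] = {}
    for one, three in ONE_TO_THREE.items():
        tri = build_tripeptide(three)
        prof_arr = to_atom_array(tri)
        radii = np.array([
            atom_radius(prof_arr.res_name[i], prof_arr.atom_name[i], prof_arr.element[i])
            for i in range(prof_arr.array_length())
        ])
        per_atom = np.asarray(struc.sasa(prof_arr, probe_radius=probe,
                                         point_number=n_points, vdw_radii=radii,
                                         ignore_ions=False), dtype=float)
        i = 0
        sc = 0.0
        for r in tri.residues:
            n_atoms = len(r.atoms)
            if r.seq_number == 2:
                sc = sum(
                    per_atom[i + k] for k, (name, *_rest) in enumerate(r.atoms)
                    if _is_sidechain_atom(r.name, name)
                )
            i += n_atoms
        ref[three] = float(sc)
    return ref


def build_tripeptide(center_res: str) -> Structure:
    """Extended Ala-X-Ala tripeptide with template side chains."""
    names = ["ALA", center_res, "ALA"]
    phi_psi = [_geometry.EXTENDED_PHI_PSI] * 3
    backbone = _geometry.build_backbone(phi_psi)
    oxygens = _geometry.carbonyl_oxygens(backbone)
    residues = []
    for i, res_name in enumerate(names):
        n, ca, c = backbone[3 * i], backbone[3 * i + 1], backbone[3 * i + 2]
        atoms = [
            ("N", "N", *map(float, n)),
            ("CA", "C", *map(float, ca)),
            ("C", "C", *map(float, c)),
            ("O", "O", *map(float, oxygens[i])),
        ]
        for name, pos in _geometry.build_side_chain(res_name, n, ca, c):
            atoms.append((name, _geometry.element_of(name), *map(float, pos)))
        residues.append(Residue(name=res_name, seq_number=i + 1, atoms=atoms))
    return Structure(id=f"AXA_{center_res}", chain_id="A", residues=residues)
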