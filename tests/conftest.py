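"""Shared fixtures: hand-written PDB texts and procedurally built structures.

All structural fixtures are generated at test time from ideal geometry;
nothing is loaded from external data.
"""

from __future__ import annotations

import numpy as np
import pytest

from saapqa import _geometry as geom
from saapqa.core import Residue, Structure


def format_pdb_atom(serial: int, name: str, res_name: str, chain: str, res_id: int,
                    x: float, y: float, z: float, occupancy: float = 1.0,
                    altloc: str = " ", element: str | None = None,
                    icode: str = " ") -> str:
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:>5d} {name_field}{altloc}{res_name:>3s} {chain}"
            f"{res_id:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
            f"{0.0:6.2f}          {element:>2s}")


def minimal_residue_lines(res_name: str, res_id: int, chain: str, serial0: int,
                          origin: tuple[float, float, float]) -> list[str]:
    ox, oy, oz = origin
    atoms = [("N", ox, oy, oz), ("CA", ox + 1.46, oy, oz),
             ("C", ox + 2.0, oy + 1.4, oz), ("O", ox + 1.6, oy + 2.5, oz)]
    return [format_pdb_atom(serial0 + i, name, res_name, chain, res_id, x, y, z)
            for i, (name, x, y, z) in enumerate(atoms)]


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written single-chain PDB with residues ALA, GLY, ILE."""
    lines = []
    serial = 1
    for i, res in enumerate(["ALA", "GLY", "ILE"]):
        lines += minimal_residue_lines(res, i + 1, "A", serial, (4.0 * i, 0.0, 0.0))
        serial += 4
    lines.append("END")
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = []
    serial = 1
    for i, res in enumerate(["ALA", "GLY"]):
        lines += minimal_residue_lines(res, i + 1, "A", serial, (4.0 * i, 0.0, 0.0))
        serial += 4
    for i, res in enumerate(["SER", "THR", "VAL"]):
        lines += minimal_residue_lines(res, i + 1, "B", serial, (4.0 * i, 8.0, 0.0))
        serial += 4
    lines.append("END")
    path = tmp_path / "two_chain.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """Residue 10 has altloc A (occupancy 0.6) and B (0.4) for its CA."""
    lines = minimal_residue_lines("ALA", 9, "A", 1, (0.0, 0.0, 0.0))
    serial = 5
    base = (4.0, 0.0, 0.0)
    lines.append(format_pdb_atom(serial, "N", "SER", "A", 10, *base)); serial += 1
    lines.append(format_pdb_atom(serial, "CA", "SER", "A", 10, base[0] + 1.46, 0.0, 0.0,
                                 occupancy=0.6, altloc="A")); serial += 1
    lines.append(format_pdb_atom(serial, "CA", "SER", "A", 10, base[0] + 1.46, 0.5, 0.5,
                                 occupancy=0.4, altloc="B")); serial += 1
    lines.append(format_pdb_atom(serial, "C", "SER", "A", 10, base[0] + 2.0, 1.4, 0.0)); serial += 1
    lines.append(format_pdb_atom(serial, "O", "SER", "A", 10, base[0] + 1.6, 2.5, 0.0)); serial += 1
    lines += minimal_residue_lines("GLY", 11, "A", serial, (8.0, 0.0, 0.0))
    lines.append("END")
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def structure_from_backbone(bb: np.ndarray, res_names: list[str] | None = None,
                            structure_id: str = "fixture", start: int = 1,
                            with_cb: bool = True) -> Structure:
    """Poly-ALA (by default) structure from a flat N/CA/C backbone array."""
    oxy = geom.carbonyl_oxygens(bb)
    n = bb.shape[0] // 3
    res_names = res_names or ["ALA"] * n
    residues = []
    for i in range(n):
        nn, ca, cc = bb[3 * i], bb[3 * i + 1], bb[3 * i + 2]
        atoms = [("N", "N", *map(float, nn)), ("CA", "C", *map(float, ca)),
                 ("C", "C", *map(float, cc)), ("O", "O", *map(float, oxy[i]))]
        if with_cb and res_names[i] != "GLY":
            cb = geom.place_atom(cc, nn, ca, 1.53, 110.4, -122.0)
            atoms.append(("CB", "C", *map(float, cb)))
        residues.append(Residue(name=res_names[i], seq_number=start + i, atoms=atoms))
    return Structure(id=structure_id, chain_id="A", residues=residues)


@pytest.fixture
def helix_structure() -> Structure:
    """Ideal 20-residue poly-alanine α-helix (φ=−57°, ψ=−47°)."""
    bb = geom.build_backbone([geom.HELIX_PHI_PSI] * 20)
    return structure_from_backbone(bb, structure_id="ideal_helix")


@pytest.fixture
def hairpin_structure() -> Structure:
    """Two antiparallel extended strands placed at sheet H-bond geometry."""
    n = 8
    bb_a = geom.build_backbone([geom.STRAND_PHI_PSI] * n)
    ca = bb_a[1::3]
    center = ca.mean(axis=0)
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    _, _, vt = np.linalg.svd(ca - center)
    u = np.array([-0.3714, 0.5571, 0.7428])
    u /= np.linalg.norm(u)
    flip = 2 * np.outer(u, u) - np.eye(3)
    t = center + 4.8 * vt[2] - 0.5 * axis
    bb_b = (bb_a - center) @ flip.T + t
    res_a = structure_from_backbone(bb_a, start=1).residues
    res_b = structure_from_backbone(bb_b, start=20).residues
    return Structure(id="hairpin", chain_id="A", residues=res_a + res_b)


@pytest.fixture
def coil_structure() -> Structure:
    """Random-torsion chain: no periodic H-bond pattern by construction."""
    rng = np.random.default_rng(42)
    phi_psi = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
               for _ in range(20)]
    bb = geom.build_backbone(phi_psi)
    return structure_from_backbone(bb, structure_id="coil")


@pytest.fixture(scope="session")
def small_benchmark():
    """3-target x 18-model synthetic benchmark shared across tests."""
    from saapqa.synthetic import DecoyPoolSpec, build_benchmark
    spec = DecoyPoolSpec(n_targets=3, models_per_target=18, chain_length=80, seed=5)
    return build_benchmark(spec)
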