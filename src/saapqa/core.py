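"""Domain types and file IO: single-chain protein structures and sequences.

All scored structures are single protein chains (multi-chain files must be
narrowed to one chain at read time).  PDB parsing is delegated to biotite;
this module reduces the parsed atoms to the package's own residue-level
bookkeeping: ATOM records only, highest-occupancy altloc, residues ordered
by author numbering plus insertion code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Canonical sequence alphabet; 'X' marks nonstandard residues observed in
#: structures (e.g. MSE) and is excluded from aggregation-propensity lookup.
SEQUENCE_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


class EmptyStructureError(ValueError):
    """Raised when no protein residues remain after chain selection."""


class FastaParseError(ValueError):
    """Raised on malformed FASTA input."""


@dataclass
class Residue:
    """One amino-acid residue with its heavy atoms.

    ``atoms`` holds (atom_name, element, x, y, z) in Å.  ``one_letter`` is
    'X' for nonstandard residue names.
    """

    name: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[tuple[str, str, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, _, x, y, z in self.atoms:
            if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
                raise ValueError(f"non-finite coordinates in residue {self.name}{self.seq_number}")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def is_standard(self) -> bool:
        return self.name in THREE_TO_ONE

    def atom_coord(self, atom_name: str) -> np.ndarray | None:
        for name, _, x, y, z in self.atoms:
            if name == atom_name:
                return np.array([x, y, z])
        return None

    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, _, x, y, z in self.atoms])

    @property
    def key(self) -> tuple[int, str]:
        """Pairing identity: author residue number plus insertion code."""
        return (self.seq_number, self.insertion_code)


@dataclass
class Structure:
    """A single protein chain with ordered residues."""

    id: str
    chain_id: str
    residues: list[Residue]
    source_path: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
            raise ValueError(f"residues of {self.id} not strictly increasing by number")
        for r in self.residues:
            if not r.atoms:
                raise ValueError(f"residue {r.name}{r.seq_number} of {self.id} has no atoms")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> dict[tuple[int, str], np.ndarray]:
        """Cα coordinate per residue key (residues without Cα omitted)."""
        out = {}
        for r in self.residues:
            ca = r.atom_coord("CA")
            if ca is not None:
                out[r.key] = ca
        return out


@dataclass
class SequenceRecord:
    """A named amino-acid sequence over the canonical alphabet (plus X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FastaParseError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r} contains non-canonical letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# PDB IO
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, chain: str | None = None,
                   structure_id: str | None = None) -> Structure:
    """Read a single protein chain from a PDB file.

    Keeps ATOM records of amino-acid residues only (waters, HETATM ligands
    and hydrogens dropped); altloc duplicates resolved by highest occupancy
    (ties to the first).  If ``chain`` is omitted the file must contain one
    protein chain, otherwise the first chain is used with a warning.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    atoms = atoms[atoms.element != "H"]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: no protein residues")
    chains = list(dict.fromkeys(atoms.chain_id))
    if chain is None:
        if len(chains) > 1:
            logger.warning("%s: %d chains present, taking first chain %r",
                           path.name, len(chains), chains[0])
        chain = chains[0]
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: no protein residues in chain {chain!r}")
    residues = _residues_from_atom_array(atoms)
    residues.sort(key=lambda r: r.key)
    return Structure(id=structure_id or path.stem, chain_id=str(chain),
                     residues=residues, source_path=str(path))


def _residues_from_atom_array(atoms: "struc.AtomArray") -> list[Residue]:
    residues: list[Residue] = []
    for start, stop in zip(*_residue_bounds(atoms)):
        sub = atoms[start:stop]
        atom_list = [
            (str(sub.atom_name[i]), str(sub.element[i]).capitalize() or "C",
             float(sub.coord[i, 0]), float(sub.coord[i, 1]), float(sub.coord[i, 2]))
            for i in range(sub.array_length())
        ]
        residues.append(Residue(
            name=str(sub.res_name[0]),
            seq_number=int(sub.res_id[0]),
            insertion_code=str(sub.ins_code[0]).strip(),
            atoms=atom_list,
        ))
    return residues


def _residue_bounds(atoms: "struc.AtomArray") -> tuple[np.ndarray, np.ndarray]:
    starts = struc.get_residue_starts(atoms)
    stops = np.append(starts[1:], atoms.array_length())
    return starts, stops


def to_atom_array(s: Structure) -> "struc.AtomArray":
    """Convert to a biotite AtomArray (used for SASA and PDB writing)."""
    n = sum(len(r.atoms) for r in s.residues)
    arr = struc.AtomArray(n)
    i = 0
    for r in s.residues:
        for name, element, x, y, z in r.atoms:
            arr.chain_id[i] = s.chain_id or "A"
            arr.res_id[i] = r.seq_number
            arr.ins_code[i] = r.insertion_code
            arr.res_name[i] = r.name
            arr.atom_name[i] = name
            arr.element[i] = element.upper()
            arr.coord[i] = (x, y, z)
            arr.hetero[i] = False
            i += 1
    return arr


def write_structure(s: Structure, path: str | Path) -> None:
    """Write the chain as a normalized single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(to_atom_array(s))
    pdb.write(str(path))


def structure_sequence(s: Structure) -> SequenceRecord:
    """One-letter sequence of the resolved residues, in chain order.

    Nonstandard residue names map to 'X' (with a warning); the sequence
    length always equals the number of resolved residues.
    """
    if not s.residues:
        raise EmptyStructureError(f"{s.id}: empty structure")
    letters = []
    for r in s.residues:
        if not r.is_standard:
            logger.warning("%s: nonstandard residue %s%d mapped to 'X'",
                           s.id, r.name, r.seq_number)
        letters.append(r.one_letter)
    return SequenceRecord(id=s.id, sequence="".join(letters))


# ---------------------------------------------------------------------------
# FASTA / CSV IO
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; sequences are uppercased and alphabet-checked."""
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        records.append(SequenceRecord(id=header, sequence=seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(f"{path}: sequence data before header")
                chunks.append(line)
        flush()
    if not records:
        raise FastaParseError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_csv_table(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write tabular results (descriptors, labels, reports) as CSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False)


def read_csv_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
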