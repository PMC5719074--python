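"""Minimal structure model and PDB/mmCIF parsing (via gemmi).

The in-memory model keeps only what interface mapping needs: heavy atoms
with chain, author residue numbering (insertion codes preserved, no
renumbering), residue and atom names, and coordinates in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

__all__ = ["Atom", "Structure", "ResKey", "parse_structure", "chain_sequence",
           "THREE_TO_ONE"]

ResKey = tuple[str, int, str]  # (chain, author position, insertion code)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    icode: str
    res_name: str
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def res_key(self) -> ResKey:
        return (self.chain, self.res_seq, self.icode)


@dataclass
class Structure:
    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates on atom {a}")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residues(self) -> dict[ResKey, str]:
        """Mapping residue key -> residue name, in file order."""
        out: dict[ResKey, str] = {}
        for a in self.atoms:
            out.setdefault(a.res_key, a.res_name)
        return out

    def atoms_of(self, key: ResKey) -> list[Atom]:
        return [a for a in self.atoms if a.res_key == key]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


def _precheck_pdb(path: Path) -> None:
    """Fail early, naming the line, on truncated or non-numeric ATOM records
    (gemmi itself is forgiving)."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"{path}: malformed record at line {ln}: "
                                     "truncated ATOM/HETATM line")
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise ValueError(f"{path}: malformed record at line {ln}: "
                                     "non-numeric coordinate field") from None


def parse_structure(path, format: Optional[str] = None) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Policy: first model only; alternate locations resolved by keeping the
    first conformer (altloc '' or 'A'); hydrogens and waters dropped.
    ``format`` may be "pdb", "mmcif", or None for extension-based detection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        fmt = gemmi.CoorFormat.Detect
    elif format == "pdb":
        fmt = gemmi.CoorFormat.Pdb
    elif format == "mmcif":
        fmt = gemmi.CoorFormat.Mmcif
    else:
        raise ValueError(f"unknown format {format!r}; expected 'pdb' or 'mmcif'")
    if format == "pdb" or (format is None and path.suffix.lower() in (".pdb", ".ent")):
        _precheck_pdb(path)
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    atoms: list[Atom] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                icode = res.seqid.icode.strip()
                for at in res:
                    atoms.append(Atom(
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        icode=icode,
                        res_name=res.name,
                        name=at.name,
                        element=at.element.name,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                    ))
    if not atoms:
        raise ValueError(f"{path}: no atoms found")
    return Structure(atoms=atoms, title=st.name or "")


def chain_sequence(struct: Structure, chain: str) -> tuple[list[ResKey], str]:
    """Residue keys and one-letter sequence of one chain, in file order.

    Non-standard residues become 'X'.
    """
    keys: list[ResKey] = []
    letters: list[str] = []
    for key, name in struct.residues().items():
        if key[0] != chain:
            continue
        keys.append(key)
        letters.append(THREE_TO_ONE.get(name, "X"))
    if not keys:
        raise ValueError(f"chain {chain!r} not found")
    return keys, "".join(letters)
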