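"""Reading and writing protein structures and sequences.

Structures are reduced to a single-chain, element-labeled atom list with
1-based residue numbering matching the sequence (the AlphaFold convention,
where residue ``i`` of the model is residue ``i`` of the UniProt entry).
Hydrogens are retained on read; dropping them is an explicit, separate step
(:func:`heavy_atoms`) because the topological encoding operates on heavy
atoms only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

_KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "S", "P", "SE", "F", "CL", "BR", "I", "B", "D",
}

#: letters accepted in FASTA sequences: the 20 amino acids plus the
#: ambiguity/dummy codes X, U, B, Z
FASTA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | set("XUBZ")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element symbol, PDB atom name, 1-based residue number,
    3-letter residue name and coordinates in Å."""

    element: str
    atom_name: str
    residue_number: int
    residue_name: str
    coords: np.ndarray

    def __post_init__(self):
        xyz = np.asarray(self.coords, dtype=float).reshape(3)
        object.__setattr__(self, "coords", xyz)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.element.upper() not in _KNOWN_ELEMENTS:
            raise ValueError(f"unrecognized element symbol {self.element!r}")


@dataclass(frozen=True)
class Structure:
    """A single-chain protein: id, 1-letter sequence and ordered atoms.

    Positions of the sequence with no atoms present read 'X'.
    """

    protein_id: str
    sequence: str
    atoms: tuple[AtomRecord, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        L = len(self.sequence)
        for a in self.atoms:
            if not 1 <= a.residue_number <= L:
                raise ValueError(
                    f"atom {a.atom_name} residue {a.residue_number} outside 1..{L}"
                )
            letter = self.sequence[a.residue_number - 1]
            expected = AA3_TO_1.get(a.residue_name, "X")
            if letter != expected:
                raise ValueError(
                    f"residue {a.residue_number} is {a.residue_name} "
                    f"but sequence says {letter!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def heavy_atoms(structure: Structure) -> list[AtomRecord]:
    """All atoms that are not hydrogen (or deuterium), in original order."""
    return [a for a in structure.atoms if a.element.upper() not in ("H", "D")]


def residue_heavy_atoms(structure: Structure, residue_number: int) -> list[AtomRecord]:
    """Heavy atoms of one residue (1-based)."""
    if not 1 <= residue_number <= len(structure):
        raise IndexError(
            f"residue_number {residue_number} outside 1..{len(structure)}"
        )
    return [
        a for a in heavy_atoms(structure) if a.residue_number == residue_number
    ]


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the winners
    chosen = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in chosen]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read the first model's single chain from a PDB or mmCIF file.

    Multi-chain models raise (the caller must extract one chain first);
    non-polymer HETATM residues are skipped with a warning.
    """
    path = Path(path)
    if format not in ("auto", "pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"no models/chains found in {path}")
    model = st[0]
    if len(model) > 1:
        names = ", ".join(ch.name for ch in model)
        raise ValueError(
            f"{path} has multiple chains ({names}); extract one chain first"
        )
    chain = model[0]

    records: list[AtomRecord] = []
    max_res = 0
    res_names: dict[int, str] = {}
    for residue in chain:
        if residue.name not in AA3_TO_1:
            logger.warning(
                "skipping nonstandard residue %s %s in %s",
                residue.name, residue.seqid.num, path.name,
            )
            continue
        num = residue.seqid.num
        if num < 1:
            raise ValueError(
                f"{path}: residue number {num} < 1; renumber the chain first"
            )
        res_names[num] = residue.name
        max_res = max(max_res, num)
        for atom in _pick_altlocs(residue):
            records.append(
                AtomRecord(
                    element=atom.element.name,
                    atom_name=atom.name,
                    residue_number=num,
                    residue_name=residue.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
            )
    if not records:
        raise ValueError(f"no standard polymer atoms found in {path}")
    seq = "".join(
        AA3_TO_1.get(res_names.get(i, ""), "X") for i in range(1, max_res + 1)
    )
    return Structure(protein_id=path.stem, sequence=seq, atoms=tuple(records))


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a normalized single-chain PDB file (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = structure.protein_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    current: gemmi.Residue | None = None
    for a in structure.atoms:
        if current is None or current.seqid.num != a.residue_number:
            current = gemmi.Residue()
            current.name = a.residue_name
            current.seqid = gemmi.SeqId(a.residue_number, " ")
            chain.add_residue(current)
            current = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coords)
        atom.occ = 1.0
        current.add_atom(atom)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        st.write_pdb(str(path))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (id, uppercased sequence) pairs.

    Characters outside the 20 amino acids and X/U/B/Z raise a validation
    error listing the offenders.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - FASTA_ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {rec.id!r} contains invalid characters: {bad}"
            )
        out.append((rec.id, seq))
    return out
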