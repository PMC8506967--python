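"""Macromolecular structure model and PDB/mmCIF input.

The in-memory model is deliberately small: chains of residues of atoms,
with waters split out, alternate locations retained and hydrogens flagged.
All residue numbering is *author* numbering (the numbering crystallographers
publish, e.g. a bromodomain spanning residues 1176-1296 with a bound histone
peptide numbered 7-20); nothing downstream ever sees a label/entity index.

Parsing is delegated to :mod:`gemmi`; writing (fixtures and transformed
models only) emits plain PDB ATOM/HETATM records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .errors import ParseError, SelectionError

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Fallback one-letter codes for modified residues commonly seen in
#: peptide-complex structures; anything else goes through gemmi's tabulated
#: components.  Acetyl-lysine maps to its parent lysine so that sequence
#: alignment treats the modified peptide as its parent sequence.
MODIFIED_RESIDUE_PARENTS = {
    "ALY": "K",  # N(6)-acetyl-lysine
    "MLY": "K",
    "M3L": "K",
    "MSE": "M",
    "CSO": "C",
    "SEP": "S",
    "TPO": "T",
    "PTR": "Y",
    "HYP": "P",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


@dataclass
class Atom:
    """A single atom site; one object per alternate location."""

    name: str
    element: str
    pos: np.ndarray  # (3,) float, Angstrom
    altloc: str = ""  # "" means no alternate
    occupancy: float = 1.0
    is_hydrogen: bool = False

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0 + 1e-6):
            raise ValueError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )


@dataclass
class Residue:
    """A residue keyed by author numbering (seq number + insertion code)."""

    chain_id: str
    seq_num: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.seq_num}{self.icode}".strip()

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atoms(self, name: str, altloc: Optional[str] = None) -> list[Atom]:
        """All alternate locations of a named atom (or just one altloc)."""
        hits = [a for a in self.atoms if a.name == name]
        if altloc is not None:
            hits = [a for a in hits if a.altloc == altloc or a.altloc == ""]
        return hits

    def altlocs(self) -> list[str]:
        seen = sorted({a.altloc for a in self.atoms if a.altloc})
        return seen

    def ca(self) -> Optional[Atom]:
        """The Calpha used for fitting: blank altloc, else highest occupancy."""
        cas = self.get_atoms("CA")
        if not cas:
            return None
        blank = [a for a in cas if a.altloc == ""]
        if blank:
            return blank[0]
        return max(cas, key=lambda a: (a.occupancy, -ord(a.altloc or "A")))


@dataclass
class Structure:
    """First model of a crystal structure: ordered chains plus waters."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    waters: list[Residue] = field(default_factory=list)
    model_index: int = 0

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def n_polymer_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())

    def n_waters(self) -> int:
        return len(self.waters)

    def all_residues(self) -> Iterable[Residue]:
        for residues in self.chains.values():
            yield from residues
        yield from self.waters

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A rigid-body transformed copy (x -> R x + t)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = Structure(id=self.id, model_index=self.model_index)
        for cid, residues in self.chains.items():
            out.chains[cid] = [_transform_residue(r, rotation, translation) for r in residues]
        out.waters = [_transform_residue(r, rotation, translation) for r in self.waters]
        return out


def _transform_residue(res: Residue, R: np.ndarray, t: np.ndarray) -> Residue:
    atoms = [
        Atom(a.name, a.element, R @ a.pos + t, a.altloc, a.occupancy, a.is_hydrogen)
        for a in res.atoms
    ]
    return Residue(res.chain_id, res.seq_num, res.res_name, atoms, res.icode)


@dataclass
class Selection:
    """Chain id plus optional inclusive author-number range."""

    chain_id: str
    lo: Optional[int] = None
    hi: Optional[int] = None

    def __post_init__(self):
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError(f"selection range lo={self.lo} > hi={self.hi}")

    def covers(self, residue: Residue) -> bool:
        if residue.chain_id != self.chain_id:
            return False
        if self.lo is not None and residue.seq_num < self.lo:
            return False
        if self.hi is not None and residue.seq_num > self.hi:
            return False
        return True


def load_structure(path, format_hint: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into the internal model.

    The first model is used (with a warning for multi-model files); all
    alternate locations are kept with their occupancies; hydrogens are kept
    but flagged; waters are moved out of the chains into ``Structure.waters``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"structure file not found: {path}")
    fmt = (format_hint or "").lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("cif", "mmcif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    if len(st) > 1:
        warnings.warn(
            f"{path.name}: {len(st)} models present; using the first", stacklevel=2
        )
    st.setup_entities()
    model = st[0]
    out = Structure(id=st.name or path.stem)
    for chain in model:
        for res in chain:
            residue = Residue(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                res_name=res.name,
                icode=(res.seqid.icode or "").strip(),
            )
            for atom in res:
                el = atom.element.name if atom.element else ""
                alt = atom.altloc or ""
                if alt in ("\0", " "):
                    alt = ""
                residue.atoms.append(
                    Atom(
                        name=atom.name,
                        element=el,
                        pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        altloc=alt,
                        occupancy=float(atom.occ),
                        is_hydrogen=el in ("H", "D"),
                    )
                )
            if residue.res_name in WATER_NAMES:
                out.waters.append(residue)
            else:
                out.chains.setdefault(chain.name, []).append(residue)
    for cid in out.chains:
        out.chains[cid].sort(key=lambda r: (r.seq_num, r.icode))
    return out


def select_residues(structure: Structure, selection: Selection) -> list[Residue]:
    """Residues of one chain within an inclusive author-number range."""
    if selection.chain_id not in structure.chains:
        raise SelectionError(
            f"chain '{selection.chain_id}' not in structure "
            f"(available: {', '.join(structure.chain_ids()) or 'none'})"
        )
    return [r for r in structure.chains[selection.chain_id] if selection.covers(r)]


def one_letter_code(res_name: str, overrides: Optional[dict] = None) -> str:
    """Parent one-letter code for a 3-letter residue name ('X' if unknown)."""
    name = res_name.upper()
    if overrides and name in overrides:
        return overrides[name]
    if name in MODIFIED_RESIDUE_PARENTS:
        return MODIFIED_RESIDUE_PARENTS[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        code = info.one_letter_code.upper()
        if code.isalpha() and code != " ":
            return code
    warnings.warn(f"unknown residue name '{res_name}' mapped to X", stacklevel=2)
    return "X"


def polymer_sequence(
    residues: Sequence[Residue], overrides: Optional[dict] = None
) -> tuple[str, list[int]]:
    """One-letter sequence over Calpha-bearing residues, with author numbers.

    Residues without a Calpha (ions, caps) are excluded with a warning.
    Modified residues map to their parent code (acetyl-lysine -> K).
    """
    if not residues:
        return "", []
    chains = {r.chain_id for r in residues}
    if len(chains) > 1:
        raise SelectionError(f"residues span multiple chains: {sorted(chains)}")
    seq = []
    numbers = []
    for res in residues:
        if res.ca() is None:
            warnings.warn(
                f"residue {res.label} has no CA atom; excluded from sequence",
                stacklevel=2,
            )
            continue
        seq.append(one_letter_code(res.res_name, overrides))
        numbers.append(res.seq_num)
    return "".join(seq), numbers


def write_pdb(structure: Structure, path) -> None:
    """Write the model back out as minimal PDB (fixtures and outputs only)."""
    lines = []
    serial = 1
    for cid in structure.chains:
        for res in structure.chains[cid]:
            for atom in res.atoms:
                lines.append(_atom_line(serial, atom, res, hetatm=False))
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    for res in structure.waters:
        for atom in res.atoms:
            lines.append(_atom_line(serial, atom, res, hetatm=True))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _atom_line(serial: int, atom: Atom, res: Residue, hetatm: bool) -> str:
    record = "HETATM" if (hetatm or res.res_name in WATER_NAMES) else "ATOM  "
    name = atom.name
    # PDB column rules: 1-char elements with short names start in column 14
    if len(atom.element) == 1 and len(name) < 4:
        name = f" {name:<3}"
    else:
        name = f"{name:<4}"
    x, y, z = atom.pos
    return (
        f"{record}{serial:>5} {name}{atom.altloc or ' '}{res.res_name:>3} "
        f"{res.chain_id:1}{res.seq_num:>4}{res.icode or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2}"
    )
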