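"""Synthetic test-data generators with exact planted ground truth.

Three generators cover the three analysis streams:

* :func:`make_complex` — a toy domain-peptide complex with planted direct
  contacts, single-water bridges, and decoy waters. Residues are sparse
  atom clusters with correct atom naming (N, CA, C, O, CB); the geometry is
  not stereochemically realistic protein structure, only exact with respect
  to the distance logic it exercises.
* :func:`make_family` — copies of a base domain under recorded random rigid
  transforms, per-atom Gaussian noise, an optionally displaced segment and
  planted sequence substitutions, emulating a homolog family with a flexible
  loop.
* :func:`make_msa` — an ortholog-style alignment with per-column classes
  (invariant / conservatively substituted / randomly substituted) at stated
  rates, plus optional gap injection.

Every generator is a pure function of its spec (which carries the seed):
repeated calls produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .conservation import AMINO_ACIDS, MSA, are_similar
from .errors import GenerationError
from .geometry import RigidTransform
from .structure_io import Atom, Residue, Structure

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# local atom offsets (Angstrom) for a toy residue centered on its CA
_RESIDUE_TEMPLATE = {
    "N": np.array([-1.2, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.0, 0.0]),
    "O": np.array([1.2, 1.0, 0.0]),
    "CB": np.array([0.0, 0.0, 1.5]),
}

_SPACING = 10.0  # along-chain residue spacing, far above any contact cutoff
_CHAIN_GAP = 25.0  # domain-to-peptide separation


def _toy_residue(chain_id: str, seq_num: int, res_name: str, origin: np.ndarray) -> Residue:
    atoms = []
    for name, offset in _RESIDUE_TEMPLATE.items():
        if name == "CB" and res_name == "GLY":
            continue
        element = name[0]
        atoms.append(Atom(name=name, element=element, pos=origin + offset))
    return Residue(chain_id=chain_id, seq_num=seq_num, res_name=res_name, atoms=atoms)


def _random_sequence(rng: np.random.Generator, n: int) -> list[str]:
    return [_AA3[AMINO_ACIDS[i]] for i in rng.integers(0, 20, size=n)]


@dataclass
class ComplexSpec:
    n_domain_residues: int = 12
    n_peptide_residues: int = 6
    # (domain residue number, peptide residue number, min heavy-atom distance)
    direct_contacts: list[tuple[int, int, float]] = field(default_factory=list)
    # (domain residue number, peptide residue number, domain leg, peptide leg)
    water_bridges: list[tuple[int, int, float, float]] = field(default_factory=list)
    n_decoy_waters: int = 10
    exclusion_shell: float = 4.5
    direct_cutoff: float = 3.0  # used only for feasibility checks
    hbond_cutoff: float = 3.5
    seed: int = 0

    def __post_init__(self):
        if self.exclusion_shell <= self.hbond_cutoff:
            raise ValueError("exclusion shell must exceed the hbond cutoff")
        if any(c[2] <= 0 for c in self.direct_contacts):
            raise ValueError("planted distances must be positive")
        if any(b[2] <= 0 or b[3] <= 0 for b in self.water_bridges):
            raise ValueError("planted leg distances must be positive")


def make_complex(spec: ComplexSpec) -> tuple[Structure, dict]:
    """Build the complex and return it with its ground-truth contact table.

    Domain residues live in chain A (numbered 1..n), peptide residues in
    chain B. A planted direct contact moves the domain residue's CB to the
    stated distance from the peptide residue's CA; a planted bridge moves
    the domain residue's O and adds a water with the stated leg distances.
    Each planted interaction must target a distinct peptide residue so that
    planted geometries cannot interfere.
    """
    rng = np.random.default_rng(spec.seed)
    pep_targets = [c[1] for c in spec.direct_contacts] + [b[1] for b in spec.water_bridges]
    if len(set(pep_targets)) != len(pep_targets):
        raise GenerationError("planted interactions must use distinct peptide residues")
    for _, j, *_ in spec.direct_contacts + spec.water_bridges:
        if not (1 <= j <= spec.n_peptide_residues):
            raise GenerationError(f"peptide residue {j} outside 1..{spec.n_peptide_residues}")
    for i, *_ in spec.direct_contacts + spec.water_bridges:
        if not (1 <= i <= spec.n_domain_residues):
            raise GenerationError(f"domain residue {i} outside 1..{spec.n_domain_residues}")
    for i, j, d in spec.direct_contacts:
        if d > spec.direct_cutoff + 2.0:
            raise GenerationError("planted direct distance far above cutoff is untestable")
    for i, j, d1, d2 in spec.water_bridges:
        if d1 + d2 <= spec.direct_cutoff:
            raise GenerationError("bridge legs too short: would create a direct contact")

    st = Structure(id=f"synthetic-complex-{spec.seed}")
    dom_seq = _random_sequence(rng, spec.n_domain_residues)
    pep_seq = _random_sequence(rng, spec.n_peptide_residues)
    # gentle out-of-plane arc keeps the Calpha traces non-collinear (so the
    # chains are usable in rigid fits) without breaking the 10 A spacing
    st.chains["A"] = [
        _toy_residue(
            "A", i + 1, dom_seq[i],
            np.array([i * _SPACING, 0.0, 2.0 * np.sin(0.7 * i)]),
        )
        for i in range(spec.n_domain_residues)
    ]
    st.chains["B"] = [
        _toy_residue(
            "B", j + 1, pep_seq[j],
            np.array([j * _SPACING, _CHAIN_GAP, 2.0 * np.cos(0.9 * j)]),
        )
        for j in range(spec.n_peptide_residues)
    ]
    dom = {r.seq_num: r for r in st.chains["A"]}
    pep = {r.seq_num: r for r in st.chains["B"]}
    protected: list[np.ndarray] = []

    # several plants from one domain residue use successive sidechain atoms
    _carbons = ["CB", "CG", "CD1", "CE1"]
    _oxygens = ["O", "OD1", "OE1", "OG1"]
    n_planted_c: dict[int, int] = {}
    n_planted_o: dict[int, int] = {}

    for i, j, d in spec.direct_contacts:
        target = pep[j]
        k = n_planted_c.get(i, 0)
        if k >= len(_carbons):
            raise GenerationError(f"too many direct contacts planted on domain residue {i}")
        n_planted_c[i] = k + 1
        name = _carbons[k]
        hits = dom[i].get_atoms(name) if name != "CB" or dom[i].res_name != "GLY" else []
        if hits:
            atom = hits[0]
        else:
            atom = Atom(name, "C", np.zeros(3))
            dom[i].atoms.append(atom)
        ca_pep = target.get_atoms("CA")[0].pos
        atom.pos = ca_pep + np.array([0.0, -d, 0.0])
        protected.extend([atom.pos, ca_pep])

    water_num = 1000
    for i, j, d1, d2 in spec.water_bridges:
        target = pep[j]
        k = n_planted_o.get(i, 0)
        if k >= len(_oxygens):
            raise GenerationError(f"too many water bridges planted on domain residue {i}")
        n_planted_o[i] = k + 1
        name = _oxygens[k]
        hits = dom[i].get_atoms(name)
        if hits:
            o_bd = hits[0]
        else:
            o_bd = Atom(name, "O", np.zeros(3))
            dom[i].atoms.append(o_bd)
        n_pep = target.get_atoms("N")[0].pos
        w_pos = n_pep + np.array([0.0, -d2, 0.0])
        o_bd.pos = w_pos + np.array([0.0, -d1, 0.0])
        water = Residue(
            chain_id="W", seq_num=water_num, res_name="HOH",
            atoms=[Atom("O", "O", w_pos)],
        )
        st.waters.append(water)
        water_num += 1
        protected.extend([w_pos, o_bd.pos, n_pep])

    chain_atoms = np.array(
        [a.pos for cid in st.chains for r in st.chains[cid] for a in r.atoms]
        + [p for p in protected]
    )
    placed = 0
    attempts = 0
    while placed < spec.n_decoy_waters:
        attempts += 1
        if attempts > 1000 * max(spec.n_decoy_waters, 1):
            raise GenerationError("could not place decoy waters outside the exclusion shell")
        pos = np.array([
            rng.uniform(-10, spec.n_domain_residues * _SPACING + 10),
            rng.uniform(-10, _CHAIN_GAP + 10),
            rng.uniform(8.0, 20.0),
        ])
        if np.min(np.linalg.norm(chain_atoms - pos, axis=1)) < spec.exclusion_shell:
            continue
        st.waters.append(
            Residue("W", water_num, "HOH", atoms=[Atom("O", "O", pos)])
        )
        water_num += 1
        placed += 1

    ground_truth = {
        "direct": sorted((i, j) for i, j, _ in spec.direct_contacts),
        "bridges": sorted((i, j) for i, j, *_ in spec.water_bridges),
        "contact_residues": sorted(
            {i for i, *_ in spec.direct_contacts} | {i for i, *_ in spec.water_bridges}
        ),
    }
    return st, ground_truth


@dataclass
class FamilySpec:
    n_residues: int = 100
    n_members: int = 5
    noise_sigma: float = 0.3
    displaced_range: Optional[tuple[int, int]] = None  # inclusive residue numbers
    displacement: Optional[Sequence[float]] = None  # vector, Angstrom
    mutations: dict[int, list[tuple[int, str]]] = field(default_factory=dict)
    # mutations: member index -> [(residue number, new 3-letter name)]
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.displaced_range is not None:
            lo, hi = self.displaced_range
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError("displaced range outside the structure")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_domain(n_residues: int, seed: int = 0, chain_id: str = "A") -> Structure:
    """A base toy domain: a compact coiled Calpha trace with full toy
    residues and a random sequence.

    The trace is a helix whose axis is bent around a circle, so the object
    is globular (extent a few tens of Angstrom) like a real ~100-residue
    domain, rather than an extended rod; that keeps rigid-fit translation
    errors from being amplified by a long lever arm.
    """
    rng = np.random.default_rng(seed)
    st = Structure(id=f"synthetic-domain-{seed}")
    seq = _random_sequence(rng, n_residues)
    major = 8.0 + 0.07 * n_residues
    residues = []
    for i in range(n_residues):
        phi = 1.5 * np.pi * i / max(n_residues, 1)
        omega = 0.7 * i
        radial = major + 5.0 * np.cos(omega)
        origin = np.array(
            [radial * np.cos(phi), radial * np.sin(phi), 5.0 * np.sin(omega) + 0.1 * i]
        )
        residues.append(_toy_residue(chain_id, i + 1, seq[i], origin))
    st.chains[chain_id] = residues
    return st


def make_family(spec: FamilySpec) -> tuple[Structure, list[Structure], list[RigidTransform]]:
    """(base domain, member structures, ground-truth transforms base->member).

    Each member is the base with Gaussian coordinate noise, the displaced
    segment offset applied after the noise, then a recorded rigid transform;
    planted sequence substitutions rename residues (coordinates untouched).
    """
    rng = np.random.default_rng(spec.seed)
    base = make_domain(spec.n_residues, seed=spec.seed)
    members = []
    transforms = []
    disp = np.asarray(spec.displacement, float) if spec.displacement is not None else None
    for k in range(spec.n_members):
        R = _random_rotation(rng)
        t = rng.uniform(-20, 20, size=3)
        member = Structure(id=f"{base.id}-member{k}")
        residues = []
        for res in base.chains["A"]:
            atoms = []
            for a in res.atoms:
                pos = a.pos + rng.normal(0, spec.noise_sigma, size=3)
                if (
                    disp is not None
                    and spec.displaced_range[0] <= res.seq_num <= spec.displaced_range[1]
                ):
                    pos = pos + disp
                atoms.append(Atom(a.name, a.element, R @ pos + t))
            residues.append(Residue("A", res.seq_num, res.res_name, atoms))
        for num, new_name in spec.mutations.get(k, []):
            residues[num - 1] = Residue(
                "A", num, new_name, residues[num - 1].atoms
            )
        member.chains["A"] = residues
        members.append(member)
        transforms.append(RigidTransform(R, t))
    return base, members, transforms


@dataclass
class MSASpec:
    master: str = ""  # one-letter master sequence; random if empty
    n_cols: int = 110
    n_rows: int = 100
    conserved_columns: tuple[int, ...] = ()  # 0-based; invariant or conservative
    conservative_rate: float = 0.05  # substitution rate within BLOSUM62>0 neighbors
    random_rate: float = 0.20  # substitution rate for background columns
    conservative_fraction: float = 0.5  # share of conserved columns that substitute
    gap_rate: float = 0.0
    column_gap_rates: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for r in (self.conservative_rate, self.random_rate, self.gap_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.master:
            self.n_cols = len(self.master)
        if any(c < 0 or c >= self.n_cols for c in self.conserved_columns):
            raise ValueError("conserved column index outside the alignment")


_SIMILAR_SETS = {
    a: [b for b in AMINO_ACIDS if b != a and are_similar(a, b)] for a in AMINO_ACIDS
}


def make_msa(spec: MSASpec) -> tuple[MSA, set[int]]:
    """(alignment, planted conserved column set).

    Row 0 is the ungapped master (the reference row). Conserved columns are
    either literally invariant or substituted only within the master
    residue's BLOSUM62-positive neighbor set at ``conservative_rate``; all
    other columns are substituted uniformly at random at ``random_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.master:
        master = spec.master.upper()
        if any(ch not in AMINO_ACIDS for ch in master):
            raise GenerationError("master sequence contains non-standard letters")
    else:
        master = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=spec.n_cols))
    conserved = set(spec.conserved_columns)
    # first half of the conserved columns stay invariant, the rest substitute
    conserved_sorted = sorted(conserved)
    n_invariant = round(len(conserved_sorted) * (1 - spec.conservative_fraction))
    invariant = set(conserved_sorted[:n_invariant])
    rows = [master]
    ids = ["reference"]
    for r in range(1, spec.n_rows):
        chars = []
        for j, ch in enumerate(master):
            if j in invariant:
                out = ch
            elif j in conserved:
                if rng.random() < spec.conservative_rate and _SIMILAR_SETS[ch]:
                    out = _SIMILAR_SETS[ch][rng.integers(0, len(_SIMILAR_SETS[ch]))]
                else:
                    out = ch
            else:
                if rng.random() < spec.random_rate:
                    out = AMINO_ACIDS[rng.integers(0, 20)]
                else:
                    out = ch
            gap_rate = spec.column_gap_rates.get(j, spec.gap_rate)
            if gap_rate and rng.random() < gap_rate:
                out = "-"
            chars.append(out)
        rows.append("".join(chars))
        ids.append(f"seq{r:04d}")
    return MSA(ids, rows, reference_id="reference"), conserved
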