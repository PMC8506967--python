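"""Domain-peptide contact detection.

A domain residue is a *contact residue* if any of its heavy atoms lies
within ``direct_cutoff`` (default 3.0 A, any atom type) of a peptide heavy
atom, or if it is linked to the peptide through a single bridging water:
the water oxygen within ``hbond_cutoff`` (default 3.5 A, the conventional
heavy-atom hydrogen-bond limit) of a polar (N/O) atom on each side.
No angular criterion is applied and hydrogens are ignored throughout;
alternate conformations count if *any* conformer satisfies the distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SelectionError
from .geometry import min_heavy_atom_distance
from .structure_io import BACKBONE_ATOMS, Residue, Selection, Structure, select_residues

DIRECT = "direct"
WATER_BRIDGE = "water_bridge"


@dataclass
class ContactParams:
    direct_cutoff: float = 3.0
    hbond_cutoff: float = 3.5
    include_sulfur: bool = False  # count S among polar bridge acceptors

    def __post_init__(self):
        if not (0 < self.direct_cutoff <= self.hbond_cutoff <= 5.0):
            raise ValueError(
                "require 0 < direct_cutoff <= hbond_cutoff <= 5.0 "
                f"(got {self.direct_cutoff}, {self.hbond_cutoff})"
            )

    @property
    def polar_elements(self) -> set[str]:
        return {"N", "O", "S"} if self.include_sulfur else {"N", "O"}


@dataclass
class ContactRecord:
    bd_residue: Residue
    peptide_residue: Residue
    kind: str  # DIRECT or WATER_BRIDGE
    distance: float  # direct: min heavy-atom distance; bridge: max of both legs
    bd_atom: str
    pep_atom: str
    water: Optional[Residue] = None
    leg_distances: tuple[float, float] = ()  # (bd-water, water-peptide) for bridges

    @property
    def bd_side(self) -> str:
        return "backbone" if self.bd_atom in BACKBONE_ATOMS else "sidechain"


def _polar_heavy(res: Residue, polar: set[str]) -> list:
    return [a for a in res.heavy_atoms() if a.element in polar]


def _check_selections(bd_res: Sequence[Residue], pep_res: Sequence[Residue]) -> None:
    if not bd_res or not pep_res:
        raise SelectionError("empty domain or peptide selection")
    bd_keys = {(r.chain_id, r.key) for r in bd_res}
    pep_keys = {(r.chain_id, r.key) for r in pep_res}
    if bd_keys & pep_keys:
        raise SelectionError("domain and peptide selections overlap")


def find_direct_contacts(
    structure: Structure,
    bd_sel: Selection,
    pep_sel: Selection,
    params: Optional[ContactParams] = None,
) -> list[ContactRecord]:
    """One record per (domain residue, peptide residue) pair within cutoff."""
    params = params or ContactParams()
    bd_res = select_residues(structure, bd_sel)
    pep_res = select_residues(structure, pep_sel)
    _check_selections(bd_res, pep_res)
    records = []
    for br in bd_res:
        if not br.heavy_atoms():
            continue
        for pr in pep_res:
            if not pr.heavy_atoms():
                continue
            dist, (a_bd, a_pep) = min_heavy_atom_distance(br, pr)
            if dist <= params.direct_cutoff:
                records.append(
                    ContactRecord(br, pr, DIRECT, dist, a_bd, a_pep)
                )
    return records


def find_water_bridges(
    structure: Structure,
    bd_sel: Selection,
    pep_sel: Selection,
    params: Optional[ContactParams] = None,
) -> list[ContactRecord]:
    """Single-water hydrogen-bond bridges between domain and peptide.

    For every water whose oxygen is within ``hbond_cutoff`` of at least one
    polar atom on each side, a record is emitted per (domain residue,
    peptide residue) pair it connects, carrying both leg distances.
    """
    params = params or ContactParams()
    bd_res = select_residues(structure, bd_sel)
    pep_res = select_residues(structure, pep_sel)
    _check_selections(bd_res, pep_res)
    polar = params.polar_elements
    records = []
    for water in structure.waters:
        oxygens = [a for a in water.heavy_atoms() if a.element == "O"]
        if not oxygens:
            continue
        w_pos = np.array([a.pos for a in oxygens])
        bd_legs = _legs_within(bd_res, w_pos, polar, params.hbond_cutoff)
        if not bd_legs:
            continue
        pep_legs = _legs_within(pep_res, w_pos, polar, params.hbond_cutoff)
        for br, (d_bd, a_bd) in bd_legs.items():
            for pr, (d_pep, a_pep) in pep_legs.items():
                records.append(
                    ContactRecord(
                        bd_residue=_res_by_key(bd_res, br),
                        peptide_residue=_res_by_key(pep_res, pr),
                        kind=WATER_BRIDGE,
                        distance=max(d_bd, d_pep),
                        bd_atom=a_bd,
                        pep_atom=a_pep,
                        water=water,
                        leg_distances=(d_bd, d_pep),
                    )
                )
    return records


def _res_by_key(residues: Sequence[Residue], key) -> Residue:
    for r in residues:
        if (r.chain_id, r.key) == key:
            return r
    raise KeyError(key)


def _legs_within(residues, water_pos, polar, cutoff):
    """Closest polar-atom leg per residue: {(chain, key): (distance, atom name)}."""
    legs = {}
    for res in residues:
        atoms = _polar_heavy(res, polar)
        if not atoms:
            continue
        pos = np.array([a.pos for a in atoms])
        d = cdist(pos, water_pos)
        dmin = d.min()
        if dmin <= cutoff:
            candidates = sorted(
                (d[i, j], atoms[i].name)
                for i, j in zip(*np.nonzero(np.isclose(d, dmin, rtol=0, atol=1e-12)))
            )
            legs[(res.chain_id, res.key)] = (float(dmin), candidates[0][1])
    return legs


@dataclass
class ContactResidue:
    residue: Residue
    kinds: set = field(default_factory=set)
    peptide_partners: list = field(default_factory=list)  # Residue refs


def contact_residue_set(
    direct: Sequence[ContactRecord], bridges: Sequence[ContactRecord]
) -> list[ContactResidue]:
    """Union of domain residues over both contact kinds, by author number."""
    merged: dict[tuple, ContactResidue] = {}
    for rec in list(direct) + list(bridges):
        key = (rec.bd_residue.chain_id, rec.bd_residue.key)
        entry = merged.setdefault(key, ContactResidue(rec.bd_residue))
        entry.kinds.add(rec.kind)
        pkey = (rec.peptide_residue.chain_id, rec.peptide_residue.key)
        if pkey not in [(p.chain_id, p.key) for p in entry.peptide_partners]:
            entry.peptide_partners.append(rec.peptide_residue)
    out = sorted(merged.values(), key=lambda e: e.residue.key)
    for entry in out:
        entry.peptide_partners.sort(key=lambda r: r.key)
    return out


def peptide_footprint(
    direct: Sequence[ContactRecord], bridges: Sequence[ContactRecord]
) -> dict[tuple[int, str], list[Residue]]:
    """Map peptide residue key -> sorted domain residues contacting it."""
    fp: dict[tuple[int, str], dict] = {}
    for rec in list(direct) + list(bridges):
        slot = fp.setdefault(rec.peptide_residue.key, {})
        slot[rec.bd_residue.key] = rec.bd_residue
    return {
        pkey: [slot[k] for k in sorted(slot)] for pkey, slot in sorted(fp.items())
    }
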