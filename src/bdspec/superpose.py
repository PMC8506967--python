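"""Sequence-guided, iteratively pruned superposition of homologous domains.

The procedure mirrors the "matchmaker" style of structure comparison tools:

1. pair residues by a global sequence alignment (BLOSUM62, affine gaps),
   keeping only aligned columns where both residues have a Calpha;
2. fit a Kabsch rigid transform on the paired Calpha atoms;
3. prune every pair whose post-fit Calpha deviation exceeds a cutoff
   (default 2.0 A) and refit, iterating to a fixed point;
4. report the rmsd over the retained pairs plus a per-residue deviation
   profile (all pairs, retained or not) in reference numbering.

The retained set can only shrink, so termination is guaranteed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import SuperpositionError
from .geometry import RigidTransform, kabsch
from .structure_io import Residue, Selection, Structure, one_letter_code, select_residues


@dataclass
class SuperposeParams:
    prune_cutoff: float = 2.0
    max_iterations: int = 50
    min_retained_pairs: int = 3
    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    min_alignment_score: float = 0.0  # warn below this
    prune_mode: str = "batch"  # "batch": drop all pairs above cutoff per
    # iteration; "worst": drop only the single worst pair per iteration

    def __post_init__(self):
        if self.prune_cutoff <= 0:
            raise ValueError("prune_cutoff must be positive")


@dataclass
class ResiduePairing:
    pairs: list[tuple[Residue, Residue]]
    score: float = 0.0

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PairDeviation:
    ref_resnum: int
    ref_resname: str
    mobile_resnum: int
    mobile_resname: str
    deviation: float
    retained: bool
    identity_match: bool


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd_retained: float
    n_retained: int
    n_total: int
    deviation_profile: list[PairDeviation] = field(default_factory=list)

    def profile_by_refnum(self) -> dict[int, PairDeviation]:
        return {p.ref_resnum: p for p in self.deviation_profile}


def _aligner(params: SuperposeParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def pair_by_sequence(
    ref_residues: Sequence[Residue],
    mobile_residues: Sequence[Residue],
    params: Optional[SuperposeParams] = None,
) -> ResiduePairing:
    """Residue correspondence from a global alignment of the two sequences.

    Only Calpha-bearing residues enter the alignment; pairs are emitted for
    aligned non-gap columns.
    """
    params = params or SuperposeParams()
    ref = [r for r in ref_residues if r.ca() is not None]
    mob = [r for r in mobile_residues if r.ca() is not None]
    if len(ref) < 10 or len(mob) < 10:
        raise SuperpositionError(
            f"sequences too short to pair ({len(ref)} and {len(mob)} residues)"
        )
    seq_ref = "".join(one_letter_code(r.res_name) for r in ref)
    seq_mob = "".join(one_letter_code(r.res_name) for r in mob)
    aligner = _aligner(params)
    alignment = next(iter(aligner.align(seq_ref, seq_mob)))
    if alignment.score < params.min_alignment_score:
        warnings.warn(
            f"alignment score {alignment.score:.1f} below sanity floor; "
            "sequences may be unrelated",
            stacklevel=2,
        )
    pairs = []
    for (r0, r1), (m0, m1) in zip(*alignment.aligned):
        for i, j in zip(range(r0, r1), range(m0, m1)):
            pairs.append((ref[i], mob[j]))
    pairs.sort(key=lambda p: p[0].key)
    return ResiduePairing(pairs=pairs, score=float(alignment.score))


def iterative_prune_superpose(
    pairing: ResiduePairing,
    params: Optional[SuperposeParams] = None,
) -> SuperpositionResult:
    """Fit, prune pairs deviating beyond the cutoff, refit to a fixed point."""
    params = params or SuperposeParams()
    n_total = len(pairing)
    if n_total < params.min_retained_pairs:
        raise SuperpositionError(
            f"only {n_total} pairs, need >= {params.min_retained_pairs}"
        )
    ref_xyz = np.array([r.ca().pos for r, _ in pairing.pairs])
    mob_xyz = np.array([m.ca().pos for _, m in pairing.pairs])
    retained = np.ones(n_total, dtype=bool)
    transform, rmsd = kabsch(mob_xyz, ref_xyz)
    for _ in range(params.max_iterations):
        dev = np.linalg.norm(transform.apply(mob_xyz) - ref_xyz, axis=1)
        drop = retained & (dev > params.prune_cutoff)
        if not drop.any():
            break
        if params.prune_mode == "worst":
            worst = np.argmax(np.where(drop, dev, -np.inf))
            drop = np.zeros_like(drop)
            drop[worst] = True
        retained &= ~drop
        if retained.sum() < params.min_retained_pairs:
            raise SuperpositionError(
                "pruned superposition diverged: retained pair set fell below "
                f"{params.min_retained_pairs}"
            )
        transform, rmsd = kabsch(mob_xyz[retained], ref_xyz[retained])
    deviations = np.linalg.norm(transform.apply(mob_xyz) - ref_xyz, axis=1)
    profile = [
        PairDeviation(
            ref_resnum=r.seq_num,
            ref_resname=r.res_name,
            mobile_resnum=m.seq_num,
            mobile_resname=m.res_name,
            deviation=float(d),
            retained=bool(keep),
            identity_match=one_letter_code(r.res_name) == one_letter_code(m.res_name),
        )
        for (r, m), d, keep in zip(pairing.pairs, deviations, retained)
    ]
    return SuperpositionResult(
        transform=transform,
        rmsd_retained=float(rmsd),
        n_retained=int(retained.sum()),
        n_total=n_total,
        deviation_profile=profile,
    )


def superpose_structures(
    ref: Structure,
    mobile: Structure,
    ref_sel: Selection,
    mobile_sel: Selection,
    params: Optional[SuperposeParams] = None,
) -> SuperpositionResult:
    """Convenience wrapper: select, pair by sequence, prune-superpose."""
    params = params or SuperposeParams()
    pairing = pair_by_sequence(
        select_residues(ref, ref_sel), select_residues(mobile, mobile_sel), params
    )
    return iterative_prune_superpose(pairing, params)


@dataclass
class ContactDeviation:
    ref_resnum: int
    deviation: Optional[float]  # None when the residue is unpaired
    identity_match: Optional[bool]
    mobile_resname: Optional[str] = None
    ref_resname: Optional[str] = None


def contact_deviation_summary(
    result: SuperpositionResult, contact_resnums: Sequence[int]
) -> dict:
    """Post-fit deviations at the contact residues (reference numbering).

    Unpaired contact residues are reported with ``deviation=None`` rather
    than zero; identity flags mark positions where the compared domain
    substitutes a different amino acid (e.g. a Glu->Arg swap at the
    arginine-binding acidic position).
    """
    by_ref = result.profile_by_refnum()
    rows = {}
    devs = []
    for num in sorted(contact_resnums):
        pd = by_ref.get(num)
        if pd is None:
            rows[num] = ContactDeviation(num, None, None)
        else:
            rows[num] = ContactDeviation(
                num, pd.deviation, pd.identity_match, pd.mobile_resname, pd.ref_resname
            )
            devs.append(pd.deviation)
    return {
        "per_residue": rows,
        "max_deviation": max(devs) if devs else None,
        "mean_deviation": float(np.mean(devs)) if devs else None,
        "n_missing": sum(1 for r in rows.values() if r.deviation is None),
    }


def superpose_peptides(
    ref: Structure,
    mobile: Structure,
    pep_sel_ref: Selection,
    pep_sel_mobile: Selection,
    residue_range: tuple[int, int],
) -> float:
    """Plain (unpruned) Calpha rmsd of two bound peptides over a residue range.

    Correspondence is by author residue number, the natural pairing for
    histone-tail peptides numbered by histone position.
    """
    lo, hi = residue_range
    wanted = list(range(lo, hi + 1))
    coords = []
    for st, sel in ((ref, pep_sel_ref), (mobile, pep_sel_mobile)):
        residues = {r.seq_num: r for r in select_residues(st, sel)}
        missing = [n for n in wanted if n not in residues or residues[n].ca() is None]
        if missing:
            raise SuperpositionError(
                f"peptide range {lo}-{hi} incomplete in {st.id}: missing Calpha "
                f"at {missing}"
            )
        coords.append(np.array([residues[n].ca().pos for n in wanted]))
    _, rmsd = kabsch(coords[1], coords[0])
    return rmsd
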