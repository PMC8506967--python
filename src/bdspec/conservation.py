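"""Ortholog-alignment conservation analysis.

Given an alignment of ~100 ortholog domain sequences, each column is scored
with the Jensen-Shannon divergence (log base 2, hence bounded in [0, 1])
between the column's amino-acid distribution (pseudocounted, gap-weighted)
and the BLOSUM62 background distribution, smoothed over a moving window of
three columns. A column is called *conserved* when the windowed score
reaches the similarity threshold AND fewer than 10% of its residues are
nonsynonymous, i.e. score <= 0 against the column consensus under BLOSUM62.

Alignments larger than the target size are reduced with a greedy maxmin
diversity subsample on normalized mismatch distance ("the N most diverse
sequences"). Conservation calls from nested sequence sets (one paralog's
orthologs, the domain family, all domains) are combined into per-residue
tiers: universal > family > paralog > none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: BLOSUM62 amino-acid background frequencies (Capra & Singh convention),
#: indexed as AMINO_ACIDS; renormalized at load time.
_BLOSUM62_BACKGROUND = np.array(
    [0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
     0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072]
)
_BLOSUM62_BACKGROUND = _BLOSUM62_BACKGROUND / _BLOSUM62_BACKGROUND.sum()

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_CHARS = {"-", "."}

TIER_UNIVERSAL = "universal"
TIER_FAMILY = "family"
TIER_PARALOG = "paralog"
TIER_NONE = "none"
_TIER_ORDER = (TIER_UNIVERSAL, TIER_FAMILY, TIER_PARALOG)


def blosum_score(a: str, b: str) -> float:
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return float(_BLOSUM62["X", "X"])


def are_similar(a: str, b: str) -> bool:
    """BLOSUM62-positive pairs (including identity) count as similar."""
    return blosum_score(a, b) > 0


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]
    reference_id: Optional[str] = None

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence id(s): {dup}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            ragged = [i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])]
            raise AlignmentFormatError(f"ragged alignment rows (e.g. {ragged[0]})")
        self.rows = [r.upper() for r in self.rows]
        if self.reference_id is not None and self.reference_id not in self.ids:
            raise AlignmentFormatError(f"reference id '{self.reference_id}' not in MSA")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def reference_row(self) -> str:
        if self.reference_id is None:
            raise AlignmentFormatError("MSA has no reference row")
        return self.rows[self.ids.index(self.reference_id)]

    def reference_column_numbers(self, start: int) -> dict[int, int]:
        """Map alignment column -> author residue number along the reference
        row's ungapped positions, numbering from ``start``."""
        mapping = {}
        num = start
        for j, ch in enumerate(self.reference_row()):
            if ch not in GAP_CHARS:
                mapping[j] = num
                num += 1
        return mapping

    def subset(self, indices: Sequence[int]) -> "MSA":
        ref = self.reference_id
        ids = [self.ids[i] for i in indices]
        if ref is not None and ref not in ids:
            ref = None
        return MSA([self.ids[i] for i in indices], [self.rows[i] for i in indices], ref)


def read_msa(path, reference_id: Optional[str] = None) -> MSA:
    """Aligned FASTA -> MSA (equal-length rows enforced, duplicate ids rejected)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no sequences in {path}")
    return MSA([r.id for r in records], [str(r.seq) for r in records], reference_id)


def write_msa(msa: MSA, path) -> None:
    records = [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(msa.ids, msa.rows)]
    SeqIO.write(records, str(Path(path)), "fasta")


def pairwise_distance_matrix(msa: MSA) -> np.ndarray:
    """Normalized mismatch distance: mismatches / columns where both rows
    are ungapped. A pair with no comparable columns gets distance 1."""
    if msa.n_rows < 2:
        raise AlignmentFormatError("need >= 2 rows for a distance matrix")
    arr = np.array([list(r) for r in msa.rows])
    gap = np.isin(arr, list(GAP_CHARS))
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        comparable = ~gap[i] & ~gap[i + 1:]
        mism = comparable & (arr[i] != arr[i + 1:])
        counts = comparable.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(counts > 0, mism.sum(axis=1) / np.maximum(counts, 1), 1.0)
        if np.any(counts == 0):
            warnings.warn("sequence pair with no comparable columns: distance set to 1")
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return d


def maxmin_subsample(msa: MSA, n: int) -> MSA:
    """Greedy maxmin diversity selection of ``n`` rows.

    Seeds with the globally most distant pair, then repeatedly adds the row
    with the largest minimum distance to the selected set. Ties break toward
    the earliest input index, so the result is deterministic. Selected rows
    are returned in input order.
    """
    if n > msa.n_rows:
        raise ValueError(f"cannot subsample {n} of {msa.n_rows} rows")
    if n < 2:
        raise ValueError("subsample size must be >= 2")
    if n == msa.n_rows:
        return msa.subset(range(msa.n_rows))
    d = pairwise_distance_matrix(msa)
    iu = np.triu_indices(msa.n_rows, k=1)
    best = np.argmax(d[iu])
    selected = [int(iu[0][best]), int(iu[1][best])]
    remaining = [i for i in range(msa.n_rows) if i not in selected]
    while len(selected) < n:
        min_d = d[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(min_d))]
        selected.append(pick)
        remaining.remove(pick)
    return msa.subset(sorted(selected))


@dataclass
class ConservationParams:
    window: int = 3
    window_weight: float = 0.5  # lambda: weight of the window mean
    background: np.ndarray = field(default_factory=lambda: _BLOSUM62_BACKGROUND.copy())
    similar_threshold: float = 0.52  # calibrated on planted synthetic alignments
    nonsyn_max_fraction: float = 0.10
    consensus_pair_min_fraction: float = 0.25
    pseudocount_scale: float = 1.0  # pseudocount = scale / (20 * rows)

    def __post_init__(self):
        if self.window % 2 != 1 or self.window < 1:
            raise ValueError("window must be odd and >= 1")
        if not (0 <= self.window_weight <= 1):
            raise ValueError("window_weight must lie in [0, 1]")
        self.background = np.asarray(self.background, float)
        if self.background.shape != (20,):
            raise ValueError("background must be a 20-vector over the amino acids")
        self.background = self.background / self.background.sum()


def _column_distribution(column: str, params: ConservationParams) -> tuple[np.ndarray, float]:
    """(pseudocounted distribution over the 20 amino acids, non-gap fraction)."""
    n = len(column)
    counts = np.zeros(20)
    n_gap = 0
    for ch in column:
        if ch in GAP_CHARS:
            n_gap += 1
        else:
            idx = AMINO_ACIDS.find(ch)
            if idx >= 0:
                counts[idx] += 1
            # unknown letters (X, B, Z) contribute to neither counts nor gaps
    pseudo = params.pseudocount_scale / (20.0 * n)
    dist = counts + pseudo
    dist = dist / dist.sum()
    return dist, 1.0 - n_gap / n if n else 0.0


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, log base 2, bounded in [0, 1]."""
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def js_divergence_column(column: str, params: Optional[ConservationParams] = None) -> float:
    """Gap-weighted JS divergence of one alignment column vs background."""
    params = params or ConservationParams()
    if not column:
        raise ValueError("empty column")
    if all(ch in GAP_CHARS for ch in column):
        return 0.0
    dist, nongap = _column_distribution(column, params)
    return _jsd(dist, params.background) * nongap


def _consensus(column: str, params: ConservationParams) -> tuple[str, ...]:
    """Most frequent residue; or a similar pair when two residues each pass
    the pair fraction and are BLOSUM62-similar (the A1/A2 notation)."""
    residues = [ch for ch in column if ch not in GAP_CHARS and ch in AMINO_ACIDS]
    if not residues:
        return ()
    vals, counts = np.unique(list(residues), return_counts=True)
    order = np.lexsort((vals, -counts))
    top = vals[order[0]]
    if len(order) > 1:
        second = vals[order[1]]
        f1 = counts[order[0]] / len(residues)
        f2 = counts[order[1]] / len(residues)
        if (
            min(f1, f2) >= params.consensus_pair_min_fraction
            and second != top
            and are_similar(top, second)
        ):
            return (top, second)
    return (top,)


def _nonsyn_fraction(column: str, consensus: tuple[str, ...]) -> float:
    """Fraction of residues scoring <= 0 under BLOSUM62 against the consensus
    (best score against either member when the consensus is a pair)."""
    residues = [ch for ch in column if ch not in GAP_CHARS and ch in AMINO_ACIDS]
    if not residues or not consensus:
        return 0.0
    bad = sum(1 for ch in residues if max(blosum_score(ch, c) for c in consensus) <= 0)
    return bad / len(residues)


@dataclass
class ColumnScore:
    column_index: int
    raw_js: float
    windowed: float
    consensus: tuple[str, ...]
    frac_nonsyn: float
    conserved: bool
    all_gap: bool = False


@dataclass
class ConservationProfile:
    columns: list[ColumnScore]
    params: ConservationParams

    def conserved_columns(self) -> set[int]:
        return {c.column_index for c in self.columns if c.conserved}


def conservation_profile(msa: MSA, params: Optional[ConservationParams] = None) -> ConservationProfile:
    """Score every column; windowed score = (1-l)*column + l*mean(window).

    The window is centered and truncated at the alignment edges. The
    nonsynonymous veto is assessed on the raw column, before smoothing.
    """
    params = params or ConservationParams()
    raw = np.array([js_divergence_column(msa.column(j), params) for j in range(msa.n_cols)])
    half = params.window // 2
    lam = params.window_weight
    scores = []
    for j in range(msa.n_cols):
        lo, hi = max(0, j - half), min(msa.n_cols, j + half + 1)
        windowed = (1 - lam) * raw[j] + lam * raw[lo:hi].mean()
        column = msa.column(j)
        all_gap = all(ch in GAP_CHARS for ch in column)
        cons = _consensus(column, params)
        frac = _nonsyn_fraction(column, cons)
        conserved = (
            not all_gap
            and windowed >= params.similar_threshold
            and frac < params.nonsyn_max_fraction
        )
        scores.append(
            ColumnScore(j, float(raw[j]), float(windowed), cons, frac, conserved, all_gap)
        )
    return ConservationProfile(scores, params)


def tier_columns(
    paralog_profiles: dict[str, ConservationProfile],
    family_profile: Optional[ConservationProfile],
    universal_profile: Optional[ConservationProfile],
    reference_mapping: dict[int, int],
) -> dict[int, str]:
    """Per-reference-residue conservation tier, highest level winning.

    ``reference_mapping`` maps alignment column -> reference author number
    and must be shared by all profiles (they are assumed column-aligned to
    the same reference row). Reference residues at columns absent from the
    mapping are simply not reported (unscored).
    """
    universal = universal_profile.conserved_columns() if universal_profile else set()
    family = family_profile.conserved_columns() if family_profile else set()
    paralog = set()
    for prof in paralog_profiles.values():
        paralog |= prof.conserved_columns()
    tiers = {}
    for col, resnum in reference_mapping.items():
        if col in universal:
            tiers[resnum] = TIER_UNIVERSAL
        elif col in family:
            tiers[resnum] = TIER_FAMILY
        elif col in paralog:
            tiers[resnum] = TIER_PARALOG
        else:
            tiers[resnum] = TIER_NONE
    return tiers
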