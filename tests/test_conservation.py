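"""Alignment I/O, diversity subsampling and conservation scoring."""

import numpy as np
import pytest

from bdspec.conservation import (
    AMINO_ACIDS,
    MSA,
    ConservationParams,
    conservation_profile,
    js_divergence_column,
    maxmin_subsample,
    pairwise_distance_matrix,
    read_msa,
    tier_columns,
    write_msa,
)
from bdspec.errors import AlignmentFormatError
from bdspec.synthetic import MSASpec, make_msa


# --------------------------------------------------------------------------
# I/O


def test_read_write_roundtrip(tmp_path):
    msa = MSA(["a", "b", "c"], ["ACD-E", "ACDFE", "GCD-E"], reference_id="a")
    p = tmp_path / "toy.fasta"
    write_msa(msa, p)
    back = read_msa(p, reference_id="a")
    assert back.ids == msa.ids and back.rows == msa.rows


def test_ragged_and_duplicate_rows_rejected(tmp_path):
    with pytest.raises(AlignmentFormatError, match="ragged"):
        MSA(["a", "b"], ["ACDE", "ACD"])
    p = tmp_path / "dup.fasta"
    p.write_text(">x\nACDE\n>x\nGCDE\n")
    with pytest.raises(AlignmentFormatError, match="duplicate"):
        read_msa(p)


def test_reference_mapping_skips_gaps():
    msa = MSA(["r", "s"], ["A-CD-E", "AACDEE"], reference_id="r")
    mapping = msa.reference_column_numbers(start=100)
    assert mapping == {0: 100, 2: 101, 3: 102, 5: 103}


# --------------------------------------------------------------------------
# distances and diversity subsampling


def test_distance_matrix_basics():
    msa = MSA(["a", "b", "c"], ["AAAAAAAAAA", "AAAAAAAAAA", "CCCAAAAAAA"])
    d = pairwise_distance_matrix(msa)
    assert d[0, 1] == 0.0
    assert d[0, 2] == pytest.approx(0.3)  # 3 mismatches of 10 comparable
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


def test_distance_matrix_matches_brute_force():
    rng = np.random.default_rng(7)
    rows = [
        "".join(rng.choice(list(AMINO_ACIDS + "-"), size=30)) for _ in range(12)
    ]
    msa = MSA([f"s{i}" for i in range(12)], rows)
    d = pairwise_distance_matrix(msa)
    for i in range(12):
        for j in range(12):
            comp = [
                (a, b) for a, b in zip(rows[i], rows[j]) if a != "-" and b != "-"
            ]
            expected = (
                sum(a != b for a, b in comp) / len(comp) if comp else 1.0
            )
            assert d[i, j] == pytest.approx(expected)


def greedy_maxmin_oracle(d, n):
    """Independent re-statement of the greedy rule with the same tie-breaks."""
    N = d.shape[0]
    best_pair, best_val = None, -1.0
    for i in range(N):
        for j in range(i + 1, N):
            if d[i, j] > best_val:
                best_val, best_pair = d[i, j], (i, j)
    selected = list(best_pair)
    while len(selected) < n:
        best_idx, best_min = None, -1.0
        for k in range(N):
            if k in selected:
                continue
            mind = min(d[k, s] for s in selected)
            if mind > best_min:
                best_min, best_idx = mind, k
        selected.append(best_idx)
    return sorted(selected)


def test_maxmin_matches_independent_oracle():
    rng = np.random.default_rng(3)
    rows = ["".join(rng.choice(list(AMINO_ACIDS), size=25)) for _ in range(8)]
    msa = MSA([f"s{i}" for i in range(8)], rows)
    d = pairwise_distance_matrix(msa)
    for n in (2, 4, 6):
        got = maxmin_subsample(msa, n)
        expected = [msa.ids[i] for i in greedy_maxmin_oracle(d, n)]
        assert got.ids == expected


def test_maxmin_trivial_cases():
    msa = MSA(["a", "b", "c"], ["AAAA", "AAAA", "CCCC"])
    assert maxmin_subsample(msa, 3).ids == ["a", "b", "c"]
    picked = maxmin_subsample(msa, 2)
    assert set(picked.rows) == {"AAAA", "CCCC"}  # duplicate row dropped first


def test_maxmin_beats_random_subsets():
    rng = np.random.default_rng(9)
    rows = ["".join(rng.choice(list(AMINO_ACIDS), size=40)) for _ in range(20)]
    msa = MSA([f"s{i}" for i in range(20)], rows)
    d = pairwise_distance_matrix(msa)
    sel = maxmin_subsample(msa, 6)
    idx = [msa.ids.index(s) for s in sel.ids]
    ours = min(d[i, j] for a, i in enumerate(idx) for j in idx[a + 1:])
    wins = 0
    trials = 300
    for _ in range(trials):
        rand = rng.choice(20, size=6, replace=False)
        rmin = min(d[i, j] for a, i in enumerate(rand) for j in rand[a + 1:])
        wins += ours >= rmin
    assert wins / trials >= 0.99


# --------------------------------------------------------------------------
# JS divergence scoring


def js_oracle(column, background, pseudocount_scale=1.0):
    """Direct formula evaluation, independent of the library code paths."""
    n = len(column)
    counts = {aa: 0.0 for aa in AMINO_ACIDS}
    gaps = 0
    for ch in column:
        if ch in "-.":
            gaps += 1
        elif ch in counts:
            counts[ch] += 1
    p = np.array([counts[aa] for aa in AMINO_ACIDS]) + pseudocount_scale / (20 * n)
    p = p / p.sum()
    q = np.asarray(background)
    m = (p + q) / 2
    kl = lambda a, b: float(np.sum(a * np.log2(a / b)))
    return (0.5 * kl(p, m) + 0.5 * kl(q, m)) * (1 - gaps / n)


def test_background_column_scores_zero():
    params = ConservationParams()
    # a column drawn exactly as the background distribution: approximate by
    # passing the background itself through the formula (pseudocounts make a
    # literal column impossible, so check the limiting behavior instead)
    col = "".join(aa * round(f * 1000) for aa, f in zip(AMINO_ACIDS, params.background))
    score = js_divergence_column(col, params)
    assert score < 0.002


def test_invariant_column_matches_hand_formula():
    params = ConservationParams()
    for aa in "AWCK":
        col = aa * 50
        assert js_divergence_column(col, params) == pytest.approx(
            js_oracle(col, params.background), abs=1e-12
        )
    # permuted columns score identically
    col = "AAAAWWWWKK"
    perm = "AWAKWAWKAW"
    assert js_divergence_column(col, params) == pytest.approx(
        js_divergence_column(perm, params)
    )


def test_scores_bounded_and_gap_downweighted():
    params = ConservationParams()
    col = "W" * 40
    full = js_divergence_column(col, params)
    half = js_divergence_column("W" * 20 + "-" * 20, params)
    assert 0 < half < full <= 1.0
    assert half == pytest.approx(
        js_oracle("W" * 20 + "-" * 20, params.background), abs=1e-12
    )
    assert js_divergence_column("-" * 30, params) == 0.0


def test_windowed_equals_raw_at_lambda_zero():
    msa, _ = make_msa(MSASpec(n_cols=30, n_rows=40, seed=2))
    prof = conservation_profile(msa, ConservationParams(window_weight=0.0))
    for c in prof.columns:
        assert c.windowed == pytest.approx(c.raw_js)


def test_nonsynonymous_veto():
    # 15% of residues dissimilar to consensus vetoes the call outright
    col_bad = "A" * 85 + "W" * 15  # BLOSUM62(A, W) = -3
    col_ok = "A" * 92 + "S" * 8  # BLOSUM62(A, S) = 1, conservative
    msa_bad = MSA([f"s{i}" for i in range(100)], [c * 5 for c in col_bad])
    msa_ok = MSA([f"s{i}" for i in range(100)], [c * 5 for c in col_ok])
    prof_bad = conservation_profile(msa_bad)
    prof_ok = conservation_profile(msa_ok)
    assert all(c.frac_nonsyn == pytest.approx(0.15) for c in prof_bad.columns)
    assert not any(c.conserved for c in prof_bad.columns)
    assert all(c.conserved for c in prof_ok.columns)


def test_two_residue_consensus_for_similar_pair():
    col = "I" * 55 + "V" * 45  # I/V similar under BLOSUM62
    msa = MSA([f"s{i}" for i in range(100)], [c * 3 for c in col])
    prof = conservation_profile(msa)
    assert prof.columns[0].consensus == ("I", "V")
    assert prof.columns[0].frac_nonsyn == 0.0


def test_planted_conservation_recovered():
    cols = tuple(range(0, 90, 3))
    msa, conserved = make_msa(
        MSASpec(n_cols=110, n_rows=100, conserved_columns=cols, seed=0)
    )
    prof = conservation_profile(msa)
    called = prof.conserved_columns()
    assert conserved <= called  # sensitivity 1.0
    fpr = len(called - conserved) / (110 - len(conserved))
    assert fpr <= 0.05


def test_tiering_prefers_highest_level():
    # strong background substitution so the toy's unplanted columns cannot be
    # drawn conserved-looking by chance; this test exercises the tier logic
    msa, _ = make_msa(MSASpec(n_cols=12, n_rows=50, conserved_columns=tuple(range(9)),
                              random_rate=0.6, seed=4))
    paralog = conservation_profile(msa)
    msa_f, _ = make_msa(
        MSASpec(master=msa.rows[0], n_rows=50, conserved_columns=tuple(range(6)),
                random_rate=0.6, seed=5)
    )
    family = conservation_profile(msa_f)
    msa_u, _ = make_msa(
        MSASpec(master=msa.rows[0], n_rows=50, conserved_columns=tuple(range(3)),
                random_rate=0.6, seed=6)
    )
    universal = conservation_profile(msa_u)
    mapping = msa.reference_column_numbers(start=1)
    tiers = tier_columns({"paralog": paralog}, family, universal, mapping)
    assert [tiers[i] for i in range(1, 13)] == (
        ["universal"] * 3 + ["family"] * 3 + ["paralog"] * 3 + ["none"] * 3
    )


def test_tiering_without_higher_profiles():
    msa, _ = make_msa(MSASpec(n_cols=8, n_rows=50, conserved_columns=(0, 1), seed=4))
    prof = conservation_profile(msa)
    tiers = tier_columns({"p": prof}, None, None, msa.reference_column_numbers(1))
    assert tiers[1] == "paralog" and tiers[8] == "none"
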