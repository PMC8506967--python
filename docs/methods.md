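# Methods

`bdspec` analyses how a reader domain (the motivating case is a bromodomain,
the ~110-residue module that binds acetylated lysines on histone tails)
achieves sequence-specific recognition of a bound peptide. Specificity in
such systems is rarely explained by the contact residues alone — most of
them are conserved across whole domain families with different binding
profiles — so the pipeline combines three measurements per contact residue:
what it touches (contacts), whether homologous domains position it the same
way (superposition deviations), and at what evolutionary depth it is
conserved (conservation tiers).

## Contact model

A domain residue is a contact residue if either

* **direct contact** — any heavy atom lies within `direct_cutoff` of any
  peptide heavy atom (default 3.0 Å, no atom-type restriction, so both polar
  hydrogen bonds and hydrophobic packing contacts are callable), or
* **water bridge** — a single water oxygen lies within `hbond_cutoff`
  (default 3.5 Å, the conventional heavy-atom hydrogen-bond limit) of at
  least one polar (N/O; optionally S) atom on each side.

The bridge criterion is distance-only: crystal structures of this
resolution rarely include hydrogens, so no donor–acceptor angle term is
applied. Only single-water bridges are considered; two-water chains are out
of scope. Alternate conformations count if *any* conformer satisfies the
distance — a sidechain that contacts the peptide in its 60%-occupancy
rotamer is a contact residue. Hydrogens are flagged at parse time and
ignored by all distance logic. Symmetry mates are never generated: contacts
across crystal-packing interfaces are artifacts for this analysis.

A contact record carries the minimal atom pair, both bridge legs where
applicable, and whether the domain-side atom is backbone (N, CA, C, O) or
sidechain.

## Superposition

Homologous domains are compared all-versus-reference:

1. **Pairing** by global sequence alignment (BLOSUM62, affine gaps open
   −11 / extend −1, via Biopython's `PairwiseAligner`), keeping aligned
   non-gap columns where both residues have a Cα. Sequence-based pairing is
   used rather than structure seeding because the compared domains share the
   fold; the iteration below corrects residual mispairing by pruning.
2. **Kabsch fit** on the paired Cα atoms: SVD of the weighted covariance
   with a determinant correction so the rotation is always proper (no
   reflections). Cα only, using the blank-altloc (else highest-occupancy)
   position.
3. **Iterative pruning**: after each fit every retained pair whose post-fit
   Cα–Cα distance exceeds `prune_cutoff` (default 2.0 Å) is dropped and the
   fit repeated, to a fixed point (`max_iterations` 50, `min_retained_pairs`
   3 or the run aborts as diverged). Batch pruning — all offenders per
   iteration — is the default for determinism and speed; a one-at-a-time
   mode (`prune_mode="worst"`) exists for borderline cases. The retained set
   only ever shrinks, which guarantees termination but means residues
   dropped early (e.g. by lever-arm distortion of the initial fit) are not
   readmitted; the reported rmsd is therefore conservative about which pairs
   it covers, and `n_retained`/`n_total` are always reported beside it.

The result carries the rigid transform, the rmsd over retained pairs, and a
**deviation profile** for *all* pairs (pruned ones included) in reference
numbering, so flexible-loop excursions remain visible. The
contact-deviation summary restricts the profile to the contact residues;
unpaired contact residues are reported as missing (never as zero), and
positions where the compared domain substitutes a different amino acid are
flagged — the classic example being a Glu→Arg swap at the acidic position
that binds the peptide's arginine.

Bound peptides are compared separately with a plain (unpruned) Kabsch fit
over a residue-number range, pairing by author number, since histone-tail
peptides are numbered by histone position in every structure.

## Conservation

Ortholog alignments are consumed as aligned FASTA (ortholog retrieval and
alignment are upstream of this package). Oversized alignments are reduced
to the *n* most diverse sequences by greedy maxmin selection on normalized
mismatch distance (mismatches / columns where both rows are ungapped):
seed with the globally most distant pair, then repeatedly add the row with
the largest minimum distance to the selection, ties broken toward the
earliest input index. Greedy maxmin is deterministic and directly encodes
"most diverse"; it is not claimed to be the optimum of the NP-hard maxmin
dispersion problem.

Each column is scored with the Jensen–Shannon divergence (log base 2, hence
bounded in [0, 1]) between the column's amino-acid distribution and the
BLOSUM62 background frequencies. Column distributions receive a pseudocount
of `1/(20·rows)` per residue; the score is multiplied by the column's
non-gap fraction. Scores are smoothed with a centered moving window
(default 3 columns, truncated at the edges):

    windowed = (1 − λ)·column + λ·mean(window),   λ = 0.5 by default

A column is called **conserved** when the windowed score reaches
`similar_threshold` *and* fewer than `nonsyn_max_fraction` (default 10%) of
its residues are nonsynonymous, where nonsynonymous means BLOSUM62 score
≤ 0 against the column consensus. The veto is assessed on the raw column,
before smoothing. The consensus is the most frequent residue, or a similar
pair (rendered `X1/X2`) when the top two residues each reach 25% of the
column and are mutually BLOSUM62-positive.

**Threshold calibration.** `similar_threshold` defaults to 0.52. It was
calibrated once on the planted synthetic alignment the generator defines as
standard (100 rows × 110 columns; 30 planted conserved columns, half
literally invariant and half substituting within BLOSUM62-positive neighbor
sets at 5%; all other columns substituting uniformly at 20%): across seeds
0–49 the threshold gives sensitivity 1.0 at every seed with a comfortable
margin (the lowest windowed score of any planted column was 0.60). The
false-positive rate is dominated not by the threshold but by background
columns whose realized substitutions happen to be few and conservative —
such columns are genuinely indistinguishable from conserved ones in the
data — and lands at or below 0.05 for 48 of those 50 seeds (mean ≈ 2 false
calls of 80 negatives). Literature-reported thresholds for conservation
scores on other scales do not transfer to the [0, 1] JS scale, so the
threshold is exposed as a first-class parameter.

**Tiers.** Conservation calls from nested sequence sets — one paralog's
orthologs, the domain family, all domains — are combined per reference
residue, the highest applicable level winning: `universal` > `family` >
`paralog` > `none`. Reference residues come from the alignment's reference
row: its ungapped positions map one-to-one onto author residue numbers from
a configured starting number.

## Classification and pipeline

`build_classification` joins the three streams into one row per contact
residue: contact kinds, backbone/sidechain side, peptide partners,
conservation tier (`unscored` when no alignment covers the residue), and
per-comparison deviation plus substitution flag. `run_pipeline` drives
everything from one YAML config and writes `classification.csv`, one
deviation profile CSV per comparison, a monospace annotated alignment
(reference row with ruler, consensus, contact-arrow and tier lanes), and a
run log with one line per stage recording parameters and input SHA-256
checksums. Outputs are deterministic for fixed inputs; any stage failure
removes partial outputs and raises a stage-named error (CLI exit code 3;
config errors exit 2).

## Synthetic data

The generators produce every input class with exact, machine-checkable
ground truth; all are pure functions of their spec (which includes the
seed), so repeated calls are byte-identical.

* **Complexes** (`make_complex`): domain and peptide chains of sparse toy
  residues with correct atom naming (N, CA, C, O, CB), 10 Å along-chain
  spacing and 25 Å chain separation so no unplanned pair can approach the
  cutoffs. Planted direct contacts place a domain sidechain atom at the
  stated distance from a peptide Cα (several plants on one residue use
  successive sidechain atom names); planted bridges position a water oxygen
  with the stated leg distances between a domain oxygen and a peptide
  nitrogen, with legs constrained so no incidental direct contact arises.
  Decoy waters are sampled outside an exclusion shell (default 4.5 Å) from
  every chain atom. Each planted interaction must target a distinct peptide
  residue. These objects exercise the distance logic exactly; they are not
  stereochemically realistic proteins, which the contact logic never
  requires.
* **Families** (`make_family`): a base domain with a compact coiled Cα
  trace (a helix bent around a circle, ~40 Å extent for 100 residues —
  globular like a real domain, so rigid-fit errors are not amplified by a
  rod-like lever arm), random sequence, full toy residues. Members apply
  per-atom Gaussian noise (σ, Å), then an optional segment displacement,
  then a recorded uniform-random rigid transform; planted sequence
  substitutions rename residues. The recorded transforms are exact ground
  truth for recovery tests.
* **Alignments** (`make_msa`): row 0 is the ungapped master/reference;
  planted conserved columns are invariant or substitute only within
  BLOSUM62-positive neighbor sets at a stated rate (default 5%); background
  columns substitute uniformly at a stated rate (default 20%); optional
  per-column gap injection.

What passing on synthetic data does *not* show: real crystal structures
have correlated coordinate error, partial occupancy, chain breaks and
non-ideal stoichiometry; real ortholog alignments have phylogenetic
correlation between rows (the generator draws rows independently), indels,
and database biases. Tests on generated data validate the algorithms'
correctness and calibration under the stated models, not performance on any
particular deposited entry — the deposited-structure checks exist for that
and run whenever the user supplies the coordinate files (`data/pdb/`).

## Numerical choices and degenerate inputs

* Kabsch requires ≥ 3 non-collinear points; rank-deficient covariance (all
  points collinear) raises rather than returning an arbitrary rotation.
* Torsions follow the IUPAC convention (cis = 0°, range (−180°, 180°]),
  validated against three independent implementations; torsion values are
  invariant under full atom-order reversal and negate under mirror
  reflection. Collinear mid-bond geometry raises an undefined-dihedral
  error. Chi-1 uses N–CA–CB–γ with the γ atom name resolved per residue
  type (OG/OG1/SG/CG1/CG); Gly/Ala have no chi-1.
* Minimum heavy-atom distances break ties by atom-name order, so results do
  not depend on file atom order.
* All-gap alignment columns score 0 and are flagged; sequence pairs with no
  comparable columns get distance 1 with a warning.
* Problem sizes in the test-suite and the acceptance script (100-instance
  oracle comparisons, 50 planted complexes, 100 family runs, one standard
  110-column alignment, 1000 random-subset trials) were chosen as the
  smallest sizes at which the binomial success criteria (≥95%, ≥99%) are
  meaningful.

## Known limitations

* Batch pruning cannot readmit pairs; rmsd values are comparable between
  runs of this tool but not bit-identical to tools with different pruning
  schedules (hence count-based anchors carry explicit ± tolerances).
* The water-bridge criterion has no angular term and will accept geometry a
  hydrogen-bond-aware method would reject.
* Conservation scoring treats alignment rows as independent; no
  phylogenetic weighting is applied.
* The first model of a multi-model file is used, with a warning; assemblies
  and symmetry mates are never generated.
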