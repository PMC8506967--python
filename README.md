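# bdspec

Structural and evolutionary specificity analysis of domain–peptide
recognition, built around the question of how acetyl-lysine reader modules
(bromodomains) recognize their acetylated histone-tail targets — e.g.
H3K14ac, whose local motif G13-K14ac-A15-P16-R17 is read by SWI/SNF-family
bromodomains. The residues a domain places within hydrogen-bonding distance
of such a peptide are largely shared across whole domain families with
different binding profiles, so contact lists alone do not explain
specificity. `bdspec` is for structural bioinformaticians who want to take
a domain–peptide complex plus homologous structures and ortholog alignments
and ask, residue by residue: what does it contact, is it positioned the
same way in related domains, and how deep does its conservation run?

## What it computes

* **Contact residues** — domain residues with any heavy atom within 3.0 Å
  of the peptide, plus residues linked through a single bridging water
  (water O within 3.5 Å of a polar atom on each side). Records carry the
  minimal atom pair, bridge legs, and backbone/sidechain annotation.
* **Pruned superposition** — Cα pairing by global sequence alignment
  (BLOSUM62, affine gaps), then an iterated Kabsch fit

      R, t = argmin Σᵢ wᵢ ‖R xᵢ + t − yᵢ‖²   (proper rotation, SVD with
                                               determinant correction)

  dropping pairs with post-fit deviation > 2.0 Å and refitting to a fixed
  point. Reports rmsd over retained pairs, retained/total counts, and a
  per-residue deviation profile in reference numbering, with substitution
  flags at contact positions.
* **Conservation tiers** — per-column Jensen–Shannon divergence (log base
  2, bounded in [0, 1]) between the column's amino-acid distribution and
  the BLOSUM62 background, smoothed over a 3-column window; a column is
  conserved when the windowed score ≥ threshold (default 0.52, calibrated —
  see `docs/methods.md`) and < 10% of its residues are nonsynonymous
  (BLOSUM62 ≤ 0 vs consensus). Oversized alignments are first reduced to
  the *n* most diverse rows by greedy maxmin selection. Calls from
  paralog / family / universal alignments combine into per-residue tiers.
* **Classification report** — one row per contact residue joining all three
  streams, plus an annotated alignment rendering and per-comparison
  deviation profiles, driven by a single YAML config.
* **Synthetic data** — seeded generators for toy complexes with planted
  contacts and water bridges, structure families with recorded rigid
  transforms and displaced segments, and ortholog alignments with planted
  conserved columns. Every generator emits exact ground truth, which is how
  the pipeline is tested end to end.

## Worked example

Generate a toy complex with known planted interactions, then call contacts
on it:

```
$ bdspec simulate complex --seed 1 --out sim
sim
$ bdspec contacts --structure sim/complex.pdb --bd-chain A --peptide-chain B --out contacts.tsv
2 direct, 1 water bridges, 3 contact residues -> contacts.tsv
$ cat contacts.tsv
bd_chain  bd_resnum  bd_resname  kind          pep_resnum  pep_resname  distance  atoms             bd_side
A         3          SER         direct        2           THR          2.8       CB..CA            sidechain
A         5          ALA         direct        4           HIS          2.9       CB..CA            sidechain
A         7          THR         water_bridge  6           LEU          2.8       O..N via HOH1000  backbone
```

Domain residues 3 and 5 touch the peptide directly at the planted 2.8 and
2.9 Å separations (sidechain atoms, within the 3.0 Å cutoff); residue 7 is
linked to peptide residue 6 through water 1000, both legs at 2.8 Å, via its
backbone carbonyl oxygen. The sidecar `sim/ground_truth.json` lists exactly
these three interactions — recovery is exact by construction when planted
distances sit clear of the cutoffs.

The same calls work on real files: point `--structure` at a deposited
domain–peptide complex in PDB or mmCIF format and name its chains. The full
pipeline (contacts + superpositions + conservation + classification) runs
from one config:

```
bdspec run --config config.yaml
```

producing `classification.csv` (one row per contact residue with kinds,
peptide partners, tier, and per-comparison deviation/substitution columns),
`profile_<id>.csv` per comparison structure, `annotated_alignment.txt`, and
a `run.log` with parameters and input checksums. See
`tests/test_classify.py::_write_pipeline_fixture` for a complete config.

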