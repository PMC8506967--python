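# Deposited coordinate files (user-supplied)

The acceptance checks against deposited crystal structures look for
coordinate files in this directory. The files are not distributed with the
package; download them from the PDB (https://www.rcsb.org) and place them
here under these names:

| file | content |
| --- | --- |
| `7LHY.pdb` | CeSMARCA4 bromodomain bound to the H3(7-20)K14ac peptide (reference complex) |
| `2GRC.pdb` | HsSMARCA4 apo bromodomain (ortholog comparison) |
| `BAZ2B_complex.pdb` | BAZ2B bromodomain-H3K14ac complex (family V comparison) |
| `ASH1L.pdb` | ASH1L bromodomain (non-binding comparison) |

mmCIF files with the same stems (`.cif`) are accepted too. Without these
files the corresponding tests in `tests/test_acceptance.py` fail with a
message pointing here; every other test runs on generated data.
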