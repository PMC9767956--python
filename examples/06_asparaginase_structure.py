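"""Surface classification of the E. coli asparaginase homotetramer.

Runs the designability pipeline on a real crystal structure.  Download
the PDB entry 3ECA (wild-type E. coli type II asparaginase, four chains
of 326 residues) and pass its path:

    python examples/06_asparaginase_structure.py 3eca.pdb

Expected: 78 of the 326 monomer positions classified surface exposed
(RSASA > 50%, most-exposed chain copy); the designable count then
follows from the active-site and interface exclusion radii.
"""

import sys

from resurf.config import ECOLI_ASN_ACTIVE_SITE
from resurf.sasa import designable_mask, relative_sasa, shrake_rupley_sasa
from resurf.structure import chain_sequence, read_structure

if len(sys.argv) != 2:
    sys.exit("usage: python examples/06_asparaginase_structure.py <3eca.pdb>")

model = read_structure(sys.argv[1])
print(f"chains: {model.chains}, residues/chain: "
      f"{len(chain_sequence(model, model.chains[0]))}")

sasa = shrake_rupley_sasa(model, probe_radius=1.4, n_points=960)
rsasa = relative_sasa(sasa, model)
mask = designable_mask(model, rsasa, ECOLI_ASN_ACTIVE_SITE)
for k, v in mask.summary().items():
    print(f"{k:>24s}: {v}")
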