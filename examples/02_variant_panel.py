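"""Propose re-surfaced variants and select a maximally diverse panel.

Proposes candidates mutated only at designable positions (surrogate
substitution scorer biased to polar/charged surface residues), profiles
their mutational distance, and picks a diverse panel by greedy max-min
Hamming distance.
"""

from resurf.simulate import ToyAssemblySpec, make_toy_tetramer
from resurf.variants import (
    mutation_profile,
    propose_candidates,
    select_diverse_subset,
    validate_variant,
)

spec = ToyAssemblySpec(seed=1)
model, mask, _ = make_toy_tetramer(spec)
wt = "G" * mask.monomer_length

pool = propose_candidates(wt, mask, n_candidates=20,
                          mutation_range=(1, 3), rng_seed=7)
print(f"proposed {len(pool)} candidates, all mask-compliant:",
      all(validate_variant(wt, v, mask) == [] for v in pool))

panel = select_diverse_subset(pool, k=4, wt=wt,
                              positions=mask.designable_positions())
print("\nselected panel (mutations, % of monomer, % of surface):")
for v in panel:
    p = mutation_profile(wt, v, mask)
    print(f"  {v.id:>8s}  n={p.n_mutations_total}  total={p.pct_total}%  "
          f"surface={p.pct_surface}%")
# The panel spreads mutation positions apart so each member probes a
# different patch of the designable surface.
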