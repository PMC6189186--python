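"""Clone sizes and seeding expectations under the branching model.

Builds the default 37-generation lineage and prints, for a few seeding
generations, the size of the resulting mutant region and the expected number
of such regions for an individual at a given mutation rate.
"""

from brainmosaic.lineage_model import (LineageParams, expected_seed_count,
                                       max_detectable_depth,
                                       prob_at_least_one_region,
                                       region_fraction)

params = LineageParams()            # 37 divisions, no cell death
rate = 1.2e-9                       # mutations per base per division
n_sites = 148                       # effective pathogenic bases

print(f"final brain: {params.final_cells:.3g} cells "
      f"({params.final_neurons:.3g} neurons)")
print(f"{'gen i':>5} {'region cells':>14} {'E[regions]':>11} {'P(>=1)':>8}")
for i in (10, 19, 25, 30):
    cells = region_fraction(i, params) * params.final_cells
    mean = expected_seed_count(rate, n_sites, i, params)
    p = prob_at_least_one_region(rate, n_sites, i, params)
    print(f"{i:>5} {cells:>14.4g} {mean:>11.4g} {p:>8.3g}")

d = max_detectable_depth(0.005)
print(f"\nat a 0.5% VAF floor, clones up to {d} generations below the "
      f"sampled block root are detectable (VAF {2 ** -(d + 1):.2%})")

# A generation-19 clone is the 2.62e5-cell region size; generation 30 gives
# the 128-cell regions.  E[regions] grows ~2x per generation while the
# region size halves, so late generations dominate the region count and
# early generations dominate the mutated-cell burden.
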